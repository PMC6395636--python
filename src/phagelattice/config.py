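"""Configuration objects, the two plain-text input files, and output writers.

A run is described by two text files: a *general-parameter* file (flat
``key = value`` lines covering the lattice, the schedule, the antibiotic
field and the mortality model) and an *ecological-setup* file (sections for
each bacterial and phage species plus whitespace-delimited host-range and
superinfection matrix blocks).  The grammar is this package's own; see the
README for a worked example.

Unknown keys are hard errors — a misspelled parameter must never silently
fall back to a default.  Every default that is actually used is echoed to
the ``phagelattice`` logger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .agents import BacterialSpecies, PhageSpecies, Prophage, SpeciesRegistry
from .engine import InoculumEntry, ScheduleConfig, Trajectory
from .errors import ValidationError
from .infection import LYSOGENY_PRESETS, KillModel, LysogenyCurve
from .lattice import AntibioticField, DeploymentMode, LatticeConfig

logger = logging.getLogger("phagelattice")


@dataclass
class GeneralParams:
    """All scalar run parameters (lattice + schedule + antibiotic + mortality)."""

    # lattice
    width: int = 100
    height: int = 100
    topology: str = "bounded"
    structure: str = "well_mixed"
    reproduction_radius: int = 3
    phage_diffusion_radius: int = 3
    phage_cap_per_location: int = 100
    # schedule
    n_iterations: int = 100
    antibiotic_application_iteration: Optional[int] = None
    repeat_doses_every: Optional[int] = None
    # antibiotic field
    antibiotic_deployment: str = "homogeneous"
    antibiotic_dose: float = 0.0
    antibiotic_n_foci: int = 1
    antibiotic_degradation_rate: float = 0.01
    antibiotic_diffusion_fraction: float = 0.25
    # mortality
    basal_death_prob: float = 0.05
    antibiotic_kill_prob: float = 0.95
    mic_threshold: float = 1.0
    # output
    snapshot_every: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        self.lattice_config()
        self.kill_model()
        DeploymentMode(self.antibiotic_deployment)
        if self.antibiotic_dose < 0:
            raise ValidationError("antibiotic_dose must be >= 0")
        if self.snapshot_every < 0:
            raise ValidationError("snapshot_every must be >= 0")
        # schedule consistency (inoculum-independent part)
        ScheduleConfig(
            n_iterations=self.n_iterations,
            antibiotic_application_iteration=self.antibiotic_application_iteration,
            repeat_doses_every=self.repeat_doses_every,
        )

    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(
            width=self.width,
            height=self.height,
            topology=self.topology,
            structure=self.structure,
            reproduction_radius=self.reproduction_radius,
            phage_diffusion_radius=self.phage_diffusion_radius,
            phage_cap_per_location=self.phage_cap_per_location,
        )

    def kill_model(self) -> KillModel:
        return KillModel(
            basal_death_prob=self.basal_death_prob,
            antibiotic_kill_prob=self.antibiotic_kill_prob,
            mic_threshold=self.mic_threshold,
        )

    def antibiotic_template(self, config: LatticeConfig) -> AntibioticField:
        return AntibioticField.zeros(
            config,
            degradation_rate=self.antibiotic_degradation_rate,
            diffusion_fraction=self.antibiotic_diffusion_fraction,
            deployment_mode=self.antibiotic_deployment,
            n_foci=self.antibiotic_n_foci,
            dose=self.antibiotic_dose,
        )

    def schedule_config(self, inoculum: list[InoculumEntry]) -> ScheduleConfig:
        return ScheduleConfig(
            n_iterations=self.n_iterations,
            antibiotic_application_iteration=self.antibiotic_application_iteration,
            repeat_doses_every=self.repeat_doses_every,
            inoculum=inoculum,
        )


@dataclass
class BacteriumSetup:
    species: BacterialSpecies
    initial_count: int = 0
    # (phage species name, attachment phenotype) carried by every founder cell
    initial_prophages: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class PhageSetup:
    species: PhageSpecies
    initial_count: int = 0
    initial_phenotype: Optional[str] = None


@dataclass
class EcoSetup:
    """Species lists, matrices and inocula — the ecological half of a run."""

    bacteria: list[BacteriumSetup] = field(default_factory=list)
    phages: list[PhageSetup] = field(default_factory=list)
    host_range: dict[tuple[str, str], float] = field(default_factory=dict)
    superinfection: dict[tuple[str, str], float] = field(default_factory=dict)

    def build_registry(self) -> SpeciesRegistry:
        registry = SpeciesRegistry(
            [b.species for b in self.bacteria],
            [p.species for p in self.phages],
            self.host_range,
            self.superinfection,
        )
        for b in self.bacteria:
            for sp_name, phenotype in b.initial_prophages:
                phage = registry.get_phage(sp_name)
                if phenotype not in phage.attachment_phenotypes:
                    raise ValidationError(
                        f"initial prophage {sp_name}:{phenotype} uses a phenotype "
                        f"unknown to phage {sp_name!r}"
                    )
        for p in self.phages:
            if (
                p.initial_phenotype is not None
                and p.initial_phenotype not in p.species.attachment_phenotypes
            ):
                raise ValidationError(
                    f"initial_phenotype {p.initial_phenotype!r} unknown to phage "
                    f"{p.species.name!r}"
                )
        return registry

    def inoculum_entries(self) -> list[InoculumEntry]:
        registry = self.build_registry()
        entries: list[InoculumEntry] = []
        for b in self.bacteria:
            prophages = [
                Prophage(registry.get_phage(sp), ph) for sp, ph in b.initial_prophages
            ]
            entries.append(
                InoculumEntry(
                    "bacterium", b.species.name, b.initial_count,
                    initial_prophages=prophages,
                )
            )
        for p in self.phages:
            entries.append(
                InoculumEntry(
                    "phage", p.species.name, p.initial_count,
                    phenotype=p.initial_phenotype,
                )
            )
        return entries


# ---------------------------------------------------------------------------
# Text-file parsing
# ---------------------------------------------------------------------------

_NONE_TOKENS = {"none", "null", ""}


def _convert(raw: str, kind: str, key: str):
    raw = raw.strip()
    try:
        if kind == "int":
            return int(raw)
        if kind == "float":
            return float(raw)
        if kind == "opt_int":
            return None if raw.lower() in _NONE_TOKENS else int(raw)
        if kind == "bool":
            if raw.lower() in ("true", "yes", "1"):
                return True
            if raw.lower() in ("false", "no", "0"):
                return False
            raise ValueError(raw)
        if kind == "str":
            return raw
    except ValueError as exc:
        raise ValidationError(f"cannot parse {key} = {raw!r} as {kind}") from exc
    raise AssertionError(kind)


_GENERAL_TYPES = {
    "width": "int",
    "height": "int",
    "topology": "str",
    "structure": "str",
    "reproduction_radius": "int",
    "phage_diffusion_radius": "int",
    "phage_cap_per_location": "int",
    "n_iterations": "int",
    "antibiotic_application_iteration": "opt_int",
    "repeat_doses_every": "opt_int",
    "antibiotic_deployment": "str",
    "antibiotic_dose": "float",
    "antibiotic_n_foci": "int",
    "antibiotic_degradation_rate": "float",
    "antibiotic_diffusion_fraction": "float",
    "basal_death_prob": "float",
    "antibiotic_kill_prob": "float",
    "mic_threshold": "float",
    "snapshot_every": "int",
}

_BACTERIUM_TYPES = {
    "initial_count": "int",
    "base_growth_rate": "float",
    "intrinsic_death_prob": "float",
    "antibiotic_resistant": "bool",
    "phage_resistance_profile": "str",
    "cost_antibiotic_resistance": "float",
    "cost_phage_resistance": "float",
    "mu_antibiotic": "float",
    "mu_phage_receptor": "float",
    "initial_prophages": "str",
}

_PHAGE_TYPES = {
    "lifestyle": "str",
    "attachment_phenotypes": "str",
    "initial_count": "int",
    "initial_phenotype": "str",
    "burst_size": "int",
    "adsorption_prob": "float",
    "decay_prob": "float",
    "mu_attachment": "float",
    "induction_prob": "float",
    "stress_induction_factor": "float",
    "lysogeny_curve": "str",
}


def _split_list(raw: str) -> list[str]:
    return [tok for tok in raw.replace(",", " ").split() if tok and tok != "-"]


def _parse_kv_block(lines: list[str], types: dict, context: str) -> dict:
    out = {}
    for line in lines:
        if "=" not in line:
            raise ValidationError(f"{context}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in types:
            raise ValidationError(f"{context}: unknown key {key!r}")
        if key in out:
            raise ValidationError(f"{context}: duplicate key {key!r}")
        out[key] = _convert(raw, types[key], key)
    return out


def _clean_lines(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def parse_general_text(text: str) -> GeneralParams:
    values = _parse_kv_block(_clean_lines(text), _GENERAL_TYPES, "general parameters")
    defaults = {
        f.name: f.default for f in dataclasses.fields(GeneralParams) if f.name not in values
    }
    for key, val in sorted(defaults.items()):
        logger.info("general parameter %s not set; using default %r", key, val)
    return GeneralParams(**values)


def _resolve_lysogeny(raw: str) -> LysogenyCurve:
    if raw in LYSOGENY_PRESETS:
        return LYSOGENY_PRESETS[raw]
    parts = raw.split(",")
    if len(parts) == 3:
        try:
            return LysogenyCurve(float(parts[0]), float(parts[1]), float(parts[2]))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"invalid lysogeny curve spec {raw!r}") from exc
    raise ValidationError(
        f"lysogeny_curve {raw!r} is neither a preset ({', '.join(LYSOGENY_PRESETS)}) "
        "nor 'p_max,half_density,hill_exponent'"
    )


def _parse_matrix_block(
    lines: list[str], context: str
) -> tuple[list[str], dict[str, list[float]]]:
    if not lines or not lines[0].startswith("columns"):
        raise ValidationError(f"{context}: first line must be 'columns = <labels>'")
    _, _, raw = lines[0].partition("=")
    columns = _split_list(raw)
    if not columns:
        raise ValidationError(f"{context}: no column labels")
    rows: dict[str, list[float]] = {}
    for line in lines[1:]:
        toks = line.split()
        label = toks[0]
        if label in rows:
            raise ValidationError(f"{context}: duplicate row {label!r}")
        if len(toks) - 1 != len(columns):
            raise ValidationError(
                f"{context}: row {label!r} has {len(toks) - 1} entries, expected {len(columns)}"
            )
        try:
            rows[label] = [float(t) for t in toks[1:]]
        except ValueError as exc:
            raise ValidationError(f"{context}: non-numeric entry in row {label!r}") from exc
    return columns, rows


def parse_eco_text(text: str) -> EcoSetup:
    lines = _clean_lines(text)
    sections: list[tuple[str, list[str]]] = []
    current: Optional[list[str]] = None
    for line in lines:
        if line.startswith("[") and line.endswith("]"):
            current = []
            sections.append((line[1:-1].strip(), current))
        elif current is None:
            raise ValidationError(f"content before any [section] header: {line!r}")
        else:
            current.append(line)

    bacteria: list[BacteriumSetup] = []
    phages: list[PhageSetup] = []
    host_range: dict[tuple[str, str], float] = {}
    superinfection: dict[tuple[str, str], float] = {}
    seen_matrix = set()
    for header, body in sections:
        parts = header.split()
        if parts[0] == "bacterium":
            if len(parts) != 2:
                raise ValidationError(f"section [{header}]: expected '[bacterium NAME]'")
            name = parts[1]
            vals = _parse_kv_block(body, _BACTERIUM_TYPES, f"[bacterium {name}]")
            profile = frozenset(_split_list(vals.pop("phage_resistance_profile", "")))
            count = vals.pop("initial_count", 0)
            pro_raw = vals.pop("initial_prophages", "")
            prophages = []
            for item in _split_list(pro_raw):
                if ":" not in item:
                    raise ValidationError(
                        f"[bacterium {name}]: initial_prophages entries must be "
                        f"'phage:phenotype', got {item!r}"
                    )
                sp, ph = item.split(":", 1)
                prophages.append((sp, ph))
            species = BacterialSpecies(name=name, phage_resistance_profile=profile, **vals)
            bacteria.append(BacteriumSetup(species, count, prophages))
        elif parts[0] == "phage":
            if len(parts) != 2:
                raise ValidationError(f"section [{header}]: expected '[phage NAME]'")
            name = parts[1]
            vals = _parse_kv_block(body, _PHAGE_TYPES, f"[phage {name}]")
            phenotypes = tuple(_split_list(vals.pop("attachment_phenotypes", "")))
            count = vals.pop("initial_count", 0)
            initial_phenotype = vals.pop("initial_phenotype", None)
            curve_raw = vals.pop("lysogeny_curve", None)
            curve = _resolve_lysogeny(curve_raw) if curve_raw is not None else None
            species = PhageSpecies(
                name=name,
                attachment_phenotypes=phenotypes,
                lysogeny_curve=curve,
                **vals,
            )
            phages.append(PhageSetup(species, count, initial_phenotype))
        elif parts[0] == "host_range":
            seen_matrix.add("host_range")
            columns, rows = _parse_matrix_block(body, "[host_range]")
            for ph, vals in rows.items():
                for sp, v in zip(columns, vals):
                    if not 0.0 <= v <= 1.0:
                        raise ValidationError(
                            f"host_range[{ph!r}, {sp!r}] = {v} outside [0, 1]"
                        )
                    host_range[(ph, sp)] = v
        elif parts[0] == "superinfection":
            seen_matrix.add("superinfection")
            columns, rows = _parse_matrix_block(body, "[superinfection]")
            for inc, vals in rows.items():
                for res, v in zip(columns, vals):
                    if not 0.0 <= v <= 1.0:
                        raise ValidationError(
                            f"superinfection[{inc!r}, {res!r}] = {v} outside [0, 1]"
                        )
                    superinfection[(inc, res)] = v
        else:
            raise ValidationError(f"unknown section [{header}]")

    setup = EcoSetup(bacteria, phages, host_range, superinfection)
    setup.build_registry()  # full referential / range validation
    return setup


def parse_configs(general_path, eco_path) -> tuple[GeneralParams, EcoSetup]:
    """Parse and validate the two input files of a run."""
    general_path, eco_path = Path(general_path), Path(eco_path)
    general = parse_general_text(general_path.read_text())
    eco = parse_eco_text(eco_path.read_text())
    return general, eco


# ---------------------------------------------------------------------------
# Serialization (round-trip with the parsers above)
# ---------------------------------------------------------------------------


def serialize_general(params: GeneralParams) -> str:
    lines = ["# general parameters"]
    for f in dataclasses.fields(GeneralParams):
        value = getattr(params, f.name)
        lines.append(f"{f.name} = {'none' if value is None else value}")
    return "\n".join(lines) + "\n"


def serialize_eco(eco: EcoSetup) -> str:
    lines = ["# ecological setup"]
    for b in eco.bacteria:
        s = b.species
        lines += [
            f"[bacterium {s.name}]",
            f"initial_count = {b.initial_count}",
            f"base_growth_rate = {s.base_growth_rate}",
            f"intrinsic_death_prob = {s.intrinsic_death_prob}",
            f"antibiotic_resistant = {str(s.antibiotic_resistant).lower()}",
            f"phage_resistance_profile = {' '.join(sorted(s.phage_resistance_profile)) or '-'}",
            f"cost_antibiotic_resistance = {s.cost_antibiotic_resistance}",
            f"cost_phage_resistance = {s.cost_phage_resistance}",
            f"mu_antibiotic = {s.mu_antibiotic}",
            f"mu_phage_receptor = {s.mu_phage_receptor}",
            f"initial_prophages = {' '.join(f'{a}:{b_}' for a, b_ in b.initial_prophages) or '-'}",
        ]
    for p in eco.phages:
        s = p.species
        lines += [
            f"[phage {s.name}]",
            f"lifestyle = {s.lifestyle.value}",
            f"attachment_phenotypes = {' '.join(s.attachment_phenotypes)}",
            f"initial_count = {p.initial_count}",
            f"burst_size = {s.burst_size}",
            f"adsorption_prob = {s.adsorption_prob}",
            f"decay_prob = {s.decay_prob}",
            f"mu_attachment = {s.mu_attachment}",
            f"induction_prob = {s.induction_prob}",
            f"stress_induction_factor = {s.stress_induction_factor}",
        ]
        if p.initial_phenotype is not None:
            lines.append(f"initial_phenotype = {p.initial_phenotype}")
        curve = s.lysogeny_curve
        if curve is not None:
            if curve.preset_name in LYSOGENY_PRESETS:
                lines.append(f"lysogeny_curve = {curve.preset_name}")
            else:
                lines.append(
                    f"lysogeny_curve = {curve.p_max},{curve.half_density},{curve.hill_exponent}"
                )
    phenotypes = sorted({ph for ph, _ in eco.host_range})
    species_names = sorted({sp for _, sp in eco.host_range})
    if phenotypes:
        lines.append("[host_range]")
        lines.append(f"columns = {' '.join(species_names)}")
        for ph in phenotypes:
            row = " ".join(str(eco.host_range[(ph, sp)]) for sp in species_names)
            lines.append(f"{ph} {row}")
    incoming = sorted({a for a, _ in eco.superinfection})
    residents = sorted({b for _, b in eco.superinfection})
    if incoming:
        lines.append("[superinfection]")
        lines.append(f"columns = {' '.join(residents)}")
        for inc in incoming:
            row = " ".join(str(eco.superinfection.get((inc, res), 0.0)) for res in residents)
            lines.append(f"{inc} {row}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trajectory and snapshot output
# ---------------------------------------------------------------------------


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as delimited text (CSV with a JSON meta header)."""
    path = Path(path)
    frame = trajectory.to_frame()
    with open(path, "w") as fh:
        fh.write("# meta " + json.dumps(trajectory.meta, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("# meta "):
            meta = json.loads(first[len("# meta ") :])
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    return Trajectory.from_frame(frame, meta=meta)


def write_snapshots(trajectory: Trajectory, path) -> None:
    """Lattice snapshots as TSV: iteration, x, y, layer, label-or-concentration."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("iteration\tx\ty\tlayer\tvalue\n")
        for row in trajectory.snapshots:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_run_metadata(params: GeneralParams, eco: EcoSetup, seed: int, path) -> None:
    """Full resolved configuration + seed, for reproducibility records."""
    import platform

    import numpy
    import scipy

    from . import __version__

    path = Path(path)
    text = (
        f"# phagelattice {__version__} | python {platform.python_version()} "
        f"| numpy {numpy.__version__} | scipy {scipy.__version__}\n"
        f"# seed = {seed}\n\n"
        + serialize_general(params)
        + "\n"
        + serialize_eco(eco)
    )
    path.write_text(text)
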