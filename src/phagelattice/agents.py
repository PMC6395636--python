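"""Species definitions, individual bacterial and phage state, interaction
matrices, fitness and mutation.

Genomes are represented minimally: a bacterium is its species reference plus
phenotype flags (antibiotic resistance, the set of phage attachment
phenotypes it resists) and the list of prophages it carries.  Resistance is
costly and the costs compose multiplicatively, so fitness stays nonnegative
and is independent of the order in which resistances were acquired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

from .errors import RegistryError, ValidationError

if TYPE_CHECKING:  # avoid a runtime cycle with the infection module
    from .infection import LysogenyCurve


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


class Lifestyle(str, Enum):
    VIRULENT = "virulent"
    TEMPERATE = "temperate"
    DEFECTIVE = "defective"


@dataclass(frozen=True)
class BacterialSpecies:
    """Heritable defaults for one bacterial species.

    ``mu_antibiotic`` and ``mu_phage_receptor`` are per-reproduction-event
    mutation probabilities: a bacterial generation is a birth, so mutation is
    applied once per offspring.
    """

    name: str
    base_growth_rate: float = 1.0
    intrinsic_death_prob: float = 0.0
    antibiotic_resistant: bool = False
    phage_resistance_profile: frozenset[str] = frozenset()
    cost_antibiotic_resistance: float = 0.0
    cost_phage_resistance: float = 0.0
    mu_antibiotic: float = 0.0
    mu_phage_receptor: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "phage_resistance_profile", frozenset(self.phage_resistance_profile)
        )
        if self.base_growth_rate < 0:
            raise ValidationError("base_growth_rate must be >= 0")
        _check_prob(self.intrinsic_death_prob, "intrinsic_death_prob")
        _check_prob(self.mu_antibiotic, "mu_antibiotic")
        _check_prob(self.mu_phage_receptor, "mu_phage_receptor")
        for cost, label in (
            (self.cost_antibiotic_resistance, "cost_antibiotic_resistance"),
            (self.cost_phage_resistance, "cost_phage_resistance"),
        ):
            if not 0.0 <= cost < 1.0:
                raise ValidationError(f"{label} must lie in [0, 1), got {cost}")


@dataclass(frozen=True)
class PhageSpecies:
    name: str
    lifestyle: Lifestyle = Lifestyle.VIRULENT
    attachment_phenotypes: tuple[str, ...] = ()
    burst_size: int = 50
    adsorption_prob: float = 0.9
    decay_prob: float = 0.05
    mu_attachment: float = 0.0
    induction_prob: float = 1e-3
    stress_induction_factor: float = 10.0
    lysogeny_curve: Optional["LysogenyCurve"] = None

    def __post_init__(self):
        object.__setattr__(self, "lifestyle", Lifestyle(self.lifestyle))
        object.__setattr__(
            self, "attachment_phenotypes", tuple(self.attachment_phenotypes)
        )
        if not self.attachment_phenotypes:
            raise ValidationError(f"phage {self.name!r} declares no attachment phenotypes")
        if self.burst_size < 0:
            raise ValidationError("burst_size must be >= 0")
        _check_prob(self.adsorption_prob, "adsorption_prob")
        _check_prob(self.decay_prob, "decay_prob")
        _check_prob(self.mu_attachment, "mu_attachment")
        _check_prob(self.induction_prob, "induction_prob")
        if self.stress_induction_factor < 1:
            raise ValidationError("stress_induction_factor must be >= 1")
        if self.lifestyle is Lifestyle.VIRULENT and self.lysogeny_curve is not None:
            raise ValidationError("virulent phages never lysogenize: drop the lysogeny curve")
        if self.lifestyle is Lifestyle.TEMPERATE and self.lysogeny_curve is None:
            raise ValidationError(f"temperate phage {self.name!r} needs a lysogeny curve")

    @property
    def effective_burst_size(self) -> int:
        """Defective phages produce no infectious burst."""
        return 0 if self.lifestyle is Lifestyle.DEFECTIVE else self.burst_size


@dataclass(frozen=True)
class Prophage:
    """A temperate phage genome integrated into a host chromosome."""

    species: PhageSpecies
    attachment_phenotype: str


class PhageParticle:
    """One free or intracellular virion."""

    __slots__ = ("species", "attachment_phenotype", "location", "age_outside_host")

    def __init__(
        self,
        species: PhageSpecies,
        attachment_phenotype: str,
        location=None,
        age_outside_host: int = 0,
    ):
        self.species = species
        self.attachment_phenotype = attachment_phenotype
        self.location = location
        self.age_outside_host = age_outside_host

    def __repr__(self):
        return (
            f"PhageParticle({self.species.name}, {self.attachment_phenotype}, "
            f"loc={self.location}, age={self.age_outside_host})"
        )


class Bacterium:
    """One cell on the lattice."""

    __slots__ = (
        "species",
        "antibiotic_resistant",
        "resisted_phage_phenotypes",
        "prophages",
        "intracellular_phages",
        "age",
        "location",
        "last_division_iteration",
        "_label",
    )

    def __init__(
        self,
        species: BacterialSpecies,
        antibiotic_resistant: Optional[bool] = None,
        resisted_phage_phenotypes: Optional[Iterable[str]] = None,
        prophages: Optional[list[Prophage]] = None,
        location=None,
    ):
        self.species = species
        self.antibiotic_resistant = (
            species.antibiotic_resistant
            if antibiotic_resistant is None
            else antibiotic_resistant
        )
        self.resisted_phage_phenotypes = (
            set(species.phage_resistance_profile)
            if resisted_phage_phenotypes is None
            else set(resisted_phage_phenotypes)
        )
        self.prophages: list[Prophage] = list(prophages or [])
        self.intracellular_phages: list[PhageParticle] = []
        self.age = 0
        self.location = location
        # a cell divides at most once per iteration; -1 = never divided
        self.last_division_iteration = -1
        self._label = None

    # phenotype changes invalidate the cached genotype label
    def gain_antibiotic_resistance(self) -> None:
        self.antibiotic_resistant = True
        self._label = None

    def gain_phage_resistance(self, phenotype: str) -> None:
        self.resisted_phage_phenotypes.add(phenotype)
        self._label = None

    def add_prophage(self, prophage: Prophage) -> None:
        self.prophages.append(prophage)
        self._label = None

    @property
    def is_lysogen(self) -> bool:
        return bool(self.prophages)

    @property
    def genotype_label(self) -> str:
        if self._label is None:
            self._label = make_genotype_label(
                self.species.name,
                self.antibiotic_resistant,
                self.resisted_phage_phenotypes,
                self.prophages,
            )
        return self._label

    def __repr__(self):
        return f"Bacterium({self.genotype_label}, loc={self.location})"


def make_genotype_label(
    species_name: str,
    antibiotic_resistant: bool,
    resisted: Iterable[str],
    prophages: Iterable[Prophage],
) -> str:
    """Canonical string form of a bacterial phenotype (pure function)."""
    ph = ",".join(sorted(resisted)) or "-"
    pro = ",".join(sorted(f"{p.species.name}:{p.attachment_phenotype}" for p in prophages)) or "-"
    ab = "R" if antibiotic_resistant else "S"
    return f"{species_name}|ab:{ab}|ph:{ph}|pro:{pro}"


def parse_genotype_label(label: str, registry: "SpeciesRegistry") -> Bacterium:
    """Reconstruct a phenotypically equal cell from its genotype label."""
    try:
        species_name, ab_part, ph_part, pro_part = label.split("|")
        ab = {"ab:R": True, "ab:S": False}[ab_part]
        ph_body = ph_part.removeprefix("ph:")
        pro_body = pro_part.removeprefix("pro:")
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"malformed genotype label {label!r}") from exc
    resisted = set() if ph_body == "-" else set(ph_body.split(","))
    prophages = []
    if pro_body != "-":
        for item in pro_body.split(","):
            sp_name, phenotype = item.split(":")
            prophages.append(Prophage(registry.get_phage(sp_name), phenotype))
    return Bacterium(
        registry.get_bacterial(species_name),
        antibiotic_resistant=ab,
        resisted_phage_phenotypes=resisted,
        prophages=prophages,
    )


class SpeciesRegistry:
    """All species definitions plus the host-range and superinfection matrices.

    ``host_range`` maps ``(attachment phenotype, bacterial species name)`` to
    the probability that a phage with that phenotype successfully infects a
    cell of that species (this is also the per-encounter adsorption scale).
    ``superinfection_exclusion`` maps ``(incoming phage species, resident
    prophage species)`` to the probability that the incoming infection aborts.
    """

    def __init__(
        self,
        bacterial_species: Iterable[BacterialSpecies],
        phage_species: Iterable[PhageSpecies],
        host_range: dict[tuple[str, str], float],
        superinfection_exclusion: Optional[dict[tuple[str, str], float]] = None,
    ):
        self.bacterial_species = list(bacterial_species)
        self.phage_species = list(phage_species)
        self.host_range = dict(host_range)
        self.superinfection_exclusion = dict(superinfection_exclusion or {})
        self._bacterial = {s.name: s for s in self.bacterial_species}
        self._phage = {s.name: s for s in self.phage_species}
        if len(self._bacterial) != len(self.bacterial_species):
            raise ValidationError("duplicate bacterial species names")
        if len(self._phage) != len(self.phage_species):
            raise ValidationError("duplicate phage species names")
        self.all_attachment_phenotypes: tuple[str, ...] = tuple(
            sorted({p for s in self.phage_species for p in s.attachment_phenotypes})
        )
        self._validate()

    def _validate(self) -> None:
        bacterial_names = set(self._bacterial)
        phage_names = set(self._phage)
        phenotypes = set(self.all_attachment_phenotypes)
        for (ph, sp), v in self.host_range.items():
            if ph not in phenotypes:
                raise ValidationError(f"host_range row {ph!r} is not a known attachment phenotype")
            if sp not in bacterial_names:
                raise ValidationError(f"host_range column {sp!r} is not a known bacterial species")
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"host_range[{ph!r}, {sp!r}] = {v} outside [0, 1]")
        for ph in phenotypes:
            for sp in bacterial_names:
                if (ph, sp) not in self.host_range:
                    raise ValidationError(f"host_range is missing entry ({ph!r}, {sp!r})")
        for (inc, res), v in self.superinfection_exclusion.items():
            if inc not in phage_names or res not in phage_names:
                raise ValidationError(
                    f"superinfection entry ({inc!r}, {res!r}) references unknown phage species"
                )
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"superinfection_exclusion[{inc!r}, {res!r}] = {v} outside [0, 1]"
                )
        for sp in self.bacterial_species:
            for ph in sp.phage_resistance_profile:
                if ph not in phenotypes:
                    raise ValidationError(
                        f"species {sp.name!r} resists unknown phenotype {ph!r}"
                    )

    def get_bacterial(self, name: str) -> BacterialSpecies:
        try:
            return self._bacterial[name]
        except KeyError:
            raise RegistryError(f"unknown bacterial species {name!r}") from None

    def get_phage(self, name: str) -> PhageSpecies:
        try:
            return self._phage[name]
        except KeyError:
            raise RegistryError(f"unknown phage species {name!r}") from None

    def host_range_prob(self, phenotype: str, species_name: str) -> float:
        try:
            return self.host_range[(phenotype, species_name)]
        except KeyError:
            raise RegistryError(
                f"no host-range entry for phenotype {phenotype!r} vs species {species_name!r}"
            ) from None

    def superinfection_prob(self, incoming: str, resident: str) -> float:
        return self.superinfection_exclusion.get((incoming, resident), 0.0)


# ---------------------------------------------------------------------------
# Fitness, selection, mutation
# ---------------------------------------------------------------------------


def fitness(cell: Bacterium) -> float:
    """Multiplicative-cost fitness of one cell.

    ``base_growth_rate * (1 - cost_ab)^[antibiotic resistant]
    * (1 - cost_phage)^(number of resisted attachment phenotypes)``
    """
    sp = cell.species
    w = sp.base_growth_rate
    if cell.antibiotic_resistant:
        w *= 1.0 - sp.cost_antibiotic_resistance
    n_ph = len(cell.resisted_phage_phenotypes)
    if n_ph:
        w *= (1.0 - sp.cost_phage_resistance) ** n_ph
    return w


def roulette_select(candidates: list[Bacterium], rng: np.random.Generator) -> Bacterium:
    """Fitness-proportionate (roulette wheel) choice of one candidate.

    If every candidate has zero fitness the choice is uniform.
    """
    if not candidates:
        raise ValidationError("roulette_select needs at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    weights = [fitness(c) for c in candidates]
    total = sum(weights)
    if total <= 0.0:
        return candidates[int(rng.integers(0, len(candidates)))]
    u = rng.random() * total
    acc = 0.0
    for cell, w in zip(candidates, weights):
        acc += w
        if u < acc:
            return cell
    return candidates[-1]  # guard against floating-point shortfall


def mutate_offspring(
    parent: Bacterium, registry: SpeciesRegistry, rng: np.random.Generator
) -> Bacterium:
    """Copy the parent's phenotype and prophages into an offspring, applying
    independent resistance mutations.

    With probability ``mu_antibiotic`` a sensitive offspring becomes
    antibiotic resistant; with probability ``mu_phage_receptor`` it gains
    resistance against one uniformly chosen attachment phenotype (from the
    registry) that it does not already resist.
    """
    sp = parent.species
    child = Bacterium(
        sp,
        antibiotic_resistant=parent.antibiotic_resistant,
        resisted_phage_phenotypes=parent.resisted_phage_phenotypes,
        prophages=list(parent.prophages),
    )
    if sp.mu_antibiotic > 0 and rng.random() < sp.mu_antibiotic:
        if not child.antibiotic_resistant:
            child.gain_antibiotic_resistance()
    if sp.mu_phage_receptor > 0 and rng.random() < sp.mu_phage_receptor:
        available = [
            p
            for p in registry.all_attachment_phenotypes
            if p not in child.resisted_phage_phenotypes
        ]
        if available:
            child.gain_phage_resistance(available[int(rng.integers(0, len(available)))])
    return child


def mutate_phage_offspring(
    parent_phenotype: str, species: PhageSpecies, rng: np.random.Generator
) -> str:
    """Attachment phenotype of one burst offspring.

    With probability ``mu_attachment`` the offspring carries a uniformly
    chosen *different* phenotype from the species' repertoire.
    """
    if parent_phenotype not in species.attachment_phenotypes:
        raise RegistryError(
            f"phenotype {parent_phenotype!r} is not defined for phage {species.name!r}"
        )
    others = [p for p in species.attachment_phenotypes if p != parent_phenotype]
    if not others or species.mu_attachment <= 0:
        return parent_phenotype
    if rng.random() < species.mu_attachment:
        return others[int(rng.integers(0, len(others)))]
    return parent_phenotype
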