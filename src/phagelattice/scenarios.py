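"""Built-in scenario presets at 50x50 desk scale.

Each preset returns a complete ``(GeneralParams, EcoSetup)`` pair encoding
one of the canonical community setups:

``fig2_antibiotic``
    Two-species community (one antibiotic-resistant/phage-sensitive, one
    phage-resistant/antibiotic-sensitive); a single slowly degrading
    antibiotic dose at iteration 10, no phage.
``fig2_phage``
    Same community; 10 virulent virions co-inoculated at time 0, no
    antibiotic.
``fig2_combined``
    Both stressors.
``fig3_evolution``
    One initially fully sensitive species under both stressors, with
    mutation to antibiotic and phage resistance (default rate 1e-4 per
    reproduction event).
``fig4_coevolution``
    Arms race: bacteria mutate receptor resistance at 1e-3, the phage
    mutates its attachment phenotype at 1e-4 (ten-fold lower).
``fig5_invasion``
    Lysogen invaders co-inoculated 1:10 with phage-sensitive residents; the
    temperate prophage induces spontaneously and lysogenizes residents.
``fig6_invasion_structured``
    The invasion setup in a fully structured environment.

Overrides are applied last: any ``GeneralParams`` field name can be
overridden directly, plus the scenario-level keys ``structure`` (which also
adjusts the dispersal radii), ``antibiotic_mode`` (none / homogeneous /
heterogeneous), ``mutation_rate``, ``mu_attachment``, ``lysogeny_curve``,
``burst_size``, ``adsorption_prob``, ``decay_prob``, ``induction_prob``,
``initial_phage_count`` and ``count:<species>``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .agents import BacterialSpecies, PhageSpecies
from .config import BacteriumSetup, EcoSetup, GeneralParams, PhageSetup
from .errors import ValidationError
from .infection import LYSOGENY_PRESETS

SCENARIO_NAMES = (
    "fig2_antibiotic",
    "fig2_phage",
    "fig2_combined",
    "fig3_evolution",
    "fig4_coevolution",
    "fig5_invasion",
    "fig6_invasion_structured",
)

#: (reproduction_radius, phage_diffusion_radius) implied by each structure
#: mode.  Fully structured environments have no free diffusion at all: phage
#: spread only through the Moore-1 dispersal of burst offspring.
_STRUCTURE_RADII = {
    "well_mixed": (3, 3),
    "semi_structured": (3, 3),
    "structured": (1, 0),
}


def _base_general(**kwargs) -> GeneralParams:
    defaults = dict(
        width=50,
        height=50,
        topology="bounded",
        structure="well_mixed",
        reproduction_radius=3,
        phage_diffusion_radius=3,
        phage_cap_per_location=50,
        n_iterations=60,
        antibiotic_application_iteration=None,
        antibiotic_deployment="homogeneous",
        antibiotic_dose=10.0,
        antibiotic_n_foci=12,
        antibiotic_degradation_rate=0.01,
        antibiotic_diffusion_fraction=0.25,
        basal_death_prob=0.05,
        antibiotic_kill_prob=0.9,
        mic_threshold=1.0,
    )
    defaults.update(kwargs)
    return GeneralParams(**defaults)


def _two_species_eco(phage_count: int) -> EcoSetup:
    ab_resistant = BacterialSpecies(
        name="AbR",
        antibiotic_resistant=True,
        cost_antibiotic_resistance=0.1,
    )
    phage_resistant = BacterialSpecies(
        name="PhR",
        phage_resistance_profile=frozenset({"p0"}),
        cost_phage_resistance=0.1,
    )
    phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
    return EcoSetup(
        bacteria=[
            BacteriumSetup(ab_resistant, 1000),
            BacteriumSetup(phage_resistant, 1000),
        ],
        phages=[PhageSetup(phage, phage_count)],
        host_range={("p0", "AbR"): 1.0, ("p0", "PhR"): 1.0},
    )


def _fig3_eco(mutation_rate: float) -> EcoSetup:
    species = BacterialSpecies(
        name="B",
        cost_antibiotic_resistance=0.1,
        cost_phage_resistance=0.1,
        mu_antibiotic=mutation_rate,
        mu_phage_receptor=mutation_rate,
    )
    phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
    return EcoSetup(
        bacteria=[BacteriumSetup(species, 2000)],
        phages=[PhageSetup(phage, 10)],
        host_range={("p0", "B"): 1.0},
    )


def _fig4_eco() -> EcoSetup:
    species = BacterialSpecies(
        name="B",
        cost_antibiotic_resistance=0.1,
        cost_phage_resistance=0.1,
        mu_antibiotic=0.0,
        mu_phage_receptor=1e-3,
    )
    phage = PhageSpecies(
        name="P",
        lifestyle="virulent",
        attachment_phenotypes=("p0", "p1"),
        mu_attachment=1e-4,
    )
    return EcoSetup(
        bacteria=[BacteriumSetup(species, 2000)],
        phages=[PhageSetup(phage, 10, initial_phenotype="p0")],
        host_range={("p0", "B"): 1.0, ("p1", "B"): 1.0},
    )


def _invasion_eco(curve_name: str = "Lysogeny1") -> EcoSetup:
    invader = BacterialSpecies(name="invader")
    resident = BacterialSpecies(name="resident")
    phage = PhageSpecies(
        name="T",
        lifestyle="temperate",
        attachment_phenotypes=("t0",),
        induction_prob=0.01,
        stress_induction_factor=10.0,
        lysogeny_curve=LYSOGENY_PRESETS[curve_name],
    )
    return EcoSetup(
        bacteria=[
            BacteriumSetup(invader, 200, initial_prophages=[("T", "t0")]),
            BacteriumSetup(resident, 2000),
        ],
        phages=[PhageSetup(phage, 0)],
        host_range={("t0", "invader"): 1.0, ("t0", "resident"): 1.0},
        superinfection={("T", "T"): 1.0},
    )


def _build(name: str) -> tuple[GeneralParams, EcoSetup]:
    if name == "fig2_antibiotic":
        return (
            _base_general(n_iterations=60, antibiotic_application_iteration=10),
            _two_species_eco(phage_count=0),
        )
    if name == "fig2_phage":
        return _base_general(n_iterations=60), _two_species_eco(phage_count=10)
    if name == "fig2_combined":
        return (
            _base_general(n_iterations=60, antibiotic_application_iteration=10),
            _two_species_eco(phage_count=10),
        )
    if name == "fig3_evolution":
        # antibiotics shortly after co-inoculation, while the phage wave is
        # still spatially limited in structured runs; a gentler kill than the
        # two-species presets so sensitive populations decline over several
        # iterations and keep supplying resistance mutations meanwhile
        return (
            _base_general(
                n_iterations=80,
                antibiotic_application_iteration=5,
                antibiotic_kill_prob=0.7,
            ),
            _fig3_eco(mutation_rate=1e-4),
        )
    if name == "fig4_coevolution":
        return _base_general(n_iterations=80), _fig4_eco()
    if name == "fig5_invasion":
        return _base_general(n_iterations=20), _invasion_eco()
    if name == "fig6_invasion_structured":
        repro, diff = _STRUCTURE_RADII["structured"]
        general = _base_general(
            n_iterations=20,
            structure="structured",
            reproduction_radius=repro,
            phage_diffusion_radius=diff,
        )
        return general, _invasion_eco()
    raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def _apply_eco_override(eco: EcoSetup, key: str, value) -> bool:
    """Mutate the eco setup in place; returns True when the key was handled."""

    def _replace_phages(**changes):
        eco.phages = [
            dataclasses.replace(p, species=dataclasses.replace(p.species, **changes))
            for p in eco.phages
        ]

    if key == "mutation_rate":
        rate = float(value)
        eco.bacteria = [
            dataclasses.replace(
                b,
                species=dataclasses.replace(
                    b.species, mu_antibiotic=rate, mu_phage_receptor=rate
                ),
            )
            for b in eco.bacteria
        ]
        return True
    if key == "mu_antibiotic":
        eco.bacteria = [
            dataclasses.replace(
                b, species=dataclasses.replace(b.species, mu_antibiotic=float(value))
            )
            for b in eco.bacteria
        ]
        return True
    if key == "mu_phage_receptor":
        eco.bacteria = [
            dataclasses.replace(
                b, species=dataclasses.replace(b.species, mu_phage_receptor=float(value))
            )
            for b in eco.bacteria
        ]
        return True
    if key == "lysogeny_curve":
        curve = LYSOGENY_PRESETS.get(str(value))
        if curve is None:
            raise ValidationError(f"unknown lysogeny curve preset {value!r}")
        changed = False
        new_phages = []
        for p in eco.phages:
            if p.species.lysogeny_curve is not None:
                new_phages.append(
                    dataclasses.replace(
                        p, species=dataclasses.replace(p.species, lysogeny_curve=curve)
                    )
                )
                changed = True
            else:
                new_phages.append(p)
        if not changed:
            raise ValidationError("no temperate phage in this scenario to assign a curve to")
        eco.phages = new_phages
        return True
    if key == "burst_size":
        _replace_phages(burst_size=int(value))
        return True
    if key == "adsorption_prob":
        _replace_phages(adsorption_prob=float(value))
        return True
    if key == "decay_prob":
        _replace_phages(decay_prob=float(value))
        return True
    if key == "induction_prob":
        _replace_phages(induction_prob=float(value))
        return True
    if key == "mu_attachment":
        _replace_phages(mu_attachment=float(value))
        return True
    if key == "initial_phage_count":
        eco.phages = [dataclasses.replace(p, initial_count=int(value)) for p in eco.phages]
        return True
    if key.startswith("count:"):
        name = key.split(":", 1)[1]
        found = False
        new = []
        for b in eco.bacteria:
            if b.species.name == name:
                new.append(dataclasses.replace(b, initial_count=int(value)))
                found = True
            else:
                new.append(b)
        if not found:
            raise ValidationError(f"override {key!r}: no bacterial species {name!r}")
        eco.bacteria = new
        return True
    return False


def scenario(
    name: str, overrides: Optional[dict] = None
) -> tuple[GeneralParams, EcoSetup]:
    """Return the config pair for a named preset, with overrides applied last."""
    general, eco = _build(name)
    general_fields = {f.name for f in dataclasses.fields(GeneralParams)}
    for key, value in (overrides or {}).items():
        if key == "structure":
            mode = str(value)
            if mode not in _STRUCTURE_RADII:
                raise ValidationError(f"unknown structure mode {mode!r}")
            general.structure = mode
            general.reproduction_radius, general.phage_diffusion_radius = (
                _STRUCTURE_RADII[mode]
            )
        elif key == "antibiotic_mode":
            mode = str(value)
            if mode == "none":
                general.antibiotic_application_iteration = None
            elif mode == "homogeneous":
                general.antibiotic_deployment = "homogeneous"
                general.antibiotic_dose = 10.0
                if general.antibiotic_application_iteration is None:
                    general.antibiotic_application_iteration = 10
            elif mode == "heterogeneous":
                # a few random foci at high dose that diffuse outwards,
                # leaving low-concentration spatial refuges
                general.antibiotic_deployment = "heterogeneous"
                general.antibiotic_dose = 200.0
                general.antibiotic_n_foci = 12
                if general.antibiotic_application_iteration is None:
                    general.antibiotic_application_iteration = 10
            else:
                raise ValidationError(f"unknown antibiotic_mode {mode!r}")
        elif key in general_fields:
            setattr(general, key, value)
        elif _apply_eco_override(eco, key, value):
            pass
        else:
            raise ValidationError(f"unknown scenario override {key!r}")
    general.validate()
    eco.build_registry()
    return general, eco
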