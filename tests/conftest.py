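import numpy as np
import pytest

from phagelattice import (
    BacterialSpecies,
    EcoSetup,
    GeneralParams,
    LatticeConfig,
    PhageSpecies,
    SpeciesRegistry,
)
from phagelattice.config import BacteriumSetup, PhageSetup
from phagelattice.infection import LYSOGENY_PRESETS


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_config():
    return LatticeConfig(width=10, height=10, phage_cap_per_location=20)


@pytest.fixture
def two_species_registry():
    """Two bacterial species and one virulent phage, as in the community
    scenarios: one antibiotic-resistant/phage-sensitive, one phage-resistant."""
    ab_r = BacterialSpecies(
        name="AbR", antibiotic_resistant=True, cost_antibiotic_resistance=0.1
    )
    ph_r = BacterialSpecies(
        name="PhR",
        phage_resistance_profile=frozenset({"p0"}),
        cost_phage_resistance=0.1,
    )
    phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
    return SpeciesRegistry(
        [ab_r, ph_r], [phage], {("p0", "AbR"): 1.0, ("p0", "PhR"): 1.0}
    )


@pytest.fixture
def temperate_registry():
    """Invader/resident pair with a temperate phage and full superinfection
    exclusion, as in the lysogen-invasion scenarios."""
    invader = BacterialSpecies(name="invader")
    resident = BacterialSpecies(name="resident")
    phage = PhageSpecies(
        name="T",
        lifestyle="temperate",
        attachment_phenotypes=("t0",),
        lysogeny_curve=LYSOGENY_PRESETS["Lysogeny1"],
        induction_prob=0.01,
    )
    return SpeciesRegistry(
        [invader, resident],
        [phage],
        {("t0", "invader"): 1.0, ("t0", "resident"): 1.0},
        {("T", "T"): 1.0},
    )


def make_state(config=None, registry=None, kill=None, antibiotic_kwargs=None):
    """Bare simulation state on a small grid (no agents placed)."""
    from phagelattice.engine import SimulationState
    from phagelattice.infection import KillModel
    from phagelattice.lattice import AntibioticField

    config = config or LatticeConfig(width=10, height=10, phage_cap_per_location=20)
    if registry is None:
        species = BacterialSpecies(name="B")
        phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
        registry = SpeciesRegistry([species], [phage], {("p0", "B"): 1.0})
    field = AntibioticField.zeros(config, **(antibiotic_kwargs or {}))
    return SimulationState(config, registry, field, kill or KillModel())


@pytest.fixture
def state_factory():
    return make_state


@pytest.fixture
def minimal_config_pair():
    """A tiny but complete (GeneralParams, EcoSetup) pair for engine tests."""
    general = GeneralParams(
        width=12,
        height=12,
        n_iterations=5,
        phage_cap_per_location=20,
        basal_death_prob=0.05,
    )
    species = BacterialSpecies(name="B")
    phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
    eco = EcoSetup(
        bacteria=[BacteriumSetup(species, 60)],
        phages=[PhageSetup(phage, 5)],
        host_range={("p0", "B"): 1.0},
    )
    return general, eco
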