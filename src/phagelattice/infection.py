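"""Phage-host interaction logic: adsorption, superinfection exclusion, the
lysis-lysogeny decision, burst, prophage induction, free-phage decay, and
antibiotic killing.

The lysis-lysogeny decision is a Hill function of the local free-virion
count (the focal location plus its Moore-1 neighborhood), reflecting the
observation that high local phage density / multiplicity of infection biases
temperate phages toward lysogeny.  Three named presets span the densities at
which lysogenization becomes likely.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .agents import (
    Bacterium,
    Lifestyle,
    PhageParticle,
    PhageSpecies,
    Prophage,
    SpeciesRegistry,
    mutate_phage_offspring,
)
from .errors import ValidationError
from .lattice import neighborhood_list


@dataclass(frozen=True)
class LysogenyCurve:
    """Hill-shaped probability of lysogenization vs local free-virion count.

    ``p(n) = p_max * n^h / (n^h + K^h)`` with ``K = half_density`` (the count
    at which the probability is half-maximal) and ``h = hill_exponent``.
    """

    p_max: float = 0.9
    half_density: float = 5.0
    hill_exponent: float = 2.0
    preset_name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.p_max <= 1.0:
            raise ValidationError("p_max must lie in [0, 1]")
        if self.half_density <= 0:
            raise ValidationError("half_density must be > 0")
        if self.hill_exponent < 1:
            raise ValidationError("hill_exponent must be >= 1")

    def probability(self, local_phage_count: int) -> float:
        return lysogeny_probability(local_phage_count, self)


#: Named decision curves ordered by the phage density they require:
#: Lysogeny1 and Lysogeny2 already give a 1-10% lysogenization chance at low
#: counts, Lysogeny3 needs very high local densities.
LYSOGENY_PRESETS: dict[str, LysogenyCurve] = {
    "Lysogeny1": LysogenyCurve(0.9, 5.0, 2.0, "Lysogeny1"),
    "Lysogeny2": LysogenyCurve(0.9, 15.0, 2.0, "Lysogeny2"),
    "Lysogeny3": LysogenyCurve(0.9, 150.0, 2.0, "Lysogeny3"),
}


def lysogeny_probability(local_phage_count: int, curve: LysogenyCurve) -> float:
    """Probability that a temperate infection lysogenizes (monotone in count)."""
    n = float(local_phage_count)
    if n <= 0:
        return 0.0
    nh = n**curve.hill_exponent
    return curve.p_max * nh / (nh + curve.half_density**curve.hill_exponent)


class InfectionOutcome(str, Enum):
    NO_ADSORPTION = "no_adsorption"
    ABORTED_SUPERINFECTION = "aborted_superinfection"
    RESISTANT_HOST = "resistant_host"
    LYSIS_INITIATED = "lysis_initiated"
    LYSOGENIZED = "lysogenized"


@dataclass(frozen=True)
class KillModel:
    """Per-iteration death probabilities.

    A cell dies from the basal hazard, or — if it is antibiotic sensitive and
    the local concentration is at or above ``mic_threshold`` — from the
    antibiotic hazard.  The two hazards compose as independent events, so the
    combined per-iteration death probability never exceeds 1.
    """

    basal_death_prob: float = 0.05
    antibiotic_kill_prob: float = 0.95
    mic_threshold: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.basal_death_prob <= 1.0:
            raise ValidationError("basal_death_prob must lie in [0, 1]")
        if not 0.0 <= self.antibiotic_kill_prob <= 1.0:
            raise ValidationError("antibiotic_kill_prob must lie in [0, 1]")
        if self.mic_threshold < 0:
            raise ValidationError("mic_threshold must be >= 0")


def attempt_infection(
    virion: PhageParticle,
    host: Bacterium,
    registry: SpeciesRegistry,
    local_phage_count: int,
    rng: np.random.Generator,
) -> InfectionOutcome:
    """Resolve one phage-host encounter through its sequential gates.

    1. a host resisting the virion's attachment phenotype blocks it;
    2. adsorption succeeds with ``host_range[phenotype, species] *
       adsorption_prob`` (defective virions never adsorb);
    3. each resident prophage independently aborts the infection with its
       superinfection-exclusion probability;
    4. virulent phages initiate lysis; temperate phages lysogenize with the
       curve probability at the local virion density, else initiate lysis.

    The caller removes adsorbed virions (every outcome except
    ``RESISTANT_HOST`` and ``NO_ADSORPTION``) from the free pool and applies
    the host-state change.
    """
    sp = virion.species
    if virion.attachment_phenotype in host.resisted_phage_phenotypes:
        return InfectionOutcome.RESISTANT_HOST
    if sp.lifestyle is Lifestyle.DEFECTIVE:
        return InfectionOutcome.NO_ADSORPTION
    p_ads = registry.host_range_prob(virion.attachment_phenotype, host.species.name)
    p_ads *= sp.adsorption_prob
    if rng.random() >= p_ads:
        return InfectionOutcome.NO_ADSORPTION
    virion.age_outside_host = 0
    for prophage in host.prophages:
        q = registry.superinfection_prob(sp.name, prophage.species.name)
        if q > 0 and rng.random() < q:
            return InfectionOutcome.ABORTED_SUPERINFECTION
    if sp.lifestyle is Lifestyle.VIRULENT:
        return InfectionOutcome.LYSIS_INITIATED
    p_lys = lysogeny_probability(local_phage_count, sp.lysogeny_curve)
    if rng.random() < p_lys:
        return InfectionOutcome.LYSOGENIZED
    return InfectionOutcome.LYSIS_INITIATED


def resolve_lysis(
    host: Bacterium,
    triggering_species: PhageSpecies,
    state,
    rng: np.random.Generator,
    parent_phenotype: Optional[str] = None,
) -> list[PhageParticle]:
    """Kill the host and release its burst into the free pool.

    The host's location is freed; ``burst_size`` offspring virions are
    created, each drawing its attachment phenotype through
    :func:`mutate_phage_offspring`, and dispersed locally within the phage
    diffusion radius subject to the per-location cap.
    """
    loc = host.location
    if state.bacteria.get(loc) is not host:
        raise ValidationError("host is not on the lattice at its recorded location")
    del state.bacteria[loc]
    host.location = None

    if parent_phenotype is None:
        parent_phenotype = triggering_species.attachment_phenotypes[0]
    burst = triggering_species.effective_burst_size
    particles: list[PhageParticle] = []
    counts: dict[str, int] = {}
    for _ in range(burst):
        phenotype = mutate_phage_offspring(parent_phenotype, triggering_species, rng)
        counts[phenotype] = counts.get(phenotype, 0) + 1
        particles.append(PhageParticle(triggering_species, phenotype, loc, 0))
    for phenotype in sorted(counts):
        _place_with_cap(
            state, loc, (triggering_species.name, phenotype), counts[phenotype], rng
        )
    return particles


def _place_with_cap(state, origin, key, count, rng: np.random.Generator) -> None:
    """Scatter ``count`` new virions near ``origin`` honoring the location cap."""
    config = state.config
    pool = state.phage_pool
    cap = config.phage_cap_per_location
    radius = max(1, config.phage_diffusion_radius)
    cells = [origin, *neighborhood_list(origin, radius, config)]
    idx = rng.integers(0, len(cells), size=count)
    remaining = 0
    for i in idx:
        cell = cells[int(i)]
        if pool.count_at(cell) < cap:
            pool.add(cell, key, 1)
        else:
            remaining += 1
    if remaining:
        order = rng.permutation(len(cells))
        for i in order:
            cell = cells[int(i)]
            room = cap - pool.count_at(cell)
            if room > 0:
                take = min(room, remaining)
                pool.add(cell, key, take)
                remaining -= take
            if remaining == 0:
                return
        r = radius + 1
        while remaining and r <= max(config.width, config.height):
            for cell in neighborhood_list(origin, r, config):
                room = cap - pool.count_at(cell)
                if room > 0:
                    take = min(room, remaining)
                    pool.add(cell, key, take)
                    remaining -= take
                if remaining == 0:
                    return
            r += 1
        if remaining:
            state.tallies["burst_capacity_lost"] = (
                state.tallies.get("burst_capacity_lost", 0) + remaining
            )


def induce_prophages(
    cell: Bacterium,
    local_antibiotic: float,
    mic_threshold: float,
    rng: np.random.Generator,
) -> Optional[Prophage]:
    """Spontaneous (possibly stress-amplified) prophage induction.

    Each carried prophage independently switches to the lytic cycle with
    probability ``induction_prob``, multiplied by ``stress_induction_factor``
    when the local antibiotic concentration reaches the MIC threshold.
    Returns the first prophage that induces (the cell then lyses this
    iteration) or ``None``.
    """
    stressed = local_antibiotic >= mic_threshold
    induced = None
    for prophage in cell.prophages:
        sp = prophage.species
        p = sp.induction_prob * (sp.stress_induction_factor if stressed else 1.0)
        p = min(1.0, p)
        if p > 0 and rng.random() < p and induced is None:
            induced = prophage
    return induced


def decay_free_phages(state, rng: np.random.Generator):
    """Age every free virion one iteration and remove each with its species'
    per-iteration decay probability (geometric lifetime)."""
    from .lattice import _regroup_pool

    pool = state.phage_pool
    keys, key_ids, xs, ys, ages = pool.flatten_arrays()
    n = len(ages)
    if n == 0:
        state.tallies["decays"] = state.tallies.get("decays", 0)
        return state
    p_by_key = np.array(
        [state.registry.get_phage(k[0]).decay_prob for k in keys], dtype=float
    )
    survive = rng.random(n) >= p_by_key[key_ids]
    removed = int(n - survive.sum())
    dest = (xs + ys * state.config.width)[survive]
    pool.replace_all(
        *_regroup_pool(keys, dest, key_ids[survive], ages[survive] + 1, state.config)
    )
    state.tallies["decays"] = state.tallies.get("decays", 0) + removed
    return state


def apply_mortality(state, kill: KillModel, rng: np.random.Generator):
    """Basal and antibiotic mortality over all cells.

    Every cell dies with the basal probability (composed with any
    species-intrinsic hazard); antibiotic-sensitive cells at locations with
    concentration >= MIC additionally die with ``antibiotic_kill_prob``.
    """
    locs = sorted(state.bacteria)
    n = len(locs)
    if n == 0:
        return state
    u_basal = rng.random(n)
    u_ab = rng.random(n)
    conc = state.antibiotic.concentration
    deaths_basal = deaths_ab = 0
    for i, loc in enumerate(locs):
        cell = state.bacteria[loc]
        basal = 1.0 - (1.0 - kill.basal_death_prob) * (
            1.0 - cell.species.intrinsic_death_prob
        )
        if u_basal[i] < basal:
            del state.bacteria[loc]
            cell.location = None
            deaths_basal += 1
            continue
        if not cell.antibiotic_resistant and conc[loc[1], loc[0]] >= kill.mic_threshold:
            if u_ab[i] < kill.antibiotic_kill_prob:
                del state.bacteria[loc]
                cell.location = None
                deaths_ab += 1
        cell.age += 1
    state.tallies["deaths_basal"] = state.tallies.get("deaths_basal", 0) + deaths_basal
    state.tallies["deaths_antibiotic"] = (
        state.tallies.get("deaths_antibiotic", 0) + deaths_ab
    )
    return state
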