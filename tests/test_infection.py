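"""Encounter gates, lysis-lysogeny decision, burst, induction, decay, killing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagelattice import (
    BacterialSpecies,
    Bacterium,
    InfectionOutcome,
    KillModel,
    LatticeConfig,
    LysogenyCurve,
    LYSOGENY_PRESETS,
    PhageParticle,
    PhageSpecies,
    Prophage,
    SpeciesRegistry,
    apply_mortality,
    attempt_infection,
    decay_free_phages,
    induce_prophages,
    lysogeny_probability,
    resolve_lysis,
)

from conftest import make_state


class TestLysogenyCurve:
    def test_zero_density_gives_zero(self):
        assert lysogeny_probability(0, LYSOGENY_PRESETS["Lysogeny1"]) == 0.0

    def test_half_density_gives_half_max(self):
        curve = LysogenyCurve(p_max=0.8, half_density=12, hill_exponent=2)
        assert lysogeny_probability(12, curve) == pytest.approx(0.4)

    @given(
        p_max=st.floats(0.01, 1.0),
        half_density=st.floats(0.5, 500),
        hill=st.floats(1.0, 6.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, p_max, half_density, hill):
        curve = LysogenyCurve(p_max, half_density, hill)
        values = [lysogeny_probability(n, curve) for n in range(0, 300, 7)]
        assert all(0.0 <= v <= p_max for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_presets_ordered_by_required_density(self):
        """At equal p_max and Hill exponent, the high-density preset never
        exceeds the low-density ones at any phage count."""
        l1, l2, l3 = (LYSOGENY_PRESETS[k] for k in ("Lysogeny1", "Lysogeny2", "Lysogeny3"))
        assert l1.half_density <= l2.half_density < l3.half_density
        for n in range(1, 10_001, 13):
            p1 = lysogeny_probability(n, l1)
            p2 = lysogeny_probability(n, l2)
            p3 = lysogeny_probability(n, l3)
            assert p3 <= p2 <= p1


def _simple_pair(lifestyle="virulent", adsorption=1.0, host_range=1.0, curve=None,
                 superinfection=None):
    host_sp = BacterialSpecies(name="B")
    phage = PhageSpecies(
        name="P",
        lifestyle=lifestyle,
        attachment_phenotypes=("p0",),
        adsorption_prob=adsorption,
        lysogeny_curve=curve,
    )
    reg = SpeciesRegistry(
        [host_sp], [phage], {("p0", "B"): host_range}, superinfection or {}
    )
    return host_sp, phage, reg


class TestAttemptInfection:
    def test_resistant_host_blocks(self, rng):
        host_sp, phage, reg = _simple_pair()
        host = Bacterium(host_sp, resisted_phage_phenotypes={"p0"})
        virion = PhageParticle(phage, "p0")
        assert attempt_infection(virion, host, reg, 1, rng) is InfectionOutcome.RESISTANT_HOST

    def test_all_gates_open_virulent_lyses(self, rng):
        host_sp, phage, reg = _simple_pair()
        host = Bacterium(host_sp)
        for _ in range(100):
            out = attempt_infection(PhageParticle(phage, "p0"), host, reg, 1, rng)
            assert out is InfectionOutcome.LYSIS_INITIATED

    def test_zero_adsorption_never_infects(self, rng):
        host_sp, phage, reg = _simple_pair(adsorption=0.0)
        host = Bacterium(host_sp)
        out = attempt_infection(PhageParticle(phage, "p0"), host, reg, 1, rng)
        assert out is InfectionOutcome.NO_ADSORPTION

    def test_full_superinfection_exclusion_always_aborts(self, rng):
        host_sp, phage, reg = _simple_pair(superinfection={("P", "P"): 1.0})
        host = Bacterium(host_sp, prophages=[Prophage(phage, "p0")])
        for _ in range(200):
            out = attempt_infection(PhageParticle(phage, "p0"), host, reg, 1, rng)
            assert out is InfectionOutcome.ABORTED_SUPERINFECTION

    def test_adsorption_resets_virion_age(self, rng):
        host_sp, phage, reg = _simple_pair()
        virion = PhageParticle(phage, "p0", age_outside_host=9)
        attempt_infection(virion, Bacterium(host_sp), reg, 1, rng)
        assert virion.age_outside_host == 0

    def test_temperate_high_density_lysogenizes_at_curve_rate(self, rng):
        curve = LYSOGENY_PRESETS["Lysogeny1"]
        host_sp, phage, reg = _simple_pair(lifestyle="temperate", curve=curve)
        n_local = 500  # far above half-density 5: probability ~ p_max
        n = 10_000
        hits = 0
        for _ in range(n):
            host = Bacterium(host_sp)
            out = attempt_infection(PhageParticle(phage, "p0"), host, reg, n_local, rng)
            hits += out is InfectionOutcome.LYSOGENIZED
        p = lysogeny_probability(n_local, curve)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sd

    def test_defective_phage_never_adsorbs(self, rng):
        host_sp = BacterialSpecies(name="B")
        phage = PhageSpecies(
            name="D", lifestyle="defective", attachment_phenotypes=("p0",), burst_size=0
        )
        reg = SpeciesRegistry([host_sp], [phage], {("p0", "B"): 1.0})
        out = attempt_infection(PhageParticle(phage, "p0"), Bacterium(host_sp), reg, 1, rng)
        assert out is InfectionOutcome.NO_ADSORPTION


class TestResolveLysis:
    def _state_with_host(self, burst, mu=0.0, phenotypes=("p0", "p1")):
        host_sp = BacterialSpecies(name="B")
        phage = PhageSpecies(
            name="P",
            lifestyle="virulent",
            attachment_phenotypes=phenotypes,
            burst_size=burst,
            mu_attachment=mu,
        )
        reg = SpeciesRegistry(
            [host_sp], [phage], {(p, "B"): 1.0 for p in phenotypes}
        )
        config = LatticeConfig(width=10, height=10, phage_cap_per_location=10_000)
        state = make_state(config=config, registry=reg)
        host = Bacterium(host_sp, location=(5, 5))
        state.bacteria[(5, 5)] = host
        return state, host, phage

    def test_zero_burst_kills_host_releases_nothing(self, rng):
        state, host, phage = self._state_with_host(burst=0)
        particles = resolve_lysis(host, phage, state, rng, "p0")
        assert particles == []
        assert (5, 5) not in state.bacteria
        assert state.phage_pool.total() == 0

    def test_burst_count_and_parental_phenotype(self, rng):
        state, host, phage = self._state_with_host(burst=50, mu=0.0)
        particles = resolve_lysis(host, phage, state, rng, "p0")
        assert len(particles) == 50
        assert all(p.attachment_phenotype == "p0" for p in particles)
        assert state.phage_pool.total() == 50

    def test_mutant_fraction_in_bursts(self, rng):
        """Pooled over 10^3 lyses of burst 100 at mu 1e-2, the mutant fraction
        is within 3 binomial SDs of the configured rate."""
        mu, burst, n_lyses = 1e-2, 100, 1000
        mutants = 0
        for _ in range(n_lyses):
            state, host, phage = self._state_with_host(burst=burst, mu=mu)
            particles = resolve_lysis(host, phage, state, rng, "p0")
            mutants += sum(p.attachment_phenotype != "p0" for p in particles)
        n = burst * n_lyses
        sd = np.sqrt(n * mu * (1 - mu))
        assert abs(mutants - n * mu) < 3 * sd


class TestInduction:
    def _lysogen(self, induction_prob, factor=10.0):
        phage = PhageSpecies(
            name="T",
            lifestyle="temperate",
            attachment_phenotypes=("t0",),
            induction_prob=induction_prob,
            stress_induction_factor=factor,
            lysogeny_curve=LYSOGENY_PRESETS["Lysogeny1"],
        )
        sp = BacterialSpecies(name="B")
        return Bacterium(sp, prophages=[Prophage(phage, "t0")])

    def test_no_prophage_never_induces(self, rng):
        cell = Bacterium(BacterialSpecies(name="B"))
        assert induce_prophages(cell, 0.0, 1.0, rng) is None

    def test_spontaneous_induction_frequency(self, rng):
        p, n = 0.01, 100_000
        cell = self._lysogen(p)
        hits = sum(induce_prophages(cell, 0.0, 1.0, rng) is not None for _ in range(n))
        sd = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sd

    def test_stress_multiplies_induction(self, rng):
        p, factor, n = 0.01, 10.0, 100_000
        cell = self._lysogen(p, factor)
        hits = sum(induce_prophages(cell, 5.0, 1.0, rng) is not None for _ in range(n))
        eff = p * factor
        sd = np.sqrt(n * eff * (1 - eff))
        assert abs(hits - n * eff) < 3 * sd


class TestDecay:
    def _state(self, decay_prob, n=100):
        phage = PhageSpecies(
            name="P",
            lifestyle="virulent",
            attachment_phenotypes=("p0",),
            decay_prob=decay_prob,
        )
        sp = BacterialSpecies(name="B")
        reg = SpeciesRegistry([sp], [phage], {("p0", "B"): 1.0})
        config = LatticeConfig(width=10, height=10, phage_cap_per_location=10**6)
        state = make_state(config=config, registry=reg)
        state.phage_pool.add((2, 2), ("P", "p0"), [3] * n)
        return state

    def test_zero_decay_increments_all_ages(self, rng):
        state = self._state(0.0, n=50)
        decay_free_phages(state, rng)
        ages = state.phage_pool.buckets_at((2, 2))[("P", "p0")]
        assert len(ages) == 50
        assert all(a == 4 for a in ages)

    def test_full_decay_removes_everything(self, rng):
        state = self._state(1.0, n=50)
        decay_free_phages(state, rng)
        assert state.phage_pool.total() == 0
        assert state.tallies["decays"] == 50

    def test_decay_fraction(self, rng):
        p, n = 0.1, 10_000
        state = self._state(p, n=n)
        decay_free_phages(state, rng)
        removed = state.tallies["decays"]
        sd = np.sqrt(n * p * (1 - p))
        assert abs(removed - n * p) < 3 * sd


class TestMortality:
    def _populated(self, n, resistant=False, kill=None, conc=0.0):
        sp = BacterialSpecies(name="B", antibiotic_resistant=resistant)
        phage = PhageSpecies(name="P", lifestyle="virulent", attachment_phenotypes=("p0",))
        reg = SpeciesRegistry([sp], [phage], {("p0", "B"): 1.0})
        config = LatticeConfig(width=50, height=50)
        state = make_state(config=config, registry=reg, kill=kill)
        state.antibiotic.concentration[:, :] = conc
        rng = np.random.default_rng(1)
        flat = rng.choice(2500, size=n, replace=False)
        for f in flat:
            loc = (int(f) % 50, int(f) // 50)
            state.bacteria[loc] = Bacterium(sp, location=loc)
        return state

    def test_no_hazard_no_deaths(self, rng):
        state = self._populated(200, kill=KillModel(basal_death_prob=0.0))
        apply_mortality(state, state.kill, rng)
        assert len(state.bacteria) == 200

    def test_certain_antibiotic_kill_extinguishes_sensitive(self, rng):
        kill = KillModel(basal_death_prob=0.0, antibiotic_kill_prob=1.0, mic_threshold=1.0)
        state = self._populated(300, kill=kill, conc=2.0)
        apply_mortality(state, kill, rng)
        assert len(state.bacteria) == 0

    def test_resistant_cells_ignore_antibiotic(self, rng):
        kill = KillModel(basal_death_prob=0.0, antibiotic_kill_prob=1.0, mic_threshold=1.0)
        state = self._populated(300, resistant=True, kill=kill, conc=2.0)
        apply_mortality(state, kill, rng)
        assert len(state.bacteria) == 300

    def test_basal_death_fraction(self, rng):
        p, n = 0.02, 2000
        kill = KillModel(basal_death_prob=p, antibiotic_kill_prob=0.0)
        state = self._populated(n, kill=kill)
        apply_mortality(state, kill, rng)
        deaths = n - len(state.bacteria)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(deaths - n * p) < 3 * sd
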