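"""The per-iteration update cycle, free-space reproduction, state recording,
and seeded replicate execution.

One iteration applies, in fixed order:

1. antibiotic deployment (if scheduled) and field diffusion/degradation;
2. well-mixed shuffling, or phage diffusion in (semi-)structured mode;
3. free-phage decay;
4. the infection pass (every free virion co-located with a cell attempts
   infection, locations and virions in random order);
5. spontaneous / stress-amplified prophage induction;
6. resolution of all lyses (host death, burst, local dispersal);
7. basal and antibiotic mortality;
8. reproduction of neighboring cells into free space (asynchronous:
   locations are filled in random order and a newly placed offspring may
   itself parent later fills in the same pass);
9. recording of the trajectory row and reset of the event tallies.

Killing precedes reproduction so that space freed in an iteration can be
colonized within the same iteration ("free space is the resource").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .agents import (
    Bacterium,
    PhageParticle,
    Prophage,
    SpeciesRegistry,
    mutate_offspring,
    roulette_select,
)
from .errors import CapacityError, ConsistencyError, ValidationError
from .infection import (
    InfectionOutcome,
    KillModel,
    apply_mortality,
    attempt_infection,
    decay_free_phages,
    induce_prophages,
    resolve_lysis,
)
from .lattice import (
    AntibioticField,
    FreePhagePool,
    LatticeConfig,
    Location,
    Structure,
    deploy_antibiotic,
    diffuse_phages,
    mix_well,
    neighborhood_list,
    update_antibiotic,
)

EVENT_NAMES = (
    "births",
    "deaths_basal",
    "deaths_antibiotic",
    "deaths_lysis",
    "lyses",
    "inductions",
    "adsorptions",
    "lysogenizations",
    "aborted_superinfections",
    "resistant_encounters",
    "no_adsorptions",
    "decays",
    "burst_virions",
    "burst_capacity_lost",
)


@lru_cache(maxsize=32)
def _all_locations(width: int, height: int) -> tuple[Location, ...]:
    return tuple((x, y) for y in range(height) for x in range(width))


@dataclass
class InoculumEntry:
    kind: str  # "bacterium" | "phage"
    species: str
    count: int
    placement: str = "random"
    # bacteria only: prophages every inoculated cell carries
    initial_prophages: list[Prophage] = field(default_factory=list)
    # phages only: attachment phenotype of the inoculated virions
    phenotype: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("bacterium", "phage"):
            raise ValidationError(f"inoculum kind must be bacterium or phage, got {self.kind!r}")
        if self.count < 0:
            raise ValidationError("inoculum count must be >= 0")
        if self.placement != "random":
            raise ValidationError(f"unknown placement rule {self.placement!r}")


@dataclass
class ScheduleConfig:
    n_iterations: int = 100
    antibiotic_application_iteration: Optional[int] = None
    repeat_doses_every: Optional[int] = None
    inoculum: list[InoculumEntry] = field(default_factory=list)

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValidationError("n_iterations must be >= 0")
        t0 = self.antibiotic_application_iteration
        if t0 is not None and not 0 <= t0 < max(self.n_iterations, 1):
            raise ValidationError(
                "antibiotic_application_iteration must lie before n_iterations"
            )
        if self.repeat_doses_every is not None and self.repeat_doses_every < 1:
            raise ValidationError("repeat_doses_every must be >= 1")

    def antibiotic_due(self, iteration: int) -> bool:
        t0 = self.antibiotic_application_iteration
        if t0 is None or iteration < t0:
            return False
        if iteration == t0:
            return True
        if self.repeat_doses_every:
            return (iteration - t0) % self.repeat_doses_every == 0
        return False


class SimulationState:
    """Full mutable state of one run: lattice occupancy, free-virion pool,
    antibiotic field, iteration counter and current-iteration event tallies."""

    __slots__ = (
        "config",
        "registry",
        "bacteria",
        "phage_pool",
        "antibiotic",
        "kill",
        "iteration",
        "tallies",
    )

    def __init__(
        self,
        config: LatticeConfig,
        registry: SpeciesRegistry,
        antibiotic: AntibioticField,
        kill: KillModel,
    ):
        self.config = config
        self.registry = registry
        self.bacteria: dict[Location, Bacterium] = {}
        self.phage_pool = FreePhagePool(config)
        self.antibiotic = antibiotic
        self.kill = kill
        self.iteration = 0
        self.tallies: dict[str, int] = {}

    def tally(self, name: str, amount: int = 1) -> None:
        self.tallies[name] = self.tallies.get(name, 0) + amount

    def n_bacteria(self) -> int:
        return len(self.bacteria)

    def free_locations(self) -> list[Location]:
        occ = self.bacteria
        return [loc for loc in _all_locations(self.config.width, self.config.height) if loc not in occ]

    def validate(self) -> None:
        """Assert occupancy/capacity invariants; raises ConsistencyError."""
        cfg = self.config
        for loc, cell in self.bacteria.items():
            if not cfg.contains(loc):
                raise ConsistencyError(f"bacterium at off-grid location {loc}")
            if cell.location != loc:
                raise ConsistencyError(
                    f"bacterium location mismatch: key {loc} vs recorded {cell.location}"
                )
        cap = cfg.phage_cap_per_location
        for loc in self.phage_pool.locations():
            if not cfg.contains(loc):
                raise ConsistencyError(f"virions at off-grid location {loc}")
            n = sum(len(a) for a in self.phage_pool.buckets_at(loc).values())
            if n != self.phage_pool.count_at(loc):
                raise ConsistencyError(
                    f"virion count grid out of sync at {loc}: "
                    f"{self.phage_pool.count_at(loc)} vs {n}"
                )
            if n > cap:
                raise ConsistencyError(f"{n} virions at {loc} exceed the cap of {cap}")
        if int(self.phage_pool.counts.sum()) != sum(
            len(a)
            for loc in self.phage_pool.locations()
            for a in self.phage_pool.buckets_at(loc).values()
        ):
            raise ConsistencyError("virion count grid total out of sync")
        if (self.antibiotic.concentration < 0).any():
            raise ConsistencyError("negative antibiotic concentration")


class Trajectory:
    """Per-iteration counts by genotype/species/class plus event tallies.

    Rows are keyed by ``(entity_class, label)``; one record per iteration
    from 0 to ``n_iterations``.  All values are stored as floats (counts are
    integral-valued).
    """

    def __init__(self, meta: Optional[dict] = None):
        self.meta: dict = dict(meta or {})
        self.iterations: list[int] = []
        self.rows: list[dict[tuple[str, str], float]] = []
        self.snapshots: list[tuple] = []  # (iteration, x, y, layer, label_or_value)

    def record(self, iteration: int, values: dict[tuple[str, str], float]) -> None:
        self.iterations.append(iteration)
        self.rows.append(dict(values))

    @property
    def n_iterations(self) -> int:
        return 0 if not self.iterations else self.iterations[-1]

    def labels(self, entity_class: str) -> list[str]:
        out = set()
        for row in self.rows:
            out.update(lbl for cls, lbl in row if cls == entity_class)
        return sorted(out)

    def series(self, entity_class: str, label: str) -> np.ndarray:
        return np.array([row.get((entity_class, label), 0.0) for row in self.rows])

    def find_series(self, label: str) -> np.ndarray:
        """Look a label up across entity classes (must be unambiguous)."""
        classes = {cls for row in self.rows for cls, lbl in row if lbl == label}
        if not classes:
            raise ValidationError(f"label {label!r} never appears in this trajectory")
        if len(classes) > 1:
            raise ValidationError(
                f"label {label!r} is ambiguous across classes {sorted(classes)}"
            )
        return self.series(classes.pop(), label)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (it, cls, lbl, val)
            for it, row in zip(self.iterations, self.rows)
            for (cls, lbl), val in sorted(row.items())
        ]
        return pd.DataFrame(recs, columns=["iteration", "entity_class", "label", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: Optional[dict] = None) -> "Trajectory":
        traj = cls(meta=meta)
        for it, group in frame.groupby("iteration", sort=True):
            traj.record(
                int(it),
                {
                    (str(r.entity_class), str(r.label)): float(r.value)
                    for r in group.itertuples()
                },
            )
        return traj

    def __eq__(self, other) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return self.iterations == other.iterations and self.rows == other.rows

    def __repr__(self):
        return f"Trajectory({len(self.rows)} records, meta={self.meta})"


def snapshot_counts(state: SimulationState) -> dict[tuple[str, str], float]:
    """Current population counts by genotype, species, phenotype class."""
    registry = state.registry
    values: dict[tuple[str, str], float] = {}
    for sp in registry.bacterial_species:
        values[("bacterium_species", sp.name)] = 0.0
        values[("bacterium_class", f"{sp.name}:ab_resistant")] = 0.0
        values[("bacterium_class", f"{sp.name}:lysogen")] = 0.0
        values[("bacterium_class", f"{sp.name}:double_resistant")] = 0.0
        for k in range(1, len(registry.all_attachment_phenotypes) + 1):
            values[("bacterium_class", f"{sp.name}:phage_res_{k}")] = 0.0
    for cell in state.bacteria.values():
        name = cell.species.name
        values[("bacterium_genotype", cell.genotype_label)] = (
            values.get(("bacterium_genotype", cell.genotype_label), 0.0) + 1.0
        )
        values[("bacterium_species", name)] += 1.0
        if cell.antibiotic_resistant:
            values[("bacterium_class", f"{name}:ab_resistant")] += 1.0
        if cell.is_lysogen:
            values[("bacterium_class", f"{name}:lysogen")] += 1.0
        k = len(cell.resisted_phage_phenotypes)
        if k:
            values[("bacterium_class", f"{name}:phage_res_{k}")] += 1.0
        if cell.antibiotic_resistant and k:
            values[("bacterium_class", f"{name}:double_resistant")] += 1.0
    values[("bacterium_total", "all")] = float(len(state.bacteria))

    for ph in registry.all_attachment_phenotypes:
        values[("phage_phenotype", ph)] = 0.0
    for sp in registry.phage_species:
        values[("phage_species", sp.name)] = 0.0
    for (sp_name, phenotype), n in sorted(state.phage_pool.counts_by_key().items()):
        values[("phage_phenotype", phenotype)] += float(n)
        values[("phage_species", sp_name)] += float(n)
    values[("phage_total", "free")] = float(state.phage_pool.total())
    values[("antibiotic", "total_mass")] = state.antibiotic.total_mass()
    return values


def _record(state: SimulationState, trajectory: Trajectory, iteration: int) -> None:
    values = snapshot_counts(state)
    for name in EVENT_NAMES:
        values[("event", name)] = float(state.tallies.get(name, 0))
    trajectory.record(iteration, values)


def _record_snapshot(state: SimulationState, trajectory: Trajectory, iteration: int) -> None:
    for loc in sorted(state.bacteria):
        cell = state.bacteria[loc]
        trajectory.snapshots.append(
            (iteration, loc[0], loc[1], "bacterium", cell.genotype_label)
        )
    for loc in state.phage_pool.locations():
        for (sp, ph), ages in sorted(state.phage_pool.buckets_at(loc).items()):
            trajectory.snapshots.append(
                (iteration, loc[0], loc[1], "phage", f"{sp}:{ph}={len(ages)}")
            )
    conc = state.antibiotic.concentration
    ys, xs = np.nonzero(conc)
    for y, x in zip(ys.tolist(), xs.tolist()):
        trajectory.snapshots.append((iteration, x, y, "antibiotic", repr(conc[y, x])))


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------

_CONSUMED = (
    InfectionOutcome.ABORTED_SUPERINFECTION,
    InfectionOutcome.LYSIS_INITIATED,
    InfectionOutcome.LYSOGENIZED,
)


def _infection_pass(
    state: SimulationState, rng: np.random.Generator
) -> dict[Location, tuple]:
    """Every free virion co-located with a cell attempts infection.

    Returns the set of hosts committed to lysis as ``{location: (species,
    phenotype)}``.  The local virion density used by the lysis-lysogeny
    decision is snapshotted per location before its encounters are resolved.
    """
    pool = state.phage_pool
    registry = state.registry
    config = state.config
    pending: dict[Location, tuple] = {}
    locs = [loc for loc in pool.locations() if loc in state.bacteria]
    if not locs:
        return pending
    for oi in rng.permutation(len(locs)):
        loc = locs[int(oi)]
        host = state.bacteria[loc]
        local_count = pool.neighborhood_count(loc, config)
        keys = sorted(pool.buckets_at(loc))
        if len(keys) > 1:
            rng.shuffle(keys)
        for key in keys:
            sp_name, phenotype = key
            species = registry.get_phage(sp_name)
            k = len(pool.buckets_at(loc).get(key, ()))
            if k == 0:
                continue
            if phenotype in host.resisted_phage_phenotypes:
                state.tally("resistant_encounters", k)
                continue
            p_base = registry.host_range_prob(phenotype, host.species.name)
            if p_base * species.adsorption_prob <= 0.0:
                state.tally("no_adsorptions", k)
                continue
            for _ in range(k):
                virion = PhageParticle(species, phenotype, loc, 0)
                outcome = attempt_infection(virion, host, registry, local_count, rng)
                if outcome is InfectionOutcome.NO_ADSORPTION:
                    state.tally("no_adsorptions")
                    continue
                if outcome is InfectionOutcome.RESISTANT_HOST:
                    state.tally("resistant_encounters")
                    continue
                pool.pop_one(loc, key)
                state.tally("adsorptions")
                if outcome is InfectionOutcome.ABORTED_SUPERINFECTION:
                    state.tally("aborted_superinfections")
                elif outcome is InfectionOutcome.LYSOGENIZED:
                    if loc in pending:
                        # the host is already committed to lysis this
                        # iteration; the virion joins the doomed cell
                        host.intracellular_phages.append(virion)
                    else:
                        host.add_prophage(Prophage(species, phenotype))
                        state.tally("lysogenizations")
                else:  # LYSIS_INITIATED
                    host.intracellular_phages.append(virion)
                    if loc not in pending:
                        pending[loc] = (species, phenotype)
    return pending


def _induction_pass(
    state: SimulationState, pending: dict[Location, tuple], rng: np.random.Generator
) -> None:
    mic = state.kill.mic_threshold
    conc = state.antibiotic.concentration
    for loc in sorted(state.bacteria):
        if loc in pending:
            continue
        cell = state.bacteria[loc]
        if not cell.prophages:
            continue
        induced = induce_prophages(cell, float(conc[loc[1], loc[0]]), mic, rng)
        if induced is not None:
            pending[loc] = (induced.species, induced.attachment_phenotype)
            state.tally("inductions")


def _resolve_all_lyses(
    state: SimulationState, pending: dict[Location, tuple], rng: np.random.Generator
) -> None:
    locs = sorted(pending)
    for oi in rng.permutation(len(locs)):
        loc = locs[int(oi)]
        species, phenotype = pending[loc]
        host = state.bacteria[loc]
        particles = resolve_lysis(host, species, state, rng, parent_phenotype=phenotype)
        state.tally("lyses")
        state.tally("deaths_lysis")
        state.tally("burst_virions", len(particles))


def reproduce_into_free_space(state: SimulationState, rng: np.random.Generator):
    """Fill free locations by fitness-proportionate competition of nearby cells.

    Free locations are visited in uniformly random order; the live bacteria
    within the reproduction radius that have not yet divided this iteration
    compete through a roulette wheel and the winner's (possibly mutated)
    offspring takes the location.  Offspring placed earlier in the pass can
    parent later fills (asynchronous reproduction), but each individual cell
    divides at most once per iteration.
    """
    config = state.config
    if config.structure is Structure.SEMI_STRUCTURED:
        radius = config.reproduction_radius
    else:
        # structured: adjacent only; well-mixed: local competition after mixing
        radius = 1
    occupied = state.bacteria
    free = state.free_locations()
    if not free:
        return state
    now = state.iteration
    births = 0
    for oi in rng.permutation(len(free)):
        loc = free[int(oi)]
        candidates = [
            cell
            for nb in neighborhood_list(loc, radius, config)
            if (cell := occupied.get(nb)) is not None
            and cell.last_division_iteration != now
        ]
        if not candidates:
            continue
        parent = roulette_select(candidates, rng)
        parent.last_division_iteration = now
        child = mutate_offspring(parent, state.registry, rng)
        child.location = loc
        occupied[loc] = child
        births += 1
    state.tally("births", births)
    return state


def step(
    state: SimulationState,
    schedule: ScheduleConfig,
    rng: np.random.Generator,
    trajectory: Optional[Trajectory] = None,
    check_invariants: bool = False,
    snapshot_every: int = 0,
) -> SimulationState:
    """Advance the simulation by one iteration (phases 1-9, fixed order)."""

    def check():
        if check_invariants:
            state.validate()

    # 1. antibiotic deployment and field update
    if schedule.antibiotic_due(state.iteration):
        state.antibiotic = deploy_antibiotic(state.antibiotic, state.config, rng)
    state.antibiotic = update_antibiotic(state.antibiotic, state.config)
    check()
    # 2. mixing or diffusion
    if state.config.structure is Structure.WELL_MIXED:
        mix_well(state, rng)
    else:
        diffuse_phages(state, rng)
    check()
    # 3. free-phage decay
    decay_free_phages(state, rng)
    check()
    # 4. infection pass
    pending = _infection_pass(state, rng)
    check()
    # 5. prophage induction
    _induction_pass(state, pending, rng)
    check()
    # 6. lysis resolution
    _resolve_all_lyses(state, pending, rng)
    check()
    # 7. mortality
    apply_mortality(state, state.kill, rng)
    check()
    # 8. reproduction into free space
    reproduce_into_free_space(state, rng)
    check()
    # 9. record and reset tallies
    state.iteration += 1
    if trajectory is not None:
        _record(state, trajectory, state.iteration)
        if snapshot_every and state.iteration % snapshot_every == 0:
            _record_snapshot(state, trajectory, state.iteration)
    state.tallies = {}
    return state


def _place_inoculum(state: SimulationState, entries: list[InoculumEntry], rng) -> None:
    config = state.config
    n_loc = config.n_locations
    width = config.width
    total_bacteria = sum(e.count for e in entries if e.kind == "bacterium")
    if total_bacteria > n_loc:
        raise CapacityError(
            f"inoculum of {total_bacteria} bacteria exceeds the {n_loc} locations"
        )
    perm = rng.permutation(n_loc)
    cursor = 0
    for entry in entries:
        if entry.kind != "bacterium":
            continue
        species = state.registry.get_bacterial(entry.species)
        prophages = getattr(entry, "initial_prophages", [])
        for _ in range(entry.count):
            flat = int(perm[cursor])
            cursor += 1
            loc = (flat % width, flat // width)
            cell = Bacterium(species, prophages=list(prophages), location=loc)
            state.bacteria[loc] = cell
    cap = config.phage_cap_per_location
    for entry in entries:
        if entry.kind != "phage":
            continue
        species = state.registry.get_phage(entry.species)
        phenotype = getattr(entry, "phenotype", None) or species.attachment_phenotypes[0]
        placed = 0
        while placed < entry.count:
            flat = int(rng.integers(0, n_loc))
            loc = (flat % width, flat // width)
            if state.phage_pool.count_at(loc) < cap:
                state.phage_pool.add(loc, (species.name, phenotype), 1)
                placed += 1


def run(
    general_params,
    eco_setup,
    seed: int,
    check_invariants: bool = False,
) -> Trajectory:
    """Initialize a state from the config pair and execute all iterations.

    The master ``seed`` fully determines the run: identical (config, seed)
    pairs yield bitwise-identical trajectories.
    """
    rng = np.random.default_rng(seed)
    config = general_params.lattice_config()
    kill = general_params.kill_model()
    registry = eco_setup.build_registry()
    state = SimulationState(
        config=config,
        registry=registry,
        antibiotic=general_params.antibiotic_template(config),
        kill=kill,
    )
    entries = eco_setup.inoculum_entries()
    _place_inoculum(state, entries, rng)
    schedule = general_params.schedule_config(entries)
    trajectory = Trajectory(
        meta={
            "width": config.width,
            "height": config.height,
            "structure": config.structure.value,
            "seed": int(seed),
            "n_iterations": schedule.n_iterations,
            "capacity": config.n_locations,
        }
    )
    if check_invariants:
        state.validate()
    _record(state, trajectory, 0)
    snapshot_every = getattr(general_params, "snapshot_every", 0)
    if snapshot_every:
        _record_snapshot(state, trajectory, 0)
    state.tallies = {}
    for _ in range(schedule.n_iterations):
        step(
            state,
            schedule,
            rng,
            trajectory=trajectory,
            check_invariants=check_invariants,
            snapshot_every=snapshot_every,
        )
    return trajectory
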