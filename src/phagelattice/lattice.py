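"""The 2-D environment: grid topology, Moore neighborhoods, agent mixing and
diffusion, and the antibiotic concentration field.

Locations are ``(x, y)`` tuples with ``x`` the column (0 .. width-1) and ``y``
the row (0 .. height-1).  The amount of environmental structure ranges from
``well_mixed`` (the contents of every location are randomized each iteration,
as in a shaken liquid culture) through ``semi_structured`` (cells are fixed
but offspring and virions disperse within a Moore radius) to ``structured``
(cells never relocate and all dispersal is to adjacent locations only, as in
a biofilm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from typing import Optional

import numpy as np

from .errors import CapacityError, CoordinateError, ValidationError

Location = tuple[int, int]


class Topology(str, Enum):
    BOUNDED = "bounded"
    TOROIDAL = "toroidal"


class Structure(str, Enum):
    WELL_MIXED = "well_mixed"
    SEMI_STRUCTURED = "semi_structured"
    STRUCTURED = "structured"


@dataclass(frozen=True)
class LatticeConfig:
    """Static geometry and dispersal parameters of the grid.

    Parameters
    ----------
    width, height
        Grid dimensions (each >= 2).
    topology
        ``bounded`` clips neighborhoods at the edge; ``toroidal`` wraps them.
    structure
        Environmental structure mode (see module docstring).
    reproduction_radius
        Moore distance within which offspring may be placed when the
        environment is semi-structured.  Fully structured environments always
        reproduce to Moore distance 1.
    phage_diffusion_radius
        Moore distance free virions may travel in one iteration (0 disables
        movement).
    phage_cap_per_location
        Maximum number of free virions a single location can hold.
    """

    width: int = 100
    height: int = 100
    topology: Topology = Topology.BOUNDED
    structure: Structure = Structure.WELL_MIXED
    reproduction_radius: int = 3
    phage_diffusion_radius: int = 3
    phage_cap_per_location: int = 100

    def __post_init__(self):
        object.__setattr__(self, "topology", Topology(self.topology))
        object.__setattr__(self, "structure", Structure(self.structure))
        if self.width < 2 or self.height < 2:
            raise ValidationError("width and height must both be >= 2")
        if self.reproduction_radius < 1:
            raise ValidationError("reproduction_radius must be >= 1")
        if self.phage_diffusion_radius < 0:
            raise ValidationError("phage_diffusion_radius must be >= 0")
        if self.phage_cap_per_location < 1:
            raise ValidationError("phage_cap_per_location must be >= 1")
        if self.structure is Structure.STRUCTURED and self.reproduction_radius != 1:
            raise ValidationError(
                "structured environments fix cells in place: reproduction_radius must be 1"
            )

    @property
    def n_locations(self) -> int:
        return self.width * self.height

    def contains(self, location: Location) -> bool:
        x, y = location
        return 0 <= x < self.width and 0 <= y < self.height

    def all_locations(self) -> list[Location]:
        return [(x, y) for y in range(self.height) for x in range(self.width)]


@lru_cache(maxsize=None)
def _moore_offsets(radius: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        (dx, dy)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if (dx, dy) != (0, 0)
    )


@lru_cache(maxsize=200_000)
def _neighborhood_cached(
    location: Location, radius: int, width: int, height: int, topology: Topology
) -> tuple[Location, ...]:
    x, y = location
    out = []
    for dx, dy in _moore_offsets(radius):
        nx, ny = x + dx, y + dy
        if topology is Topology.TOROIDAL:
            out.append((nx % width, ny % height))
        elif 0 <= nx < width and 0 <= ny < height:
            out.append((nx, ny))
    # wrap-around can fold distinct offsets onto the same cell on tiny grids
    return tuple(sorted(set(out)))


def neighborhood(location: Location, radius: int, config: LatticeConfig) -> set[Location]:
    """All distinct locations within Moore (Chebyshev) distance 1..``radius``.

    The focal location is excluded.  Bounded grids drop off-grid coordinates;
    toroidal grids wrap them.
    """
    if not config.contains(location):
        raise CoordinateError(f"location {location} outside {config.width}x{config.height} grid")
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if radius == 0:
        return set()
    cells = _neighborhood_cached(
        location, radius, config.width, config.height, config.topology
    )
    return set(cells)


def neighborhood_list(location: Location, radius: int, config: LatticeConfig) -> tuple[Location, ...]:
    """Sorted tuple variant of :func:`neighborhood` (deterministic iteration)."""
    if not config.contains(location):
        raise CoordinateError(f"location {location} outside {config.width}x{config.height} grid")
    if radius == 0:
        return ()
    return _neighborhood_cached(location, radius, config.width, config.height, config.topology)


# ---------------------------------------------------------------------------
# Antibiotic field
# ---------------------------------------------------------------------------


class DeploymentMode(str, Enum):
    HOMOGENEOUS = "homogeneous"
    HETEROGENEOUS = "heterogeneous"


@dataclass
class AntibioticField:
    """Per-location antibiotic concentration with diffusion and decay.

    ``concentration`` is indexed ``[y, x]`` (row, column) in arbitrary dose
    units.  Each iteration every location keeps ``1 - diffusion_fraction`` of
    its concentration and shares the rest equally among its eight Moore-1
    neighbors; on bounded grids the share that would leave the grid stays in
    place, so diffusion never destroys mass.  Afterwards the whole field is
    scaled by ``1 - degradation_rate``.
    """

    concentration: np.ndarray
    degradation_rate: float = 0.0
    diffusion_fraction: float = 0.0
    deployment_mode: DeploymentMode = DeploymentMode.HOMOGENEOUS
    n_foci: int = 1
    dose: float = 0.0

    def __post_init__(self):
        self.deployment_mode = DeploymentMode(self.deployment_mode)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.ndim != 2:
            raise ValidationError("concentration must be a 2-D array")
        if (self.concentration < 0).any():
            raise ValidationError("concentrations must be >= 0")
        if not 0.0 <= self.degradation_rate <= 1.0:
            raise ValidationError("degradation_rate must lie in [0, 1]")
        if not 0.0 <= self.diffusion_fraction <= 1.0:
            raise ValidationError("diffusion_fraction must lie in [0, 1]")
        if self.dose < 0:
            raise ValidationError("dose must be >= 0")
        if self.n_foci < 1:
            raise ValidationError("n_foci must be >= 1")

    @classmethod
    def zeros(cls, config: LatticeConfig, **kwargs) -> "AntibioticField":
        return cls(np.zeros((config.height, config.width)), **kwargs)

    def total_mass(self) -> float:
        return float(self.concentration.sum())

    def at(self, location: Location) -> float:
        x, y = location
        return float(self.concentration[y, x])


def deploy_antibiotic(
    field: AntibioticField, config: LatticeConfig, rng: np.random.Generator
) -> AntibioticField:
    """Apply one antibiotic dose.

    Homogeneous mode sets every location to ``dose``; heterogeneous mode sets
    ``n_foci`` distinct, uniformly chosen locations to ``dose`` and leaves the
    rest untouched.
    """
    if field.dose < 0:
        raise ValidationError("dose must be >= 0")
    conc = field.concentration.copy()
    if field.deployment_mode is DeploymentMode.HOMOGENEOUS:
        conc[:, :] = field.dose
    else:
        n_loc = config.n_locations
        if field.n_foci > n_loc:
            raise CapacityError(
                f"n_foci={field.n_foci} exceeds the {n_loc} available locations"
            )
        flat = rng.choice(n_loc, size=field.n_foci, replace=False)
        ys, xs = np.divmod(flat, config.width)
        conc[ys, xs] = field.dose
    return replace(field, concentration=conc)


def update_antibiotic(field: AntibioticField, config: LatticeConfig) -> AntibioticField:
    """One step of 8-neighbor diffusion followed by first-order degradation."""
    c = field.concentration
    f = field.diffusion_fraction
    if f > 0:
        share = c * (f / 8.0)
        new = c * (1.0 - f)
        if config.topology is Topology.TOROIDAL:
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    new += np.roll(share, shift=(dy, dx), axis=(0, 1))
        else:
            h, w = c.shape
            n_neighbors = np.full((h, w), 8.0)
            n_neighbors[0, :] -= 3
            n_neighbors[-1, :] -= 3
            n_neighbors[:, 0] -= 3
            n_neighbors[:, -1] -= 3
            # corners were decremented twice for each adjoining edge: 8-3-3=2
            # but a corner has exactly 3 neighbors, so add 1 back
            n_neighbors[0, 0] += 1
            n_neighbors[0, -1] += 1
            n_neighbors[-1, 0] += 1
            n_neighbors[-1, -1] += 1
            # the share that cannot leave a bounded grid stays in place
            new += share * (8.0 - n_neighbors)
            padded = np.pad(share, 1)
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    new += padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
    else:
        new = c.copy()
    new *= 1.0 - field.degradation_rate
    np.maximum(new, 0.0, out=new)
    return replace(field, concentration=new)


# ---------------------------------------------------------------------------
# Free-phage pool
# ---------------------------------------------------------------------------

BucketKey = tuple[str, str]  # (phage species name, attachment phenotype)


class FreePhagePool:
    """Free virions, aggregated per location by (species, phenotype).

    Per-virion state beyond species and phenotype reduces to the age outside
    a host, so each bucket stores a flat list of ages.  Ages within a bucket
    are exchangeable with respect to every dynamic rule (decay is an
    age-independent hazard), which allows bulk vectorized updates.  A numpy
    grid of per-location totals is maintained incrementally so capacity and
    local-density queries are O(1).
    """

    __slots__ = ("_by_loc", "counts", "_width")

    def __init__(self, config: LatticeConfig):
        self._by_loc: dict[Location, dict[BucketKey, list[int]]] = {}
        self.counts = np.zeros((config.height, config.width), dtype=np.int64)
        self._width = config.width

    # -- mutation ----------------------------------------------------------
    def add(self, location: Location, key: BucketKey, ages) -> None:
        if isinstance(ages, int):
            ages = [0] * ages
        else:
            ages = list(ages)
        if not ages:
            return
        self._by_loc.setdefault(location, {}).setdefault(key, []).extend(ages)
        self.counts[location[1], location[0]] += len(ages)

    def pop_one(self, location: Location, key: BucketKey) -> int:
        """Remove one virion from a bucket and return its age."""
        bucket = self._by_loc[location][key]
        age = bucket.pop()
        if not bucket:
            del self._by_loc[location][key]
            if not self._by_loc[location]:
                del self._by_loc[location]
        self.counts[location[1], location[0]] -= 1
        return age

    def replace_all(
        self,
        by_loc: dict[Location, dict[BucketKey, list[int]]],
        counts: Optional[np.ndarray] = None,
    ) -> None:
        self._by_loc = by_loc
        if counts is not None:
            self.counts = counts
        else:
            self.counts = np.zeros_like(self.counts)
            for loc, buckets in by_loc.items():
                self.counts[loc[1], loc[0]] = sum(len(a) for a in buckets.values())

    # -- queries -----------------------------------------------------------
    def count_at(self, location: Location) -> int:
        return int(self.counts[location[1], location[0]])

    def buckets_at(self, location: Location) -> dict[BucketKey, list[int]]:
        return self._by_loc.get(location, {})

    def locations(self) -> list[Location]:
        return sorted(self._by_loc)

    def total(self) -> int:
        return int(self.counts.sum())

    def counts_by_key(self) -> dict[BucketKey, int]:
        out: dict[BucketKey, int] = {}
        for buckets in self._by_loc.values():
            for key, ages in buckets.items():
                out[key] = out.get(key, 0) + len(ages)
        return out

    def neighborhood_count(self, location: Location, config: LatticeConfig) -> int:
        """Virions at the focal location plus its Moore-1 neighborhood."""
        n = self.count_at(location)
        for cell in neighborhood_list(location, 1, config):
            n += int(self.counts[cell[1], cell[0]])
        return n

    def flatten_arrays(self):
        """Per-virion flat arrays ``(keys, key_ids, xs, ys, ages)``.

        ``keys`` is the sorted list of distinct bucket keys; the other four
        are parallel int64 arrays over all virions (deterministic order).
        """
        keys = sorted({k for b in self._by_loc.values() for k in b})
        key_index = {k: i for i, k in enumerate(keys)}
        b_key, b_x, b_y, b_len = [], [], [], []
        ages_chunks: list[list[int]] = []
        for loc in sorted(self._by_loc):
            for k in sorted(self._by_loc[loc]):
                a = self._by_loc[loc][k]
                b_key.append(key_index[k])
                b_x.append(loc[0])
                b_y.append(loc[1])
                b_len.append(len(a))
                ages_chunks.append(a)
        if not b_len:
            z = np.zeros(0, np.int64)
            return keys, z, z.copy(), z.copy(), z.copy()
        lengths = np.asarray(b_len, dtype=np.int64)
        key_ids = np.repeat(np.asarray(b_key, np.int64), lengths)
        xs = np.repeat(np.asarray(b_x, np.int64), lengths)
        ys = np.repeat(np.asarray(b_y, np.int64), lengths)
        flat_ages: list[int] = []
        for chunk in ages_chunks:
            flat_ages.extend(chunk)
        return keys, key_ids, xs, ys, np.asarray(flat_ages, dtype=np.int64)


def _regroup_pool(
    keys: list[BucketKey],
    dest_flat: np.ndarray,
    key_ids: np.ndarray,
    ages: np.ndarray,
    config: LatticeConfig,
) -> tuple[dict[Location, dict[BucketKey, list[int]]], np.ndarray]:
    """Rebuild the pool mapping + count grid from flat per-virion arrays."""
    width = config.width
    counts = np.bincount(dest_flat, minlength=config.n_locations).reshape(
        config.height, config.width
    )
    by_loc: dict[Location, dict[BucketKey, list[int]]] = {}
    if len(ages) == 0:
        return by_loc, counts
    order = np.lexsort((key_ids, dest_flat))
    dest_s, key_s, ages_s = dest_flat[order], key_ids[order], ages[order]
    boundaries = np.flatnonzero((np.diff(dest_s) != 0) | (np.diff(key_s) != 0))
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(dest_s)]))
    for s, e in zip(starts, ends):
        flat = int(dest_s[s])
        loc = (flat % width, flat // width)
        by_loc.setdefault(loc, {})[keys[int(key_s[s])]] = ages_s[s:e].tolist()
    return by_loc, counts


def mix_well(state, rng: np.random.Generator):
    """Randomize the contents of every location (well-mixed environments).

    Bacteria are assigned a uniformly random injection into the set of
    locations (at most one per location); free virions are redistributed
    uniformly over all locations subject to the per-location cap.  The
    multisets of agents are unchanged.  In any other structure mode this is
    the identity.
    """
    config: LatticeConfig = state.config
    if config.structure is not Structure.WELL_MIXED:
        return state
    n_loc = config.n_locations
    width = config.width

    cells = [state.bacteria[loc] for loc in sorted(state.bacteria)]
    if len(cells) > n_loc:
        raise CapacityError("more bacteria than lattice locations")
    if cells:
        flat = rng.choice(n_loc, size=len(cells), replace=False)
        new_bacteria = {}
        for cell, f in zip(cells, flat):
            loc = (int(f) % width, int(f) // width)
            cell.location = loc
            new_bacteria[loc] = cell
        state.bacteria = new_bacteria

    keys, key_ids, _xs, _ys, ages = state.phage_pool.flatten_arrays()
    total = len(ages)
    if total:
        cap = config.phage_cap_per_location
        if total > n_loc * cap:
            raise CapacityError("more free virions than total lattice capacity")
        dest = rng.integers(0, n_loc, size=total)
        dest = _enforce_cap_global(dest, n_loc, cap, rng)
        state.phage_pool.replace_all(*_regroup_pool(keys, dest, key_ids, ages, config))
    return state


def _enforce_cap_global(
    dest: np.ndarray, n_loc: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Reassign virions exceeding a location cap to remaining free capacity."""
    counts = np.bincount(dest, minlength=n_loc)
    if (counts <= cap).all():
        return dest
    # randomly chosen virions above the cap move to remaining free capacity
    excess = _excess_indices(dest, counts, cap, rng)
    room = cap - np.minimum(counts, cap)
    slots = np.repeat(np.arange(n_loc), room)
    take = rng.choice(len(slots), size=len(excess), replace=False)
    dest = dest.copy()
    dest[excess] = slots[take]
    return dest


def _sample_moves(
    xs: np.ndarray,
    ys: np.ndarray,
    radius: int,
    config: LatticeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform destination (flat index) within the Moore radius of each origin.

    The focal cell is a candidate.  On bounded grids, off-grid draws are
    redrawn, which makes the destination uniform over the in-grid candidates.
    """
    n = len(xs)
    dx = rng.integers(-radius, radius + 1, size=n)
    dy = rng.integers(-radius, radius + 1, size=n)
    nx, ny = xs + dx, ys + dy
    if config.topology is Topology.TOROIDAL:
        nx %= config.width
        ny %= config.height
    else:
        bad = (nx < 0) | (nx >= config.width) | (ny < 0) | (ny >= config.height)
        while bad.any():
            nb = int(bad.sum())
            nx[bad] = xs[bad] + rng.integers(-radius, radius + 1, size=nb)
            ny[bad] = ys[bad] + rng.integers(-radius, radius + 1, size=nb)
            bad = (nx < 0) | (nx >= config.width) | (ny < 0) | (ny >= config.height)
    return nx + ny * config.width


def diffuse_phages(state, rng: np.random.Generator):
    """Move every free virion to a uniform location within its Moore radius.

    Staying in place is one of the candidate moves.  Virions landing on
    locations that are already at capacity are redrawn among the cells of
    their origin's radius until they find room; the handful that cannot are
    placed sequentially (origin first, then expanding rings), so no virion is
    ever silently lost.
    """
    config: LatticeConfig = state.config
    radius = config.phage_diffusion_radius
    pool: FreePhagePool = state.phage_pool
    if radius == 0 or pool.total() == 0:
        return state
    cap = config.phage_cap_per_location

    keys, key_ids, xs, ys, ages = pool.flatten_arrays()
    dest = _sample_moves(xs, ys, radius, config, rng)
    counts = np.bincount(dest, minlength=config.n_locations)
    if (counts > cap).any():
        dest = _resolve_overflow_local(dest, xs, ys, radius, counts, cap, config, rng)
    state.phage_pool.replace_all(*_regroup_pool(keys, dest, key_ids, ages, config))
    return state


def _excess_indices(dest: np.ndarray, counts: np.ndarray, cap: int, rng) -> np.ndarray:
    """Randomly chosen virions that must leave over-capacity destinations."""
    perm = rng.permutation(len(dest))
    d = dest[perm]
    order = np.argsort(d, kind="stable")
    sorted_d = d[order]
    starts = np.searchsorted(sorted_d, np.arange(len(counts)), side="left")
    ranks = np.arange(len(d)) - starts[sorted_d]
    return perm[order[ranks >= cap]]


def _resolve_overflow_local(dest, xs, ys, radius, counts, cap, config, rng):
    """Redraw over-capacity placements near their origins until all fit."""
    dest = dest.copy()
    for _ in range(12):
        if (counts <= cap).all():
            return dest
        excess = _excess_indices(dest, counts, cap, rng)
        dest[excess] = _sample_moves(xs[excess], ys[excess], radius, config, rng)
        counts = np.bincount(dest, minlength=config.n_locations)
    # sequential fallback for the stubborn remainder (saturated radii)
    excess = _excess_indices(dest, counts, cap, rng)
    width = config.width
    for i in excess:
        origin = (int(xs[i]), int(ys[i]))
        of = origin[0] + origin[1] * width
        d = int(dest[i])
        if counts[d] <= cap:
            continue
        placed = False
        cands = (origin,) + neighborhood_list(origin, radius, config)
        for ci in rng.permutation(len(cands)):
            c = cands[int(ci)]
            cf = c[0] + c[1] * width
            if counts[cf] < cap:
                counts[d] -= 1
                counts[cf] += 1
                dest[i] = cf
                placed = True
                break
        if not placed:
            r = radius + 1
            while not placed:
                ring = neighborhood_list(origin, r, config)
                free = [c for c in ring if counts[c[0] + c[1] * width] < cap]
                if free:
                    c = free[int(rng.integers(0, len(free)))]
                    cf = c[0] + c[1] * width
                    counts[d] -= 1
                    counts[cf] += 1
                    dest[i] = cf
                    placed = True
                r += 1
                if r > max(config.width, config.height):
                    raise CapacityError("no free phage capacity anywhere on the lattice")
    return dest
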