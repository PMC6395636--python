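"""Replicate ensembles, emergence statistics, invasion metrics, and the
random-forest parameter-importance harness.

The summary statistics here operate on :class:`~phagelattice.engine.Trajectory`
objects and ensembles of them: emergence times (first iteration a genotype
reaches a detection threshold), their coefficient of variation across
replicates, Yates-corrected contingency tests on emergence counts,
population-level adsorption-rate estimation from free-virion decline, and
quadratic early-growth fits with an interaction (ANCOVA-style) test between
environments.

The sensitivity harness samples random parameter combinations, appends a
purposefully random dummy parameter, runs replicate simulations per
combination, and measures each parameter's permutation importance (%IncMSE,
the percentage increase in out-of-bag mean squared prediction error when the
parameter's values are permuted) in a random forest predicting the response.
The dummy's importance is the noise floor: parameters at or below it are
flagged non-important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import BaggingRegressor
from sklearn.metrics import mean_squared_error
from sklearn.tree import DecisionTreeRegressor

from . import scenarios
from .engine import Trajectory, run
from .errors import ValidationError

MAX_SEED = 2**31 - 1


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % MAX_SEED) for s in state]


@dataclass
class Ensemble:
    """Replicate trajectories sharing one configuration."""

    general: object
    eco: object
    seeds: list[int]
    trajectories: list[Trajectory]

    def __post_init__(self):
        if len(self.seeds) != len(self.trajectories):
            raise ValidationError("one trajectory per seed")

    @property
    def n_replicates(self) -> int:
        return len(self.trajectories)

    def stack(self, entity_class: str, label: str) -> np.ndarray:
        """(n_replicates, n_iterations + 1) array of one counted label."""
        return np.vstack([t.series(entity_class, label) for t in self.trajectories])

    def mean_ci(
        self, entity_class: str, label: str, level: float = 0.95
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-iteration mean and normal-approximation confidence band.

        With a single replicate (or zero variance) the band has width 0.
        """
        data = self.stack(entity_class, label)
        mean = data.mean(axis=0)
        n = data.shape[0]
        if n < 2:
            half = np.zeros_like(mean)
        else:
            z = scipy.stats.norm.ppf(0.5 + level / 2.0)
            half = z * data.std(axis=0, ddof=1) / np.sqrt(n)
        return mean, mean - half, mean + half


def run_ensemble(
    general,
    eco,
    n_replicates: int,
    master_seed: int,
    check_invariants: bool = False,
) -> Ensemble:
    """Run ``n_replicates`` seeded trajectories of one configuration."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    seeds = derive_seeds(master_seed, n_replicates)
    trajectories = [
        run(general, eco, seed, check_invariants=check_invariants) for seed in seeds
    ]
    return Ensemble(general, eco, seeds, trajectories)


# ---------------------------------------------------------------------------
# Emergence statistics
# ---------------------------------------------------------------------------


def emergence_time(
    trajectory: Trajectory, label: str, threshold: int = 100
) -> Optional[int]:
    """First iteration at which ``label`` is counted in >= ``threshold``
    individuals, or ``None`` if it never is."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    series = trajectory.find_series(label)
    hits = np.flatnonzero(series >= threshold)
    if len(hits) == 0:
        return None
    return int(trajectory.iterations[int(hits[0])])


def emergence_cv(
    ensemble: Ensemble, label: str, threshold: int = 100
) -> tuple[Optional[float], int]:
    """Coefficient of variation of emergence times across detected replicates.

    Replicates where the genotype never reaches the threshold are excluded;
    returns ``(cv, n_detected)`` with ``cv = None`` when fewer than two
    replicates detect.
    """
    times = [
        t
        for t in (
            emergence_time(traj, label, threshold) for traj in ensemble.trajectories
        )
        if t is not None
    ]
    if len(times) < 2:
        return None, len(times)
    arr = np.asarray(times, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None, len(times)
    return float(arr.std(ddof=1) / mean), len(times)


def emergence_contingency(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float]:
    """Yates-corrected chi-squared test on a 2x2 emergence table.

    The table is ``[[k1, n1 - k1], [k2, n2 - k2]]`` (detections vs
    non-detections in two conditions); 1 degree of freedom.  Identical
    proportions (including degenerate zero margins) give statistic 0, p 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValidationError("each condition needs at least one replicate")
        if not 0 <= k <= n:
            raise ValidationError(f"detections {k} outside [0, {n}]")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n_total = a + b + c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    num = max(0.0, abs(a * d - b * c) - n_total / 2.0) ** 2 * n_total
    den = (a + b) * (c + d) * col1 * col2
    stat = num / den
    if stat == 0.0:
        return 0.0, 1.0
    return float(stat), float(scipy.stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Population-level adsorption rate
# ---------------------------------------------------------------------------


def estimate_population_adsorption(
    ensemble: Ensemble,
    window: tuple[int, int] = (0, 5),
    min_points: int = 3,
    decay_prob: Optional[float] = None,
) -> float:
    """Population-level adsorption rate from early free-virion decline.

    For each trajectory the log free-virion count, corrected for the known
    per-iteration decay probability, is regressed on the cumulative host
    exposure ``sum_{s<t} H_s``; minus the slope is the per-host per-iteration
    adsorption rate.  The ensemble estimate is the mean over replicates.
    """
    if decay_prob is None:
        phages = getattr(ensemble.eco, "phages", None)
        if not phages:
            raise ValidationError("decay_prob not given and not recoverable from the config")
        decay_prob = phages[0].species.decay_prob
    if decay_prob >= 1.0:
        raise ValidationError("decay_prob must be < 1 to correct the decline")
    log_survival = np.log(1.0 - decay_prob)
    lo, hi = window
    rates = []
    for traj in ensemble.trajectories:
        phage = traj.series("phage_total", "free")
        hosts = traj.series("bacterium_total", "all")
        ts = np.arange(lo, min(hi + 1, len(phage)))
        ts = ts[phage[ts] > 0]
        if len(ts) < min_points:
            raise ValidationError(
                f"only {len(ts)} usable points in window {window}; need {min_points}"
            )
        exposure = np.concatenate(([0.0], np.cumsum(hosts)))  # sum over s < t
        x = exposure[ts]
        y = np.log(phage[ts]) - ts * log_survival
        slope = scipy.stats.linregress(x, y).slope
        rates.append(-slope)
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# Invasion metrics
# ---------------------------------------------------------------------------


@dataclass
class InvasionMetrics:
    frame: pd.DataFrame  # iteration, invader, resident_sensitive, resident_lysogen (counts + freqs), free_phage
    response_iteration: int
    response: float  # lysogenized residents at the response iteration


def invasion_metrics(
    trajectory: Trajectory,
    invader: str = "invader",
    resident: str = "resident",
    response_iteration: int = 15,
) -> InvasionMetrics:
    """Per-iteration frequencies of the three bacterial subpopulations of an
    invasion scenario plus the free-phage count.

    Frequencies are relative to lattice capacity, so the three subpopulation
    frequencies plus the empty-location fraction sum to 1.  The response
    variable is the lysogenized-resident count at ``response_iteration``.
    """
    capacity = trajectory.meta.get("capacity")
    if capacity is None:
        raise ValidationError("trajectory meta lacks the lattice capacity")
    inv = trajectory.series("bacterium_species", invader)
    res = trajectory.series("bacterium_species", resident)
    res_lys = trajectory.series("bacterium_class", f"{resident}:lysogen")
    if not inv.any() and invader not in trajectory.labels("bacterium_species"):
        raise ValidationError(f"no species {invader!r} in this trajectory")
    if not res.any() and resident not in trajectory.labels("bacterium_species"):
        raise ValidationError(f"no species {resident!r} in this trajectory")
    phage = trajectory.series("phage_total", "free")
    res_sens = res - res_lys
    frame = pd.DataFrame(
        {
            "iteration": trajectory.iterations,
            "invader": inv,
            "resident_sensitive": res_sens,
            "resident_lysogen": res_lys,
            "free_phage": phage,
            "invader_freq": inv / capacity,
            "resident_sensitive_freq": res_sens / capacity,
            "resident_lysogen_freq": res_lys / capacity,
        }
    )
    if response_iteration >= len(res_lys):
        raise ValidationError(
            f"trajectory has no iteration {response_iteration} (length {len(res_lys)})"
        )
    return InvasionMetrics(frame, response_iteration, float(res_lys[response_iteration]))


# ---------------------------------------------------------------------------
# Early-lysogenization quadratic fit + interaction test
# ---------------------------------------------------------------------------


@dataclass
class EarlyGrowthFit:
    coefficients: dict[str, np.ndarray]  # per environment: highest degree first
    interaction_statistic: float
    interaction_pvalue: float
    window: int


def early_lysogenization_fit(
    ensemble_a: Ensemble,
    ensemble_b: Ensemble,
    window: int = 10,
    label: str = "resident:lysogen",
    names: tuple[str, str] = ("A", "B"),
) -> EarlyGrowthFit:
    """Degree-2 polynomial fits of a count over the first ``window``
    iterations in two environments, plus a test for equal linear trend.

    The trend test is covariance-adjusted at the replicate level: a quadratic
    is fitted to every replicate trajectory and the linear-trend coefficients
    of the two environments are compared with a Welch t-test.  Points within
    a trajectory are strongly autocorrelated, so pooling them into one
    regression would overstate the evidence; one trend coefficient per
    replicate keeps the test calibrated under the null.
    """
    if window < 2:
        raise ValidationError("window must span at least 2 iterations")
    coefficients = {}
    trend_coeffs: dict[str, list[float]] = {}
    ts = np.arange(window + 1, dtype=float)
    for name, ens in zip(names, (ensemble_a, ensemble_b)):
        if ens.n_replicates < 2:
            raise ValidationError("each ensemble needs >= 2 replicates for the trend test")
        ys_all, trends = [], []
        for traj in ens.trajectories:
            series = traj.find_series(label) if "|" in label else traj.series(
                "bacterium_class", label
            )
            if len(series) <= window:
                raise ValidationError(
                    f"window {window} longer than trajectory ({len(series) - 1} iterations)"
                )
            ys = series[: window + 1]
            ys_all.append(ys)
            trends.append(float(np.polyfit(ts, ys, 2)[1]))
        coefficients[name] = np.polyfit(
            np.tile(ts, len(ys_all)), np.concatenate(ys_all), 2
        )
        trend_coeffs[name] = trends
    a = np.asarray(trend_coeffs[names[0]])
    b = np.asarray(trend_coeffs[names[1]])
    if a.var() == 0.0 and b.var() == 0.0:
        # degenerate deterministic ensembles: no evidence either way unless
        # the trends differ exactly
        stat = 0.0 if a.mean() == b.mean() else np.inf
        pval = 1.0 if a.mean() == b.mean() else 0.0
    else:
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        stat, pval = float(res.statistic), float(res.pvalue)
    return EarlyGrowthFit(coefficients, stat, pval, window)


# ---------------------------------------------------------------------------
# Parameter sweep + random-forest importance
# ---------------------------------------------------------------------------

#: Default parameter ranges for the invasion sweep.  Categorical parameters
#: are encoded as integer codes in the table (mapping in SweepTable.codes).
DEFAULT_SWEEP_RANGES: dict[str, tuple] = {
    "burst_size": ("randint", 10, 100),
    "adsorption_prob": ("uniform", 0.1, 1.0),
    "decay_prob": ("uniform", 0.01, 0.2),
    "induction_prob": ("uniform", 0.001, 0.05),
    "lysogeny_curve": ("choice", ("Lysogeny1", "Lysogeny2", "Lysogeny3")),
    "structure": ("choice", ("well_mixed", "semi_structured", "structured")),
}

DUMMY_COLUMN = "random_dummy"


@dataclass
class SweepTable:
    """Sampled parameter combinations, the dummy column, and the response."""

    frame: pd.DataFrame
    codes: dict[str, tuple] = field(default_factory=dict)  # column -> category labels
    response_column: str = "response"

    @property
    def parameter_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.response_column]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _sample_parameters(
    ranges: dict[str, tuple], n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, tuple]]:
    """Sample ``n`` combinations plus the dummy parameter (uniform {1,2,3})."""
    if not ranges:
        raise ValidationError("parameter ranges must not be empty")
    columns: dict[str, np.ndarray] = {}
    codes: dict[str, tuple] = {}
    for name, spec in ranges.items():
        law = spec[0]
        if law == "uniform":
            lo, hi = float(spec[1]), float(spec[2])
            columns[name] = rng.uniform(lo, hi, size=n)
        elif law == "randint":
            lo, hi = int(spec[1]), int(spec[2])
            columns[name] = rng.integers(lo, hi + 1, size=n).astype(float)
        elif law == "choice":
            values = tuple(spec[1])
            if not values:
                raise ValidationError(f"empty choice set for {name!r}")
            codes[name] = values
            columns[name] = rng.integers(0, len(values), size=n).astype(float)
        else:
            raise ValidationError(f"unknown sampling law {law!r} for {name!r}")
    columns[DUMMY_COLUMN] = rng.integers(1, 4, size=n).astype(float)
    return pd.DataFrame(columns), codes


def sample_sweep(
    ranges: dict[str, tuple],
    n_combinations: int,
    repeats: int,
    master_seed: int,
    scenario_name: str = "fig5_invasion",
    base_overrides: Optional[dict] = None,
    response_iteration: int = 15,
) -> SweepTable:
    """Sample parameter combinations and run replicate invasions for each.

    The response is the mean (over ``repeats`` seeded replicates) number of
    lysogenized resident bacteria at ``response_iteration``.
    """
    if n_combinations < 1 or repeats < 1:
        raise ValidationError("n_combinations and repeats must be >= 1")
    rng = np.random.default_rng(master_seed)
    frame, codes = _sample_parameters(ranges, n_combinations, rng)
    rep_seed_root = int(rng.integers(0, MAX_SEED))
    responses = []
    for i in range(n_combinations):
        overrides = dict(base_overrides or {})
        for name in ranges:
            value = frame.iloc[i][name]
            if name in codes:
                overrides[name] = codes[name][int(value)]
            elif name == "burst_size":
                overrides[name] = int(value)
            else:
                overrides[name] = float(value)
        general, eco = scenarios.scenario(scenario_name, overrides)
        seeds = derive_seeds((rep_seed_root + i) % MAX_SEED, repeats)
        values = []
        for seed in seeds:
            traj = run(general, eco, seed)
            values.append(
                invasion_metrics(traj, response_iteration=response_iteration).response
            )
        responses.append(float(np.mean(values)))
    frame["response"] = responses
    return SweepTable(frame, codes)


@dataclass
class ImportanceReport:
    """Permutation importances (%IncMSE) with the dummy as the noise floor."""

    importances: dict[str, float]
    ranking: list[str]
    dummy_importance: float
    non_important: list[str]
    oob_mse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.ranking,
                "pct_inc_mse": [self.importances[p] for p in self.ranking],
            }
        )


def permutation_importance(
    table: SweepTable,
    n_trees: int = 10_000,
    seed: int = 0,
    min_rows: int = 50,
) -> ImportanceReport:
    """Random-forest permutation importance of every parameter (incl. dummy).

    A bagged ensemble of regression trees (each split drawing from a third of
    the features, the standard regression-forest choice) is fitted to the
    response.  For each parameter, its column is permuted within each tree's
    out-of-bag samples; the importance is the percentage increase of the
    out-of-bag MSE relative to the unpermuted out-of-bag MSE.
    """
    frame = table.frame
    if len(frame) < min_rows:
        raise ValidationError(f"need at least {min_rows} rows, got {len(frame)}")
    params = table.parameter_columns
    X = frame[params].to_numpy(dtype=float)
    y = frame[table.response_column].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        warnings.warn("constant response: all importances are 0", stacklevel=2)
        zero = {p: 0.0 for p in params}
        return ImportanceReport(zero, sorted(params), 0.0, sorted(set(params) - {DUMMY_COLUMN}), 0.0)

    forest = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=1.0 / 3.0, random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=int(seed) % MAX_SEED,
        n_jobs=1,
    )
    forest.fit(X, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    base_mses = []
    perm_mses = np.zeros((n_trees, len(params)))
    for t, (tree, in_bag) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), np.unique(in_bag))
        if len(oob) == 0:
            base_mses.append(np.nan)
            perm_mses[t, :] = np.nan
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base = mean_squared_error(y_oob, tree.predict(X_oob))
        base_mses.append(base)
        for j in range(len(params)):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            perm_mses[t, j] = mean_squared_error(y_oob, tree.predict(Xp))
    base_arr = np.asarray(base_mses)
    valid = ~np.isnan(base_arr)
    mean_base = float(base_arr[valid].mean())
    importances = {}
    for j, p in enumerate(params):
        if mean_base <= 0:
            importances[p] = 0.0
        else:
            inc = perm_mses[valid, j].mean() - mean_base
            importances[p] = float(100.0 * inc / mean_base)
    ranking = sorted(params, key=lambda p: importances[p], reverse=True)
    dummy = importances.get(DUMMY_COLUMN, 0.0)
    non_important = [
        p for p in params if p != DUMMY_COLUMN and importances[p] <= dummy
    ]
    return ImportanceReport(importances, ranking, dummy, non_important, mean_base)
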