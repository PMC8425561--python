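"""Experiment harness: factorial sweeps and random-sampling sensitivity analysis.

Two designs cover the study's experiments.  The *cost sweep* varies the
handling cost at low competition; the *competition sweep* crosses
pollinator abundance (0.1–2 pollinators per flower) with three nectar
refill rates (1, 2.5 and 5 full refills per 1,000-step run) and the two
foraging strategies (scent-mark users vs non-users).  The sensitivity
harness draws parameter vectors i.i.d. uniform from each parameter's
variation interval, runs one simulation per draw, and ranks parameter
importance for mean nectar collected with a random-forest regression.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PARAMETER_INTERVALS, SimulationConfig
from .engine import run_simulation
from .metrics import summarize

__all__ = [
    "SweepDesign",
    "SensitivityDesign",
    "SensitivityResult",
    "run_sweep",
    "sample_sensitivity",
    "run_sensitivity",
    "cost_sweep_design",
    "competition_sweep_design",
]

logger = logging.getLogger(__name__)

#: experiment values from the study design
REFILL_LEVELS = (0.001, 0.0025, 0.005)
RATIO_LEVELS = (0.1, 0.3, 0.5, 1.0, 2.0)
COST_LEVELS = tuple(range(1, 11))

#: integer-valued parameters in sensitivity sampling
_INT_PARAMS = {"n_steps", "cost"}


def derive_seed(*keys: int) -> int:
    """Deterministic, well-mixed seed below 2**31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepDesign:
    """A full-factorial sweep: base config x axes x replicates.

    Every (cell, replicate) pair gets a unique seed derived from
    ``base_seed`` and its indices, so the whole table is reproducible
    bit-for-bit and the replicates are independent.
    """

    base: SimulationConfig = field(default_factory=SimulationConfig)
    axes: dict = field(default_factory=dict)  #: parameter name -> list of values
    replicates: int = 10
    base_seed: int = 0

    def cells(self) -> list[dict]:
        names = list(self.axes)
        return [dict(zip(names, combo)) for combo in itertools.product(*(self.axes[n] for n in names))]


def cost_sweep_design(replicates: int = 10, base_seed: int = 0, costs=COST_LEVELS,
                      refill_levels=REFILL_LEVELS) -> SweepDesign:
    """Handling-cost sweep at low competition (0.1 pollinators per flower)."""
    base = SimulationConfig(pollinator_ratio=0.1)
    return SweepDesign(
        base=base,
        axes={"cost": list(costs), "refill_coef": list(refill_levels),
              "use_scent": [True, False]},
        replicates=replicates,
        base_seed=base_seed,
    )


def competition_sweep_design(replicates: int = 10, base_seed: int = 0,
                             ratios=RATIO_LEVELS, refill_levels=REFILL_LEVELS) -> SweepDesign:
    """Competition x refill x strategy sweep (the main experiment)."""
    return SweepDesign(
        base=SimulationConfig(),
        axes={"pollinator_ratio": list(ratios), "refill_coef": list(refill_levels),
              "use_scent": [True, False]},
        replicates=replicates,
        base_seed=base_seed,
    )


def run_sweep(design: SweepDesign, carryover_window: int | None = None) -> pd.DataFrame:
    """Run every (cell, replicate) and return one tidy row per run.

    Columns: the swept parameters, ``replicate``, ``seed``, and all
    :class:`~scentforage.metrics.SummaryMetrics` fields.  A failing run is
    recorded with an ``error`` column instead of aborting the sweep.
    """
    rows = []
    for cell_index, cell in enumerate(design.cells()):
        for rep in range(design.replicates):
            seed = derive_seed(design.base_seed, cell_index, rep)
            row: dict = dict(cell)
            row["replicate"] = rep
            row["seed"] = seed
            try:
                config = design.base.replace(seed=seed, **cell)
                result = run_simulation(config)
                row.update(summarize(result, carryover_window).to_dict())
            except Exception as exc:  # per-run failures must not kill the sweep
                logger.warning("run failed for cell %s replicate %d: %s", cell, rep, exc)
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityDesign:
    """Random-sampling design for global sensitivity analysis.

    ``intervals`` maps parameter names to (low, high) sampling bounds
    (``n_steps`` and ``cost`` are sampled as integers); ``use_scent`` is a
    fair Boolean draw.  The random forest uses ``n_trees`` regression trees
    with ``max_features`` candidate variables per split.
    """

    intervals: dict = field(default_factory=lambda: dict(PARAMETER_INTERVALS))
    n_samples: int = 10_000
    n_trees: int = 2000
    max_features: int = 3
    response: str = "mean_nectar_collected"
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if name not in PARAMETER_INTERVALS:
                raise ValueError(f"unknown sensitivity parameter {name!r}")
            full_lo, full_hi = PARAMETER_INTERVALS[name]
            if not (full_lo <= lo <= hi <= full_hi):
                raise ValueError(
                    f"{name} sampling interval [{lo}, {hi}] outside valid range "
                    f"[{full_lo}, {full_hi}]"
                )


def reduced_sensitivity_design(n_samples: int = 300, base_seed: int = 0) -> SensitivityDesign:
    """Sanity-scale sensitivity design: narrow neighborhoods of the default
    experiment values, except the refill coefficient which keeps its full
    range (it is the factor whose dominance the analysis probes)."""
    return SensitivityDesign(
        intervals={
            "size_map": (45.0, 55.0),
            "n_steps": (900, 1100),
            "flower_density": (0.08, 0.12),
            "refill_coef": (0.001, 0.005),
            "pollinator_ratio": (0.2, 0.4),
            "cost": (3, 7),
            "inertia": (0.05, 0.15),
        },
        n_samples=n_samples,
        base_seed=base_seed,
    )


@dataclass
class SensitivityResult:
    samples: pd.DataFrame  #: one row per simulation: parameters + response
    importances: pd.Series  #: permutation importance, sorted descending
    variance_explained: float  #: out-of-bag R^2 of the forest


def sample_sensitivity(design: SensitivityDesign) -> pd.DataFrame:
    """Draw the parameter table and run one simulation per row.

    Sampling and simulation are independent of the regression step, so the
    table is produced even if the forest fit is skipped or fails.
    """
    rng = np.random.default_rng(derive_seed(design.base_seed, 7_001))
    rows = []
    for i in range(design.n_samples):
        params: dict = {}
        for name, (lo, hi) in design.intervals.items():
            if name in _INT_PARAMS:
                params[name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                params[name] = float(rng.uniform(lo, hi))
        params["use_scent"] = bool(rng.random() < 0.5)
        seed = derive_seed(design.base_seed, 7_002, i)
        config = SimulationConfig(seed=seed, **params)
        result = run_simulation(config)
        metrics = summarize(result).to_dict()
        rows.append({**params, "seed": seed, **metrics})
    return pd.DataFrame(rows)


def run_sensitivity(design: SensitivityDesign, samples: pd.DataFrame | None = None) -> SensitivityResult:
    """Full sensitivity analysis: sample, simulate, fit the forest, rank.

    The forest regresses the response (mean nectar collected by default)
    on the sampled parameters; importance is permutation importance on the
    fitted forest and the variance explained is the out-of-bag R^2.  The
    tested contract is the *ranking*, not the absolute importances.
    """
    if samples is None:
        samples = sample_sensitivity(design)
    try:
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.inspection import permutation_importance
    except ImportError as exc:  # pragma: no cover - backend always present in CI
        raise RuntimeError(
            "random-forest backend (scikit-learn) unavailable; "
            "the sample table was computed and can be analysed elsewhere"
        ) from exc

    predictors = list(design.intervals) + ["use_scent"]
    X = samples[predictors].astype(float)
    y = samples[design.response].astype(float)
    forest = RandomForestRegressor(
        n_estimators=design.n_trees,
        max_features=design.max_features,
        oob_score=True,
        random_state=derive_seed(design.base_seed, 7_003),
        n_jobs=1,
    )
    forest.fit(X, y)
    perm = permutation_importance(
        forest, X, y, n_repeats=10, random_state=derive_seed(design.base_seed, 7_004), n_jobs=1
    )
    importances = pd.Series(perm.importances_mean, index=predictors).sort_values(ascending=False)
    return SensitivityResult(
        samples=samples,
        importances=importances,
        variance_explained=float(forest.oob_score_),
    )
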