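"""Individual- and community-level summaries of a simulation.

The per-run report covers four quantities — nectar collected per
pollinator, nectar remaining per flower at the end, accepted visits per
flower, and pollen carryover per flower — each as a mean and a coefficient
of variation, plus the mean nectar gained per accepted visit.  Pollen
carryover of a focal flower counts the distinct flowers a pollinator goes
on to visit after leaving it, a proxy for how widely the focal flower's
pollen is disseminated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = ["SummaryMetrics", "coefficient_of_variation", "pollen_transfer", "summarize"]


@dataclass(frozen=True)
class SummaryMetrics:
    """Per-run aggregates; undefined values (e.g. a CV at zero mean) are NaN."""

    mean_nectar_collected: float
    cv_nectar_collected: float
    mean_nectar_per_visit: float
    mean_nectar_remaining: float
    cv_nectar_remaining: float
    mean_visits_per_flower: float
    cv_visits_per_flower: float
    mean_pollen_transfer: float
    cv_pollen_transfer: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean.

    Returns NaN — a missing value, not an error — when fewer than two
    values are given or the mean is not positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return math.nan
    mean = arr.mean()
    if mean <= 0:
        return math.nan
    return float(arr.std(ddof=1) / mean)


def pollen_transfer(events: pd.DataFrame, carryover_window: int | None = None) -> pd.Series:
    """Mean pollen carryover per flower, over flowers with >= 1 accepted visit.

    For every accepted visit (pollinator p, flower f), the carryover is the
    number of *distinct* flowers other than f that p subsequently visits
    (accepted visits only) before the end of the run; each flower's score
    averages the carryover over its own visits.  ``carryover_window``, when
    given, restricts "subsequently" to visits within that many steps of the
    focal visit (the default, no window, lets the run horizon bound
    dissemination).

    Returns a Series indexed by flower id; empty when there are no accepted
    visits.
    """
    acc = events[events["accepted"] == 1]
    if len(acc) == 0:
        return pd.Series(dtype=float, name="pollen_transfer")
    acc = acc.sort_values("step", kind="stable")
    per_flower: dict[int, list[int]] = {}
    for _, seq in acc.groupby("pollinator_id", sort=False):
        steps = seq["step"].to_numpy()
        flowers_visited = seq["flower_id"].to_numpy()
        n = len(flowers_visited)
        if carryover_window is None:
            # backward scan: `downstream` holds the distinct flowers visited
            # strictly after position i
            downstream: set[int] = set()
            counts = np.empty(n, dtype=int)
            for i in range(n - 1, -1, -1):
                f = int(flowers_visited[i])
                counts[i] = len(downstream) - (1 if f in downstream else 0)
                downstream.add(f)
            for i in range(n):
                per_flower.setdefault(int(flowers_visited[i]), []).append(int(counts[i]))
        else:
            for i in range(n):
                f = flowers_visited[i]
                horizon = steps[i] + carryover_window
                later = {
                    int(g)
                    for j, g in enumerate(flowers_visited[i + 1 :], start=i + 1)
                    if steps[j] <= horizon and g != f
                }
                per_flower.setdefault(int(f), []).append(len(later))
    out = pd.Series(
        {fid: float(np.mean(counts)) for fid, counts in sorted(per_flower.items())},
        name="pollen_transfer",
    )
    return out


def summarize(result: SimulationResult, carryover_window: int | None = None) -> SummaryMetrics:
    """Compute all per-run summary metrics from a complete result."""
    collected = result.per_pollinator["nectar_collected"].to_numpy()
    remaining = result.per_flower["nectar"].to_numpy()
    visits = result.per_flower["visit_count"].to_numpy()
    accepted = result.events[result.events["accepted"] == 1] if len(result.events) else result.events

    n_accepted = len(accepted)
    total_gained = float(accepted["nectar_gained"].sum()) if n_accepted else 0.0
    carry = pollen_transfer(result.events, carryover_window)

    return SummaryMetrics(
        mean_nectar_collected=float(collected.mean()) if collected.size else math.nan,
        cv_nectar_collected=coefficient_of_variation(collected),
        mean_nectar_per_visit=total_gained / n_accepted if n_accepted else math.nan,
        mean_nectar_remaining=float(remaining.mean()),
        cv_nectar_remaining=coefficient_of_variation(remaining),
        mean_visits_per_flower=float(visits.mean()),
        cv_visits_per_flower=coefficient_of_variation(visits),
        mean_pollen_transfer=float(carry.mean()) if len(carry) else math.nan,
        cv_pollen_transfer=coefficient_of_variation(carry.to_numpy()) if len(carry) else math.nan,
    )
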