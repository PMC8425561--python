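"""Flower state and dynamics: linear nectar refill and scent-mark fade.

Each flower holds nectar as a fraction of a unit capacity and a scent-mark
concentration in [0, 1].  Both are driven by a single linear clock, the
time since the last accepted visit: nectar refills at ``refill_coef`` per
step (capped at 1) while the mark fades at the same rate (floored at 0),
so ``nectar + scent == 1`` until the flower saturates.  A harvest empties
the flower, sets the mark to 1 and restarts the clock.  Never-visited
flowers start full and unmarked.

The clock pauses while a pollinator occupies the flower: nectar is not
secreted (and the mark does not fade) under a sitting visitor, so heavy
occupancy depresses a flower's nectar production.
"""

from __future__ import annotations

__all__ = ["FlowerState", "nectar_at", "scent_at", "harvest", "tick_flowers"]


def nectar_at(time_since_visit: float, refill_coef: float) -> float:
    """Nectar fraction of a visited flower ``time_since_visit`` steps after harvest.

    Linear in time, capped at capacity 1; e.g. coefficient 0.001 yields
    exactly one full refill over a 1,000-step run.
    """
    if time_since_visit < 0:
        raise ValueError(f"time_since_visit must be >= 0, got {time_since_visit}")
    return min(1.0, refill_coef * time_since_visit)


def scent_at(time_since_visit: float, refill_coef: float) -> float:
    """Scent-mark concentration ``time_since_visit`` steps after harvest.

    Complement of :func:`nectar_at` while unsaturated: the mark is a
    reliable cue of how much nectar has refilled.
    """
    if time_since_visit < 0:
        raise ValueError(f"time_since_visit must be >= 0, got {time_since_visit}")
    return max(0.0, 1.0 - refill_coef * time_since_visit)


class FlowerState:
    """One immobile flower on the torus.

    ``time_since_visit`` is ``None`` until the first accepted visit, which
    represents the initial condition (full nectar, no mark) exactly.
    ``occupant`` is the id of the pollinator currently on the flower, or
    ``None``; the engine guarantees at most one occupant.
    """

    __slots__ = ("id", "x", "y", "nectar", "scent", "time_since_visit", "visit_count", "occupant")

    def __init__(self, id: int, x: float, y: float):
        self.id = id
        self.x = x
        self.y = y
        self.nectar = 1.0
        self.scent = 0.0
        self.time_since_visit: int | None = None
        self.visit_count = 0
        self.occupant: int | None = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FlowerState(id={self.id}, pos=({self.x:.2f}, {self.y:.2f}), "
            f"nectar={self.nectar:.3f}, scent={self.scent:.3f}, "
            f"tau={self.time_since_visit}, visits={self.visit_count})"
        )


def harvest(flower: FlowerState) -> float:
    """Empty the flower and return the nectar gained.

    The pollinator takes all standing nectar; the flower is reset to
    (nectar 0, scent 1, clock 0) and its accepted-visit count incremented.
    """
    gain = flower.nectar
    flower.nectar = 0.0
    flower.scent = 1.0
    flower.time_since_visit = 0
    flower.visit_count += 1
    return gain


def tick_flowers(flowers: list[FlowerState], refill_coef: float) -> float:
    """Advance every flower's clock by one step; run after all pollinator actions.

    Visited, unoccupied flowers refill and their marks fade per the linear
    clock; never-visited flowers stay full and unmarked, and occupied
    flowers pause (no refill under a sitting pollinator).  Returns the
    total nectar delivered by refill during this tick (used for
    conservation checks).
    """
    delivered = 0.0
    for f in flowers:
        tau = f.time_since_visit
        if tau is None or f.occupant is not None:
            continue
        tau += 1
        f.time_since_visit = tau
        before = f.nectar
        f.nectar = min(1.0, refill_coef * tau)
        f.scent = max(0.0, 1.0 - refill_coef * tau)
        delivered += f.nectar - before
    return delivered
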