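"""Pollinator state machine: search, assess, handle.

A pollinator is always in one of three behavioural modes.  *Searching*: it
scans for a free, novel flower within its detection radius; if none is
found it takes a correlated-random-walk step (heading perturbed by a
zero-mean Gaussian turning angle, one length unit of travel).  *Assessing*:
standing on a flower it just landed on, it decides whether to harvest; a
scent-mark user runs a Bernoulli trial whose rejection probability equals
the mark concentration (fresh marks repel), a non-user always harvests.
*Handling*: it sits inside an accepted flower for ``cost`` steps.  One
action per step, so an accepted visit costs ``1 + cost`` steps of foraging
time plus the landing step.
"""

from __future__ import annotations

import math
from collections import deque
from typing import NamedTuple, Optional

import numpy as np

from .config import SimulationConfig
from .flowers import FlowerState, harvest
from .space import torus_distance, wrap

__all__ = [
    "SEARCHING",
    "ASSESSING",
    "HANDLING",
    "PollinatorState",
    "VisitEvent",
    "decide_visit",
    "detect_candidates",
    "sample_turn",
    "act",
]

SEARCHING = 0
ASSESSING = 1
HANDLING = 2

_TWO_PI = 2.0 * math.pi


class VisitEvent(NamedTuple):
    """One flower encounter, accepted or rejected — the raw material of all
    community metrics."""

    step: int
    pollinator_id: int
    flower_id: int
    accepted: bool
    nectar_gained: float


class PollinatorState:
    """One mobile forager on the torus.

    ``recent_flowers`` is the novelty memory: a bounded queue of the ids of
    the flowers most recently left or rejected, which the pollinator will
    not target while searching.  Depth 1 would exclude only the very last
    flower; slightly deeper memory (default 4) also prevents endless
    shuttling within a tight cluster of mutually in-range flowers.
    """

    __slots__ = (
        "id",
        "x",
        "y",
        "heading",
        "mode",
        "handling_timer",
        "current_flower",
        "recent_flowers",
        "nectar_collected",
        "visit_sequence",
        "uses_scent",
    )

    def __init__(
        self,
        id: int,
        x: float,
        y: float,
        heading: float,
        uses_scent: bool,
        novelty_memory: int = 4,
    ):
        self.id = id
        self.x = x
        self.y = y
        self.heading = heading
        self.mode = SEARCHING
        self.handling_timer = 0
        self.current_flower: Optional[int] = None
        self.recent_flowers: deque[int] = deque(maxlen=novelty_memory)
        self.nectar_collected = 0.0
        #: ordered (step, flower id) pairs of accepted visits
        self.visit_sequence: list[tuple[int, int]] = []
        self.uses_scent = uses_scent

    @property
    def last_flower(self) -> Optional[int]:
        """Id of the flower most recently left or rejected, or None."""
        return self.recent_flowers[-1] if self.recent_flowers else None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        mode = {SEARCHING: "searching", ASSESSING: "assessing", HANDLING: "handling"}[self.mode]
        return (
            f"PollinatorState(id={self.id}, pos=({self.x:.2f}, {self.y:.2f}), "
            f"mode={mode}, collected={self.nectar_collected:.3f})"
        )


def decide_visit(scent: float, rng: np.random.Generator, semantics: str = "repellent") -> bool:
    """Bernoulli visit decision of a scent-mark user standing on a flower.

    Under the default repellent semantics P(accept) = 1 - scent: a freshly
    marked (just-emptied) flower always repels, an unmarked (refilled) one
    is always accepted.  ``semantics="literal"`` inverts this
    (P(accept) = scent), which makes the mark an attractant; it exists only
    so the consequences of that reading can be examined.
    """
    if not (0.0 <= scent <= 1.0):
        raise ValueError(f"scent must be in [0, 1], got {scent}")
    p_accept = scent if semantics == "literal" else 1.0 - scent
    return rng.random() < p_accept


def detect_candidates(
    p: PollinatorState,
    flowers: list[FlowerState],
    detection_radius: float,
    size_map: float,
    in_range_ids: Optional[list[int]] = None,
) -> list[int]:
    """Ids of flowers the searching pollinator may move onto this step.

    A candidate must be within the detection radius, unoccupied (no other
    pollinator on or inside it, including same-step claims resolved earlier
    in the activation order) and novel, i.e. not in the pollinator's
    recent-flower memory.

    ``in_range_ids`` lets the engine pass a precomputed within-radius id
    list (flowers are immobile, so a spatial index answers range queries);
    when omitted the distances are computed directly.
    """
    if in_range_ids is None:
        in_range_ids = [
            f.id
            for f in flowers
            if torus_distance(p.x, p.y, f.x, f.y, size_map) <= detection_radius
        ]
    recent = p.recent_flowers
    return [i for i in in_range_ids if flowers[i].occupant is None and i not in recent]


def sample_turn(heading: float, inertia: float, rng: np.random.Generator) -> float:
    """New heading after one correlated-random-walk turn.

    The turning angle is Normal(0, sigma^2) with sigma = 2*pi*inertia
    radians, mapping the inertia range (0, 1) from near-ballistic to
    near-diffusive motion; the result is wrapped to [0, 2*pi).
    """
    return (heading + rng.normal(0.0, _TWO_PI * inertia)) % _TWO_PI


def act(
    p: PollinatorState,
    flowers: list[FlowerState],
    config: SimulationConfig,
    rng: np.random.Generator,
    step: int,
    in_range_ids: Optional[list[int]] = None,
) -> Optional[VisitEvent]:
    """Execute the pollinator's single action for this step.

    Exactly one branch runs, by mode:

    * handling — decrement the timer; on reaching zero release the flower,
      remember it as non-novel and resume searching (from the next step);
    * assessing — decide (non-users auto-accept); on accept harvest, start
      handling for ``cost`` steps and emit an accepted event; on reject
      release the flower, remember it as non-novel and emit a rejected
      event;
    * searching — move onto a uniformly chosen candidate flower and claim
      it (assessment happens next step), or take one correlated-random-walk
      step of unit length if no candidate exists.

    Returns the emitted :class:`VisitEvent`, if any.
    """
    mode = p.mode
    if mode == HANDLING:
        p.handling_timer -= 1
        if p.handling_timer == 0:
            f = flowers[p.current_flower]
            f.occupant = None
            p.recent_flowers.append(p.current_flower)
            p.current_flower = None
            p.mode = SEARCHING
        return None

    if mode == ASSESSING:
        f = flowers[p.current_flower]
        if not p.uses_scent or decide_visit(f.scent, rng, config.scent_semantics):
            gain = harvest(f)
            p.nectar_collected += gain
            p.visit_sequence.append((step, f.id))
            p.mode = HANDLING
            p.handling_timer = config.cost
            return VisitEvent(step, p.id, f.id, True, gain)
        f.occupant = None
        p.recent_flowers.append(f.id)
        p.current_flower = None
        p.mode = SEARCHING
        return VisitEvent(step, p.id, f.id, False, 0.0)

    # searching
    candidates = detect_candidates(p, flowers, config.detection_radius, config.size_map, in_range_ids)
    if candidates:
        fid = candidates[rng.integers(len(candidates))] if len(candidates) > 1 else candidates[0]
        f = flowers[fid]
        f.occupant = p.id
        p.current_flower = fid
        p.x = f.x
        p.y = f.y
        p.mode = ASSESSING
    else:
        h = sample_turn(p.heading, config.inertia, rng)
        p.heading = h
        p.x, p.y = wrap(p.x + math.cos(h), p.y + math.sin(h), config.size_map)
    return None
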