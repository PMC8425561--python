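"""Simulation engine: initialization, global schedule, replayable results.

Each step, every pollinator acts exactly once in a fresh uniform-random
permutation (fixed activation order would grant systematic priority in
flower-claiming conflicts); when all pollinators have acted, every flower's
nectar and scent mark are updated.  Flower claims are resolved sequentially
within the step: the first claimant in the permutation wins and later
searchers simply exclude the taken flower.  A single seeded random stream
drives everything, so identical (config, seed) pairs replay bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .flowers import FlowerState, tick_flowers
from .pollinators import (
    SEARCHING,
    PollinatorState,
    VisitEvent,
    act,
)

__all__ = ["World", "SimulationResult", "initialize", "step", "run_simulation"]


@dataclass
class SimulationResult:
    """Complete, replayable outcome of one run."""

    config: SimulationConfig
    seed: int
    per_pollinator: pd.DataFrame  #: columns id, nectar_collected, visits
    per_flower: pd.DataFrame  #: columns id, x, y, nectar, scent, visit_count
    events: pd.DataFrame  #: columns step, pollinator_id, flower_id, accepted, nectar_gained
    total_refill: float  #: nectar delivered by refill over the whole run

    @property
    def n_flowers(self) -> int:
        return len(self.per_flower)

    @property
    def n_pollinators(self) -> int:
        return len(self.per_pollinator)


class World:
    """Mutable state of a running simulation."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.step_index = 0
        self.total_refill = 0.0
        self.events: list[VisitEvent] = []

        n_flowers = config.n_flowers
        n_pollinators = config.n_pollinators
        fx = rng.uniform(0.0, config.size_map, n_flowers)
        fy = rng.uniform(0.0, config.size_map, n_flowers)
        self.flowers = [FlowerState(i, fx[i], fy[i]) for i in range(n_flowers)]

        px = rng.uniform(0.0, config.size_map, n_pollinators)
        py = rng.uniform(0.0, config.size_map, n_pollinators)
        headings = rng.uniform(0.0, 2.0 * math.pi, n_pollinators)
        self.pollinators = [
            PollinatorState(i, px[i], py[i], headings[i], config.use_scent,
                            config.novelty_memory)
            for i in range(n_pollinators)
        ]

        # flowers are immobile: one periodic KD-tree answers all range queries
        self._tree = cKDTree(np.column_stack([fx, fy]), boxsize=config.size_map)

    def check_occupancy_exclusive(self) -> None:
        """Assert each flower has at most one occupant and each pollinator
        occupies at most one flower; raises AssertionError on violation."""
        occupants = [f.occupant for f in self.flowers if f.occupant is not None]
        assert len(occupants) == len(set(occupants)), "one pollinator on several flowers"
        on_flower = [p.current_flower for p in self.pollinators if p.current_flower is not None]
        assert len(on_flower) == len(set(on_flower)), "several pollinators on one flower"
        for p in self.pollinators:
            if p.current_flower is not None:
                assert self.flowers[p.current_flower].occupant == p.id


def initialize(config: SimulationConfig, rng: np.random.Generator | None = None) -> World:
    """Set up a run: flowers and pollinators i.i.d. uniform on the torus,
    flowers full of nectar and unmarked, pollinators searching with uniform
    headings and zero harvest."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return World(config, rng)


def step(world: World) -> World:
    """Advance the world by one step.

    Pollinators act in a fresh uniform-random permutation; afterwards every
    flower updates its nectar and scent mark.
    """
    config = world.config
    pollinators = world.pollinators
    flowers = world.flowers
    rng = world.rng
    events = world.events
    now = world.step_index

    # Only pollinators searching at the start of the step perform a range
    # query this step (a rejection or handling end changes the mode during
    # the owner's own action, and that pollinator moves only next step), so
    # the within-radius lists can be batched before the activation loop.
    searcher_ids = [p.id for p in pollinators if p.mode == SEARCHING]
    in_range: dict[int, list[int]] = {}
    if searcher_ids:
        pts = np.array([(pollinators[i].x, pollinators[i].y) for i in searcher_ids])
        hits = world._tree.query_ball_point(pts, config.detection_radius)
        for i, ids in zip(searcher_ids, hits):
            ids.sort()  # deterministic order for the uniform tie-break
            in_range[i] = ids

    for i in rng.permutation(len(pollinators)):
        p = pollinators[i]
        ev = act(p, flowers, config, rng, now, in_range.get(p.id))
        if ev is not None:
            events.append(ev)

    world.total_refill += tick_flowers(flowers, config.refill_coef)
    world.step_index = now + 1
    return world


def run_simulation(config: SimulationConfig, check_invariants: bool = False) -> SimulationResult:
    """Run a complete simulation from ``config`` (seeded by ``config.seed``).

    ``check_invariants`` turns on per-step occupancy-exclusivity assertions
    (a debug mode; quadratic bookkeeping cost).
    """
    world = initialize(config)
    for _ in range(config.n_steps):
        step(world)
        if check_invariants:
            world.check_occupancy_exclusive()
    return collect_result(world)


def collect_result(world: World) -> SimulationResult:
    """Freeze a finished world into a :class:`SimulationResult`."""
    per_pollinator = pd.DataFrame(
        {
            "id": [p.id for p in world.pollinators],
            "nectar_collected": [p.nectar_collected for p in world.pollinators],
            "visits": [len(p.visit_sequence) for p in world.pollinators],
        }
    )
    per_flower = pd.DataFrame(
        {
            "id": [f.id for f in world.flowers],
            "x": [f.x for f in world.flowers],
            "y": [f.y for f in world.flowers],
            "nectar": [f.nectar for f in world.flowers],
            "scent": [f.scent for f in world.flowers],
            "visit_count": [f.visit_count for f in world.flowers],
        }
    )
    events = pd.DataFrame(world.events, columns=VisitEvent._fields)
    events["accepted"] = events["accepted"].astype(int)
    return SimulationResult(
        config=world.config,
        seed=world.config.seed,
        per_pollinator=per_pollinator,
        per_flower=per_flower,
        events=events,
        total_refill=world.total_refill,
    )
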