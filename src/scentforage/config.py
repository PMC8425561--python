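"""Simulation configuration: the single source of truth for a run.

A :class:`SimulationConfig` together with its ``seed`` fully determines a
simulation: flower and pollinator counts are deterministic functions of the
config, and one seeded pseudo-random stream drives every stochastic event
(placement, update order, turning angles, Bernoulli trials, tie-breaking),
so any run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["SimulationConfig", "PARAMETER_INTERVALS"]

#: Valid variation range of each tunable parameter (used for validation and
#: for uniform sampling in the sensitivity harness).
PARAMETER_INTERVALS: dict[str, tuple[float, float]] = {
    "size_map": (30.0, 100.0),
    "n_steps": (700, 1300),
    "flower_density": (0.02, 2.0),
    "refill_coef": (0.001, 0.005),
    "pollinator_ratio": (0.1, 2.0),
    "cost": (1, 10),
    "inertia": (0.01, 0.4),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one foraging simulation.

    Attributes
    ----------
    size_map:
        Side of the square toroidal meadow, in length units.
    n_steps:
        Foraging duration in discrete steps; one step is the time of one
        pollinator action.
    flower_density:
        Flowers per unit area.  The realized flower count is
        ``round(flower_density * size_map**2)``.
    refill_coef:
        Fraction of full nectar capacity regenerated per step; also the
        rate at which a scent mark fades (the mark is treated as a reliable
        signal of refill, so the two share one linear clock).
    pollinator_ratio:
        Pollinators per flower; realized pollinator count is
        ``round(pollinator_ratio * n_flowers)``.
    use_scent:
        Whether pollinators use scent marks as repellent cues.  Homogeneous
        within a run.
    cost:
        Handling time: steps spent inside an accepted flower.
    detection_radius:
        Distance within which a searching pollinator perceives flowers.
    inertia:
        Directional-persistence parameter in (0, 1); the turning-angle
        standard deviation is ``2 * pi * inertia`` radians, so small values
        give near-ballistic paths.
    seed:
        Seed of the single pseudo-random stream of the run.
    scent_semantics:
        ``"repellent"`` (default): probability of accepting a flower is
        ``1 - scent``, so marked flowers are avoided.  ``"literal"``:
        acceptance probability equals the scent concentration itself —
        exposed only to examine the consequences of the attractive reading.
    novelty_memory:
        Number of recently departed or rejected flowers a pollinator treats
        as non-novel and will not target while searching.  Must be >= 1;
        the default 4 is just deep enough to stop a forager cycling within
        a tight cluster of mutually in-range flowers.
    """

    size_map: float = 50.0
    n_steps: int = 1000
    flower_density: float = 0.1
    refill_coef: float = 0.0025
    pollinator_ratio: float = 0.3
    use_scent: bool = True
    cost: int = 5
    detection_radius: float = 1.0
    inertia: float = 0.1
    seed: int = 0
    scent_semantics: str = "repellent"
    novelty_memory: int = 4

    def __post_init__(self) -> None:
        if not self.size_map > 0:
            raise ValueError(f"size_map must be > 0, got {self.size_map}")
        if int(self.n_steps) != self.n_steps or self.n_steps < 0:
            raise ValueError(f"n_steps must be a non-negative integer, got {self.n_steps}")
        if not self.flower_density > 0:
            raise ValueError(f"flower_density must be > 0, got {self.flower_density}")
        if not (0 < self.refill_coef <= 1):
            raise ValueError(f"refill_coef must be in (0, 1], got {self.refill_coef}")
        if self.pollinator_ratio < 0:
            raise ValueError(f"pollinator_ratio must be >= 0, got {self.pollinator_ratio}")
        if int(self.cost) != self.cost or self.cost < 1:
            raise ValueError(f"cost must be an integer >= 1, got {self.cost}")
        if not self.detection_radius > 0:
            raise ValueError(f"detection_radius must be > 0, got {self.detection_radius}")
        if not (0 < self.inertia < 1):
            raise ValueError(f"inertia must be in (0, 1), got {self.inertia}")
        if int(self.novelty_memory) != self.novelty_memory or self.novelty_memory < 1:
            raise ValueError(f"novelty_memory must be an integer >= 1, got {self.novelty_memory}")
        if self.scent_semantics not in ("repellent", "literal"):
            raise ValueError(
                f"scent_semantics must be 'repellent' or 'literal', got {self.scent_semantics!r}"
            )
        if self.n_flowers < 1:
            raise ValueError(
                f"config realizes {self.n_flowers} flowers; need at least 1 "
                f"(flower_density={self.flower_density}, size_map={self.size_map})"
            )

    @property
    def n_flowers(self) -> int:
        """Realized flower count: density times area, rounded to nearest."""
        return int(round(self.flower_density * self.size_map**2))

    @property
    def n_pollinators(self) -> int:
        """Realized pollinator count: ratio times flower count, rounded."""
        return int(round(self.pollinator_ratio * self.n_flowers))

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        """Build a config from a flat mapping; unknown keys are an error."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(
                f"unknown config field(s): {', '.join(sorted(unknown))}; "
                f"valid fields are {', '.join(sorted(known))}"
            )
        return cls(**mapping)
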