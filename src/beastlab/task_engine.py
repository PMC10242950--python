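"""Stimulus schedule and calibrated social information.

The task shows five animal images in a fixed order (43, 58, 34, 44, 39
animals) and, after the first estimate E1, displays a "peer" estimate X.
X is calibrated to E1 so that every round offers a comparable relative
scope for adjustment, which removes distance-weighting effects (people
discount advice that sits far from their own estimate).  The calibration
used here is a symmetric multiplicative band: X = round(E1 * (1 + delta))
with |delta| uniform on ``delta_band`` and the sign taken from a balanced
per-round schedule, so offsets are scale-invariant in E1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

TRUE_COUNTS = (43, 58, 34, 44, 39)


@dataclass(frozen=True)
class TaskConfig:
    true_counts: tuple[int, ...] = TRUE_COUNTS
    delta_band: tuple[float, float] = (0.15, 0.25)
    #: +1 / -1 per round; balanced so a participant sees both directions.
    sign_schedule: tuple[int, ...] = (1, -1, 1, -1, 1)
    min_distance: int = 2
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        low, high = self.delta_band
        if not 0 < low < high < 1:
            raise ValueError(f"delta_band must satisfy 0 < low < high < 1, got {self.delta_band}")
        if len(self.sign_schedule) != len(self.true_counts):
            raise ValueError("sign_schedule must have one sign per round")
        if any(s not in (-1, 1) for s in self.sign_schedule):
            raise ValueError("sign_schedule entries must be +1 or -1")
        n_pos = sum(1 for s in self.sign_schedule if s == 1)
        if min(n_pos, len(self.sign_schedule) - n_pos) < 2:
            raise ValueError("sign_schedule must contain at least two of each sign")
        if self.min_distance < 1:
            raise ValueError("min_distance must be >= 1")


def stimulus_sequence(config: TaskConfig = TaskConfig()) -> tuple[int, ...]:
    """The five true animal counts, in presentation order."""
    return tuple(config.true_counts)


def generate_social_info(
    e1: int,
    round_index: int,
    config: TaskConfig = TaskConfig(),
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Draw the calibrated social information X for a round.

    X = round(e1 * (1 + delta)), |delta| ~ U(delta_band), sign from the
    round's slot in ``sign_schedule``.  If integer rounding collapses the
    offset below ``min_distance`` (only possible for small E1), delta is
    resampled up to 100 times and then the offset is forced to exactly
    ``min_distance``; a forced offset that would push X below 1 flips to the
    positive side.  X != E1 always, so s is computable on every round.
    """
    if e1 < 1:
        raise ValueError(f"e1 must be >= 1, got {e1}")
    if not 1 <= round_index <= len(config.sign_schedule):
        raise ValueError(f"round_index must be 1..{len(config.sign_schedule)}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sign = config.sign_schedule[round_index - 1]
    low, high = config.delta_band
    for _ in range(100):
        delta = sign * rng.uniform(low, high)
        x = int(round(e1 * (1.0 + delta)))
        if x >= 1 and abs(x - e1) >= config.min_distance:
            return x
    # Deterministic fallback for tiny E1 where the band cannot produce
    # an offset of min_distance.
    x = e1 + sign * config.min_distance
    if x < 1:
        x = e1 + config.min_distance
    return x
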