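"""SNR-priority acquisition: repeated 2x2 block averaging and level selection.

Averaging each 2x2 pixel block and decimating quarters the pixel count M
and halves the noise standard deviation.  If the specimen signal is
oversampled (features span many pixels), the signal sd survives almost
unchanged, so the measured SNR doubles per step.  The stability index
M*SNR^4/(2*SNR^2+1) then grows ~4x per step -- until averaging starts to
erode the signal itself, after which the index falls.  The sweep records
the full index-vs-level curve and picks the maximizing level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frame_metrics import (
    Frame,
    FramePair,
    SnrEstimate,
    StabilityIndex,
    estimate_snr,
    stability_index,
)

__all__ = [
    "ReductionLevel",
    "ReductionSweep",
    "block_average",
    "reduce_pair",
    "reduction_sweep",
    "select_optimal_reduction",
]

#: Default number of 2x2 reduction repetitions to sweep (levels 0..5).
DEFAULT_R_MAX = 5


def block_average(f: Frame) -> Frame:
    """Average non-overlapping 2x2 pixel blocks, halving each dimension.

    A trailing odd row/column is discarded (padding would bias the block
    means).  Raises ``ValueError`` once a frame can no longer support the
    reduction (output would be smaller than 2x2).
    """
    px = f.pixels
    h2, w2 = px.shape[0] // 2, px.shape[1] // 2
    if h2 < 2 or w2 < 2:
        raise ValueError(
            f"reduction exhausted: {px.shape[1]}x{px.shape[0]} frame cannot be halved"
        )
    out = px[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))
    return Frame(out, meta=f.meta)


def can_reduce(f: Frame) -> bool:
    """True if one more 2x2 reduction keeps the frame at least 2x2."""
    return f.height // 2 >= 2 and f.width // 2 >= 2


def reduce_pair(p: FramePair) -> FramePair:
    """Reduce both frames of a pair in lockstep (keeps the pair registered)."""
    return FramePair(block_average(p.t1), block_average(p.t2))


@dataclass(frozen=True)
class ReductionLevel:
    """One point on the index-vs-repetitions curve."""

    level: int
    pair: FramePair
    estimate: SnrEstimate
    index: StabilityIndex

    @property
    def snr(self) -> float:
        return self.estimate.snr

    @property
    def m(self) -> int:
        return self.estimate.m

    @property
    def index_value(self) -> float:
        return self.index.value

    @property
    def width(self) -> int:
        return self.pair.t1.width

    @property
    def height(self) -> int:
        return self.pair.t1.height


@dataclass(frozen=True)
class ReductionSweep:
    """Ordered reduction levels 0..r and the index-maximizing choice."""

    levels: tuple[ReductionLevel, ...]
    chosen: int

    def to_frame(self) -> pd.DataFrame:
        """Sweep as a flat table (one row per level)."""
        rows = [
            {
                "level": lv.level,
                "width": lv.width,
                "height": lv.height,
                "m": lv.m,
                "snr": lv.snr,
                "index_value": lv.index_value,
                "chosen": int(i == self.chosen),
            }
            for i, lv in enumerate(self.levels)
        ]
        return pd.DataFrame(rows)


def _argmax_first(values: list[float]) -> int:
    """Index of the maximum; ties broken toward the smallest index."""
    best, best_i = -math.inf, 0
    for i, v in enumerate(values):
        if v > best:
            best, best_i = v, i
    return best_i


def reduction_sweep(p: FramePair, r_max: int = DEFAULT_R_MAX) -> ReductionSweep:
    """Evaluate SNR and stability index at reduction levels 0..r_max.

    Both frames are reduced in lockstep so the covariance estimator stays
    valid at every level.  The sweep truncates early once frames can no
    longer be halved; ``chosen`` points at the global index maximum, ties
    broken toward the smaller level (preserve resolution when
    indifferent).
    """
    if r_max < 0:
        raise ValueError(f"r_max must be >= 0, got {r_max}")
    levels: list[ReductionLevel] = []
    cur = p
    for r in range(r_max + 1):
        est = estimate_snr(cur)
        idx = stability_index(est.snr, est.m)
        levels.append(ReductionLevel(level=r, pair=cur, estimate=est, index=idx))
        if r == r_max or not can_reduce(cur.t1):
            break
        cur = reduce_pair(cur)
    chosen = _argmax_first([lv.index_value for lv in levels])
    return ReductionSweep(levels=tuple(levels), chosen=chosen)


def select_optimal_reduction(sweep: ReductionSweep) -> ReductionLevel:
    """Return the level with maximal index value (ties: smaller level)."""
    if not sweep.levels:
        raise ValueError("empty reduction sweep")
    return sweep.levels[sweep.chosen]


def reduce_n(f: Frame, n: int) -> Frame:
    """Apply ``n`` 2x2 reductions to a single frame."""
    for _ in range(int(n)):
        f = block_average(f)
    return f


def reduce_pair_n(p: FramePair, n: int) -> FramePair:
    """Apply ``n`` lockstep 2x2 reductions to a pair."""
    for _ in range(int(n)):
        p = reduce_pair(p)
    return p
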