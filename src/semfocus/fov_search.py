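"""Active field-of-view search by beam shift.

When the current field's texture is too weak for a steady focus metric
(the sufficiency check fails), a stronger field can usually be found
nearby without moving the stage: small beam shifts translate the scanned
region.  Candidates are evaluated with the same reduced-frame SNR /
stability-index metric as the focusing chain and ranked from strongest
to weakest.  Because the SNR is invariant to display contrast and
brightness, the ranking depends only on true specimen texture -- and it
keeps working under defocus, since blur attenuates every candidate's
signal alike (a rough focus is still recommended first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .frame_metrics import FramePair, SnrEstimate, StabilityIndex, estimate_snr, stability_index
from .snr_priority import reduce_pair_n
from .virtual_sem import AcquisitionParams, OpticsState, VirtualSpecimen, render_pair

__all__ = [
    "FieldCandidate",
    "SimulatedFieldProvider",
    "ring_shifts",
    "evaluate_field",
    "search_best_field",
    "candidates_to_frame",
]

#: A provider yields a registered frame pair for a beam-shift offset.
PairProvider = Callable[[tuple[float, float]], FramePair]


@dataclass(frozen=True)
class FieldCandidate:
    """One evaluated field of view around the observation region."""

    shift: tuple[float, float]
    estimate: SnrEstimate
    index: StabilityIndex

    @property
    def snr(self) -> float:
        return self.estimate.snr

    @property
    def index_value(self) -> float:
        return self.index.value


class SimulatedFieldProvider:
    """Renders candidate fields from a virtual specimen.

    All candidates share one optics state (same defocus/astigmatism);
    only the beam shift varies.  Each render consumes two fresh noise
    ticks so candidates have independent noise but remain reproducible
    from the acquisition seed.
    """

    def __init__(
        self,
        specimen: VirtualSpecimen,
        optics: OpticsState,
        acq: AcquisitionParams,
        start_tick: int = 0,
    ) -> None:
        self.specimen = specimen
        self.optics = optics
        self.acq = acq
        self._tick = int(start_tick)

    def __call__(self, shift: tuple[float, float]) -> FramePair:
        optics = replace(self.optics, beam_shift=tuple(shift))
        pair = render_pair(self.specimen, optics, self.acq, tick=self._tick)
        self._tick += 2
        return pair


def ring_shifts(radius: float, n: int = 8, include_center: bool = True) -> list[tuple[float, float]]:
    """Default candidate grid: the center plus ``n`` shifts on a ring."""
    shifts: list[tuple[float, float]] = [(0.0, 0.0)] if include_center else []
    for i in range(int(n)):
        ang = 2.0 * math.pi * i / n
        shifts.append((radius * math.cos(ang), radius * math.sin(ang)))
    return shifts


def evaluate_field(
    source: PairProvider, shift: tuple[float, float], reduction: int = 0
) -> FieldCandidate:
    """Evaluate one candidate field at the configured reduction level."""
    pair = reduce_pair_n(source(shift), int(reduction))
    est = estimate_snr(pair)
    idx = stability_index(est.snr, est.m)
    return FieldCandidate(shift=tuple(float(v) for v in shift), estimate=est, index=idx)


def search_best_field(
    candidates: Sequence[tuple[float, float]],
    source: PairProvider,
    reduction: int = 0,
) -> list[FieldCandidate]:
    """Evaluate all candidate shifts, sorted by index value, descending.

    The head of the list is the recommended field.  The sort is stable,
    so exact ties keep the caller's scan order.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate shift")
    evaluated = [evaluate_field(source, s, reduction) for s in candidates]
    return sorted(evaluated, key=lambda c: -c.index_value)


def candidates_to_frame(ranked: Sequence[FieldCandidate]) -> pd.DataFrame:
    """Ranked candidates as a flat table (rank 1 = recommended field)."""
    return pd.DataFrame(
        {
            "dx": [c.shift[0] for c in ranked],
            "dy": [c.shift[1] for c in ranked],
            "snr": [c.snr for c in ranked],
            "index_value": [c.index_value for c in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
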