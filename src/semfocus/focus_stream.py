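"""Temporal processing of the focus-metric stream.

A focusing or stigmator sweep produces a time-ordered series of frames
with a changing control value.  This module turns that stream into a
graph of SNR (or covariance) versus time, applying three stabilisers --
each causal, so the graph can drive a live adjustment:

* frame integration: pixelwise mean of the last n frames (noise sd down
  by sqrt(n), at the cost of a time lag),
* SNR-priority reduction: a fixed number of lockstep 2x2 reductions,
* a causal moving average over the last ``window`` graph points.

"Just focus" is the control setting where the smoothed graph changes
from rising to falling; :func:`detect_just_focus` accepts the global
maximum only when its rise and fall both clear a prominence threshold,
so a graph that is pure noise yields "no peak" rather than a random
tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .frame_metrics import (
    STATUS_ZERO_NOISE,
    Frame,
    FramePair,
    estimate_snr,
    stability_index,
)
from .snr_priority import ReductionLevel, reduce_pair_n

__all__ = [
    "FocusSample",
    "FocusGraph",
    "SweepEvaluator",
    "moving_average",
    "integrate_frames",
    "evaluate_sweep",
    "detect_just_focus",
    "assess_sufficiency",
    "select_reduction_for_frames",
]

#: Defaults matching the experimentally chosen operating point: a moving
#: average over four graph points and integration over four frames.
DEFAULT_WINDOW = 4
DEFAULT_INTEGRATION = 4


def moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Causal moving mean: at position k, the mean of the last
    min(window, k+1) values.  NaN entries are skipped (a window that is
    all-NaN stays NaN).  Output length equals input length."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    return pd.Series(x).rolling(window, min_periods=1).mean().to_numpy()


def integrate_frames(frames: Sequence[Frame], n: int) -> Frame:
    """Pixelwise mean of the last ``n`` frames (sliding integration)."""
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(frames) < n:
        raise ValueError(f"need at least {n} frames, have {len(frames)}")
    tail = frames[-n:]
    shape = tail[0].pixels.shape
    for f in tail[1:]:
        if f.pixels.shape != shape:
            raise ValueError("frame dimensions changed mid-stream")
    mean = np.mean([f.pixels for f in tail], axis=0)
    return Frame(mean, meta=tail[-1].meta)


@dataclass(frozen=True)
class FocusSample:
    """One graph point: control value and raw/smoothed metric."""

    tick: int
    control: float
    snr_raw: float
    snr_smooth: float
    status: str


@dataclass
class FocusGraph:
    """Time-ordered metric graph for one focusing/stigmator sweep."""

    samples: list[FocusSample] = field(default_factory=list)
    window: int = DEFAULT_WINDOW
    integration: int = 1
    metric: str = "snr"
    peak_tick: int | None = None

    @property
    def ticks(self) -> np.ndarray:
        return np.array([s.tick for s in self.samples], dtype=int)

    @property
    def controls(self) -> np.ndarray:
        return np.array([s.control for s in self.samples], dtype=float)

    @property
    def raw(self) -> np.ndarray:
        return np.array([s.snr_raw for s in self.samples], dtype=float)

    @property
    def smooth(self) -> np.ndarray:
        return np.array([s.snr_smooth for s in self.samples], dtype=float)

    def control_at(self, tick: int) -> float:
        for s in self.samples:
            if s.tick == tick:
                return s.control
        raise KeyError(f"no sample at tick {tick}")

    @property
    def lag(self) -> float:
        """Group delay (ticks) of the causal chain: the metric value
        emitted at tick k is centred on data from tick k - lag."""
        return (2 * self.integration - 1) / 2.0 + (self.window - 1) / 2.0

    def focus_estimate(self, peak_tick: int, controls: Sequence[float] | None = None) -> float:
        """Just-focus control estimate with the known causal lag removed.

        Integration and the moving average are causal, so the peak
        sample is centred ``lag`` ticks in the past; this reads the
        control value at that centre (from ``controls``, indexed by
        tick, or from the recorded samples).
        """
        centre = max(0, int(round(peak_tick - self.lag)))
        if controls is not None:
            return float(controls[centre])
        best = min(self.samples, key=lambda s: abs(s.tick - centre))
        return best.control

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tick": self.ticks,
                "control": self.controls,
                "snr_raw": self.raw,
                "snr_smooth": self.smooth,
                "status": [s.status for s in self.samples],
            }
        )
        df["peak"] = (df["tick"] == self.peak_tick).astype(int) if self.peak_tick is not None else 0
        return df


class SweepEvaluator:
    """Incrementally consumes (frame, control) and maintains a FocusGraph.

    Metric samples pair two *disjoint* block means of ``integration``
    consecutive frames each (frames k-2n+1..k-n vs k-n+1..k), so the two
    members never share a noise realisation and the covariance SNR stays
    unbiased.  With integration = 1 this is plain consecutive-frame
    pairing (t_{k-1}, t_k).  Samples therefore start at tick 2n-1.
    """

    def __init__(
        self,
        reduction: int = 0,
        window: int = DEFAULT_WINDOW,
        integration: int = 1,
        metric: str = "snr",
    ) -> None:
        if metric not in ("snr", "cov"):
            raise ValueError(f"metric must be 'snr' or 'cov', got {metric!r}")
        if integration < 1:
            raise ValueError("integration must be >= 1")
        self.reduction = int(reduction)
        self.window = int(window)
        self.integration = int(integration)
        self.metric = metric
        self._frames: list[Frame] = []
        self._raw: list[float] = []
        self._graph = FocusGraph(
            samples=[], window=self.window, integration=self.integration, metric=metric
        )
        self._count = 0

    def update(self, frame: Frame, control: float, tick: int | None = None) -> FocusSample | None:
        """Feed one frame; returns the new graph sample once available."""
        if tick is None:
            tick = self._count
        self._count += 1
        n = self.integration
        self._frames.append(frame)
        # keep only what the two disjoint integration blocks need
        if len(self._frames) > 2 * n:
            self._frames = self._frames[-2 * n :]
        if len(self._frames) < 2 * n:
            return None
        a = integrate_frames(self._frames[: n], n) if n > 1 else self._frames[0]
        b = integrate_frames(self._frames[n:], n) if n > 1 else self._frames[1]
        pair = reduce_pair_n(FramePair(a, b), self.reduction)
        try:
            est = estimate_snr(pair)
            status = est.status
            value = est.cov if self.metric == "cov" else est.snr
            if status == STATUS_ZERO_NOISE:
                value = math.nan  # sentinel: excluded from smoothing/detection
        except ValueError:
            status = "degenerate"
            value = math.nan
        self._raw.append(value)
        tail = self._raw[-self.window :]
        finite = [v for v in tail if math.isfinite(v)]
        smooth = float(np.mean(finite)) if finite else math.nan
        sample = FocusSample(
            tick=int(tick),
            control=float(control),
            snr_raw=value,
            snr_smooth=smooth,
            status=status,
        )
        self._graph.samples.append(sample)
        return sample

    def graph(self) -> FocusGraph:
        return self._graph


def _controls_from_frames(frames: Sequence[Frame], control_key: str) -> list[float]:
    controls = []
    for f in frames:
        if f.meta is None or control_key not in f.meta:
            raise ValueError(f"frame metadata lacks control key {control_key!r}")
        controls.append(float(f.meta[control_key]))
    return controls


def select_reduction_for_frames(
    frames: Sequence[Frame],
    r_max: int = 5,
    n_pairs: int = 4,
    min_pixels: int = 64,
) -> int:
    """Choose a reduction level from the head of a stream.

    Averages the estimated SNR over up to ``n_pairs`` disjoint
    consecutive pairs, evaluates the stability index per candidate
    level, and returns the maximizing level among those retaining at
    least ``min_pixels`` pixels (very small frames give covariance
    statistics too scattered to act on).
    """
    pairs: list[FramePair] = []
    for i in range(0, min(len(frames) - 1, 2 * n_pairs - 1), 2):
        pairs.append(FramePair(frames[i], frames[i + 1]))
    if not pairs:
        raise ValueError("need at least two frames to select a reduction level")
    best_r, best_val = 0, -math.inf
    for r in range(r_max + 1):
        snrs = []
        m = None
        try:
            for p in pairs:
                reduced = reduce_pair_n(p, r)
                est = estimate_snr(reduced)
                m = est.m
                if math.isfinite(est.snr):
                    snrs.append(est.snr)
        except ValueError:
            break  # reduction exhausted (or degenerate pair): stop the scan
        if m is None or m < min_pixels or not snrs:
            break
        val = stability_index(float(np.mean(snrs)), m).value
        if val > best_val:
            best_r, best_val = r, val
    return best_r


def evaluate_sweep(
    frames: Sequence[Frame],
    controls: Sequence[float] | None = None,
    control_key: str = "defocus",
    reduction: int | str = 0,
    window: int = DEFAULT_WINDOW,
    integration: int = 1,
    metric: str = "snr",
    r_max: int = 5,
) -> FocusGraph:
    """Run the full metric chain over an ordered frame stream.

    ``reduction`` may be a fixed level or ``"auto"`` to select the level
    from the head of the stream via the stability index.  Control values
    come either from ``controls`` or from frame metadata under
    ``control_key``.
    """
    if controls is None:
        controls = _controls_from_frames(frames, control_key)
    if len(controls) != len(frames):
        raise ValueError("controls and frames must have equal length")
    if reduction == "auto":
        reduction = select_reduction_for_frames(frames, r_max=r_max)
    ev = SweepEvaluator(
        reduction=int(reduction), window=window, integration=integration, metric=metric
    )
    for i, (f, c) in enumerate(zip(frames, controls)):
        ev.update(f, c, tick=i)
    return ev.graph()


def detect_just_focus(graph: FocusGraph, prominence: float | None = None) -> int | None:
    """Tick of the just-focus peak, or None if the graph is unusable.

    The global maximum of the smoothed metric is accepted only if both
    its rise (peak minus the minimum before it) and fall (peak minus the
    minimum after it) exceed a prominence threshold.  The default
    threshold estimates the raw-series noise sd robustly from second
    differences (insensitive to a smooth underlying trend) and scales it
    for the series length and smoothing window:

        threshold = 4 * sigma_hat * sqrt(2 * ln N) / sqrt(window),

    which keeps the expected extreme range of an information-free
    (pure-noise) graph below threshold, so such graphs report no peak.
    """
    smooth = graph.smooth
    raw = graph.raw
    ticks = graph.ticks
    valid = np.isfinite(smooth)
    if valid.sum() < 3:
        return None
    vs = smooth[valid]
    vt = ticks[valid]
    k = int(np.argmax(vs))
    if prominence is None:
        fr = raw[np.isfinite(raw)]
        if fr.size < 4:
            return None
        d2 = fr[2:] - 2.0 * fr[1:-1] + fr[:-2]
        mad = float(np.median(np.abs(d2 - np.median(d2))))
        sigma = 1.4826 * mad / math.sqrt(6.0)
        n = fr.size
        prominence = 4.0 * sigma * math.sqrt(2.0 * math.log(n)) / math.sqrt(max(graph.window, 1))
    rise = vs[k] - float(np.min(vs[: k + 1]))
    fall = vs[k] - float(np.min(vs[k:]))
    if rise > prominence and fall > prominence:
        return int(vt[k])
    return None


def assess_sufficiency(level: "ReductionLevel | float", threshold: float) -> str:
    """Step-3 check: is the stability index large enough to act on?

    Returns ``"sufficient"`` iff the index value meets ``threshold``;
    an insufficient outcome is the trigger for searching nearby fields
    of view for a stronger signal.
    """
    value = level.index_value if isinstance(level, ReductionLevel) else float(level)
    return "sufficient" if value >= threshold else "insufficient"
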