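"""Virtual scanning-electron-microscope video source with known ground truth.

Forward model of a TV-scan SEM stream for testing the focusing chain:

specimen texture --crop at beam shift / magnification-->
  --convolve with an elliptical (astigmatic) Gaussian PSF-->
  --add per-frame independent zero-mean noise-->  frame

* The specimen is a seeded stationary Gaussian random texture with a
  controllable correlation length (``feature_scale``), optionally
  modulated by planted high- or low-strength patches for field-search
  scenarios.  Weak stationary texture stands in for a sputtered metal
  film whose fine structure gives only faint contrast.
* Defocus and astigmatism blur with principal sigmas
  ``sigma_u = psf_scale*|defocus + a|`` and ``sigma_v = psf_scale*|defocus - a|``
  where ``a = hypot(astig_x, astig_y)`` and the axis angle is
  ``atan2(astig_y, astig_x)/2`` (two-line-foci stigmator model: at
  defocus = +-a one principal direction comes to a line focus).
* Noise sd scales as ``dwell_scale / sqrt(current * dwell)``: halving
  probe current or dwell time raises the noise amplitude by sqrt(2).
  Frame-to-frame noise is independent while the signal repeats -- exactly
  the statistical model the two-frame covariance estimator assumes.

Everything is reproducible from (seed, parameters); per-frame noise is
keyed on (seed, tick) so streams can be regenerated frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import fftconvolve

from .frame_metrics import Frame

__all__ = [
    "VirtualSpecimen",
    "OpticsState",
    "AcquisitionParams",
    "generate_specimen",
    "render_frame",
    "ground_truth_snr",
    "noise_sd",
    "stream",
    "focus_ramp",
    "stigmator_ramp",
    "constant_trajectory",
    "calibrate_dwell_scale",
]

# Below this sigma (pixels) a blur direction is treated as a delta.
_SIGMA_EPS = 1e-3


@dataclass(frozen=True)
class VirtualSpecimen:
    """Noise-free ground-truth intensity map.

    ``texture`` already includes the mean level and any strength
    modulation; ``texture_sd`` is the nominal signal sd of the
    unmodulated background.
    """

    texture: np.ndarray = field(compare=False)
    feature_scale: float
    mean_level: float
    texture_sd: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.texture.shape


@dataclass(frozen=True)
class OpticsState:
    """Instrument control vector at one instant.

    defocus : focal offset in arbitrary focal units (0 = just focus)
    astig_x, astig_y : stigmator offsets ((0, 0) = corrected)
    beam_shift : (dx, dy) field translation in specimen pixels
    magnification : crop scale factor (>1 samples a smaller specimen
        region onto the same output grid, i.e. oversampling)
    current : probe current, pA
    """

    defocus: float = 0.0
    astig_x: float = 0.0
    astig_y: float = 0.0
    beam_shift: tuple[float, float] = (0.0, 0.0)
    magnification: float = 1.0
    current: float = 26.0

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")
        if self.current <= 0:
            raise ValueError("current must be > 0")
        object.__setattr__(self, "beam_shift", tuple(float(v) for v in self.beam_shift))


@dataclass(frozen=True)
class AcquisitionParams:
    """Scan geometry, timing and noise scaling.

    ``dwell_scale`` is the instrument constant mapping exposure
    (current * dwell time) to noise amplitude; the default puts a
    26 pA TV scan (25 frames/s) near SNR 0.3 for a unit-sd texture,
    emulating a visibly very noisy fast-scan image.  ``psf_scale`` is
    the blur sigma in pixels per focal unit.
    """

    width: int = 640
    height: int = 480
    frame_rate: float = 25.0
    dwell_scale: float = 3.4
    seed: int = 0
    psf_scale: float = 1.5
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("frame dimensions must be at least 2x2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def frame_time(self) -> float:
        """Per-frame acquisition time, s (1 / frame_rate)."""
        return 1.0 / self.frame_rate


def generate_specimen(
    shape: tuple[int, int] = (768, 768),
    feature_scale: float = 8.0,
    texture_sd: float = 1.0,
    mean_level: float = 100.0,
    block_size: int = 1,
    patches: Sequence[dict] | None = None,
    seed: int = 0,
) -> VirtualSpecimen:
    """Seeded smooth random texture with correlation length ``feature_scale``.

    Parameters
    ----------
    block_size : int
        If > 1, the texture is generated at reduced resolution and
        replicated so it is exactly constant on block_size x block_size
        pixel blocks -- the idealised oversampled regime in which block
        averaging removes noise only.
    patches : sequence of dict
        Planted signal-strength modulations for field-search scenarios.
        Each patch has ``offset`` (dx, dy) from the specimen centre,
        ``radius`` (pixels, Gaussian) and ``strength`` (multiplier on
        the background texture sd inside the patch).
    """
    if feature_scale < 1:
        raise ValueError("feature_scale must be >= 1")
    block_size = int(block_size)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    H, W = int(shape[0]), int(shape[1])
    rng = np.random.default_rng(seed)
    h0 = -(-H // block_size)
    w0 = -(-W // block_size)
    base = rng.standard_normal((h0, w0))
    sigma = feature_scale / block_size
    if sigma > 0:
        base = gaussian_filter(base, sigma, mode="wrap")
    base -= base.mean()
    sd = base.std()
    if sd > 0:
        base /= sd
    if block_size > 1:
        base = np.kron(base, np.ones((block_size, block_size)))[:H, :W]
    strength = np.ones((H, W))
    if patches:
        yy, xx = np.mgrid[0:H, 0:W]
        cy0, cx0 = (H - 1) / 2.0, (W - 1) / 2.0
        for p in patches:
            dx, dy = p.get("offset", (0.0, 0.0))
            radius = float(p["radius"])
            s = float(p["strength"])
            r2 = (yy - (cy0 + dy)) ** 2 + (xx - (cx0 + dx)) ** 2
            strength += (s - 1.0) * np.exp(-r2 / (2.0 * radius**2))
    texture = mean_level + texture_sd * base * strength
    return VirtualSpecimen(
        texture=texture,
        feature_scale=float(feature_scale),
        mean_level=float(mean_level),
        texture_sd=float(texture_sd),
    )


def _psf_params(optics: OpticsState, psf_scale: float) -> tuple[float, float, float]:
    a = math.hypot(optics.astig_x, optics.astig_y)
    theta = 0.5 * math.atan2(optics.astig_y, optics.astig_x) if a > 0 else 0.0
    sigma_u = psf_scale * abs(optics.defocus + a)
    sigma_v = psf_scale * abs(optics.defocus - a)
    return sigma_u, sigma_v, theta


def psf_sigmas(optics: OpticsState, acq: AcquisitionParams) -> tuple[float, float, float]:
    """Principal blur sigmas (pixels) and axis angle (radians) of the PSF."""
    return _psf_params(optics, acq.psf_scale)


def _psf_kernel(sigma_u: float, sigma_v: float, theta: float) -> np.ndarray | None:
    if sigma_u < _SIGMA_EPS and sigma_v < _SIGMA_EPS:
        return None
    radius = int(math.ceil(4.0 * max(sigma_u, sigma_v, 0.5)))
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    su = max(sigma_u, _SIGMA_EPS)
    sv = max(sigma_v, _SIGMA_EPS)
    k = np.exp(-(u**2) / (2.0 * su**2) - (v**2) / (2.0 * sv**2))
    return k / k.sum()


def _render_clean(
    spec: VirtualSpecimen, optics: OpticsState, acq: AcquisitionParams
) -> np.ndarray:
    """Noise-free crop -> blur pipeline shared by all render paths."""
    kernel = _psf_kernel(*_psf_params(optics, acq.psf_scale))
    margin = (kernel.shape[0] - 1) // 2 if kernel is not None else 0
    h, w = acq.height, acq.width
    mag = optics.magnification
    dx, dy = optics.beam_shift
    H, W = spec.shape
    cy = (H - 1) / 2.0 + dy
    cx = (W - 1) / 2.0 + dx
    # The core field of view (blur margin excluded) must lie inside the
    # specimen; the margin may reflect at the borders.
    half_h = (h - 1) / 2.0 / mag
    half_w = (w - 1) / 2.0 / mag
    if (
        cy - half_h < 0
        or cy + half_h > H - 1
        or cx - half_w < 0
        or cx + half_w > W - 1
    ):
        raise ValueError(
            f"field of view outside specimen: shift={optics.beam_shift}, "
            f"mag={mag}, frame={w}x{h}, specimen={W}x{H}"
        )
    hm, wm = h + 2 * margin, w + 2 * margin
    y0 = cy - (hm - 1) / 2.0
    x0 = cx - (wm - 1) / 2.0
    if (
        mag == 1.0
        and abs(y0 - round(y0)) < 1e-9
        and abs(x0 - round(x0)) < 1e-9
    ):
        # Grid-aligned crop: exact slice, no interpolation.
        padded = np.pad(spec.texture, margin, mode="reflect") if margin else spec.texture
        iy = int(round(y0)) + margin
        ix = int(round(x0)) + margin
        window = padded[iy : iy + hm, ix : ix + wm]
    else:
        ys = cy + (np.arange(hm) - (hm - 1) / 2.0) / mag
        xs = cx + (np.arange(wm) - (wm - 1) / 2.0) / mag
        grid = np.meshgrid(ys, xs, indexing="ij")
        window = map_coordinates(spec.texture, grid, order=1, mode="reflect")
    if kernel is None:
        return np.ascontiguousarray(window)
    return fftconvolve(window, kernel, mode="valid")


def noise_sd(
    optics: OpticsState, acq: AcquisitionParams, dwell_multiplier: float = 1.0
) -> float:
    """Noise amplitude: dwell_scale / sqrt(current * dwell time)."""
    dwell = acq.frame_time * dwell_multiplier
    return acq.dwell_scale / math.sqrt(optics.current * dwell)


def _frame_meta(
    optics: OpticsState, acq: AcquisitionParams, tick: int, dwell_multiplier: float
) -> dict:
    return {
        "tick": int(tick),
        "frame_time": acq.frame_time,
        "dwell": acq.frame_time * dwell_multiplier,
        "noise_sd": noise_sd(optics, acq, dwell_multiplier),
        "defocus": optics.defocus,
        "astig_x": optics.astig_x,
        "astig_y": optics.astig_y,
        "beam_shift_x": optics.beam_shift[0],
        "beam_shift_y": optics.beam_shift[1],
        "magnification": optics.magnification,
        "current": optics.current,
    }


def _add_noise(
    clean: np.ndarray,
    nsd: float,
    rng: np.random.Generator,
    model: str,
) -> np.ndarray:
    if model == "gaussian":
        return clean + rng.normal(0.0, nsd, clean.shape)
    # Poisson mode: counting noise whose sd at the mean intensity matches
    # the Gaussian-mode amplitude.  Signal-dependent, so the covariance
    # model holds only approximately (documented limitation).
    mean_i = float(clean.mean())
    if mean_i <= 0 or nsd <= 0:
        raise ValueError("poisson noise requires positive mean intensity and noise sd")
    gain = mean_i / nsd**2  # counts per intensity unit
    return rng.poisson(np.clip(clean, 0.0, None) * gain) / gain


def render_frame(
    spec: VirtualSpecimen,
    optics: OpticsState,
    acq: AcquisitionParams,
    tick: int = 0,
    dwell_multiplier: float = 1.0,
) -> Frame:
    """Render one frame; noise is keyed on (acq.seed, tick)."""
    clean = _render_clean(spec, optics, acq)
    rng = np.random.default_rng([acq.seed, int(tick)])
    nsd = noise_sd(optics, acq, dwell_multiplier)
    pixels = _add_noise(clean, nsd, rng, acq.noise_model)
    return Frame(pixels, meta=_frame_meta(optics, acq, tick, dwell_multiplier))


def render_pair(
    spec: VirtualSpecimen,
    optics: OpticsState,
    acq: AcquisitionParams,
    tick: int = 0,
    dwell_multiplier: float = 1.0,
):
    """Two frames of the same state with independent noise (ticks t, t+1)."""
    from .frame_metrics import FramePair

    clean = _render_clean(spec, optics, acq)
    nsd = noise_sd(optics, acq, dwell_multiplier)
    frames = []
    for t in (tick, tick + 1):
        rng = np.random.default_rng([acq.seed, int(t)])
        pixels = _add_noise(clean, nsd, rng, acq.noise_model)
        frames.append(Frame(pixels, meta=_frame_meta(optics, acq, t, dwell_multiplier)))
    return FramePair(frames[0], frames[1])


def ground_truth_snr(
    spec: VirtualSpecimen,
    optics: OpticsState,
    acq: AcquisitionParams,
    dwell_multiplier: float = 1.0,
) -> float:
    """True SNR: sd of the blurred noise-free crop over the noise sd."""
    clean = _render_clean(spec, optics, acq)
    nsd = noise_sd(optics, acq, dwell_multiplier)
    if nsd == 0:
        return math.inf
    return float(np.std(clean, ddof=1)) / nsd


def calibrate_dwell_scale(
    spec: VirtualSpecimen,
    optics: OpticsState,
    acq: AcquisitionParams,
    target_snr: float,
    dwell_multiplier: float = 1.0,
) -> AcquisitionParams:
    """Return acquisition params whose noise level yields ``target_snr``
    at the given optics state (instrument constants are unknown in
    physical units, so scenarios are pinned by their ground-truth SNR)."""
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    clean = _render_clean(spec, optics, acq)
    clean_sd = float(np.std(clean, ddof=1))
    dwell = acq.frame_time * dwell_multiplier
    new_scale = clean_sd / target_snr * math.sqrt(optics.current * dwell)
    return replace(acq, dwell_scale=new_scale)


def stream(
    spec: VirtualSpecimen,
    trajectory: Iterable[OpticsState],
    acq: AcquisitionParams,
    frames_per_state: int = 1,
    dwell_multiplier: float = 1.0,
    start_tick: int = 0,
) -> list[Frame]:
    """Render an ordered frame stream along an optics trajectory.

    One clean render per distinct consecutive state; ``frames_per_state``
    noise realisations each.  Slow-scan acquisition is expressed through
    ``dwell_multiplier`` (e.g. 2000 for an 80 s scan against a 0.04 s TV
    frame), which lowers the noise sd by sqrt of the dwell ratio.
    """
    if frames_per_state < 1:
        raise ValueError("frames_per_state must be >= 1")
    frames: list[Frame] = []
    tick = int(start_tick)
    prev: OpticsState | None = None
    clean: np.ndarray | None = None
    nsd = 0.0
    for state in trajectory:
        if prev is None or state != prev:
            clean = _render_clean(spec, state, acq)
            nsd = noise_sd(state, acq, dwell_multiplier)
            prev = state
        for _ in range(frames_per_state):
            rng = np.random.default_rng([acq.seed, tick])
            pixels = _add_noise(clean, nsd, rng, acq.noise_model)
            frames.append(
                Frame(pixels, meta=_frame_meta(state, acq, tick, dwell_multiplier))
            )
            tick += 1
    return frames


def focus_ramp(
    start: float, stop: float, steps: int, base: OpticsState = OpticsState()
) -> list[OpticsState]:
    """Linear defocus ramp, other controls held at ``base``."""
    return [replace(base, defocus=float(d)) for d in np.linspace(start, stop, steps)]


def stigmator_ramp(
    start: float,
    stop: float,
    steps: int,
    axis: str = "y",
    base: OpticsState = OpticsState(),
) -> list[OpticsState]:
    """Linear stigmator ramp along one axis at fixed focus."""
    key = {"x": "astig_x", "y": "astig_y"}[axis]
    return [replace(base, **{key: float(a)}) for a in np.linspace(start, stop, steps)]


def constant_trajectory(state: OpticsState, steps: int) -> list[OpticsState]:
    """The same optics state repeated ``steps`` times."""
    return [state] * int(steps)
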