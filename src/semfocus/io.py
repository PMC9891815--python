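"""File I/O and scenario configuration.

Frames come in as grayscale TIFF or PNG (8/16-bit, or float TIFF); RGB
inputs are collapsed with the Rec. 709 luminance weights
0.2126 R + 0.7152 G + 0.0722 B (a declared, logged rule -- the SNR
estimate is affine-invariant, so the exact weights do not bias it as
long as one rule is used throughout).  Simulated streams are written as
multi-page float32 TIFF with a CSV sidecar of per-frame optics state.

A *scenario* is a YAML mapping with ``seed``, ``specimen``, ``optics``,
``acquisition`` and ``trajectory`` blocks describing a virtual-SEM
session; :func:`build_scenario` turns it into concrete objects.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .frame_metrics import Frame
from .virtual_sem import (
    AcquisitionParams,
    OpticsState,
    VirtualSpecimen,
    calibrate_dwell_scale,
    constant_trajectory,
    focus_ramp,
    generate_specimen,
    stigmator_ramp,
)

logger = logging.getLogger("semfocus")

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _to_gray(arr: np.ndarray, path: str | Path) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        logger.info("converting RGB input %s to gray with Rec.709 luminance", path)
        arr = arr[..., :3].astype(float) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(float)


def read_frame(path: str | Path) -> Frame:
    """Read a single grayscale TIFF/PNG frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
            arr = arr[0]  # first page of a stack
    else:
        arr = iio.imread(path)
    return Frame(_to_gray(arr, path), meta={"source": str(path)})


def read_stack(path: str | Path) -> list[Frame]:
    """Read an ordered frame stack from a multi-page TIFF (or one image)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return [Frame(_to_gray(arr, path), meta={"source": str(path), "page": 0})]
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return [Frame(_to_gray(arr, path), meta={"source": str(path), "page": 0})]
    return [
        Frame(_to_gray(page, path), meta={"source": str(path), "page": i})
        for i, page in enumerate(arr)
    ]


def write_stack(path: str | Path, frames: Sequence[Frame]) -> None:
    """Write frames as a multi-page float32 TIFF."""
    data = np.stack([f.pixels for f in frames]).astype(np.float32)
    tifffile.imwrite(path, data)


def frames_metadata(frames: Sequence[Frame]) -> pd.DataFrame:
    """Per-frame metadata sidecar (tick, timing, optics controls)."""
    rows = [dict(f.meta) if f.meta else {} for f in frames]
    return pd.DataFrame(rows)


def write_sidecar(path: str | Path, frames: Sequence[Frame]) -> None:
    frames_metadata(frames).to_csv(path, index=False)


def read_controls(path: str | Path, column: str) -> list[float]:
    """Read a per-frame control column from a CSV sidecar."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"{path}: no column {column!r} (have {list(df.columns)})")
    return [float(v) for v in df[column]]


def load_scenario(path: str | Path) -> dict[str, Any]:
    """Load a YAML scenario config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: scenario must be a mapping")
    return cfg


_KNOWN_KEYS = {"seed", "specimen", "optics", "acquisition", "trajectory", "target_snr"}
_TRAJECTORY_KINDS = {"focus_ramp", "stigmator_ramp", "constant"}


def build_scenario(
    cfg: dict[str, Any], seed: int | None = None
) -> tuple[VirtualSpecimen, list[OpticsState], AcquisitionParams, OpticsState, int]:
    """Instantiate (specimen, trajectory, acquisition, base optics,
    frames_per_state) from a scenario config.

    ``seed`` overrides the config seed; all randomness (texture and
    per-frame noise) flows from it.  If ``target_snr`` is given, the
    noise scaling is calibrated so the ground-truth SNR at the base
    optics state (shift/astigmatism/defocus as configured, defocus
    forced to 0) equals it.
    """
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if seed is None:
        seed = int(cfg.get("seed", 0))
    spec_cfg = dict(cfg.get("specimen", {}))
    spec_cfg.setdefault("seed", seed)
    specimen = generate_specimen(
        shape=tuple(spec_cfg.get("shape", (768, 768))),
        feature_scale=spec_cfg.get("feature_scale", 8.0),
        texture_sd=spec_cfg.get("texture_sd", 1.0),
        mean_level=spec_cfg.get("mean_level", 100.0),
        block_size=spec_cfg.get("block_size", 1),
        patches=spec_cfg.get("patches"),
        seed=spec_cfg["seed"],
    )
    opt_cfg = dict(cfg.get("optics", {}))
    if "beam_shift" in opt_cfg:
        opt_cfg["beam_shift"] = tuple(opt_cfg["beam_shift"])
    base = OpticsState(**opt_cfg)
    acq_cfg = dict(cfg.get("acquisition", {}))
    acq = AcquisitionParams(seed=seed, **acq_cfg)
    if "target_snr" in cfg:
        acq = calibrate_dwell_scale(
            specimen, replace(base, defocus=0.0), acq, float(cfg["target_snr"])
        )
    traj_cfg = dict(cfg.get("trajectory", {"kind": "constant", "steps": 2}))
    kind = traj_cfg.pop("kind", "constant")
    if kind not in _TRAJECTORY_KINDS:
        raise ValueError(f"trajectory.kind must be one of {sorted(_TRAJECTORY_KINDS)}")
    frames_per_state = int(traj_cfg.pop("frames_per_state", 1))
    if kind == "constant":
        trajectory = constant_trajectory(base, int(traj_cfg.pop("steps", 2)))
    elif kind == "focus_ramp":
        trajectory = focus_ramp(
            float(traj_cfg.pop("start", -3.0)),
            float(traj_cfg.pop("stop", 3.0)),
            int(traj_cfg.pop("steps", 61)),
            base=base,
        )
    else:
        trajectory = stigmator_ramp(
            float(traj_cfg.pop("start", -3.0)),
            float(traj_cfg.pop("stop", 3.0)),
            int(traj_cfg.pop("steps", 61)),
            axis=traj_cfg.pop("axis", "y"),
            base=base,
        )
    if traj_cfg:
        raise ValueError(f"unknown trajectory keys: {sorted(traj_cfg)}")
    logger.info(
        "scenario: seed=%d, specimen=%s, kind=%s, steps=%d, frames_per_state=%d, "
        "dwell_scale=%.4g",
        seed,
        specimen.shape,
        kind,
        len(trajectory),
        frames_per_state,
        acq.dwell_scale,
    )
    return specimen, trajectory, acq, base, frames_per_state
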