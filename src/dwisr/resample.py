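"""Degrade/restore operators: factor-3 block downsampling, interpolation back
to the target grid, and intensity-range renormalization.

The super-resolution task is framed as: degrade a high-resolution volume by
block averaging at ratio 1/3, restore the grid by interpolation at ratio 3,
and learn the residual between that interpolated image and the original.
Interpolation uses voxel-center alignment (output center i maps to input
coordinate (i + 1/2)/factor - 1/2) with edge replication at the borders, so
constants are reproduced exactly and no extrapolation artifacts appear.

After every resolution change the intensity range is restored by a two-point
linear map onto a reference image's [min, max] (interpolation shrinks the
range; the pipeline renormalizes so compared images share one range).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = ["ResampleSpec", "downsample", "interpolate_up", "normalize_range"]

_METHOD_ORDER = {"nearest": 0, "trilinear": 1, "tricubic": 3}


@dataclasses.dataclass(frozen=True)
class ResampleSpec:
    factor: int = 3
    method: str = "tricubic"
    renormalize: bool = True

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError(f"factor must be >= 1, got {self.factor}")
        if self.method not in _METHOD_ORDER:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {sorted(_METHOD_ORDER)}"
            )


def downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    """Block-average each factor^3 cube into one voxel (anti-aliased 1/factor).

    Every spatial dimension must be divisible by ``factor``; callers pad
    first if not.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if any(s % factor for s in vol.shape):
        raise ValueError(
            f"shape {vol.shape} not divisible by factor {factor}; pad first"
        )
    nx, ny, nz = (s // factor for s in vol.shape)
    blocks = vol.reshape(nx, factor, ny, factor, nz, factor)
    return blocks.mean(axis=(1, 3, 5))


def interpolate_up(vol: np.ndarray, factor: int, method: str = "tricubic") -> np.ndarray:
    """Upsample by ``factor`` with nearest/trilinear/tricubic interpolation.

    Output dimensions are exactly input * factor.  Voxel-center alignment:
    output index i samples input coordinate (i + 0.5)/factor - 0.5, with
    border values replicated outside the source lattice.
    """
    if method not in _METHOD_ORDER:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_METHOD_ORDER)}"
        )
    vol = np.asarray(vol, dtype=np.float64)
    if factor == 1:
        return vol.copy()
    order = _METHOD_ORDER[method]
    coords = [
        (np.arange(s * factor, dtype=np.float64) + 0.5) / factor - 0.5
        for s in vol.shape
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(vol, np.stack(grid), order=order, mode="nearest")
    if not np.all(np.isfinite(out)):
        raise ValueError("interpolation produced non-finite values")
    return out


def normalize_range(vol: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Linearly map ``vol`` so its min/max equal the reference's exactly.

    A constant input cannot be stretched; it is returned at the reference
    minimum with a warning.
    """
    vol = np.asarray(vol, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    ref_min, ref_max = float(reference.min()), float(reference.max())
    if not ref_max > ref_min:
        raise ValueError("reference must have max > min")
    v_min, v_max = float(vol.min()), float(vol.max())
    if v_max == v_min:
        warnings.warn(
            "normalize_range: constant input, returning reference minimum",
            stacklevel=2,
        )
        return np.full_like(vol, ref_min)
    out = (vol - v_min) * ((ref_max - ref_min) / (v_max - v_min)) + ref_min
    # Pin the extremes so the output range matches the reference bit-exactly
    # (the linear map alone can miss by one ulp).
    out = np.clip(out, ref_min, ref_max)
    out[vol == v_min] = ref_min
    out[vol == v_max] = ref_max
    return out
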