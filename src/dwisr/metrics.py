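"""Volumetric image-quality metrics: PSNR, global SSIM, cosine similarity,
intensity histograms, Table-style summaries and the normalized three-index
product used for checkpoint selection.

Conventions
-----------
* PSNR is reported in dB: 10*log10(Imax^2 / MSE).  Identical images have
  MSE = 0 and are reported as +inf; summaries exclude infinities with a
  warning.
* SSIM is the *global* (single-window) variant: luminance, contrast and
  structure factors computed from whole-volume statistics,

      l = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)
      c = (2 s_x s_y + C2) / (s_x^2 + s_y^2 + C2)
      s = (s_xy + C3) / (s_x s_y + C3),     SSIM = l^alpha c^beta s^gamma

  with C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2 / 2 and dynamic range
  L = 2^bit_depth - 1, or the reference maximum for floating-point data
  ("auto").  Variances use the population (1/N) convention.  A sliding-window
  variant is available behind ``windowed=True`` for comparison.
* The product score normalizes each checkpoint's average PSNR by the best
  checkpoint-average PSNR (so the best PSNR factor is exactly 1) and
  multiplies by average SSIM and average cosine similarity.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

__all__ = [
    "SSIMParams",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "cosine_similarity",
    "intensity_histogram",
    "evaluate_pair",
    "summarize_reports",
    "product_score",
]


@dataclasses.dataclass(frozen=True)
class SSIMParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    bit_depth: object = "auto"  # integer, or "auto" = reference max

    def dynamic_range(self, *grids) -> float:
        if self.bit_depth == "auto":
            # Symmetric in the compared grids, so SSIM stays symmetric.
            L = max(float(np.max(np.abs(g))) for g in grids)
            if L <= 0:
                L = 1.0  # both-constant-zero comparisons collapse to C/C anyway
        else:
            L = float(2 ** int(self.bit_depth) - 1)
        return L

    def constants(self, *grids):
        L = self.dynamic_range(*grids)
        c1 = (0.01 * L) ** 2
        c2 = (0.03 * L) ** 2
        return c1, c2, c2 / 2.0


def _check_same_shape(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x, y) -> float:
    """Mean squared voxel difference."""
    x, y = _check_same_shape(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, imax="auto") -> float:
    """Peak signal-to-noise ratio of ``x`` against reference ``y``, in dB.

    ``imax`` is the dynamic-range peak; "auto" uses the reference maximum.
    Identical inputs return +inf.
    """
    x, y = _check_same_shape(x, y)
    if imax == "auto":
        imax = float(np.max(np.abs(y)))
    imax = float(imax)
    if imax <= 0:
        raise ValueError(f"Imax must be positive, got {imax}")
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return float(10.0 * np.log10(imax**2 / err))


def ssim(x, y, params: SSIMParams = SSIMParams(), windowed: bool = False,
         window: int = 7) -> float:
    """Structural similarity; global single-window statistics by default."""
    x, y = _check_same_shape(x, y)
    if np.array_equal(x, y):
        return 1.0  # every factor is identically 1
    c1, c2, c3 = params.constants(x, y)
    if not windowed:
        return float(_ssim_stats(x, y, c1, c2, c3, params))
    from scipy import ndimage

    size = (window,) * x.ndim
    mu_x = ndimage.uniform_filter(x, size)
    mu_y = ndimage.uniform_filter(y, size)
    xx = ndimage.uniform_filter(x * x, size) - mu_x**2
    yy = ndimage.uniform_filter(y * y, size) - mu_y**2
    xy = ndimage.uniform_filter(x * y, size) - mu_x * mu_y
    xx, yy = np.maximum(xx, 0.0), np.maximum(yy, 0.0)
    sx, sy = np.sqrt(xx), np.sqrt(yy)
    l_map = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    c_map = (2 * sx * sy + c2) / (sx**2 + sy**2 + c2)
    s_map = (xy + c3) / (sx * sy + c3)
    vals = (
        np.sign(l_map) * np.abs(l_map) ** params.alpha
        * np.abs(c_map) ** params.beta
        * np.sign(s_map) * np.abs(s_map) ** params.gamma
    )
    return float(np.mean(vals))


def _ssim_stats(x, y, c1, c2, c3, params):
    mu_x, mu_y = x.mean(), y.mean()
    sx = x.std()  # population convention
    sy = y.std()
    sxy = ((x - mu_x) * (y - mu_y)).mean()
    l_f = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    c_f = (2 * sx * sy + c2) / (sx**2 + sy**2 + c2)
    s_f = (sxy + c3) / (sx * sy + c3)
    return (
        np.sign(l_f) * np.abs(l_f) ** params.alpha
        * np.abs(c_f) ** params.beta
        * np.sign(s_f) * np.abs(s_f) ** params.gamma
    )


def cosine_similarity(x, y) -> float:
    """<x, y> / (|x| |y|) over flattened voxels; two all-zero grids are
    identical and return 1 (with a warning)."""
    x, y = _check_same_shape(x, y)
    nx = float(np.linalg.norm(x.ravel()))
    ny = float(np.linalg.norm(y.ravel()))
    if nx == 0.0 and ny == 0.0:
        warnings.warn("cosine_similarity: both grids all-zero, returning 1", stacklevel=2)
        return 1.0
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x.ravel(), y.ravel()) / (nx * ny))


def intensity_histogram(x, bins: int, value_range) -> np.ndarray:
    """Histogram counts over half-open bins [lo, hi), last bin closed.

    Values outside the range are clipped into the terminal bins so that the
    counts always sum to the voxel count (compared images share one range).
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    lo, hi = float(value_range[0]), float(value_range[1])
    if not hi > lo:
        raise ValueError(f"inverted range ({lo}, {hi})")
    x = np.clip(np.asarray(x, dtype=np.float64).ravel(), lo, hi)
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return counts


@dataclasses.dataclass
class MetricReport:
    """PSNR/SSIM/cosine/MSE for one compared pair (or their averages)."""

    psnr: float
    ssim: float
    cosine: float
    mse: float
    imax: float

    def product(self, psnr_norm: float = None) -> float:
        p = self.psnr if psnr_norm is None else self.psnr / psnr_norm
        return p * self.ssim * self.cosine

    def as_dict(self):
        return {
            "psnr": self.psnr if math.isfinite(self.psnr) else "inf",
            "ssim": self.ssim,
            "cosine": self.cosine,
            "mse": self.mse,
            "imax": self.imax,
        }


def evaluate_pair(pred, reference, imax="auto",
                  ssim_params: SSIMParams = SSIMParams()) -> MetricReport:
    """All three indices plus MSE for one predicted/reference volume pair."""
    pred, reference = _check_same_shape(pred, reference)
    used_imax = float(np.max(np.abs(reference))) if imax == "auto" else float(imax)
    return MetricReport(
        psnr=psnr(pred, reference, imax=imax),
        ssim=ssim(pred, reference, params=ssim_params),
        cosine=cosine_similarity(pred, reference),
        mse=mse(pred, reference),
        imax=used_imax,
    )


def _finite_mean(values):
    finite = [v for v in values if math.isfinite(v)]
    if len(finite) < len(values):
        warnings.warn(
            "summary excludes infinite PSNR values from identical pairs",
            stacklevel=3,
        )
    return finite


def summarize_reports(reports):
    """Average / Std / Max / Min block per metric over a set of reports."""
    if not reports:
        raise ValueError("no reports to summarize")
    out = {}
    for name in ("psnr", "ssim", "cosine", "mse"):
        vals = [getattr(r, name) for r in reports]
        if name == "psnr":
            vals = _finite_mean(vals)
            if not vals:
                out[name] = {"average": math.inf, "std": 0.0,
                             "max": math.inf, "min": math.inf}
                continue
        arr = np.asarray(vals, dtype=np.float64)
        out[name] = {
            "average": float(arr.mean()),
            "std": float(arr.std()),
            "max": float(arr.max()),
            "min": float(arr.min()),
        }
    return out


def product_score(checkpoint_summaries):
    """Normalized three-index product per checkpoint.

    Each entry must provide average PSNR/SSIM/cosine (a summary dict from
    :func:`summarize_reports` or a MetricReport of averages).  PSNR averages
    are divided by the best checkpoint average so the top factor is exactly 1.
    """
    if not checkpoint_summaries:
        raise ValueError("need at least one checkpoint summary")
    triples = []
    for s in checkpoint_summaries:
        if isinstance(s, MetricReport):
            triples.append((s.psnr, s.ssim, s.cosine))
        else:
            triples.append((s["psnr"]["average"], s["ssim"]["average"],
                            s["cosine"]["average"]))
    psnrs = [t[0] for t in triples]
    if all(math.isinf(p) for p in psnrs):
        raise ValueError("all checkpoint PSNRs are infinite; product undefined")
    best = max(p for p in psnrs if math.isfinite(p))
    scores = []
    for p, s, c in triples:
        factor = 1.0 if math.isinf(p) else p / best
        scores.append(float(factor * s * c))
    return scores
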