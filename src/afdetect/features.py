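"""Window -> feature-vector pipeline.

A 60-beat window yields 59 consecutive RR differences; scattering each
difference against the previous one gives the 58-point Lorenz
(Poincare) plot of dRR dynamics.  Consecutive dRR values are
intrinsically anti-correlated (corr ~ -0.5 for independent intervals),
so the cloud is sheared along the anti-diagonal; the de-correlation
transform

    Y' = Y + alpha * sign(X) * |X|**beta      (alpha=0.5, beta=0.75)

counteracts that shear.  The transformed cloud is rasterized onto a
64x64 grid spanning +/-600 ms and reduced to its 8x8 low-pass band by a
3-level separable wavelet decomposition (CDF 9/7, the JPEG 2000 lossy
filter), giving a 64-value feature vector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pywt

from .rr_io import Window

__all__ = [
    "DecorrelationParams",
    "FeatureConfig",
    "delta_series",
    "lorenz_points",
    "decorrelate",
    "rasterize",
    "wavelet_approx",
    "extract_features",
    "feature_matrix",
]

#: Supported filter modes.  ``cdf97`` is the biorthogonal 9/7 pair of
#: JPEG 2000's irreversible path, computed by the standard lifting
#: scheme with whole-sample symmetric extension (non-expansive, so a
#: 64-sample signal yields exactly 32+32 coefficients); ``haar`` is
#: orthonormal and serves as an exactly-checkable oracle mode.
_WAVELET_MODES = ("cdf97", "haar")

# CDF 9/7 lifting constants (predict/update coefficients and the final
# scaling factor), as used by the JPEG 2000 irreversible transform.
_LIFT_ALPHA = -1.586134342
_LIFT_BETA = -0.05298011854
_LIFT_GAMMA = 0.8829110762
_LIFT_DELTA = 0.4435068522
_LIFT_K = 1.149604398


def _dwt97_1d(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """One CDF 9/7 analysis level along ``axis`` via lifting.

    Whole-sample symmetric extension by 4 samples on each side covers
    the four lifting passes, so the retained coefficients equal those of
    an infinitely extended signal.  Normalization matches the usual
    sqrt(2)-DC-gain convention for the low-pass branch.
    """
    x = np.moveaxis(np.asarray(x, dtype=float), axis, -1)
    n = x.shape[-1]
    if n % 2:
        raise ValueError("signal length must be even")
    ext = 4
    idx = np.concatenate([np.arange(ext, 0, -1),
                          np.arange(n),
                          np.arange(n - 2, n - 2 - ext, -1)])
    y = x[..., idx].copy()
    m = y.shape[-1]
    for coef, parity in ((_LIFT_ALPHA, 1), (_LIFT_BETA, 0),
                         (_LIFT_GAMMA, 1), (_LIFT_DELTA, 0)):
        start = parity if parity else 2
        sl = np.arange(start, m - 1, 2)
        y[..., sl] += coef * (y[..., sl - 1] + y[..., sl + 1])
    lo = y[..., ext:ext + n:2] * _LIFT_K
    hi = y[..., ext + 1:ext + n:2] / _LIFT_K
    return np.moveaxis(lo, -1, axis), np.moveaxis(hi, -1, axis)


def _ll_band_cdf97(image: np.ndarray, levels: int) -> np.ndarray:
    """Level-``levels`` approximation band of the separable 9/7 DWT."""
    ll = image
    for _ in range(levels):
        lo_r, _ = _dwt97_1d(ll, axis=1)
        ll, _ = _dwt97_1d(lo_r, axis=0)
    return ll


@dataclass(frozen=True)
class DecorrelationParams:
    """Coefficients of the de-correlation transform Y' = Y + alpha*X^beta."""

    alpha: float = 0.5
    beta: float = 0.75

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


@dataclass(frozen=True)
class FeatureConfig:
    """Everything that determines the window -> vector mapping.

    ``fingerprint()`` hashes the canonical content; trained models store
    it and refuse to score features produced under a different config.
    """

    alpha: float = 0.5
    beta: float = 0.75
    resolution: int = 64
    extent_ms: float = 600.0
    wavelet: str = "cdf97"
    levels: int = 3

    def __post_init__(self) -> None:
        DecorrelationParams(self.alpha, self.beta)
        if self.resolution < 16 or self.resolution & (self.resolution - 1):
            raise ValueError("resolution must be a power of two >= 16")
        if self.extent_ms <= 0:
            raise ValueError("extent must be positive")
        if self.wavelet not in _WAVELET_MODES:
            raise ValueError(f"unknown wavelet mode {self.wavelet!r}")
        if self.resolution != (self.resolution >> self.levels) << self.levels \
                or self.resolution >> self.levels < 1:
            raise ValueError("resolution must divide cleanly by 2^levels")

    @property
    def decorrelation(self) -> DecorrelationParams:
        return DecorrelationParams(self.alpha, self.beta)

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def delta_series(window: Window | np.ndarray) -> np.ndarray:
    """Successive RR differences dRR[k] = RR[k] - RR[k-1], in ms."""
    rr = window.intervals if isinstance(window, Window) else np.asarray(window, float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    return np.diff(rr)


def lorenz_points(deltas: np.ndarray) -> np.ndarray:
    """Pair each dRR with its predecessor: point i = (X=d[i+1], Y=d[i]).

    Returns an (n-1, 2) array of (X, Y) coordinates.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two deltas to form a Lorenz point")
    return np.column_stack([d[1:], d[:-1]])


def decorrelate(
    points: np.ndarray,
    params: DecorrelationParams = DecorrelationParams(),
) -> np.ndarray:
    """Apply Y' = Y + alpha*sign(X)*|X|**beta; X is left untouched.

    The signed power extends X**beta (undefined over the reals for
    negative X at beta=0.75) as an odd function, preserving the plot's
    point symmetry about the origin.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("point coordinates must be finite")
    x, y = pts[:, 0], pts[:, 1]
    yp = y + params.alpha * np.sign(x) * np.abs(x) ** params.beta
    return np.column_stack([x, yp])


def rasterize(
    points: np.ndarray,
    resolution: int = 64,
    extent_ms: float = 600.0,
) -> np.ndarray:
    """2D histogram of the point cloud on a square grid.

    Bin index = floor((coord + extent) / (2*extent) * resolution),
    clamped to [0, resolution-1] so out-of-range points accumulate in
    the edge bins and no point is ever lost.  Row 0 holds the most
    negative Y', column 0 the most negative X; counts sum to the number
    of points.
    """
    pts = np.asarray(points, dtype=float)
    grid = np.zeros((resolution, resolution), dtype=np.int64)
    if pts.size == 0:
        return grid
    scale = resolution / (2.0 * extent_ms)
    cols = np.clip(np.floor((pts[:, 0] + extent_ms) * scale).astype(int),
                   0, resolution - 1)
    rows = np.clip(np.floor((pts[:, 1] + extent_ms) * scale).astype(int),
                   0, resolution - 1)
    np.add.at(grid, (rows, cols), 1)
    return grid


def wavelet_approx(
    image: np.ndarray,
    levels: int = 3,
    wavelet: str = "cdf97",
) -> np.ndarray:
    """Flattened low-pass (LL) band of a ``levels``-deep 2D decomposition.

    With the default 64x64 input and 3 levels the LL band is 8x8 and the
    result has 64 values, row-major.  ``cdf97`` uses whole-sample
    symmetric extension (the JPEG 2000 lossy path); ``haar`` uses
    periodization, which keeps the transform exactly orthonormal and is
    intended for oracle testing.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square")
    side = img.shape[0]
    if side % (1 << levels):
        raise ValueError(
            f"side {side} not divisible by 2^{levels}"
        )
    if wavelet == "cdf97":
        ll = _ll_band_cdf97(img, levels)
    elif wavelet == "haar":
        ll = pywt.wavedec2(img, "haar", mode="periodization", level=levels)[0]
    else:
        raise ValueError(f"unknown wavelet mode {wavelet!r}")
    return ll.ravel()


def extract_features(
    window: Window | np.ndarray,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Full deterministic pipeline: window -> 64-value feature vector."""
    deltas = delta_series(window)
    pts = lorenz_points(deltas)
    dec = decorrelate(pts, config.decorrelation)
    img = rasterize(dec, config.resolution, config.extent_ms)
    return wavelet_approx(img, config.levels, config.wavelet)


def feature_matrix(
    windows,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Stack feature vectors for a sequence of windows, one row each."""
    return np.array([extract_features(w, config) for w in windows])


def write_feature_csv(path, features: np.ndarray, labels=None) -> None:
    """Interchange format: one row per window, columns f00..f63
    (+ optional ``label`` column with AF / NON_AF values)."""
    import pandas as pd

    x = np.atleast_2d(np.asarray(features, dtype=float))
    df = pd.DataFrame(x, columns=[f"f{i:02d}" for i in range(x.shape[1])])
    if labels is not None:
        df["label"] = [getattr(lb, "value", lb) for lb in labels]
    df.to_csv(path, index=False)


def read_feature_csv(path):
    """Inverse of :func:`write_feature_csv`; returns (features, labels)
    where labels is None when the CSV has no label column."""
    import pandas as pd

    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = list(df.pop("label"))
    return df.to_numpy(dtype=float), labels
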