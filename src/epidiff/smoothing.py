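"""Savitzky–Golay smoothing of per-cytosine count tracks.

Methylated and unmethylated read counts are smoothed independently along a
chromosome track of cytosines of one sequence context, using a local
least-squares quadratic fit over a fixed number of *index-adjacent*
cytosines (not a fixed bp window).  Interior points use the classical
Savitzky–Golay filter; points closer than half a window to a track end use
a least-squares fit over the truncated available window, which preserves
the property that any polynomial of degree <= the fit degree is reproduced
exactly everywhere.  Because read counts are physically non-negative, the
smoothed output is clamped at zero from below (the filter can undershoot
near sharp spikes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["SmoothingParams", "savitzky_golay_smooth"]


@dataclass(frozen=True)
class SmoothingParams:
    """Parameters of the local polynomial smoother.

    window
        Odd number of adjacent track values in the fit window (default 11).
    degree
        Degree of the local least-squares polynomial (default 2, quadratic).
    """

    window: int = 11
    degree: int = 2

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        if self.degree < 0 or self.degree >= self.window:
            raise ValueError(
                f"degree must satisfy 0 <= degree < window, got degree={self.degree}, "
                f"window={self.window}"
            )


def _truncated_fit(x: np.ndarray, i: int, half: int, degree: int) -> float:
    """Least-squares polynomial fit over the available window around index i,
    evaluated at i.  The window is the full window clipped to the track."""
    lo = max(0, i - half)
    hi = min(len(x), i + half + 1)
    deg = min(degree, hi - lo - 1)
    t = np.arange(lo, hi, dtype=float) - i
    design = np.vander(t, deg + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, x[lo:hi], rcond=None)
    return float(coef[0])


def savitzky_golay_smooth(
    values,
    params: SmoothingParams | None = None,
    clamp: bool = True,
) -> np.ndarray:
    """Smooth a 1-D sequence with a Savitzky–Golay filter.

    Parameters
    ----------
    values
        Ordered real sequence (length >= 1, all finite).
    params
        Window/degree; default 11-point quadratic.
    clamp
        Clamp the output at 0 from below (default True; counts cannot be
        negative).

    Returns
    -------
    numpy.ndarray of the same length as ``values``.
    """
    if params is None:
        params = SmoothingParams()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < 1:
        raise ValueError("values must contain at least one element")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    w, d = params.window, params.degree
    half = w // 2
    n = x.size
    if n >= w:
        out = savgol_filter(x, w, d, mode="interp")
        # replace the edge estimates with truncated-window fits
        for i in range(half):
            out[i] = _truncated_fit(x, i, half, d)
            out[n - 1 - i] = _truncated_fit(x, n - 1 - i, half, d)
    else:
        out = np.array([_truncated_fit(x, i, half, d) for i in range(n)])
    if clamp:
        np.maximum(out, 0.0, out=out)
    return out
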