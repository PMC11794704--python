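"""Local quadratic regression (loess) with tricube weights.

Used to estimate the noise floor of fit errors across conditions: a
second-order loess with span 0.75 smooths RMSRE values against an
arbitrary covariate.  The smoother is generic — it makes no assumption
about what x and y are.

At each evaluation point the nearest ``floor(span * n)`` observations are
weighted by the tricube kernel of their scaled distance and a weighted
quadratic polynomial is fitted; the smoothed value is the polynomial's
value at that point.  This is the classic loess definition with an exact
(direct) surface.
"""

from __future__ import annotations

import numpy as np


def loess_quadratic(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    xout: np.ndarray | None = None,
) -> np.ndarray:
    """Second-order loess fit of ``y`` on ``x``, evaluated at ``xout``.

    Parameters
    ----------
    x, y:
        Observations; at least 5 points so the local quadratic (3
        parameters) is meaningfully overdetermined.
    span:
        Fraction of points in each local neighbourhood, in (0, 1].
    xout:
        Evaluation points; defaults to ``x`` itself.

    Returns
    -------
    ndarray of fitted values at ``xout``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 5:
        raise ValueError(f"loess needs at least 5 points, got {n}")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if xout is None:
        xout = x
    xout = np.asarray(xout, dtype=float)

    q = max(int(np.floor(span * n)), 3)
    q = min(q, n)
    out = np.empty(len(xout))
    for k, x0 in enumerate(xout):
        d = np.abs(x - x0)
        d_q = np.sort(d)[q - 1]
        if d_q == 0:
            # all neighbours coincide with x0; fall back to their mean
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / d_q, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
        mask = w > 0
        xm = x[mask] - x0
        design = np.column_stack([np.ones(mask.sum()), xm, xm**2])
        sw = np.sqrt(w[mask])
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[mask] * sw, rcond=None)
        out[k] = beta[0]
    return out


def loess_noise_floor(x: np.ndarray, y: np.ndarray, span: float = 0.75) -> np.ndarray:
    """Noise-floor estimate: second-order loess of error values ``y`` on ``x``
    with span 0.75, evaluated at the input x."""
    return loess_quadratic(x, y, span=span)
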