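"""High-breakdown robust association between two variables (MM-estimate).

The contribution analysis scores each feature by the linear association
between its normative Z-score and the (corrected) PAD, estimated robustly
so that a handful of gross outliers cannot dominate.  The estimator is an
MM-type simple regression on robustly standardized variables:

1. both variables are centered by the median and scaled by the normalized
   MAD (1.4826 * median absolute deviation);
2. an S-estimate of the regression (slope, intercept) minimizes an
   M-scale of the residuals built from Tukey's bisquare rho with
   breakdown point 0.5 (c = 1.547), searched over seeded two-point
   elemental candidates and refined by iteratively reweighted least
   squares (IRLS);
3. the final M-step runs IRLS with the redescending bisquare psi at
   c = 3.44 (85% efficiency at the normal) keeping the S-scale fixed.

On standardized variables the slope is a correlation-like effect size;
it is clipped to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

_MAD_CONST = 1.4826


@dataclass
class MMConfig:
    """Tuning constants for the MM effect-size estimator."""

    c_s: float = 1.547      # bisquare tuning for the S-stage (50% breakdown)
    c_m: float = 3.44       # bisquare tuning for the M-stage (85% efficiency)
    breakdown: float = 0.5  # target b = E[rho] / rho(inf) in the M-scale
    n_candidates: int = 50  # elemental two-point starts in the S-search
    max_iter: int = 100
    tol: float = 1e-8
    seed: int = 0


def _bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho, normalized so rho(inf) = 1."""
    t = np.clip(u / c, -1.0, 1.0)
    return 1.0 - (1.0 - t**2) ** 3


def _bisquare_weight(u: np.ndarray, c: float) -> np.ndarray:
    """IRLS weight psi(u)/u for the bisquare."""
    t = u / c
    w = (1.0 - t**2) ** 2
    w[np.abs(t) >= 1.0] = 0.0
    return w


def _m_scale(resid: np.ndarray, c: float, b: float, tol: float = 1e-10) -> float:
    """Solve mean(rho(r/s)) = b for s (fixed point, from the MAD start)."""
    r = np.asarray(resid, dtype=float)
    s = np.median(np.abs(r)) / 0.6745
    if s == 0:
        return 0.0
    for _ in range(200):
        m = float(np.mean(_bisquare_rho(r / s, c)))
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return s_new
        s = s_new
    return s


def mad(x) -> float:
    """Normalized median absolute deviation (consistent at the normal)."""
    x = np.asarray(x, dtype=float)
    return _MAD_CONST * float(np.median(np.abs(x - np.median(x))))


def _irls(x, y, beta, scale, c, max_iter, tol):
    """IRLS for (slope, intercept) with fixed scale and bisquare weights."""
    X = np.column_stack([x, np.ones_like(x)])
    for _ in range(max_iter):
        r = y - X @ beta
        w = _bisquare_weight(r / scale, c)
        if w.sum() == 0:
            break
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) <= tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


def mm_regression(x, y, config: Optional[MMConfig] = None) -> Tuple[float, float, float]:
    """MM simple regression of y on x: (slope, intercept, s_scale)."""
    cfg = config or MMConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rng = np.random.default_rng(cfg.seed)

    # S-stage: elemental candidates (lines through two points) + LS start
    candidates = []
    X = np.column_stack([x, np.ones_like(x)])
    candidates.append(np.linalg.lstsq(X, y, rcond=None)[0])
    for _ in range(cfg.n_candidates):
        i, j = rng.choice(n, 2, replace=False)
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        candidates.append(np.array([slope, y[i] - slope * x[i]]))
    best_beta, best_scale = None, np.inf
    for beta in candidates:
        s = _m_scale(y - X @ beta, cfg.c_s, cfg.breakdown)
        if s < best_scale:
            best_scale, best_beta = s, beta
    # refine the S-estimate: a few IRLS steps at c_s, re-evaluating the scale
    beta = best_beta
    for _ in range(10):
        beta = _irls(x, y, beta, max(best_scale, 1e-12), cfg.c_s, 5, cfg.tol)
        s = _m_scale(y - X @ beta, cfg.c_s, cfg.breakdown)
        if s >= best_scale * (1 - 1e-10):
            break
        best_scale, best_beta = s, beta
    scale = max(best_scale, 1e-12)
    # M-stage at high efficiency, scale fixed
    beta = _irls(x, y, best_beta, scale, cfg.c_m, cfg.max_iter, cfg.tol)
    return float(beta[0]), float(beta[1]), float(scale)


def robust_effect_size(z_values, pad_values, config: Optional[MMConfig] = None):
    """Signed robust effect size of the Z-vs-PAD association.

    Both vectors are standardized by median/MAD, the MM regression slope
    of standardized PAD on standardized Z is the effect size, clipped to
    [-1, 1].  Returns (es, flags) where flags is a dict with
    ``degenerate`` (zero MAD in either variable; es is nan) and
    ``n`` (observations used).
    """
    z = np.asarray(z_values, dtype=float)
    p = np.asarray(pad_values, dtype=float)
    if z.shape != p.shape:
        raise ValueError("z and pad vectors must have equal length")
    ok = np.isfinite(z) & np.isfinite(p)
    z, p = z[ok], p[ok]
    n = len(z)
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    sz, sp = mad(z), mad(p)
    if sz == 0 or sp == 0:
        return float("nan"), {"degenerate": True, "n": n}
    zs = (z - np.median(z)) / sz
    ps = (p - np.median(p)) / sp
    slope, _, _ = mm_regression(zs, ps, config)
    return float(np.clip(slope, -1.0, 1.0)), {"degenerate": False, "n": n}
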