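"""Group-level statistics for PAD scores.

ANCOVA with covariate adjustment (group effect tested by nested linear
models), Benjamini-Hochberg-adjusted pairwise post-hoc comparisons,
partial correlation by residualization, Fisher r-to-z comparison of two
independent correlations, clinical-score association tables, and the
lowest-k outlier-exclusion re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _covariate_matrix(covariates, n: int) -> Tuple[np.ndarray, List[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{i}" for i in range(arr.shape[1])]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank deficient design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


@dataclass
class GroupComparison:
    """ANCOVA result: omnibus group F-test plus pairwise post-hoc tests."""

    groups: List[str]
    covariate_names: List[str]
    f_statistic: float
    df: Tuple[int, int]
    p_value: float
    adjusted_means: Dict[str, float]
    posthoc: pd.DataFrame  # columns: group_a, group_b, p_raw, p_adjusted

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "covariates": self.covariate_names,
            "F": self.f_statistic,
            "df": list(self.df),
            "p": self.p_value,
            "adjusted_means": self.adjusted_means,
            "posthoc": self.posthoc.to_dict(orient="records"),
        }


def ancova_compare(values, groups, covariates=None, posthoc: bool = True) -> GroupComparison:
    """Compare group means of ``values`` adjusting for covariates.

    The omnibus F for the group factor comes from nested OLS models
    (full: intercept + group dummies + covariates; reduced: intercept +
    covariates), F = ((RSS_red - RSS_full)/df1) / (RSS_full/df2) with
    df1 = n_groups - 1 and df2 = n - n_groups - n_covariates.  Post-hoc
    tests are the analogous two-group ANCOVAs, BH-adjusted across pairs.
    Adjusted means evaluate the full model at the grand covariate means.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = len(y)
    if len(groups) != n:
        raise ValueError("values and groups must have equal length")
    C, cov_names = _covariate_matrix(covariates, n)
    if len(C) != n:
        raise ValueError("covariates length mismatch")
    labels = sorted(pd.unique(groups).tolist())
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")

    dummies = np.column_stack([(groups == lab).astype(float) for lab in labels[1:]])
    intercept = np.ones((n, 1))
    X_full = np.column_stack([intercept, dummies, C])
    X_red = np.column_stack([intercept, C])
    try:
        coef_full, rss_full = _ols_rss(X_full, y)
        _, rss_red = _ols_rss(X_red, y)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"collinear design (group dummies + covariates {cov_names}): {exc}"
        ) from exc
    df1 = g - 1
    df2 = n - g - C.shape[1]
    if df2 <= 0:
        raise ValueError("not enough observations for the requested design")
    # guard the numerically-degenerate case where covariates explain the
    # outcome exactly (both RSS at rounding level): the group F is then 0
    tss = float(np.sum((y - y.mean()) ** 2))
    eps = 1e-12 * max(tss, 1.0)
    diff = max(rss_red - rss_full, 0.0)
    if rss_full <= eps:
        F = 0.0 if diff <= eps else float("inf")
    else:
        F = (diff / df1) / (rss_full / df2)
    p = float(sps.f.sf(F, df1, df2))

    cov_mean = C.mean(axis=0) if C.shape[1] else np.empty(0)
    adj = {}
    for i, lab in enumerate(labels):
        x0 = np.concatenate([[1.0], np.zeros(g - 1), cov_mean])
        if i > 0:
            x0[i] = 1.0
        adj[lab] = float(x0 @ coef_full)

    rows = []
    if posthoc and g >= 2:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
        for a, b in pairs:
            mask = (groups == a) | (groups == b)
            sub = ancova_compare(y[mask], groups[mask], C[mask] if C.shape[1] else None,
                                 posthoc=False)
            rows.append({"group_a": a, "group_b": b, "p_raw": sub.p_value})
        post = pd.DataFrame(rows)
        post["p_adjusted"] = bh_adjust(post["p_raw"].to_numpy())
    else:
        post = pd.DataFrame(columns=["group_a", "group_b", "p_raw", "p_adjusted"])
    return GroupComparison(labels, cov_names, float(F), (df1, df2), p, adj, post)


def partial_correlation(x, y, covariates=None) -> Tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by OLS and the
    residuals correlated; the p-value uses a t distribution with
    n - 2 - k degrees of freedom (k covariates).  With no covariates this
    reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    C, _ = _covariate_matrix(covariates, n)
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, k={k})")
    Z = np.column_stack([np.ones(n), C])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("zero residual variance")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return rho, p


def compare_correlations(rho1: float, n1: int, rho2: float, n2: int) -> Tuple[float, float]:
    """Fisher r-to-z test for two independent correlation coefficients.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    p from the standard normal.
    """
    for rho, n in ((rho1, n1), (rho2, n2)):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1 for the z-transform")
        if n <= 3:
            raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p


def clinical_associations(
    pads: pd.DataFrame,
    participants: pd.DataFrame,
    scores: Sequence[str],
    covariate_names: Sequence[str] = ("age", "sex", "education"),
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Partial correlations of corrected PAD with clinical scores per group.

    ``pads`` has columns id, modality, corrected_pad; ``participants``
    carries the scores and covariates.  Missing scores are dropped
    pairwise (n reported per row); an all-missing score yields a flagged
    row rather than being silently dropped.
    """
    from .cohort import sex_to_code

    merged = pads.merge(participants, on="id", how="left")
    if groups is None:
        groups = sorted(merged["group"].unique())
    rows = []
    for (modality, group), sub in merged.groupby(["modality", "group"]):
        if group not in groups:
            continue
        for score in scores:
            if score not in sub.columns:
                rows.append(
                    {"modality": modality, "group": group, "score": score,
                     "n": 0, "rho": np.nan, "p": np.nan, "flag": "score absent"}
                )
                continue
            vals = pd.to_numeric(sub[score], errors="coerce")
            ok = vals.notna().to_numpy()
            n_ok = int(ok.sum())
            if covariate_names:
                covs = pd.DataFrame(
                    {
                        name: (sex_to_code(sub["sex"]) if name == "sex"
                               else sub[name].to_numpy(dtype=float))
                        for name in covariate_names
                    }
                )
            else:
                covs = None
            if n_ok <= len(covariate_names) + 2:
                rows.append(
                    {"modality": modality, "group": group, "score": score,
                     "n": n_ok, "rho": np.nan, "p": np.nan,
                     "flag": "all missing" if n_ok == 0 else "insufficient n"}
                )
                continue
            rho, p = partial_correlation(
                sub["corrected_pad"].to_numpy(dtype=float)[ok],
                vals.to_numpy(dtype=float)[ok],
                covs.loc[ok] if covs is not None else None,
            )
            rows.append(
                {"modality": modality, "group": group, "score": score,
                 "n": n_ok, "rho": rho, "p": p, "flag": ""}
            )
    return pd.DataFrame(rows)


def exclude_lowest(values, group_labels, counts_per_group: Dict[str, int]) -> np.ndarray:
    """Inclusion mask dropping the k smallest values within each group.

    Ties are broken by first-occurrence order (stable argsort).  Used for
    the outlier-exclusion re-analysis; the caller reruns
    :func:`ancova_compare` on the masked sample.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    mask = np.ones(len(values), dtype=bool)
    for group, count in counts_per_group.items():
        idx = np.flatnonzero(group_labels == group)
        if count > len(idx):
            raise ValueError(
                f"cannot exclude {count} from group {group!r} of size {len(idx)}"
            )
        if count > 0:
            order = idx[np.argsort(values[idx], kind="stable")]
            mask[order[:count]] = False
    return mask
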