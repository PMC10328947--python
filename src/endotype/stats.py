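"""Exact and rank-based tests used throughout the pipeline.

All routines are small enough to be verified against brute-force oracles:
the two-sided Fisher test sums hypergeometric point probabilities (the
R-style convention, which reproduces the printed clinical-table p-values),
the Mann-Whitney test uses exact enumeration for small samples and the
tie-corrected normal approximation otherwise, and Spearman correlation is
the Pearson correlation of average ranks with a t-approximation p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fisher_exact_2x2",
    "mann_whitney",
    "spearman",
    "hypergeometric_overlap",
    "table1_summary",
]

#: relative slack when collecting tables "as or less probable" than observed
_FISHER_REL_SLACK = 1e-7


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("table has zero total")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (within a small relative slack to absorb floating-point noise).
    """
    t = _as_2x2(table)
    a = t[0, 0]
    r1 = t[0, 0] + t[0, 1]
    c1 = t[0, 0] + t[1, 0]
    n = t.sum()
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_REL_SLACK)].sum())
    return min(p, 1.0)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when both samples have at most 8 observations and no
    ties are present; otherwise the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson of average ranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def hypergeometric_overlap(set1_size: int, set2_size: int, overlap: int, universe: int) -> float:
    """Upper-tail overlap p-value: P(X >= overlap) for X ~ Hypergeom."""
    if not (0 <= overlap <= min(set1_size, set2_size) <= universe):
        raise ValueError("require overlap <= min(set sizes) <= universe")
    if max(set1_size, set2_size) > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return float(min(1.0, sps.hypergeom.sf(overlap - 1, universe, set1_size, set2_size)))


_UNKNOWN_TOKENS = {"unknown", "na", "nan", ""}


def _is_known(series: pd.Series) -> pd.Series:
    known = series.notna()
    str_vals = series.astype(str).str.strip().str.lower()
    return known & ~str_vals.isin(_UNKNOWN_TOKENS)


def table1_summary(
    clinical: pd.DataFrame,
    assignment: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    group_col: str = "response_class",
    groups: tuple[str, str] = ("GR", "PR"),
) -> pd.DataFrame:
    """Demographics-style group summary with per-level Fisher and rank tests.

    For each categorical covariate, every level is tested level-vs-rest in a
    2x2 table against group membership with unknowns excluded; continuous
    covariates are compared by the two-sided Mann-Whitney test. Medians,
    counts and percentages are reported alongside the p-values.
    """
    merged = clinical.merge(
        assignment[["patient_id", group_col]], on="patient_id", how="inner"
    )
    merged = merged[merged[group_col].isin(groups)]
    if merged[group_col].nunique() < 2:
        raise ValueError("assignment must cover at least 2 groups")
    if categorical is None:
        categorical = [
            c
            for c in ("er_status", "her2_status", "grade", "histology", "chemo")
            if c in merged.columns
        ]
    if continuous is None:
        continuous = [
            c
            for c in ("ki67_baseline", "ki67_2wk", "pc", "estradiol", "tils")
            if c in merged.columns
        ]

    g0 = merged[merged[group_col] == groups[0]]
    g1 = merged[merged[group_col] == groups[1]]
    rows = []
    for var in categorical:
        known = merged[_is_known(merged[var])]
        if known.empty:
            warnings.warn(f"covariate {var!r} is all-unknown; skipped")
            continue
        k0 = known[known[group_col] == groups[0]]
        k1 = known[known[group_col] == groups[1]]
        for level in sorted(known[var].astype(str).unique()):
            a = int((k0[var].astype(str) == level).sum())
            b = int(len(k0) - a)
            c = int((k1[var].astype(str) == level).sum())
            d = int(len(k1) - c)
            if len(k0) == 0 or len(k1) == 0:
                warnings.warn(f"covariate {var!r} all-unknown in one group; skipped")
                break
            p = fisher_exact_2x2([[a, b], [c, d]])
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    f"{groups[0]}_n": a,
                    f"{groups[0]}_pct": 100.0 * a / len(k0),
                    f"{groups[1]}_n": c,
                    f"{groups[1]}_pct": 100.0 * c / len(k1),
                    "test": "fisher",
                    "p": p,
                }
            )
    for var in continuous:
        x = pd.to_numeric(g0[var], errors="coerce").dropna().to_numpy()
        y = pd.to_numeric(g1[var], errors="coerce").dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            warnings.warn(f"covariate {var!r} has no usable values in a group; skipped")
            continue
        _, p = mann_whitney(x, y)
        rows.append(
            {
                "variable": var,
                "level": None,
                f"{groups[0]}_n": x.size,
                f"{groups[0]}_pct": float(np.median(x)),
                f"{groups[1]}_n": y.size,
                f"{groups[1]}_pct": float(np.median(y)),
                "test": "mann-whitney",
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    return out
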