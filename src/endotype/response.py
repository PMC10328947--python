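"""Responder selection, Ki67-category matching and ESR1 stratification.

The anti-proliferative response to two weeks of neoadjuvant aromatase
inhibitor is measured as the proportional change in the Ki67 proliferation
index between the baseline and surgery biopsies. Poor responders (PR) are
the eligible patients in the worst ``pr_fraction`` tail of proportional
Ki67 change; good responders (GR) are drawn from the best
``gr_pool_fraction`` of responses and matched to PRs on baseline-Ki67
categories so the two groups carry comparable baseline proliferation.
PRs are further stratified by log2-normalized ESR1 expression at a fixed
threshold into ESR1-high and ESR1-low subgroups.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .de import NormalizedMatrix

__all__ = [
    "AnalysisConfig",
    "proportional_ki67_change",
    "eligibility_filter",
    "select_responder_groups",
    "stratify_by_esr1",
    "tils_category",
    "cohort_representation",
]


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds and fractions of the responder analysis.

    ``pr_fraction``: worst tail of proportional Ki67 change labelled PR.
    ``gr_pool_fraction``: best fraction forming the GR matching pool.
    ``ki67_eligibility_threshold``: baseline Ki67 must be strictly above
    this percentage. ``esr1_log2_threshold``: ESR1 log2-normalized-count
    split between HIGH and LOW strata (the boundary value is HIGH).
    ``estradiol_exclusion``: plasma estradiol strictly above this value
    (pmol/L) is excluded as not plausibly postmenopausal. ``tils_bounds``:
    (low upper bound, high lower bound) for the stromal-TILs categories.
    """

    pr_fraction: float = 0.15
    gr_pool_fraction: float = 0.50
    ki67_eligibility_threshold: float = 10.0
    esr1_log2_threshold: float = 12.0
    estradiol_exclusion: float = 130.0
    tils_bounds: tuple = (11.0, 60.0)
    match_ratio: float = 1.0
    match_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pr_fraction", "gr_pool_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("ki67_eligibility_threshold", "esr1_log2_threshold", "estradiol_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: baseline-Ki67 matching categories, half-open on the left boundary
KI67_CATEGORIES = ("10-20", "20-30", ">=30")


def ki67_category(baseline: float) -> str:
    """Baseline-Ki67 matching category: [10,20), [20,30), [30,100]."""
    if baseline < 10:
        raise ValueError(f"baseline Ki67 {baseline:g} below the eligible range")
    if baseline < 20:
        return "10-20"
    if baseline < 30:
        return "20-30"
    return ">=30"


def proportional_ki67_change(baseline, two_week):
    """Proportional Ki67 change in percent: 100*(2wk - baseline)/baseline.

    Negative values indicate suppression of proliferation.
    """
    baseline = np.asarray(baseline, dtype=float)
    two_week = np.asarray(two_week, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline Ki67 must be positive")
    out = 100.0 * (two_week - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def eligibility_filter(clinical: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.Index:
    """Patients eligible for responder selection.

    ER-positive, HER2-negative, baseline Ki67 strictly above the threshold,
    and both paired Ki67 measurements present.
    """
    config = config or AnalysisConfig()
    ok = (
        (clinical["er_status"].astype(str).str.lower() == "pos")
        & (clinical["her2_status"].astype(str).str.lower() == "neg")
        & (clinical["ki67_baseline"] > config.ki67_eligibility_threshold)
        & clinical["ki67_baseline"].notna()
        & clinical["ki67_2wk"].notna()
    )
    return pd.Index(clinical.loc[ok.fillna(False), "patient_id"])


def select_responder_groups(
    clinical: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Select poor responders and category-matched good responders.

    PRs are all eligible patients whose proportional Ki67 change lies at or
    above the ``1 - pr_fraction`` sample quantile (linear interpolation;
    ties at the threshold are all included). The GR pool is the eligible
    patients at or below the median change; GRs are drawn at random
    (seeded) within each baseline-Ki67 category to match the PR count per
    category, taking the whole pool with a warning where it is too small.

    Returns one row per eligible patient with columns ``patient_id``,
    ``pc``, ``response_class`` (GR/PR/unassigned) and ``ki67_category``.
    """
    config = config or AnalysisConfig()
    eligible = eligibility_filter(clinical, config)
    if len(eligible) == 0:
        raise ValueError("no eligible patients")
    if len(eligible) < 10:
        raise ValueError(f"too few eligible patients ({len(eligible)}) for selection")
    sub = clinical.set_index("patient_id").loc[eligible]
    pc = proportional_ki67_change(
        sub["ki67_baseline"].to_numpy(), sub["ki67_2wk"].to_numpy()
    )
    out = pd.DataFrame(
        {
            "patient_id": eligible,
            "pc": pc,
            "ki67_category": [ki67_category(b) for b in sub["ki67_baseline"]],
            "response_class": "unassigned",
        }
    )
    pr_threshold = float(np.quantile(pc, 1.0 - config.pr_fraction))
    gr_threshold = float(np.quantile(pc, config.gr_pool_fraction))
    out.loc[out["pc"] >= pr_threshold, "response_class"] = "PR"

    rng = np.random.default_rng(config.match_seed)
    pool = out[(out["pc"] <= gr_threshold) & (out["response_class"] != "PR")]
    for cat in KI67_CATEGORIES:
        n_pr = int(((out["response_class"] == "PR") & (out["ki67_category"] == cat)).sum())
        want = int(round(config.match_ratio * n_pr))
        if want == 0:
            continue
        cat_pool = pool[pool["ki67_category"] == cat]
        if len(cat_pool) < want:
            warnings.warn(
                f"GR pool has only {len(cat_pool)} patients in Ki67 category "
                f"{cat} for {n_pr} PRs; category under-matched"
            )
            chosen = cat_pool.index
        else:
            chosen = rng.choice(cat_pool.index.to_numpy(), size=want, replace=False)
        out.loc[chosen, "response_class"] = "GR"
    return out.reset_index(drop=True)


def stratify_by_esr1(
    norm: NormalizedMatrix | pd.DataFrame,
    assignment: pd.DataFrame,
    config: AnalysisConfig | None = None,
    gene: str = "ESR1",
) -> pd.DataFrame:
    """Annotate response assignments with the ESR1 stratum.

    The stratum is HIGH when log2-normalized ESR1 is at or above the
    threshold (boundary value HIGH by documented decision), LOW below it,
    and NA for patients without expression data.
    """
    config = config or AnalysisConfig()
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if gene not in values.index:
        raise KeyError(f"{gene} not present in the expression matrix")
    esr1 = values.loc[gene]
    out = assignment.copy()
    out["esr1_log2"] = out["patient_id"].map(esr1)
    out["esr1_stratum"] = np.where(
        out["esr1_log2"].isna(),
        "NA",
        np.where(out["esr1_log2"] >= config.esr1_log2_threshold, "HIGH", "LOW"),
    )
    return out


def tils_category(tils: float, config: AnalysisConfig | None = None) -> str:
    """Stromal-TILs category: low (<11), intermediate (11-59), high (>=60)."""
    config = config or AnalysisConfig()
    if not 0.0 <= tils <= 100.0:
        raise ValueError(f"TILs percentage out of [0, 100]: {tils:g}")
    low_ub, high_lb = config.tils_bounds
    if tils < low_ub:
        return "low"
    if tils < high_lb:
        return "intermediate"
    return "high"


def cohort_representation(selection_fraction: float, eligible_fraction: float) -> int:
    """Percent of the full population a selected group represents, nearest integer.

    E.g. selecting the worst 15% of the 67% eligible patients represents
    10% of the whole population; a 50% pool of the same eligible set is 34%.
    """
    return round(100.0 * selection_fraction * eligible_fraction)
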