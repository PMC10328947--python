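"""Parameter-recovery benchmarks run on synthetic cohorts.

These are the package's own validation studies: they regenerate synthetic
cohorts under the documented study conditions, run the full analysis, and
measure how well the known ground truth is recovered. Both the test suite
and the reproduction script drive them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import de as de_mod
from . import genomics, response, scoring, simulate, subtype
from .stats import fisher_exact_2x2

__all__ = [
    "calibration_benchmark",
    "de_calibration_benchmark",
    "end_to_end_run",
]


def _one_calibration_cohort(
    seed: int,
    n_patients: int,
    platform_shift_sd: float,
    n_ref: int,
    ref_error: float,
    n_iter: int,
) -> dict:
    cfg = simulate.SimConfig(
        n_patients=n_patients, seed=seed, platform_shift_sd=platform_shift_sd
    )
    _, counts, _, _, truth = simulate.generate_cohort(cfg)
    norm = de_mod.log2_normalized(counts)
    training, labels = simulate.generate_training_set(cfg, 30)
    ref = simulate.generate_reference_calls(truth, n_ref, ref_error, seed=seed + 10_000)
    calib = subtype.calibration_search(
        norm.values, ref, training, labels, truth.centroids, n_iter=n_iter, seed=seed
    )
    calls = subtype.assign_subtypes(norm.values, calib, truth.centroids)
    naive = subtype.naive_median_centering_calls(norm.values, truth.centroids)
    true_sub = truth.samples.set_index("patient_id")["subtype"]
    ref_ids = ref.index
    return {
        "seed": seed,
        "calibrated_accuracy": float(
            (calls.loc[ref_ids, "label"] == true_sub.loc[ref_ids]).mean()
        ),
        "naive_accuracy": float(
            (naive.loc[ref_ids, "label"] == true_sub.loc[ref_ids]).mean()
        ),
        "best_concordance": calib.best_concordance,
        "best_k": calib.best_k,
    }


def calibration_benchmark(
    n_cohorts: int = 20,
    n_patients: int = 300,
    platform_shift_sd: float = 0.8,
    n_ref: int = 59,
    ref_error: float = 0.03,
    n_iter: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibrated vs naive-median-centering subtype accuracy over cohorts.

    Each cohort is luminal-skewed (the default composition) with a
    per-gene platform shift between study and training platforms;
    accuracy is measured against the true subtype on the reference
    samples, whose reference calls carry ``ref_error`` label noise.
    """
    rows = [
        _one_calibration_cohort(
            seed + i, n_patients, platform_shift_sd, n_ref, ref_error, n_iter
        )
        for i in range(n_cohorts)
    ]
    return pd.DataFrame(rows)


def de_calibration_benchmark(
    seed: int = 0,
    n_null_genes: int = 10_000,
    n_spiked_genes: int = 500,
    n_background_genes: int = 5_000,
    n_per_group: int = 20,
    dispersion: float = 0.05,
    spike_log2fc: float = 2.0,
) -> dict:
    """Type-I error on null NB genes and power on spiked genes.

    Null calibration: genes drawn NB with identical means in both groups;
    the reported rate is the fraction with p < 0.05. Power: spiked genes
    with a true log2 fold change embedded in a null background, detected
    at FDR < 0.05.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    r = 1.0 / dispersion

    def nb(mu):
        return rng.negative_binomial(r, r / (r + mu))

    null_mean = rng.lognormal(5.0, 1.5, n_null_genes)
    null_counts = pd.DataFrame(
        nb(np.tile(null_mean[:, None], (1, n))),
        index=[f"null{i}" for i in range(n_null_genes)],
        columns=[f"s{j}" for j in range(n)],
    )
    res_null = de_mod.nb_wald_test(null_counts, labels)
    type1 = float((res_null["p_value"] < 0.05).mean())

    spike_mean = rng.lognormal(5.0, 1.0, n_spiked_genes) + 20.0
    mu = np.tile(spike_mean[:, None], (1, n))
    mu[:, n_per_group:] *= 2.0**spike_log2fc
    bg_mean = rng.lognormal(5.0, 1.0, n_background_genes)
    counts = pd.DataFrame(
        np.vstack([nb(mu), nb(np.tile(bg_mean[:, None], (1, n)))]),
        index=[f"spike{i}" for i in range(n_spiked_genes)]
        + [f"bg{i}" for i in range(n_background_genes)],
        columns=[f"s{j}" for j in range(n)],
    )
    res = de_mod.nb_wald_test(counts, labels)
    power = float(
        (res.loc[[f"spike{i}" for i in range(n_spiked_genes)], "fdr"] < 0.05).mean()
    )
    return {"type1_rate": type1, "power": power}


def _fisher_enrichment(flag_group: pd.Series, flag_event: pd.Series) -> dict:
    a = int((flag_group & flag_event).sum())
    b = int((flag_group & ~flag_event).sum())
    c = int((~flag_group & flag_event).sum())
    d = int((~flag_group & ~flag_event).sum())
    p = fisher_exact_2x2([[a, b], [c, d]])
    odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))  # Haldane-corrected
    return {"table": (a, b, c, d), "odds_ratio": float(odds), "p_value": float(p)}


def end_to_end_run(seed: int = 0, n_patients: int = 400, n_iter: int = 2_000) -> dict:
    """Full pipeline on one synthetic cohort: simulate, respond, subtype,
    score, genomics; returns the intermediate tables and enrichment tests."""
    cfg = simulate.SimConfig(n_patients=n_patients, seed=seed)
    clinical, counts, muts, segs, truth = simulate.generate_cohort(cfg)
    norm = de_mod.log2_normalized(counts)
    acfg = response.AnalysisConfig(match_seed=seed)
    assignment = response.select_responder_groups(clinical, acfg)
    assignment = response.stratify_by_esr1(norm, assignment, acfg)

    training, labels = simulate.generate_training_set(cfg, 30)
    ref = simulate.generate_reference_calls(truth, 59, 0.03, seed=seed + 10_000)
    calib = subtype.calibration_search(
        norm.values, ref, training, labels, truth.centroids, n_iter=n_iter, seed=seed
    )
    calls = subtype.assign_subtypes(norm.values, calib, truth.centroids)

    scores = scoring.score_matrix(norm, truth.gene_sets)
    hi = scoring.hi_ratio(norm)

    filtered, _ = genomics.filter_somatic(muts)
    called = genomics.call_segments(segs)
    tp53 = genomics.tp53_compound_status(
        filtered, called, samples=clinical["patient_id"].tolist()
    )

    truth_s = truth.samples.set_index("patient_id")
    sel = assignment[assignment["response_class"].isin(["GR", "PR"])].set_index("patient_id")
    is_pr = sel["response_class"] == "PR"
    resistant = truth_s.loc[sel.index, "resistant"]
    pr_enrichment = _fisher_enrichment(is_pr, resistant)
    compound = tp53.loc[sel.index] == "compound"
    tp53_enrichment = _fisher_enrichment(is_pr, compound)

    pr_ids = sel.index[is_pr]
    gr_ids = sel.index[~is_pr]
    tmb_cmp = genomics.group_tmb_compare(
        genomics.tmb(filtered, gr_ids), genomics.tmb(filtered, pr_ids)
    )
    return {
        "config": cfg,
        "assignment": assignment,
        "calibration": calib,
        "calls": calls,
        "scores": scores,
        "hi_ratio": hi,
        "tp53_status": tp53,
        "pr_resistance_enrichment": pr_enrichment,
        "tp53_compound_enrichment": tp53_enrichment,
        "tmb_compare": tmb_cmp,
        "truth": truth,
    }
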