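"""Synthetic ER+HER2- cohort generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage — responder selection, ESR1 stratification,
calibrated subtyping, signature scoring, differential expression and
genomic comparisons — can be exercised and validated without access to
restricted patient data:

* a study cohort with skewed (luminal-heavy) intrinsic-subtype composition
  versus a balanced training set, separated by a per-gene platform shift;
* negative-binomial gene counts whose log2 means combine subtype
  centroids, an immune program, an estradiol-coupled oestrogen-response
  program and sample noise;
* bimodal ESR1 expression with the low mode concentrated in non-luminal
  tumours;
* Ki67 response: proportional two-week change drawn from a good-responder
  distribution unless the sample is resistant, where resistance is a
  Bernoulli whose log-odds combine ESR1-low status, subtype, TP53 mutation
  and immune infiltration (intercept solved so the marginal resistant
  fraction hits its target);
* somatic driver mutations at configured per-gene prevalences plus
  filter-exercising artifact rows, and segment-level copy number with
  TP53-loss and chr6q-gain enrichment in resistant tumours.

Every random draw flows from ``SimConfig.seed`` through named child
streams, so identical configs give identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genomics import HG38_AUTOSOME_LENGTHS, TP53_LOCUS
from .subtype import SUBTYPES

__all__ = [
    "SimConfig",
    "CnaParams",
    "EstradiolParams",
    "SyntheticTruth",
    "generate_cohort",
    "generate_training_set",
    "generate_reference_calls",
    "write_cohort",
]

#: region on 6q whose gain is enriched in resistant tumours (covers ESR1)
CHR6Q_LOCUS = ("chr6", 151_000_000, 153_000_000)


@dataclasses.dataclass
class CnaParams:
    """Segment-level copy-number model parameters.

    Per-segment gain/loss probabilities apply to ordinary segments; the
    dedicated TP53 segment on chr17 and the chr6q segment are driven by
    their own event probabilities, elevated in resistant tumours. TP53
    mutant tumours get a mild genome-wide instability multiplier.
    """

    base_gain_p: float = 0.10
    base_loss_p: float = 0.10
    tp53_loss_p: float = 0.35
    tp53_loss_p_resistant: float = 0.75
    chr6q_gain_p: float = 0.10
    chr6q_gain_p_resistant: float = 0.35
    segments_per_chrom: float = 1.2
    gain_log2: float = 0.45
    loss_log2: float = -0.50
    call_sd: float = 0.08
    neutral_sd: float = 0.03
    tp53_instability_factor: float = 1.5


@dataclasses.dataclass
class EstradiolParams:
    """Plasma estradiol (pmol/L): lognormal with a resistant-stratum shift.

    The shift (log scale) applies to resistant tumours that are not
    ESR1-low, mirroring lower estradiol in ESR1-high poor responders.
    A small outlier fraction draws implausibly-postmenopausal values to
    exercise the >130 pmol/L exclusion rule.
    """

    log_mean: float = 2.71  # ~15 pmol/L
    log_sd: float = 0.55
    resistant_shift: float = -0.40
    outlier_fraction: float = 0.01
    outlier_range: tuple = (150.0, 400.0)
    missing_fraction: float = 0.05


def _default_subtype_proportions() -> dict:
    return {"LumA": 0.45, "LumB": 0.40, "HER2e": 0.08, "Basal": 0.07}


def _default_resistance_effects() -> dict:
    return {
        "esr1_low": 3.0,
        "her2e": 1.0,
        "basal": 1.5,
        "tp53_mut": 1.0,
        "immune_score": 0.8,
    }


def _default_ki67_baseline_params() -> dict:
    # (log mean, log sd) of a clipped lognormal, percent scale
    return {
        "LumA": (np.log(16.0), 0.45),
        "LumB": (np.log(30.0), 0.40),
        "HER2e": (np.log(35.0), 0.40),
        "Basal": (np.log(50.0), 0.35),
    }


def _default_mutation_prevalence() -> dict:
    return {
        "PIK3CA": 0.35, "TP53": 0.24, "CDH1": 0.10, "KMT2C": 0.10,
        "GATA3": 0.10, "MAP3K1": 0.09, "KMT2D": 0.08, "ARID1A": 0.07,
        "NCOR1": 0.06, "FOXA1": 0.06, "SPEN": 0.06, "ZFHX3": 0.06,
        "AKT1": 0.05, "CBFB": 0.05, "TBX3": 0.05, "NF1": 0.05,
        "SF3B1": 0.05, "DNAH11": 0.05, "ATM": 0.05, "PIK3R1": 0.05,
        "KMT2A": 0.05, "MAP2K4": 0.05, "BRCA2": 0.05, "RUNX1": 0.04,
        "PTEN": 0.04, "ARID1B": 0.04, "ESR1": 0.04, "PTPRD": 0.04,
        "CHEK2": 0.04, "SETD2": 0.04, "ERBB3": 0.04, "RB1": 0.03,
        "ERBB2": 0.03, "FGFR1": 0.03, "CCND1": 0.03,
    }


@dataclasses.dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions emulated."""

    n_patients: int = 400
    subtype_proportions: dict = field(default_factory=_default_subtype_proportions)
    n_pam_genes: int = 50
    n_background_genes: int = 500
    centroid_separation: float = 1.0  # log2 units, scale of latent-axis loadings
    sample_noise_sd: float = 0.6  # log2 units
    platform_shift_sd: float = 0.8  # log2 units, study-vs-training per gene
    nb_dispersion: float = 0.05
    library_size_log_mean: float = 0.0
    library_size_log_sd: float = 0.2
    # population-level fraction; ESR1-low tumours concentrate in the poor
    # responders after selection, making up roughly a third of that group
    esr1_low_fraction: float = 0.05
    resistant_fraction: float = 0.15
    resistance_effects: dict = field(default_factory=_default_resistance_effects)
    ki67_baseline_params: dict = field(default_factory=_default_ki67_baseline_params)
    gr_fall_params: tuple = (-100.0, -80.0)  # uniform bounds, percent
    pr_fall_params: tuple = (-48.0, 184.0)
    mutation_prevalence: dict = field(default_factory=_default_mutation_prevalence)
    # rate ratio of non-TP53 driver mutations in resistant tumours; the
    # per-gene marginal prevalence is preserved by lowering the sensitive-
    # stratum rate accordingly (emulates the higher burden of poor responders)
    mutation_resistant_rate_ratio: float = 1.5
    cna_params: CnaParams = field(default_factory=CnaParams)
    estradiol_params: EstradiolParams = field(default_factory=EstradiolParams)
    immune_coupling: float = 0.8  # log2 shift per immune-score SD
    estrogen_coupling: float = 0.6  # log2 shift per log-estradiol SD
    hi_resistant_shift: float = 0.5  # HOXB13 log2 shift in resistant tumours
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, expected 1")
        for name in ("esr1_low_fraction", "resistant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.mutation_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("mutation prevalences must lie in [0, 1]")
        if self.n_patients <= 0 or self.n_pam_genes <= 0 or self.n_background_genes < 0:
            raise ValueError("counts must be positive")
        unknown = set(self.subtype_proportions) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes: {sorted(unknown)}")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated cohort."""

    samples: pd.DataFrame  # per-sample latent state
    genes: pd.DataFrame  # per-gene architecture incl. platform offsets
    centroids: pd.DataFrame  # PAM genes x subtypes, training platform
    gene_sets: dict  # named programs for scoring tests


# relative propensity of ESR1-low status by subtype
_ESR1_LOW_WEIGHTS = {"LumA": 0.3, "LumB": 1.0, "HER2e": 5.0, "Basal": 8.0}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gene_architecture(config: SimConfig):
    """Deterministic (given seed) gene list, baselines, programs, centroids."""
    rng = _rng(config, 0)
    pam = [f"PAM{i + 1:03d}" for i in range(config.n_pam_genes)]
    special = ["ESR1", "HOXB13", "IL17BR", "MKI67"]
    n_bg = config.n_background_genes
    n_imm = min(40, max(n_bg // 4, 0))
    n_est = min(30, max(n_bg // 4, 0))
    immune = [f"IMM{i + 1:03d}" for i in range(n_imm)]
    estrogen = [f"ESTR{i + 1:03d}" for i in range(n_est)]
    background = [f"BG{i + 1:04d}" for i in range(n_bg - n_imm - n_est)]
    genes = pam + special + immune + estrogen + background
    baseline = pd.Series(rng.normal(8.0, 1.5, size=len(genes)), index=genes)
    baseline[["ESR1", "HOXB13", "IL17BR", "MKI67"]] = [0.0, 6.0, 6.0, 5.0]
    # correlated centroids built from shared latent axes (oestrogen-receptor,
    # proliferation, HER2, basal keratin programs): luminal subtypes differ
    # mainly on the proliferation axis, mirroring real PAM50 structure
    b = baseline[pam].to_numpy()
    u, v, w, z = rng.normal(size=(4, len(pam)))
    sep = config.centroid_separation
    centroids = pd.DataFrame(
        np.stack(
            [
                b + sep * (0.8 * u - 0.5 * v),
                b + sep * (0.8 * u + 0.5 * v),
                b + sep * (-0.3 * u + 0.5 * v + 0.9 * w),
                b + sep * (-0.9 * u + 0.7 * v + 0.9 * z),
            ],
            axis=1,
        ),
        index=pam,
        columns=list(SUBTYPES),
    )
    offsets = pd.Series(0.0, index=genes)
    offsets[pam] = _rng(config, 1).normal(0.0, config.platform_shift_sd, size=len(pam))
    component = pd.Series("background", index=genes)
    component[pam] = "pam"
    component[immune] = "immune"
    component[estrogen] = "estrogen"
    component[["ESR1", "HOXB13", "IL17BR", "MKI67"]] = ["esr1", "hi", "hi", "proliferation"]
    gene_sets = {"IMMUNE_PROGRAM": immune, "ESTROGEN_RESPONSE": estrogen}
    genes_df = pd.DataFrame(
        {"component": component, "baseline": baseline, "platform_offset": offsets}
    )
    genes_df.index.name = "gene"
    return genes_df, centroids, gene_sets


def _solve_resistance_intercept(lp: np.ndarray, target: float) -> float:
    if target <= 0:
        return -np.inf
    if target >= 1:
        return np.inf
    f = lambda b: float(np.mean(expit(b + lp))) - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _draw_samples(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, 2)
    n = config.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]
    props = np.array([config.subtype_proportions.get(s, 0.0) for s in SUBTYPES])
    subtype = rng.choice(len(SUBTYPES), size=n, p=props)
    subtype_names = np.array(SUBTYPES, dtype=object)[subtype]

    w = np.array([_ESR1_LOW_WEIGHTS[s] for s in SUBTYPES])
    denom = float((props * w).sum())
    p_low = np.clip(config.esr1_low_fraction * w / max(denom, 1e-12), 0.0, 0.95)
    esr1_low = rng.random(n) < p_low[subtype]

    immune = rng.normal(size=n)
    tp53_mut = rng.random(n) < config.mutation_prevalence.get("TP53", 0.0)

    eff = config.resistance_effects
    lp = (
        eff.get("esr1_low", 0.0) * esr1_low
        + eff.get("her2e", 0.0) * (subtype_names == "HER2e")
        + eff.get("basal", 0.0) * (subtype_names == "Basal")
        + eff.get("tp53_mut", 0.0) * tp53_mut
        + eff.get("immune_score", 0.0) * immune
    ).astype(float)
    b = _solve_resistance_intercept(lp, config.resistant_fraction)
    resistant = rng.random(n) < expit(b + lp)

    # paired Ki67
    ki67_base = np.empty(n)
    for i, s in enumerate(subtype_names):
        m, sd = config.ki67_baseline_params[s]
        ki67_base[i] = np.exp(rng.normal(m, sd))
    ki67_base = np.clip(ki67_base, 2.0, 97.0).round(1)
    pc = np.where(
        resistant,
        rng.uniform(*config.pr_fall_params, size=n),
        rng.uniform(*config.gr_fall_params, size=n),
    )
    ki67_2wk = np.clip(ki67_base * (1.0 + pc / 100.0), 0.0, 100.0).round(1)

    # plasma estradiol
    ep = config.estradiol_params
    log_e2 = rng.normal(ep.log_mean, ep.log_sd, size=n)
    log_e2 = log_e2 + ep.resistant_shift * (resistant & ~esr1_low)
    estradiol = np.exp(log_e2)
    outlier = rng.random(n) < ep.outlier_fraction
    estradiol[outlier] = rng.uniform(*ep.outlier_range, size=int(outlier.sum()))
    e2_z = (log_e2 - ep.log_mean) / ep.log_sd

    # stromal TILs: zero-inflated Beta on [0, 60), pushed up by immune score
    tils = np.zeros(n)
    nonzero = rng.random(n) >= 0.25
    beta_b = 8.0 * np.exp(-0.6 * immune)
    tils[nonzero] = 60.0 * rng.beta(1.2, beta_b[nonzero])
    tils = tils.round(1)

    grade_probs = {
        "LumA": (0.20, 0.68, 0.12),
        "LumB": (0.05, 0.60, 0.35),
        "HER2e": (0.03, 0.47, 0.50),
        "Basal": (0.01, 0.24, 0.75),
    }
    grade = np.array(
        [rng.choice(["1", "2", "3"], p=grade_probs[s]) for s in subtype_names],
        dtype=object,
    )
    grade[rng.random(n) < 0.02] = "unknown"
    histology = rng.choice(["IDC", "ILC", "other"], size=n, p=[0.86, 0.11, 0.03]).astype(object)
    histology[rng.random(n) < 0.01] = "unknown"
    chemo = np.where(rng.random(n) < 0.25 + 0.15 * resistant, "yes", "no").astype(object)
    chemo[rng.random(n) < 0.02] = "unknown"

    er_status = np.where(rng.random(n) < 0.02, "neg", "pos")
    her2_status = np.where(rng.random(n) < 0.03, "pos", "neg")
    miss_2wk = rng.random(n) < 0.02
    miss_e2 = rng.random(n) < ep.missing_fraction
    miss_tils = rng.random(n) < 0.003

    return pd.DataFrame(
        {
            "patient_id": ids,
            "subtype": subtype_names,
            "esr1_low": esr1_low,
            "immune_score": immune,
            "tp53_mut": tp53_mut,
            "resistant": resistant,
            "ki67_baseline": ki67_base,
            "ki67_2wk": np.where(miss_2wk, np.nan, ki67_2wk),
            "pc_true": pc,
            "estradiol": np.where(miss_e2, np.nan, estradiol.round(1)),
            "e2_z": e2_z,
            "tils": np.where(miss_tils, np.nan, tils),
            "grade": grade,
            "histology": histology,
            "chemo": chemo,
            "er_status": er_status,
            "her2_status": her2_status,
        }
    )


def _expression_log2(
    config: SimConfig,
    samples: pd.DataFrame,
    genes_df: pd.DataFrame,
    centroids: pd.DataFrame,
    rng: np.random.Generator,
    platform_shift: bool,
) -> np.ndarray:
    """Noise-free plus sample-noise log2 expression, genes x samples."""
    n = len(samples)
    genes = genes_df.index
    x = np.tile(genes_df["baseline"].to_numpy()[:, None], (1, n))
    pam_mask = (genes_df["component"] == "pam").to_numpy()
    sub_idx = samples["subtype"].map({s: i for i, s in enumerate(SUBTYPES)}).to_numpy()
    x[pam_mask, :] = centroids.to_numpy()[:, sub_idx]

    imm = (genes_df["component"] == "immune").to_numpy()
    est = (genes_df["component"] == "estrogen").to_numpy()
    x[imm, :] += config.immune_coupling * samples["immune_score"].to_numpy()[None, :]
    x[est, :] += config.estrogen_coupling * samples["e2_z"].to_numpy()[None, :]

    gi = {g: i for i, g in enumerate(genes)}
    esr1_mode = np.where(samples["esr1_low"], 9.5, 13.5)
    x[gi["ESR1"], :] = esr1_mode
    x[gi["HOXB13"], :] += config.hi_resistant_shift * samples["resistant"].to_numpy()
    x[gi["MKI67"], :] += 0.03 * samples["ki67_baseline"].to_numpy()

    x += rng.normal(0.0, config.sample_noise_sd, size=x.shape)
    if platform_shift:
        x += genes_df["platform_offset"].to_numpy()[:, None]
    return x


def _counts_from_log2(
    config: SimConfig, x: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[1]
    lib = np.exp(rng.normal(config.library_size_log_mean, config.library_size_log_sd, size=n))
    mu = lib[None, :] * np.power(2.0, x)
    if config.nb_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return counts.astype(np.int64), lib


def _draw_mutations(config: SimConfig, samples: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 4)
    ids = samples["patient_id"].to_numpy()
    n = len(ids)
    rows = []
    classifications = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]

    def driver_row(sample, gene):
        vaf = 0.05 + 0.55 * rng.beta(2.0, 3.0)
        depth = int(rng.integers(80, 300))
        alt = max(5, int(round(vaf * depth)))
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                "vaf": round(vaf, 4),
                "alt_reads": alt,
                "consequence_class": rng.choice(["high", "moderate"], p=[0.4, 0.6]),
                "pop_af": 0.0,
                "variant_classification": rng.choice(classifications, p=[0.6, 0.15, 0.15, 0.1]),
            }
        )

    resistant = samples["resistant"].to_numpy()
    rr = config.mutation_resistant_rate_ratio
    f_res = config.resistant_fraction
    for gene, prev in config.mutation_prevalence.items():
        if gene == "TP53":
            carriers = samples["tp53_mut"].to_numpy()
        else:
            # marginal prevalence preserved: prev = f*r*p + (1-f)*p
            p_sens = prev / (f_res * rr + (1.0 - f_res))
            p = np.where(resistant, np.minimum(rr * p_sens, 1.0), p_sens)
            carriers = rng.random(n) < p
        for sample in ids[carriers]:
            driver_row(sample, gene)

    panel = list(config.mutation_prevalence)
    modes = ["low_vaf", "low_alt", "low_consequence", "common_af"]
    for sample in ids:
        for _ in range(rng.poisson(1.5)):
            mode = rng.choice(modes)
            gene = panel[int(rng.integers(len(panel)))]
            vaf = 0.05 + 0.25 * rng.beta(2.0, 3.0)
            depth = int(rng.integers(80, 300))
            alt = max(5, int(round(vaf * depth)))
            csq = rng.choice(["high", "moderate"], p=[0.4, 0.6])
            pop_af = 0.0
            if mode == "low_vaf":
                vaf = float(rng.uniform(0.005, 0.049))
                alt = max(1, int(round(vaf * depth)))
            elif mode == "low_alt":
                alt = int(rng.integers(1, 5))
                depth = int(rng.integers(20, 60))
                vaf = alt / depth
            elif mode == "low_consequence":
                csq = rng.choice(["low", "modifier"])
            else:
                pop_af = float(10 ** rng.uniform(-4.0, -2.0))
            rows.append(
                {
                    "sample_id": sample,
                    "gene": gene,
                    "vaf": round(vaf, 4),
                    "alt_reads": alt,
                    "consequence_class": csq,
                    "pop_af": pop_af,
                    "variant_classification": rng.choice(classifications, p=[0.6, 0.15, 0.15, 0.1]),
                }
            )
    return pd.DataFrame(rows)


def _draw_segments(config: SimConfig, samples: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, 5)
    cp = config.cna_params
    tp53_chrom, tp53_start, tp53_end = TP53_LOCUS
    six_chrom, six_start, six_end = CHR6Q_LOCUS
    # carve the special loci out as dedicated segments
    forced = {
        tp53_chrom: (7_000_000, 7_700_000),
        six_chrom: (six_start, six_end),
    }
    assert forced[tp53_chrom][0] <= tp53_start and tp53_end <= forced[tp53_chrom][1]
    rows = []
    resistant = samples["resistant"].to_numpy()
    tp53_mut = samples["tp53_mut"].to_numpy()
    tp53_loss = np.empty(len(samples), dtype=bool)
    chr6q_gain = np.empty(len(samples), dtype=bool)
    for i, sample in enumerate(samples["patient_id"]):
        amp = cp.tp53_instability_factor if tp53_mut[i] else 1.0
        gain_p = min(cp.base_gain_p * amp, 0.45)
        loss_p = min(cp.base_loss_p * amp, 0.45)
        p_tp53 = cp.tp53_loss_p_resistant if resistant[i] else cp.tp53_loss_p
        p_6q = cp.chr6q_gain_p_resistant if resistant[i] else cp.chr6q_gain_p
        tp53_loss[i] = rng.random() < p_tp53
        chr6q_gain[i] = rng.random() < p_6q
        for chrom, length in HG38_AUTOSOME_LENGTHS.items():
            cuts = {0, length}
            if chrom in forced:
                cuts.update(forced[chrom])
            n_extra = rng.poisson(cp.segments_per_chrom)
            cuts.update(int(v) for v in rng.integers(1, length, size=n_extra))
            edges = sorted(cuts)
            for s, e in zip(edges[:-1], edges[1:]):
                if chrom in forced and (s, e) == forced[chrom]:
                    if chrom == tp53_chrom:
                        state = "loss" if tp53_loss[i] else "neutral"
                    else:
                        state = "gain" if chr6q_gain[i] else "neutral"
                else:
                    u = rng.random()
                    state = "gain" if u < gain_p else "loss" if u < gain_p + loss_p else "neutral"
                if state == "gain":
                    lr = rng.normal(cp.gain_log2, cp.call_sd)
                elif state == "loss":
                    lr = rng.normal(cp.loss_log2, cp.call_sd)
                else:
                    lr = rng.normal(0.0, cp.neutral_sd)
                rows.append((sample, chrom, s, e, round(float(lr), 4)))
    seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "log2_ratio"])
    seg.attrs["tp53_loss"] = tp53_loss
    seg.attrs["chr6q_gain"] = chr6q_gain
    return seg


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a study cohort.

    Returns ``(clinical, counts, mutations, segments, truth)``: the
    clinical covariate table, the gene-by-sample integer count matrix (with
    the study-side platform shift applied to the PAM genes), the MAF-like
    mutation table, the SEG-style segment table (0-based half-open), and
    the ground truth.
    """
    genes_df, centroids, gene_sets = _gene_architecture(config)
    samples = _draw_samples(config)
    rng_expr = _rng(config, 3)
    x = _expression_log2(config, samples, genes_df, centroids, rng_expr, platform_shift=True)
    counts, lib = _counts_from_log2(config, x, rng_expr)
    counts_df = pd.DataFrame(
        counts, index=genes_df.index.copy(), columns=samples["patient_id"].to_numpy()
    )
    counts_df.columns.name = None
    mutations = _draw_mutations(config, samples)
    segments = _draw_segments(config, samples)

    truth_samples = samples.copy()
    truth_samples["tp53_loss"] = segments.attrs["tp53_loss"]
    truth_samples["chr6q_gain"] = segments.attrs["chr6q_gain"]
    truth_samples["library_factor"] = lib
    truth_samples["esr1_stratum_true"] = np.where(truth_samples["esr1_low"], "LOW", "HIGH")

    clinical = samples[
        [
            "patient_id", "ki67_baseline", "ki67_2wk", "er_status", "her2_status",
            "grade", "histology", "chemo", "estradiol", "tils",
        ]
    ].copy()
    truth = SyntheticTruth(
        samples=truth_samples, genes=genes_df, centroids=centroids, gene_sets=gene_sets
    )
    return clinical, counts_df, mutations, segments, truth


def generate_training_set(
    config: SimConfig, n_per_subtype: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Balanced training expression matrix on the centroid (training) platform.

    PAM genes only, ``n_per_subtype`` samples per subtype, log2 scale with
    sample noise but no platform shift and no count noise (microarray-like).
    """
    if n_per_subtype < 1:
        raise ValueError("n_per_subtype must be >= 1")
    genes_df, centroids, _ = _gene_architecture(config)
    rng = _rng(config, 6)
    cols, labels, blocks = [], [], []
    for s in SUBTYPES:
        mu = centroids[s].to_numpy()[:, None]
        block = mu + rng.normal(0.0, config.sample_noise_sd, size=(len(centroids), n_per_subtype))
        blocks.append(block)
        cols += [f"TR_{s}_{i + 1:03d}" for i in range(n_per_subtype)]
        labels += [s] * n_per_subtype
    matrix = pd.DataFrame(np.hstack(blocks), index=centroids.index, columns=cols)
    return matrix, pd.Series(labels, index=cols, name="subtype")


def generate_reference_calls(
    truth: SyntheticTruth, n_ref: int, error_rate: float = 0.0, seed: int = 0
) -> pd.Series:
    """Reference subtype calls for a random subset of the cohort.

    Emulates an orthogonal assay applied to ``n_ref`` samples: each call
    equals the true subtype with probability ``1 - error_rate``, otherwise
    one of the other subtypes uniformly.
    """
    n = len(truth.samples)
    if not 0 < n_ref <= n:
        raise ValueError(f"n_ref must lie in 1..{n}, got {n_ref}")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_ref, replace=False)
    chosen = truth.samples.iloc[idx]
    calls = []
    for s in chosen["subtype"]:
        if rng.random() < error_rate:
            others = [t for t in SUBTYPES if t != s]
            calls.append(others[int(rng.integers(len(others)))])
        else:
            calls.append(s)
    return pd.Series(calls, index=chosen["patient_id"].to_numpy(), name="reference_call")


def write_cohort(out_dir, clinical, counts, mutations, segments, truth) -> None:
    """Write a simulated cohort to plain-text files in ``out_dir``."""
    from pathlib import Path

    from . import io as eio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_counts(counts, out / "counts.tsv")
    eio.write_clinical(clinical, out / "clinical.csv")
    eio.write_maf(mutations, out / "mutations.maf.tsv")
    eio.write_seg(segments, out / "segments.seg")
    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.centroids.to_csv(out / "centroids.tsv", sep="\t")
    eio.write_gmt(truth.gene_sets, out / "programs.gmt")
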