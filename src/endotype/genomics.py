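"""Somatic-mutation and copy-number comparisons between response groups.

Mutations are filtered to likely-somatic, protein-altering events (VAF >=
5%, >= 5 alternate reads, high/moderate consequence, population allele
frequency < 1e-5) before per-gene Fisher comparisons and tumour mutation
burden. Copy-number segments are thresholded into gain/loss/neutral calls,
projected onto ~3 Mbp genomic bins by majority overlap, and compared per
bin and direction between groups. Chromosomal instability is the fraction
of the covered genome carrying a gain or loss, and compound TP53 status
flags tumours with both a retained TP53 mutation and copy-number loss at
the TP53 locus.

Coordinates are 0-based half-open throughout (the readers convert from the
1-based inclusive on-disk SEG convention).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .de import bh_adjust
from .stats import fisher_exact_2x2, mann_whitney

__all__ = [
    "HG38_AUTOSOME_LENGTHS",
    "TP53_LOCUS",
    "filter_somatic",
    "tmb",
    "group_tmb_compare",
    "gene_mutation_compare",
    "call_segments",
    "bin_cna",
    "bin_group_compare",
    "chromosomal_instability",
    "tp53_compound_status",
]

#: hg38 autosome lengths (bp), chr1..chr22
HG38_AUTOSOME_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}

#: TP53 gene body on hg38 (0-based half-open), configurable in callers
TP53_LOCUS = ("chr17", 7_668_420, 7_687_490)


@dataclasses.dataclass
class FilterLog:
    """Counts of mutation rows removed by each somatic filter."""

    input_rows: int
    removed_vaf: int
    removed_alt_reads: int
    removed_consequence: int
    removed_pop_af: int
    retained: int


def filter_somatic(
    muts: pd.DataFrame,
    min_vaf: float = 0.05,
    min_alt_reads: int = 5,
    consequences: tuple[str, ...] = ("high", "moderate"),
    max_pop_af: float = 1e-5,
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the somatic filters conjunctively; returns (retained rows, log).

    Null population AFs are treated as absent from the population databases
    (i.e. they pass the rarity filter); null VAF or alt-read counts fail
    their filters.
    """
    vaf_ok = muts["vaf"] >= min_vaf
    alt_ok = pd.to_numeric(muts["alt_reads"], errors="coerce") >= min_alt_reads
    csq_ok = muts["consequence_class"].astype(str).str.lower().isin(consequences)
    af = pd.to_numeric(muts["pop_af"], errors="coerce")
    af_ok = af.isna() | (af < max_pop_af)
    keep = vaf_ok.fillna(False) & alt_ok.fillna(False) & csq_ok & af_ok
    log = FilterLog(
        input_rows=len(muts),
        removed_vaf=int((~vaf_ok.fillna(False)).sum()),
        removed_alt_reads=int((~alt_ok.fillna(False)).sum()),
        removed_consequence=int((~csq_ok).sum()),
        removed_pop_af=int((~af_ok).sum()),
        retained=int(keep.sum()),
    )
    return muts[keep].copy(), log


def tmb(filtered: pd.DataFrame, samples=None) -> pd.Series:
    """Tumour mutation burden: retained mutations per sample.

    ``samples`` optionally supplies the full cohort so tumours with zero
    retained mutations contribute 0 rather than being absent.
    """
    counts = filtered.groupby("sample_id").size()
    if samples is not None:
        counts = counts.reindex(pd.Index(samples), fill_value=0)
    return counts.rename("tmb").astype(float)


def group_tmb_compare(tmb_a: pd.Series, tmb_b: pd.Series) -> dict:
    """Group TMB means plus a two-sided Mann-Whitney comparison."""
    if tmb_a.empty or tmb_b.empty:
        raise ValueError("both groups must be non-empty")
    u, p = mann_whitney(tmb_a.to_numpy(), tmb_b.to_numpy())
    return {
        "mean_a": float(tmb_a.mean()),
        "mean_b": float(tmb_b.mean()),
        "u_stat": u,
        "p_value": p,
    }


def gene_mutation_compare(
    filtered_a: pd.DataFrame,
    filtered_b: pd.DataFrame,
    n_a: int,
    n_b: int,
    min_mutated: int = 3,
) -> pd.DataFrame:
    """Per-gene mutated-vs-wild-type Fisher comparison between two cohorts.

    ``n_a`` and ``n_b`` are the cohort sizes (a sample with no retained
    mutations is wild-type everywhere). Genes with fewer than
    ``min_mutated`` mutated samples in total are skipped; BH adjustment
    runs across the tested genes.
    """
    mut_a = filtered_a.groupby("gene")["sample_id"].nunique()
    mut_b = filtered_b.groupby("gene")["sample_id"].nunique()
    genes = sorted(set(mut_a.index) | set(mut_b.index))
    rows = []
    for gene in genes:
        a = int(mut_a.get(gene, 0))
        b = int(mut_b.get(gene, 0))
        if a + b < min_mutated:
            continue
        p = fisher_exact_2x2([[a, n_a - a], [b, n_b - b]])
        rows.append(
            {
                "gene": gene,
                "mutated_a": a,
                "mutated_b": b,
                "frac_a": a / n_a,
                "frac_b": b / n_b,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.set_index("gene")
    return out


# ---------------------------------------------------------------------------
# copy number


def call_segments(
    segs: pd.DataFrame, gain_log2: float = 0.2, loss_log2: float = -0.2
) -> pd.DataFrame:
    """Threshold segment log2 ratios into gain/neutral/loss calls.

    Boundaries are inclusive: log2 ratio >= gain threshold is a gain,
    <= loss threshold a loss.
    """
    out = segs.copy()
    lr = out["log2_ratio"].to_numpy(dtype=float)
    out["call"] = np.where(lr >= gain_log2, "gain", np.where(lr <= loss_log2, "loss", "neutral"))
    return out


def _bin_edges(length: int, bin_size: int) -> np.ndarray:
    n = int(np.ceil(length / bin_size))
    edges = np.arange(n + 1, dtype=np.int64) * bin_size
    edges[-1] = length
    return edges


def bin_cna(
    called: pd.DataFrame,
    bin_size: int = 3_000_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Project segment calls onto a fixed genomic bin tiling.

    Each bin takes the call of whichever call class (gain/neutral/loss)
    covers most of it; coverage ties resolve to neutral and bins with no
    overlapping segment are flagged ``uncovered``. Returns a long-format
    DataFrame (sample_id, chrom, start, end, call).
    """
    chrom_lengths = chrom_lengths or HG38_AUTOSOME_LENGTHS
    samples = sorted(called["sample_id"].unique())
    classes = ("gain", "neutral", "loss")
    chrom_bins = {
        chrom: _bin_edges(length, bin_size) for chrom, length in chrom_lengths.items()
    }
    by_sample_chrom = dict(tuple(called.groupby(["sample_id", "chrom"], sort=False)))
    records = []
    for sample in samples:
        for chrom, edges in chrom_bins.items():
            starts, ends = edges[:-1], edges[1:]
            grp = by_sample_chrom.get((sample, chrom))
            if grp is None:
                calls = np.full(starts.size, "uncovered", dtype=object)
            else:
                seg_s = grp["start"].to_numpy()[None, :]
                seg_e = grp["end"].to_numpy()[None, :]
                ov = np.maximum(
                    np.minimum(ends[:, None], seg_e) - np.maximum(starts[:, None], seg_s), 0
                )  # (n_bins, n_segs)
                seg_cls = grp["call"].to_numpy()
                cover = np.stack(
                    [ov[:, seg_cls == c].sum(axis=1) for c in classes], axis=1
                )  # (n_bins, 3)
                best = cover.max(axis=1)
                n_best = (cover == best[:, None]).sum(axis=1)
                winner = np.array(classes, dtype=object)[np.argmax(cover, axis=1)]
                calls = np.where(best == 0, "uncovered", np.where(n_best > 1, "neutral", winner))
            for s, e, c in zip(starts, ends, calls):
                records.append((sample, chrom, int(s), int(e), c))
    return pd.DataFrame(
        records, columns=["sample_id", "chrom", "start", "end", "call"]
    )


def bin_group_compare(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> pd.DataFrame:
    """Per-bin, per-direction Fisher comparison of CNA calls between groups.

    For each bin and each direction (gain, loss) the 2x2 table is
    (has that call, does not) by group, over samples with a covered bin;
    BH adjustment runs across all bin-by-direction tests.
    """
    key = ["chrom", "start", "end"]
    tiling_a = bins_a[key].drop_duplicates().reset_index(drop=True)
    tiling_b = bins_b[key].drop_duplicates().reset_index(drop=True)
    if not tiling_a.equals(tiling_b):
        raise ValueError("groups must share the same bin tiling")
    rows = []
    grp_a = bins_a.groupby(key, sort=False)
    grp_b = bins_b.groupby(key, sort=False)
    for bin_key, sub_a in grp_a:
        sub_b = grp_b.get_group(bin_key)
        cov_a = sub_a[sub_a["call"] != "uncovered"]
        cov_b = sub_b[sub_b["call"] != "uncovered"]
        if cov_a.empty or cov_b.empty:
            continue
        for direction in ("gain", "loss"):
            a = int((cov_a["call"] == direction).sum())
            b = int((cov_b["call"] == direction).sum())
            p = fisher_exact_2x2(
                [[a, len(cov_a) - a], [b, len(cov_b) - b]]
            )
            rows.append(
                {
                    "chrom": bin_key[0],
                    "start": bin_key[1],
                    "end": bin_key[2],
                    "direction": direction,
                    "frac_a": a / len(cov_a),
                    "frac_b": b / len(cov_b),
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def chromosomal_instability(called: pd.DataFrame) -> pd.Series:
    """Fraction of each sample's covered genome carrying a gain or loss."""
    lengths = (called["end"] - called["start"]).to_numpy()
    if np.any(lengths <= 0):
        raise ValueError("segments must have positive length")
    df = called.assign(_len=lengths, _alt=(called["call"] != "neutral") * lengths)
    agg = df.groupby("sample_id").agg(total=("_len", "sum"), altered=("_alt", "sum"))
    if (agg["total"] == 0).any():
        raise ValueError("sample with zero covered length")
    return (agg["altered"] / agg["total"]).rename("cin")


def tp53_compound_status(
    filtered_muts: pd.DataFrame,
    called: pd.DataFrame,
    tp53_locus: tuple[str, int, int] = TP53_LOCUS,
    samples=None,
    gene: str = "TP53",
) -> pd.Series:
    """Per-sample TP53 status: compound / mut_only / loss_only / neither.

    ``compound`` requires at least one retained TP53 mutation and at least
    one loss-called segment overlapping the TP53 locus.
    """
    chrom, start, end = tp53_locus
    mut_samples = set(filtered_muts.loc[filtered_muts["gene"] == gene, "sample_id"])
    loss = called[
        (called["call"] == "loss")
        & (called["chrom"] == chrom)
        & (called["start"] < end)
        & (called["end"] > start)
    ]
    loss_samples = set(loss["sample_id"])
    if samples is None:
        samples = sorted(set(called["sample_id"]) | set(filtered_muts["sample_id"]))
    status = []
    for s in samples:
        has_mut = s in mut_samples
        has_loss = s in loss_samples
        status.append(
            "compound" if has_mut and has_loss
            else "mut_only" if has_mut
            else "loss_only" if has_loss
            else "neither"
        )
    return pd.Series(status, index=pd.Index(samples, name="sample_id"), name="tp53_status")
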