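"""Somatic-mutation filtering and copy-number comparison behaviour."""

import numpy as np
import pandas as pd
import pytest

from endotype import genomics
from endotype.stats import fisher_exact_2x2


def _muts(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "vaf", "alt_reads", "consequence_class", "pop_af"],
    )


@pytest.fixture()
def mixed_muts():
    return _muts(
        [
            ("S1", "TP53", 0.30, 30, "high", 0.0),        # retained
            ("S1", "PIK3CA", 0.04, 10, "high", 0.0),      # low VAF
            ("S2", "TP53", 0.20, 4, "moderate", 0.0),     # low alt reads
            ("S2", "GATA3", 0.25, 25, "low", 0.0),        # low consequence
            ("S3", "CDH1", 0.25, 25, "high", 1e-3),       # common in population
            ("S3", "TP53", 0.50, 60, "moderate", None),   # retained (null AF passes)
        ]
    )


class TestFilterSomatic:
    def test_each_rule_applied(self, mixed_muts):
        kept, log = genomics.filter_somatic(mixed_muts)
        assert len(kept) == 2
        assert set(kept["sample_id"]) == {"S1", "S3"}
        assert log.removed_vaf == 1
        assert log.removed_alt_reads == 1
        assert log.removed_consequence == 1
        assert log.removed_pop_af == 1
        assert log.retained == 2

    def test_conjunction_order_independent(self, mixed_muts):
        kept, _ = genomics.filter_somatic(mixed_muts)
        # apply the same rules one at a time in a different order
        step = mixed_muts[pd.to_numeric(mixed_muts["pop_af"]).fillna(0) < 1e-5]
        step = step[step["consequence_class"].isin(["high", "moderate"])]
        step = step[step["alt_reads"] >= 5]
        step = step[step["vaf"] >= 0.05]
        assert set(map(tuple, kept[["sample_id", "gene"]].values)) == set(
            map(tuple, step[["sample_id", "gene"]].values)
        )

    def test_retained_subset_of_input(self, small_cohort):
        kept, log = genomics.filter_somatic(small_cohort["mutations"])
        assert log.retained <= log.input_rows
        assert kept.index.isin(small_cohort["mutations"].index).all()


class TestTmb:
    def test_zero_mutation_sample(self, mixed_muts):
        kept, _ = genomics.filter_somatic(mixed_muts)
        burden = genomics.tmb(kept, samples=["S1", "S2", "S3"])
        assert burden["S2"] == 0.0
        assert burden["S1"] == 1.0

    def test_identical_groups_not_significant(self):
        a = pd.Series([1.0, 2.0, 3.0, 2.0])
        res = genomics.group_tmb_compare(a, a.copy())
        assert res["p_value"] > 0.8
        assert res["mean_a"] == res["mean_b"]

    def test_enriched_group_recovered(self, rng):
        a = pd.Series(rng.poisson(2.5, 120).astype(float))
        b = pd.Series(rng.poisson(4.0, 120).astype(float))
        res = genomics.group_tmb_compare(a, b)
        assert res["mean_b"] > res["mean_a"]
        assert res["p_value"] < 0.01


class TestGeneMutationCompare:
    def test_sparse_gene_skipped_and_extreme_table(self):
        fa = _muts([(f"A{i}", "TP53", 0.3, 20, "high", 0.0) for i in range(10)])
        fb = _muts([("B0", "RARE", 0.3, 20, "high", 0.0)])
        res = genomics.gene_mutation_compare(fa, fb, 10, 10, min_mutated=3)
        assert "RARE" not in res.index
        assert res.loc["TP53", "p_value"] == pytest.approx(
            fisher_exact_2x2([[10, 0], [0, 10]])
        )

    def test_equal_prevalence_fdr_controlled(self, rng):
        rows_a, rows_b = [], []
        for g in range(40):
            for i in range(60):
                if rng.random() < 0.15:
                    rows_a.append((f"A{i}", f"G{g}", 0.3, 20, "high", 0.0))
                if rng.random() < 0.15:
                    rows_b.append((f"B{i}", f"G{g}", 0.3, 20, "high", 0.0))
        res = genomics.gene_mutation_compare(_muts(rows_a), _muts(rows_b), 60, 60)
        assert (res["fdr"] < 0.05).mean() <= 0.05


class TestSegmentCalls:
    @pytest.mark.parametrize(
        "lr,call", [(0.0, "neutral"), (0.2, "gain"), (-0.2, "loss"), (-0.5, "loss"), (0.19, "neutral")]
    )
    def test_thresholds_inclusive(self, lr, call):
        segs = pd.DataFrame(
            {"sample_id": ["S"], "chrom": ["chr1"], "start": [0], "end": [100], "log2_ratio": [lr]}
        )
        assert genomics.call_segments(segs).loc[0, "call"] == call


class TestBinCna:
    def test_whole_chromosome_gain(self):
        segs = pd.DataFrame(
            {"sample_id": ["S"], "chrom": ["chr21"], "start": [0],
             "end": [genomics.HG38_AUTOSOME_LENGTHS["chr21"]], "log2_ratio": [0.5]}
        )
        bins = genomics.bin_cna(genomics.call_segments(segs), chrom_lengths={"chr21": genomics.HG38_AUTOSOME_LENGTHS["chr21"]})
        assert (bins["call"] == "gain").all()

    def test_majority_overlap_wins(self):
        # 40% loss / 60% gain within one 3 Mbp bin
        segs = pd.DataFrame(
            {
                "sample_id": ["S", "S"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 1_200_000],
                "end": [1_200_000, 3_000_000],
                "log2_ratio": [-0.5, 0.5],
            }
        )
        bins = genomics.bin_cna(genomics.call_segments(segs), chrom_lengths={"chr1": 3_000_000})
        assert bins.loc[0, "call"] == "gain"

    def test_uncovered_bin_flagged(self):
        segs = pd.DataFrame(
            {"sample_id": ["S"], "chrom": ["chr1"], "start": [0], "end": [3_000_000], "log2_ratio": [0.0]}
        )
        bins = genomics.bin_cna(genomics.call_segments(segs), chrom_lengths={"chr1": 6_000_000})
        assert bins["call"].tolist() == ["neutral", "uncovered"]


class TestBinGroupCompare:
    def _bins(self, frac_gain, n, prefix):
        rng = np.random.default_rng(hash(prefix) % 2**31)
        rows = []
        for i in range(n):
            call = "gain" if rng.random() < frac_gain else "neutral"
            rows.append((f"{prefix}{i}", "chr1", 0, 3_000_000, call))
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "call"])

    def test_identical_groups_nothing_significant(self):
        a = self._bins(0.3, 100, "A")
        res = genomics.bin_group_compare(a, a.rename(columns={}))
        assert (res["fdr"] < 0.05).sum() == 0

    def test_strong_difference_detected(self):
        res = genomics.bin_group_compare(self._bins(0.8, 100, "A"), self._bins(0.05, 100, "B"))
        gain = res[res["direction"] == "gain"]
        assert (gain["fdr"] < 0.05).all()

    def test_tiling_mismatch_rejected(self):
        a = self._bins(0.3, 10, "A")
        b = self._bins(0.3, 10, "B")
        b["end"] = 4_000_000
        with pytest.raises(ValueError):
            genomics.bin_group_compare(a, b)


class TestChromosomalInstability:
    def test_extremes(self):
        def seg(lr):
            return pd.DataFrame(
                {"sample_id": ["S"], "chrom": ["chr1"], "start": [0], "end": [100], "log2_ratio": [lr]}
            )

        assert genomics.chromosomal_instability(genomics.call_segments(seg(0.0)))["S"] == 0.0
        assert genomics.chromosomal_instability(genomics.call_segments(seg(0.9)))["S"] == 1.0

    def test_half_lost(self):
        segs = pd.DataFrame(
            {"sample_id": ["S"] * 2, "chrom": ["chr1"] * 2, "start": [0, 100],
             "end": [100, 200], "log2_ratio": [-0.6, 0.0]}
        )
        assert genomics.chromosomal_instability(genomics.call_segments(segs))["S"] == 0.5

    def test_invariant_under_segment_splitting(self):
        whole = pd.DataFrame(
            {"sample_id": ["S"], "chrom": ["chr1"], "start": [0], "end": [900], "log2_ratio": [0.6]}
        )
        split = pd.DataFrame(
            {"sample_id": ["S"] * 3, "chrom": ["chr1"] * 3, "start": [0, 300, 600],
             "end": [300, 600, 900], "log2_ratio": [0.6] * 3}
        )
        a = genomics.chromosomal_instability(genomics.call_segments(whole))
        b = genomics.chromosomal_instability(genomics.call_segments(split))
        assert a["S"] == b["S"]


class TestTp53Compound:
    def _loss_seg(self, sample, lr=-0.6):
        chrom, start, end = genomics.TP53_LOCUS
        return (sample, chrom, start - 1000, end + 1000, lr)

    def test_status_classes(self):
        muts = _muts([("S1", "TP53", 0.3, 20, "high", 0.0), ("S2", "TP53", 0.3, 20, "high", 0.0)])
        segs = pd.DataFrame(
            [self._loss_seg("S1"), self._loss_seg("S2", 0.0), self._loss_seg("S3")],
            columns=["sample_id", "chrom", "start", "end", "log2_ratio"],
        )
        called = genomics.call_segments(segs)
        status = genomics.tp53_compound_status(muts, called, samples=["S1", "S2", "S3", "S4"])
        assert status.to_dict() == {
            "S1": "compound", "S2": "mut_only", "S3": "loss_only", "S4": "neither"
        }

    def test_nonoverlapping_loss_does_not_count(self):
        muts = _muts([("S1", "TP53", 0.3, 20, "high", 0.0)])
        chrom, start, end = genomics.TP53_LOCUS
        segs = pd.DataFrame(
            [("S1", chrom, end + 10_000, end + 50_000, -0.6)],
            columns=["sample_id", "chrom", "start", "end", "log2_ratio"],
        )
        status = genomics.tp53_compound_status(muts, genomics.call_segments(segs))
        assert status["S1"] == "mut_only"
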