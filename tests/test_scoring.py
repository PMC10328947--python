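"""Signature scoring: ssGSEA oracle equivalence, GSEA behaviour, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import endotype as et
from endotype import scoring
from endotype.de import NormalizedMatrix


def ssgsea_oracle(expr: pd.Series, gene_set, alpha=0.25) -> float:
    """Direct loop evaluation of the weighted-ECDF running sum."""
    genes = list(expr.index)
    ranks = sps.rankdata(expr.to_numpy())  # ascending, average ties
    order = sorted(range(len(genes)), key=lambda i: (-expr.iloc[i], genes[i]))
    members = set(gene_set)
    w_total = sum(abs(ranks[i]) ** alpha for i in order if genes[i] in members)
    n_out = sum(1 for g in genes if g not in members)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in order:
        if genes[i] in members:
            cum_in += abs(ranks[i]) ** alpha / w_total
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


class TestSsgsea:
    def test_top_placement_is_maximal(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.Series(np.sort(rng.normal(size=30))[::-1], index=genes)
        top = scoring.ssgsea_score(expr, genes[:5])
        for _ in range(50):
            other = list(rng.choice(genes, size=5, replace=False))
            assert scoring.ssgsea_score(expr, other) <= top + 1e-12
        assert top > 0

    def test_identical_samples_identical_scores(self, rng):
        genes = [f"g{i}" for i in range(40)]
        expr = pd.Series(rng.normal(size=40), index=genes)
        s = scoring.ssgsea_score(expr, genes[3:10])
        assert scoring.ssgsea_score(expr.copy(), genes[3:10]) == s

    def test_matches_bruteforce_oracle(self, rng):
        genes = [f"g{i}" for i in range(25)]
        for _ in range(20):
            expr = pd.Series(rng.normal(size=25), index=genes)
            members = list(rng.choice(genes, size=int(rng.integers(2, 10)), replace=False))
            assert scoring.ssgsea_score(expr, members) == pytest.approx(
                ssgsea_oracle(expr, members), abs=1e-12
            )

    def test_rank_invariance_under_monotone_transform(self, rng):
        genes = [f"g{i}" for i in range(20)]
        expr = pd.Series(rng.normal(size=20), index=genes)
        members = genes[::4]
        assert scoring.ssgsea_score(expr, members) == pytest.approx(
            scoring.ssgsea_score(np.exp(expr), members), abs=1e-12
        )

    def test_complementary_sets_sum_to_zero_at_alpha0(self, rng):
        genes = [f"g{i}" for i in range(15)]
        expr = pd.Series(rng.normal(size=15), index=genes)
        a = scoring.ssgsea_score(expr, genes[:6], alpha=0.0)
        b = scoring.ssgsea_score(expr, genes[6:], alpha=0.0)
        assert a + b == pytest.approx(0.0, abs=1e-10)

    def test_no_overlap_warns_nan(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="no overlap"):
            assert np.isnan(scoring.ssgsea_score(expr, ["zzz"]))


class TestScoreMatrix:
    def test_size_filter_and_duplicates(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = pd.DataFrame(
            rng.normal(size=(30, 4)), index=genes, columns=list("ABCD")
        )
        sets = {"small": genes[:2], "ok": genes[:8], "dup": genes[:8]}
        scores = scoring.score_matrix(values, sets, min_size=5)
        assert "small" not in scores.index
        assert np.allclose(scores.loc["ok"], scores.loc["dup"])

    def test_empty_collection(self, rng):
        values = pd.DataFrame(np.zeros((3, 2)), index=list("abc"), columns=["S1", "S2"])
        assert scoring.score_matrix(values, {}).empty


class TestPrerankedGsea:
    def _ranking(self, rng, n=300):
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_extreme_top_set(self, rng):
        stats = self._ranking(rng)
        top = list(stats.sort_values(ascending=False).index[:20])
        res = scoring.preranked_gsea(stats, {"TOP": top}, n_perm=200, seed=0)
        assert res.table.loc["TOP", "es"] > 0
        assert res.table.loc["TOP", "p_value"] <= 1.0 / 201.0 + 1e-12

    def test_reversed_ranking_flips_es(self, rng):
        stats = self._ranking(rng)
        sets = {
            "A": [f"g{i}" for i in range(0, 300, 17)],
            "B": list(stats.sort_values().index[:25]),
        }
        fwd = scoring.preranked_gsea(stats, sets, n_perm=100, seed=1)
        rev = scoring.preranked_gsea(-stats, sets, n_perm=100, seed=1)
        for name in sets:
            assert fwd.table.loc[name, "es"] == pytest.approx(
                -rev.table.loc[name, "es"], abs=1e-12
            )

    def test_null_p_uniform(self):
        rng = np.random.default_rng(123)
        stats = self._ranking(rng, n=400)
        sets = {
            f"R{k}": list(rng.choice(stats.index.to_numpy(), size=20, replace=False))
            for k in range(60)
        }
        res = scoring.preranked_gsea(stats, sets, n_perm=200, seed=7)
        assert sps.kstest(res.table["p_value"], "uniform").pvalue > 1e-3

    def test_min_permutations_enforced(self, rng):
        stats = self._ranking(rng)
        with pytest.raises(ValueError):
            scoring.preranked_gsea(stats, {"A": ["g1"]}, n_perm=10)


class TestHiRatio:
    def test_equal_expression_zero(self):
        values = pd.DataFrame(
            {"S1": [5.0, 5.0], "S2": [7.0, 5.0]}, index=["HOXB13", "IL17BR"]
        )
        norm = NormalizedMatrix(values=values, size_factors=pd.Series(1.0, index=["S1", "S2"]))
        hi = et.hi_ratio(norm)
        assert hi["S1"] == pytest.approx(0.0)
        assert hi["S2"] == pytest.approx(2.0)  # 4x on the linear scale

    def test_missing_gene_rejected(self, toy_norm):
        with pytest.raises(KeyError):
            et.hi_ratio(toy_norm, hoxb13="NOPE")

    def test_resistant_shift_direction(self, small_cohort, small_norm):
        truth = small_cohort["truth"].samples.set_index("patient_id")
        hi = et.hi_ratio(small_norm)
        assert hi[truth.resistant].mean() > hi[~truth.resistant].mean()


class TestCorrelations:
    def test_self_and_negated_rows(self, rng):
        base = rng.normal(size=20)
        scores = pd.DataFrame(
            {"s": base, "neg": -base, "other": rng.normal(size=20)}
        ).T
        scores.columns = [f"P{i}" for i in range(20)]
        rho, fdr = scoring.score_correlation_matrix(scores)
        assert rho.loc["s", "s"] == pytest.approx(1.0)
        assert rho.loc["s", "neg"] == pytest.approx(-1.0)
        assert rho.equals(rho.T)

    def test_independent_rows_fdr_calibrated(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(
            rng.normal(size=(12, 80)), index=[f"S{i}" for i in range(12)]
        )
        _, fdr = scoring.score_correlation_matrix(scores)
        iu = np.triu_indices(12, 1)
        assert (fdr.to_numpy()[iu] < 0.05).mean() <= 0.05

    def test_covariate_exclusion_rule(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(2, 10)), index=["A", "B"], columns=[f"P{i}" for i in range(10)]
        )
        cov = pd.Series(np.linspace(10, 100, 10), index=scores.columns)
        cov.iloc[0] = 135.0  # above the estradiol exclusion threshold
        res = scoring.covariate_score_correlation(cov, scores, exclusion_threshold=130.0)
        assert (res["n"] == 9).all()

    def test_covariate_identical_to_score(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(2, 12)), index=["A", "B"], columns=[f"P{i}" for i in range(12)]
        )
        res = scoring.covariate_score_correlation(scores.loc["A"], scores)
        assert res.loc["A", "rho"] == pytest.approx(1.0)

    def test_too_few_usable_samples(self, rng):
        scores = pd.DataFrame(rng.normal(size=(1, 4)), index=["A"], columns=list("wxyz"))
        cov = pd.Series([np.nan, np.nan, 1.0, 2.0], index=list("wxyz"))
        with pytest.raises(ValueError):
            scoring.covariate_score_correlation(cov, scores)


class TestSignatureScorer:
    def test_transformer_matches_score_matrix(self, small_norm, small_cohort):
        sets = small_cohort["truth"].gene_sets
        X = small_norm.values.T.iloc[:10]
        scorer = scoring.SignatureScorer(gene_sets=sets)
        out = scorer.fit(X).transform(X)
        direct = scoring.score_matrix(X.T, sets)
        assert np.allclose(out.to_numpy(), direct.T.to_numpy())

    def test_estradiol_coupling_recovered(self, small_cohort, small_norm):
        # configured estradiol -> oestrogen-response coupling shows up as a
        # positive, significant Spearman correlation
        truth = small_cohort["truth"]
        scores = scoring.score_matrix(small_norm, truth.gene_sets)
        clinical = small_cohort["clinical"].set_index("patient_id")
        res = scoring.covariate_score_correlation(
            clinical["estradiol"], scores, exclusion_threshold=130.0
        )
        row = res.loc["ESTROGEN_RESPONSE"]
        assert row["rho"] > 0 and row["fdr"] < 0.05
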