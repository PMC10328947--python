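"""Nearest-centroid subtyping and the calibration search."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from sklearn.base import clone

import endotype as et
from endotype import subtype as st


@pytest.fixture(scope="module")
def toy_centroids(rng=None):
    rng = np.random.default_rng(99)
    genes = [f"g{i}" for i in range(12)]
    return pd.DataFrame(
        rng.normal(8, 2, size=(12, 4)), index=genes, columns=list(st.SUBTYPES)
    )


class TestCentering:
    def test_zero_vector_identity(self, toy_centroids):
        v = pd.Series(0.0, index=toy_centroids.index)
        assert st.gene_center(toy_centroids, v).equals(toy_centroids)

    def test_constant_vector_shifts(self, toy_centroids):
        v = pd.Series(2.5, index=toy_centroids.index)
        out = st.gene_center(toy_centroids, v)
        assert np.allclose(out.to_numpy(), toy_centroids.to_numpy() - 2.5)

    def test_median_center_zeroes_medians(self, rng):
        m = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 9)))
        v = st.median_centering_vector(m)
        assert np.allclose(st.gene_center(m, v).median(axis=1), 0.0)

    def test_median_vector_examples(self):
        single = pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"])
        assert st.median_centering_vector(single).tolist() == [1.0, 2.0]
        two = pd.DataFrame({"S1": [0.0], "S2": [4.0]}, index=["a"])
        assert st.median_centering_vector(two).tolist() == [2.0]
        five = pd.DataFrame(
            [[5, 1, 3, 2, 4], [10, 30, 20, 50, 40]], index=["a", "b"],
            columns=list("vwxyz"),
        )
        assert st.median_centering_vector(five).tolist() == [3.0, 30.0]

    def test_missing_gene_rejected(self, toy_centroids):
        v = pd.Series(0.0, index=toy_centroids.index[:-1])
        with pytest.raises(KeyError):
            st.gene_center(toy_centroids, v)


class TestCentroidCorrelate:
    def test_self_correlation(self, toy_centroids):
        sample = toy_centroids[["LumA"]].rename(columns={"LumA": "S1"})
        call = st.centroid_correlate(sample, toy_centroids)
        assert call.loc["S1", "label"] == "LumA"
        assert call.loc["S1", "confidence"] == pytest.approx(1.0)

    def test_anticorrelation_lowest(self, toy_centroids):
        ranks = sps.rankdata(toy_centroids["Basal"])
        sample = pd.DataFrame({"S1": -ranks}, index=toy_centroids.index)
        call = st.centroid_correlate(sample, toy_centroids)
        assert call.loc["S1", "Basal"] == call.loc["S1", list(st.SUBTYPES)].min()

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(6)]
        cents = pd.DataFrame(rng.normal(size=(6, 4)), index=genes, columns=list(st.SUBTYPES))
        sample = pd.DataFrame({"S1": rng.normal(size=6)}, index=genes)
        call = st.centroid_correlate(sample, cents)
        for s in st.SUBTYPES:
            oracle = sps.spearmanr(sample["S1"], cents[s])[0]
            assert call.loc["S1", s] == pytest.approx(oracle, rel=1e-12)

    def test_constant_profile_unclassifiable(self, toy_centroids):
        sample = pd.DataFrame({"S1": np.ones(12)}, index=toy_centroids.index)
        call = st.centroid_correlate(sample, toy_centroids)
        assert bool(call.loc["S1", "unclassifiable"])
        assert call.loc["S1", "label"] == "unclassifiable"

    def test_monotone_transform_invariance(self, toy_centroids):
        rng = np.random.default_rng(8)
        sample = pd.DataFrame({"S1": rng.normal(8, 2, 12)}, index=toy_centroids.index)
        a = st.centroid_correlate(sample, toy_centroids)
        b = st.centroid_correlate(np.exp(sample / 3.0), toy_centroids)
        assert np.allclose(
            a[list(st.SUBTYPES)].to_numpy(), b[list(st.SUBTYPES)].to_numpy()
        )


class TestCompositionMatchedSubset:
    def test_exact_composition(self):
        labels = pd.Series(["Basal"] * 10 + ["HER2e"] * 10 + ["LumB"] * 10)
        idx = st.composition_matched_subset(
            labels, {"Basal": 4, "HER2e": 3, "LumB": 1}, rng=0
        )
        assert len(idx) == 8
        got = labels.iloc[idx].value_counts().to_dict()
        assert got == {"Basal": 4, "HER2e": 3, "LumB": 1}

    def test_empty_target_rejected(self):
        labels = pd.Series(["Basal"] * 5)
        with pytest.raises(ValueError):
            st.composition_matched_subset(labels, {"Basal": 0})

    def test_insufficient_pool_signals_redraw(self):
        labels = pd.Series(["Basal"] * 2)
        with pytest.raises(st.InsufficientPoolError):
            st.composition_matched_subset(labels, {"Basal": 4})


def _calibration_inputs(seed=1, shift=0.0, n=200, noise=0.3):
    cfg = et.SimConfig(
        n_patients=n, seed=seed, platform_shift_sd=shift, sample_noise_sd=noise
    )
    clinical, counts, _, _, truth = et.generate_cohort(cfg)
    norm = et.log2_normalized(counts)
    training, labels = et.generate_training_set(cfg, 25)
    ref = et.generate_reference_calls(truth, 40, 0.0, seed=seed + 1)
    return norm, training, labels, ref, truth


class TestCalibrationSearch:
    def test_shift_free_limit_perfect_concordance(self):
        norm, training, labels, ref, truth = _calibration_inputs()
        calib = st.calibration_search(
            norm.values, ref, training, labels, truth.centroids, n_iter=500, seed=2
        )
        assert calib.best_concordance == pytest.approx(1.0)
        assert 5 <= calib.best_k <= 15

    def test_determinism_and_nested_seed_monotonicity(self):
        norm, training, labels, ref, truth = _calibration_inputs(seed=3, shift=0.8)
        run = lambda n_iter: st.calibration_search(
            norm.values, ref, training, labels, truth.centroids, n_iter=n_iter, seed=9
        )
        a, a2, b = run(300), run(300), run(900)
        assert a.centering_vector.equals(a2.centering_vector)
        assert b.best_concordance >= a.best_concordance

    def test_concordance_matches_reassignment(self):
        norm, training, labels, ref, truth = _calibration_inputs(seed=4, shift=0.8)
        calib = st.calibration_search(
            norm.values, ref, training, labels, truth.centroids, n_iter=400, seed=1
        )
        calls = st.assign_subtypes(norm.values, calib, truth.centroids)
        concordance = (calls.loc[ref.index, "label"] == ref).mean()
        assert concordance == pytest.approx(calib.best_concordance)

    def test_study_side_offset_cancels(self):
        # a per-gene vector added to the study matrix is absorbed by the
        # centering vector, leaving calibrated calls invariant
        norm, training, labels, ref, truth = _calibration_inputs(seed=5)
        w = pd.Series(
            np.random.default_rng(0).normal(0, 2, len(norm.values)),
            index=norm.values.index,
        )
        calib1 = st.calibration_search(
            norm.values, ref, training, labels, truth.centroids, n_iter=200, seed=4
        )
        calib2 = st.calibration_search(
            norm.values.add(w, axis=0), ref, training, labels, truth.centroids,
            n_iter=200, seed=4,
        )
        calls1 = st.assign_subtypes(norm.values, calib1, truth.centroids)
        calls2 = st.assign_subtypes(norm.values.add(w, axis=0), calib2, truth.centroids)
        assert calls1["label"].equals(calls2["label"])
        diff = calib2.centering_vector - calib1.centering_vector
        assert np.allclose(diff, w.reindex(diff.index), atol=1e-10)

    def test_bad_args_rejected(self):
        norm, training, labels, ref, truth = _calibration_inputs()
        with pytest.raises(ValueError):
            st.calibration_search(
                norm.values, ref, training, labels, truth.centroids, n_iter=0
            )
        with pytest.raises(ValueError):
            st.calibration_search(
                norm.values, ref.iloc[:0], training, labels, truth.centroids, n_iter=10
            )


class TestAssignSubtypes:
    def test_recovers_centroid_copies(self, toy_centroids):
        rng = np.random.default_rng(2)
        cols, labels = [], []
        blocks = []
        for s in st.SUBTYPES:
            for i in range(3):
                blocks.append(toy_centroids[s].to_numpy() + rng.normal(0, 0.01, 12))
                cols.append(f"{s}_{i}")
                labels.append(s)
        matrix = pd.DataFrame(np.column_stack(blocks), index=toy_centroids.index, columns=cols)
        calib = st.CalibrationResult(
            centering_vector=pd.Series(0.0, index=toy_centroids.index),
            best_k=5, best_composition={}, best_concordance=1.0,
            iterations_run=1, seed=0,
        )
        calls = st.assign_subtypes(matrix, calib, toy_centroids)
        assert calls["label"].tolist() == labels


class TestEstimator:
    def test_fit_predict_and_sklearn_protocol(self):
        norm, training, labels, ref, truth = _calibration_inputs(seed=6)
        clf = st.CalibratedSubtypeClassifier(
            centroids=truth.centroids, training=training, training_labels=labels,
            n_iter=300, random_state=0,
        )
        clone(clf)  # get_params/set_params round-trip
        X_ref = norm.values.loc[truth.centroids.index, ref.index].T
        clf.fit(X_ref, ref.to_numpy())
        assert 0.9 <= clf.best_concordance_ <= 1.0
        X_all = norm.values.loc[truth.centroids.index].T
        preds = clf.predict(X_all)
        tr = truth.samples.set_index("patient_id")
        assert (preds == tr.loc[X_all.index, "subtype"]).mean() > 0.9
        assert clf.score(X_ref, ref.to_numpy()) == pytest.approx(clf.best_concordance_)
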