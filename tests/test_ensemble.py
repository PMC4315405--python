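"""Bootstrap ensemble, Chebyshev reject option, and the model/results API."""

import math

import numpy as np
import pandas as pd
import pytest

from pathoforest.ensemble import (
    BootstrapForestClassifier,
    BootstrapForestResults,
    EnsembleConfig,
    chebyshev_classify,
    chebyshev_k,
    stratified_bootstrap,
)


class TestStratifiedBootstrap:
    def test_per_class_counts_preserved(self):
        labels = np.array([1] * 10 + [0] * 14)
        rng = np.random.default_rng(0)
        for _ in range(5):
            idx = stratified_bootstrap(labels, rng)
            assert len(idx) == 24
            assert labels[idx].sum() == 10

    def test_seed_determinism_and_variation(self):
        labels = np.array([1] * 30 + [0] * 30)
        a = stratified_bootstrap(labels, np.random.default_rng(42))
        b = stratified_bootstrap(labels, np.random.default_rng(42))
        assert np.array_equal(a, b)
        # different seeds give different multisets with overwhelming probability
        draws = {
            tuple(sorted(stratified_bootstrap(labels, np.random.default_rng(s))))
            for s in range(20)
        }
        assert len(draws) == 20

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_bootstrap(np.zeros(10), np.random.default_rng(0))


class TestChebyshev:
    def test_k_at_95(self):
        assert chebyshev_k(0.95) == pytest.approx(math.sqrt(20))

    def test_confident_pathogenic(self):
        # 0.9 +/- sqrt(20)*0.01 = 0.9 +/- 0.0447 excludes 0.5
        assert chebyshev_classify(0.9, 0.01, 0.95) == "pathogenic"

    def test_wide_interval_unknown(self):
        # 0.6 +/- 0.447 contains 0.5
        assert chebyshev_classify(0.6, 0.1, 0.95) == "unknown"

    def test_midpoint_always_unknown(self):
        for sigma in (0.0, 0.05, 1.0):
            assert chebyshev_classify(0.5, sigma, 0.95) == "unknown"

    def test_boundary_endpoint_is_unknown(self):
        # interval endpoint exactly at 0.5 does not exclude it
        k = chebyshev_k(0.75)  # k = 2
        assert chebyshev_classify(0.6, 0.05, 0.75) == "unknown"
        assert chebyshev_classify(0.6, 0.049, 0.75) == "pathogenic"
        assert k == pytest.approx(2.0)

    def test_zero_sigma_decided_by_mu(self):
        assert chebyshev_classify(0.51, 0.0, 0.9999) == "pathogenic"
        assert chebyshev_classify(0.49, 0.0, 0.9999) == "neutral"

    def test_invalid_confidence(self):
        for c in (0.0, 1.0, -1.0, 2.0):
            with pytest.raises(ValueError):
                chebyshev_classify(0.5, 0.1, c)


class TestTraining:
    def test_separable_data_high_heldout_accuracy(self, fitted_separable, separable_split):
        _, _, X_test, y_test = separable_split
        preds = fitted_separable.predict(X_test)
        acc = (preds.frame["binary_call"] == y_test).mean()
        assert acc > 0.9

    def test_smoke_config_member_count(self, separable_split):
        X_train, y_train, _, _ = separable_split
        cfg = EnsembleConfig(n_bootstrap=2, n_trees=5, seed=0)
        res = BootstrapForestClassifier(X_train, y_train, config=cfg, go_feature=None).fit()
        assert res.n_members == 2

    def test_seed_reproducibility_bit_identical(self, separable_split):
        X_train, y_train, X_test, _, = separable_split
        cfg = EnsembleConfig(n_bootstrap=4, n_trees=10, seed=9)
        p1 = (
            BootstrapForestClassifier(X_train, y_train, config=cfg, go_feature=None)
            .fit()
            .predict(X_test)
        )
        p2 = (
            BootstrapForestClassifier(X_train, y_train, config=cfg, go_feature=None)
            .fit()
            .predict(X_test)
        )
        assert np.array_equal(p1.member_probs, p2.member_probs)

    def test_fully_missing_column_rejected(self, separable_split):
        X_train, y_train, _, _ = separable_split
        X = X_train.copy()
        X["dead"] = np.nan
        with pytest.raises(ValueError, match="dead"):
            BootstrapForestClassifier(X, y_train)

    def test_single_class_rejected(self, separable_split):
        X_train, y_train, _, _ = separable_split
        with pytest.raises(ValueError, match="both classes"):
            BootstrapForestClassifier(X_train, ["pathogenic"] * len(X_train))

    def test_prediction_invariant_to_row_order(self, fitted_separable, separable_split):
        _, _, X_test, _ = separable_split
        perm = np.random.default_rng(0).permutation(len(X_test))
        straight = fitted_separable.predict(X_test).frame
        shuffled = fitted_separable.predict(X_test.iloc[perm]).frame
        merged = straight["mu"].loc[shuffled.index]
        assert np.allclose(merged.to_numpy(), shuffled["mu"].to_numpy())


class TestRejectOption:
    def test_member_probs_in_unit_interval(self, fitted_overlap, overlap_split):
        _, _, X_test, _ = overlap_split
        probs = fitted_overlap.member_probabilities(X_test)
        assert probs.shape == (len(X_test), fitted_overlap.n_members)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_coverage_monotone_in_confidence(self, fitted_overlap, overlap_split):
        _, _, X_test, _ = overlap_split
        coverages = [
            fitted_overlap.predict(X_test, confidence=c).coverage
            for c in (0.5, 0.8, 0.95, 0.99)
        ]
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))

    def test_raising_confidence_never_classifies_an_unknown(
        self, fitted_overlap, overlap_split
    ):
        _, _, X_test, _ = overlap_split
        lo = fitted_overlap.predict(X_test, confidence=0.8).frame["call"]
        hi = fitted_overlap.predict(X_test, confidence=0.95).frame["call"]
        became_classified = (lo == "unknown") & (hi != "unknown")
        assert not became_classified.any()

    def test_classified_only_accuracy_at_least_binary(self, fitted_overlap, overlap_split):
        _, _, X_test, y_test = overlap_split
        preds = fitted_overlap.predict(X_test, confidence=0.95).frame
        classified = preds["call"] != "unknown"
        assert classified.any()
        acc_reliable = (preds.loc[classified, "call"] == y_test[classified]).mean()
        acc_all = (preds["binary_call"] == y_test).mean()
        assert acc_reliable >= acc_all

    def test_ambiguous_point_rejected_then_classified(self, fitted_overlap, overlap_data):
        # a point in the class-overlap region: high member spread around 0.5
        cols = fitted_overlap.feature_names
        row = {c: 0.0 for c in cols}
        for c in ("inf_1", "inf_2", "inf_3"):
            row[c] = 0.7  # middle of the overlapping supports
        row["omega"] = 0.6
        X = pd.DataFrame([row], index=["ambig"])[cols]
        strict = fitted_overlap.predict(X, confidence=0.95).frame["call"].iloc[0]
        assert strict == "unknown"
        # at low confidence the interval shrinks toward mu and more of the
        # batch is classified
        batch = pd.DataFrame(
            [
                {**row, "inf_1": v, "inf_2": v, "inf_3": v}
                for v in np.linspace(0.3, 1.1, 9)
            ],
            index=[f"q{i}" for i in range(9)],
        )[cols]
        cov_lo = fitted_overlap.predict(batch, confidence=0.5).coverage
        cov_hi = fitted_overlap.predict(batch, confidence=0.95).coverage
        assert cov_lo > cov_hi


class TestAnnotationCombination:
    def test_zero_prior_identity(self, fitted_overlap, overlap_split):
        _, _, X_test, _ = overlap_split
        pa = pd.Series(0.0, index=X_test.index)
        plain = fitted_overlap.predict(X_test)
        with_pa = fitted_overlap.predict(X_test, annotation_pa=pa)
        assert np.allclose(plain.frame["mu"], with_pa.frame["mu"])
        assert (plain.frame["call"] == with_pa.frame["call"]).all()
        assert with_pa.frame["combined"].all()

    def test_unit_prior_absorbing(self, fitted_overlap, overlap_split):
        _, _, X_test, _ = overlap_split
        pa = pd.Series(1.0, index=X_test.index)
        preds = fitted_overlap.predict(X_test, annotation_pa=pa, confidence=0.999)
        assert np.allclose(preds.frame["mu"], 1.0)
        assert np.allclose(preds.frame["sigma"], 0.0)
        assert (preds.frame["call"] == "pathogenic").all()

    def test_per_member_combination_moves_the_interval(self, fitted_overlap, overlap_split):
        _, _, X_test, _ = overlap_split
        pa = pd.Series(0.9, index=X_test.index)
        plain = fitted_overlap.predict(X_test, confidence=0.95)
        combined = fitted_overlap.predict(X_test, annotation_pa=pa, confidence=0.95)
        # noisy-OR with a strong prior shrinks spread, so rejection decreases
        assert combined.coverage >= plain.coverage
        assert (combined.frame["sigma"] <= plain.frame["sigma"] + 1e-12).all()


class TestGoFallback:
    def test_rows_missing_go_served_by_fallback(self, separable_data):
        X = separable_data.features.values.copy()
        y = separable_data.dataset.labels
        X = X.rename(columns={"inf_1": "go_lr"})
        X.loc[X.index[:20], "go_lr"] = np.nan
        cfg = EnsembleConfig(n_bootstrap=4, n_trees=10, seed=1)
        res = BootstrapForestClassifier(X, y, config=cfg, go_feature="go_lr").fit()
        assert res.fallback_members is not None
        assert "go_lr" not in res.fallback_feature_names
        preds = res.predict(X)
        assert len(preds.frame) == len(X)
        assert preds.frame["mu"].notna().all()
        # imputation-only mode has no fallback ensemble
        res2 = BootstrapForestClassifier(
            X, y, config=cfg, go_feature="go_lr", go_fallback=False
        ).fit()
        assert res2.fallback_members is None


class TestPersistence:
    def test_save_load_identical_predictions(self, fitted_separable, separable_split, tmp_path):
        _, _, X_test, _ = separable_split
        fitted_separable.save(tmp_path / "model")
        loaded = BootstrapForestResults.load(tmp_path / "model")
        a = fitted_separable.predict(X_test)
        b = loaded.predict(X_test)
        assert np.array_equal(a.member_probs, b.member_probs)
        assert (a.frame["call"] == b.frame["call"]).all()

    def test_summary_mentions_config(self, fitted_separable):
        text = fitted_separable.summary()
        assert "members" in text and "trees" in text and "0.95" in text
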