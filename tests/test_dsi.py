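import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from petselect import DIAGNOSES, cross_validate, dsi_profile, fit_pair_models
from petselect.dsi import (
    DSIClassifier,
    aggregate_profiles,
    composite_pairwise_dsi,
    feature_dsi,
    feature_dsi_batch,
    fit_feature_evidence,
    make_folds,
    weighted_composite,
    youden_relevance,
)


# -- independent counting oracles (used again by the acceptance sweep) ----------

def oracle_direction(p, n):
    """Orientation from integer-exact mean comparison."""
    p, n = np.asarray(p, float), np.asarray(n, float)
    return 1 if p.sum() * n.size >= n.sum() * p.size else -1


def oracle_relevance(p, n):
    """Max Youden index by explicit comparison at every candidate threshold."""
    d = oracle_direction(p, n)
    po, no = d * np.asarray(p, float), d * np.asarray(n, float)
    best = 0.0
    for t in np.unique(np.concatenate([po, no])):
        sens = (po >= t).mean()
        spec = (no < t).mean()
        best = max(best, sens + spec - 1.0)
    return d, best


def oracle_dsi(p, n, x):
    """FN/(FN+FP) by explicit counting (0.5 in the degenerate gap)."""
    d = oracle_direction(p, n)
    po, no = d * np.asarray(p, float), d * np.asarray(n, float)
    xo = d * x
    fn = (po < xo).mean()
    fp = (no >= xo).mean()
    return 0.5 if fn + fp == 0 else fn / (fn + fp)


# -- per-feature evidence ---------------------------------------------------------

class TestRelevance:
    def test_interleaved_samples(self):
        ev = fit_feature_evidence("f", "continuous", [2, 4, 6], [1, 3, 5])
        assert ev.direction == 1  # mean 4 > mean 3
        assert ev.relevance == pytest.approx(1 / 3)

    def test_identical_multisets_are_irrelevant(self):
        ev = fit_feature_evidence("f", "continuous", [1, 2, 3], [1, 2, 3])
        assert ev.relevance == 0.0

    def test_full_separation_is_maximal(self):
        ev = fit_feature_evidence("f", "continuous", [10, 11], [1, 2])
        assert ev.relevance == 1.0

    def test_too_few_training_values_drops_feature(self):
        assert fit_feature_evidence("f", "continuous", [1.0], [1, 2, 3]) is None
        assert fit_feature_evidence("f", "continuous", [1, np.nan], [1, 2]) is None

    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
        st.lists(st.integers(0, 4), min_size=2, max_size=8),
    )
    def test_matches_counting_oracle_on_random_samples(self, p, n):
        ev = fit_feature_evidence("f", "continuous", p, n)
        d, rel = oracle_relevance(p, n)
        assert ev.direction == d
        assert ev.relevance == pytest.approx(rel, abs=1e-12)


class TestFeatureDSI:
    def test_balanced_query_point(self):
        ev = fit_feature_evidence("f", "continuous", [2, 4, 6], [1, 3, 5])
        assert feature_dsi(ev, 3.5) == pytest.approx(0.5)  # FN=1/3, FP=1/3

    def test_deep_limits(self):
        ev = fit_feature_evidence("f", "continuous", [2, 4, 6], [1, 3, 5])
        assert feature_dsi(ev, -10.0) == 0.0
        assert feature_dsi(ev, 10.0) == 1.0

    def test_degenerate_gap_returns_half(self):
        # max(N) < x <= min(P): FN = FP = 0
        ev = fit_feature_evidence("f", "continuous", [10, 11], [1, 2])
        assert feature_dsi(ev, 5.0) == 0.5

    def test_binary_laplace_rates(self):
        # 68/98 carriers smooth to 0.69; 38/98 to 0.39
        p = [1.0] * 68 + [0.0] * 30
        n = [1.0] * 38 + [0.0] * 60
        ev = fit_feature_evidence("apoe", "binary", p, n)
        assert ev.p_rate == pytest.approx(0.69)
        assert ev.n_rate == pytest.approx(0.39)
        assert feature_dsi(ev, 1.0) == pytest.approx(0.69 / 1.08)

    def test_missing_value_rejected(self):
        ev = fit_feature_evidence("f", "continuous", [2, 4], [1, 3])
        with pytest.raises(ValueError):
            feature_dsi(ev, float("nan"))

    @given(st.data())
    def test_monotone_and_bounded_after_orientation(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        p = rng.normal(1.0, 1.0, size=data.draw(st.integers(2, 20)))
        n = rng.normal(0.0, 1.0, size=data.draw(st.integers(2, 20)))
        ev = fit_feature_evidence("f", "continuous", p, n)
        xs = rng.normal(0.5, 2.0, size=25)
        # order queries by oriented value; DSI must be non-decreasing along it
        xs = xs[np.argsort(ev.direction * xs)]
        vals = feature_dsi_batch(ev, xs)
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)
        assert np.all(np.diff(vals) >= -1e-12)


# -- composites and profiles -------------------------------------------------------

class TestComposite:
    def test_equal_weights_reduce_to_mean(self):
        assert weighted_composite([0.8, 0.4], [1.0, 1.0]) == pytest.approx(0.6)

    def test_zero_relevance_feature_contributes_nothing(self):
        assert weighted_composite([0.8, 0.4], [1.0, 0.0]) == pytest.approx(0.8)

    def test_weighted_mean_arithmetic(self):
        out = weighted_composite([1.0, 0.0, 0.5], [0.5, 0.25, 0.25])
        assert out == pytest.approx(0.625)

    def test_undefined_when_no_positive_weight(self):
        assert weighted_composite([0.3], [0.0]) is None

    def test_patient_missing_features_skipped(self):
        X = pd.DataFrame({"f": [2.0, 3.0, 1.0, 2.0], "g": [1.0, 1.0, 0.0, 0.0]})
        y = ["AD", "AD", "CN", "CN"]
        clf = DSIClassifier().fit(X, y)
        model = clf.pair_models_[("CN", "AD")]
        full = composite_pairwise_dsi(model, {"f": 1.5, "g": 0.5})
        only_f = composite_pairwise_dsi(model, {"f": 1.5})
        assert full is not None and only_f is not None
        ev_f = model.evidence["f"]
        assert only_f == pytest.approx(feature_dsi(ev_f, 1.5))


class TestProfiles:
    def test_group_value_is_mean_of_its_three_pairs(self):
        pair_vals = {
            ("AD", "CN"): np.array([0.9]),
            ("AD", "FTD"): np.array([0.6]),
            ("AD", "VaD"): np.array([0.75]),
            ("CN", "FTD"): np.array([0.5]),
            ("CN", "VaD"): np.array([0.5]),
            ("FTD", "VaD"): np.array([0.5]),
        }
        frame = aggregate_profiles(pair_vals, list(DIAGNOSES), ["p1"])
        assert frame.loc["p1", "AD"] == pytest.approx((0.9 + 0.6 + 0.75) / 3)
        # CN sees AD-CN reversed: (1-0.9 + 0.5 + 0.5)/3
        assert frame.loc["p1", "CN"] == pytest.approx((0.1 + 0.5 + 0.5) / 3)

    def test_exact_four_way_tie_breaks_to_canonical_first(self):
        pair_vals = {pair: np.array([0.5]) for pair in [
            ("CN", "AD"), ("CN", "FTD"), ("CN", "VaD"),
            ("AD", "FTD"), ("AD", "VaD"), ("FTD", "VaD")]}
        frame = aggregate_profiles(pair_vals, list(DIAGNOSES), ["p1"])
        assert frame.loc["p1", "top_label"] == "CN"
        assert bool(frame.loc["p1", "tie_flag"])
        assert frame.loc["p1", "margin"] == 0.0

    def test_margin_is_gap_between_two_highest(self):
        pair_vals = {
            ("CN", "AD"): np.array([0.2]),
            ("CN", "FTD"): np.array([0.3]),
            ("CN", "VaD"): np.array([0.3]),
            ("AD", "FTD"): np.array([0.9]),
            ("AD", "VaD"): np.array([0.9]),
            ("FTD", "VaD"): np.array([0.5]),
        }
        frame = aggregate_profiles(pair_vals, list(DIAGNOSES), ["p1"])
        vals = sorted(frame.loc["p1", list(DIAGNOSES)], reverse=True)
        assert frame.loc["p1", "margin"] == pytest.approx(vals[0] - vals[1])
        assert frame.loc["p1", "top_label"] == "AD"

    def test_patient_with_no_usable_features_raises(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 1.5, 2.5]})
        clf = DSIClassifier().fit(X, ["CN", "CN", "AD", "AD"])
        with pytest.raises(ValueError, match="no usable features"):
            clf.profiles_frame(pd.DataFrame({"f": [np.nan]}, index=["ghost"]))

    def test_dsi_profile_wrapper_roundtrip(self, default_cohort):
        models = fit_pair_models(default_cohort)
        rec = default_cohort.record(default_cohort.patient_ids[0])
        prof = dsi_profile(models, rec)
        assert set(prof.dsi) == set(DIAGNOSES)
        assert all(0.0 <= v <= 1.0 for v in prof.dsi.values())
        assert prof.top_label == max(DIAGNOSES, key=lambda g: (prof.dsi[g], -DIAGNOSES.index(g)))

    def test_absent_training_label_is_named(self, default_cohort):
        sub = default_cohort.data[default_cohort.data.true_label != "VaD"]
        from petselect import Cohort
        with pytest.raises(ValueError, match="VaD"):
            fit_pair_models(Cohort(sub, default_cohort.specs))


# -- anti-symmetry & missing-data contract ------------------------------------------

@given(st.integers(0, 10_000))
def test_pairwise_antisymmetry_off_training_points(seed):
    """Swapping the P/N roles flips the score to 1 - DSI away from training values."""
    rng = np.random.default_rng(seed)
    p = rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(2, 15))
    n = rng.normal(0.0, 1.0, size=rng.integers(2, 15))
    fwd = fit_feature_evidence("f", "continuous", p, n)
    rev = fit_feature_evidence("f", "continuous", n, p)
    xs = rng.normal(0.0, 2.0, size=20)  # a.s. distinct from training values
    f = feature_dsi_batch(fwd, xs)
    r = feature_dsi_batch(rev, xs)
    assert np.all(np.abs(f + r - 1.0) <= 1e-9)


def test_missing_feature_equals_removed_feature(default_cohort):
    """A missing value and a feature excluded from the selection are identical."""
    feats = default_cohort.default_features()
    X = default_cohort.feature_matrix(feats)
    y = default_cohort.labels()
    clf = DSIClassifier(features=feats).fit(X, y)

    target = "npi_total"
    X_missing = X.iloc[:20].copy()
    X_missing[target] = np.nan
    with_missing = clf.profiles_frame(X_missing)

    reduced = [f for f in feats if f != target]
    clf2 = DSIClassifier(features=reduced).fit(X[reduced], y)
    removed = clf2.profiles_frame(X.iloc[:20][reduced])

    pd.testing.assert_frame_equal(
        with_missing[list(DIAGNOSES)], removed[list(DIAGNOSES)]
    )


# -- cross-validation -----------------------------------------------------------------

class TestCrossValidate:
    def test_every_patient_scored_exactly_once(self, default_cohort):
        out = cross_validate(default_cohort, k=5, seed=1)
        assert sorted(out) == sorted(default_cohort.patient_ids)

    def test_same_seed_reproduces_folds_and_profiles(self, default_cohort):
        y = default_cohort.labels()
        f1 = make_folds(y, 5, seed=11)
        f2 = make_folds(y, 5, seed=11)
        pd.testing.assert_series_equal(f1, f2)
        a = cross_validate(default_cohort, k=5, seed=11)
        b = cross_validate(default_cohort, k=5, seed=11)
        assert all(a[p].dsi == b[p].dsi and a[p].margin == b[p].margin for p in a)

    def test_stratification_spreads_small_groups(self, default_cohort):
        y = default_cohort.labels()
        folds = make_folds(y, 5, seed=2)
        vad = folds[y == "VaD"]
        assert sorted(vad.value_counts()) == [2, 2, 2, 2, 2]  # 10 VaD over 5 folds

    def test_k_below_two_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            cross_validate(default_cohort, k=1, seed=0)

    def test_well_separated_cohort_is_almost_perfectly_classified(self, separable_cohort):
        out = cross_validate(separable_cohort, k=5, seed=9)
        truth = separable_cohort.labels()
        acc = np.mean([out[p].top_label == truth[p] for p in out])
        assert acc > 0.95
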