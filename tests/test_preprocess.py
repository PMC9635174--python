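"""Preprocessing: transforms, filters, imputation, harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omod import (
    OmodError,
    RunConfig,
    SimDesign,
    bland_altman_cv,
    cv_filter,
    finalize,
    harmonize,
    log2_proteins,
    metabolite_prep,
    preprocess_cohort,
    simulate_cohort,
    winsorize,
)
from conftest import make_matrix


class TestLog2Proteins:
    def test_exact_values(self):
        m = make_matrix(np.array([[8.0], [1.0], [4.0]]), scale="raw")
        out = log2_proteins(m)
        assert out.scale_state == "log2"
        np.testing.assert_allclose(out.values.iloc[:, 0], [3.0, 0.0, 2.0])

    def test_nonpositive_raises(self):
        m = make_matrix(np.array([[1.0], [-2.0]]), scale="raw")
        with pytest.raises(OmodError, match="A1"):
            log2_proteins(m)

    def test_symmetrizes_lognormal_column(self):
        rng = np.random.default_rng(0)
        raw = np.exp2(rng.normal(5, 1, size=(4000, 1)))
        m = make_matrix(raw, scale="raw")
        from scipy.stats import skew

        assert skew(raw[:, 0]) > 1.0
        assert abs(skew(log2_proteins(m).values.iloc[:, 0])) < 0.1


class TestWinsorize:
    def test_inliers_unchanged(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(100, 3)))
        out = winsorize(m, k=5.0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_outlier_clamped_to_original_moments(self):
        # single-pass: the clamp bound uses mean/SD of the ORIGINAL column
        col = np.array([0.0] * 9 + [100.0])
        m = make_matrix(col.reshape(-1, 1))
        mu, s = col.mean(), col.std(ddof=1)
        out = winsorize(m, k=2.0)
        assert out.values.iloc[-1, 0] == pytest.approx(mu + 2 * s)
        np.testing.assert_allclose(out.values.iloc[:9, 0], 0.0)

    def test_extreme_outlier_clamped_at_default_k(self):
        col = np.concatenate([np.zeros(99), [1.0], [1e4]])
        m = make_matrix(col.reshape(-1, 1))
        mu, s = col.mean(), col.std(ddof=1)
        out = winsorize(m, k=5.0)
        assert out.values.iloc[-1, 0] == pytest.approx(mu + 5 * s)

    def test_constant_column_unchanged(self):
        m = make_matrix(np.full((10, 1), 3.0))
        out = winsorize(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], 3.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_t(df=2, size=(50, 2))
        m = make_matrix(vals)
        out = winsorize(m, k=2.0)
        mu = vals.mean(0)
        sd = vals.std(0, ddof=1)
        assert (out.values.to_numpy() <= mu + 2 * sd + 1e-12).all()
        assert (out.values.to_numpy() >= mu - 2 * sd - 1e-12).all()


class TestCvFilter:
    def test_hand_computed_pair_excluded(self):
        # pairs (10,10),(10,30): sqrt(mean(diff^2)/2)=10, grand mean 15 -> 0.667
        cv = bland_altman_cv([10.0, 10.0], [10.0, 30.0])
        assert cv == pytest.approx(10.0 / 15.0)
        vals = np.array([[10.0], [10.0], [10.0], [30.0]])
        m = make_matrix(vals, scale="raw")
        m.values.index = ["s1", "s2", "d1", "d2"]
        kept, excluded = cv_filter(m, [("s1", "d1"), ("s2", "d2")], cv_max=0.5)
        assert list(excluded["analyte_id"]) == ["A1"]
        assert excluded["statistic"].iloc[0] == pytest.approx(2 / 3)
        assert kept.values.shape[1] == 0

    def test_identical_duplicates_kept(self):
        vals = np.array([[5.0], [7.0], [5.0], [7.0]])
        m = make_matrix(vals, scale="raw")
        m.values.index = ["s1", "s2", "d1", "d2"]
        kept, excluded = cv_filter(m, [("s1", "d1"), ("s2", "d2")])
        assert len(excluded) == 0 and kept.values.shape[1] == 1

    def test_requires_duplicates(self):
        m = make_matrix(np.ones((3, 1)), scale="raw")
        with pytest.raises(OmodError):
            cv_filter(m, [], cv_max=0.5)

    def test_scale_invariance(self):
        a = np.array([3.0, 9.0, 5.0])
        b = np.array([4.0, 7.0, 6.0])
        assert bland_altman_cv(10 * a, 10 * b) == pytest.approx(bland_altman_cv(a, b))

    def test_recovers_true_high_cv_analytes(self):
        """With 100 duplicate pairs, exclusions coincide with the analytes
        whose generative measurement CV exceeds the threshold."""
        design = SimDesign(n_duplicate_pairs=100)
        bundle, truth = simulate_cohort(design, seed=5)
        proteins = bundle.abundances.subset_analytes(
            bundle.abundances.analytes_of_type("protein")
        )
        _, excluded = cv_filter(proteins, bundle.duplicates, cv_max=0.5)
        true_high = set(
            truth.duplicate_cv_of_analyte.index[
                (truth.duplicate_cv_of_analyte > 0.5)
                & (truth.factor_of_analyte.index.str.startswith("P"))
            ]
        )
        found = set(excluded["analyte_id"])
        n_proteins = proteins.values.shape[1]
        disagree = len(true_high ^ found) / n_proteins
        assert disagree <= 0.05


class TestMetabolitePrep:
    def _metab(self, values, xeno=None):
        m = make_matrix(values, analyte_types=["metabolite"] * values.shape[1],
                        prefix="M", scale="raw")
        if xeno:
            m.meta.loc[xeno, "xenobiotic"] = True
        return m

    def test_median_scaling_log2(self):
        m = self._metab(np.array([[1.0], [2.0], [4.0]]))
        out, excluded = metabolite_prep(m, var_min=0.01)
        np.testing.assert_allclose(out.values.iloc[:, 0], [-1.0, 0.0, 1.0])
        assert len(excluded) == 0

    def test_missingness_rule(self):
        col = np.full((100, 1), np.nan)
        col[:19, 0] = 2.0  # 81% missing
        m = self._metab(col)
        out, excluded = metabolite_prep(m, missing_max=0.80)
        assert out.values.shape[1] == 0
        row = excluded.iloc[0]
        assert row["rule"] == "missingness" and row["statistic"] == pytest.approx(0.81)

    def test_constant_column_low_variance(self):
        m = self._metab(np.full((10, 1), 4.0))
        out, excluded = metabolite_prep(m)
        assert excluded.iloc[0]["rule"] == "low_variance"
        assert out.values.shape[1] == 0

    def test_xenobiotic_excluded_first(self):
        m = self._metab(np.array([[1.0, 1.0], [2.0, 2.0], [4.0, 4.0]]), xeno=["M2"])
        out, excluded = metabolite_prep(m)
        assert list(out.values.columns) == ["M1"]
        assert excluded.loc[excluded.analyte_id == "M2", "rule"].iloc[0] == "xenobiotic"

    def test_each_exclusion_reported_once(self, pipeline):
        excl = pipeline["exclusions"]
        assert not excl.duplicated(["cohort", "analyte_id"]).any()


class TestFinalize:
    def test_minimum_imputation(self):
        vals = np.array([[1.0], [2.0], [np.nan]])
        out = finalize(make_matrix(vals))
        np.testing.assert_allclose(out.values.iloc[:, 0], [1.0, 2.0, 1.0])
        assert not out.missing_mask.any().any()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(50, 4))
        vals[rng.random((50, 4)) < 0.1] = np.nan
        once = finalize(make_matrix(vals))
        twice = finalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_left_censored_column_imputes_at_minimum(self):
        """Detection-limit missingness makes the observed minimum the natural
        stand-in for the censored values."""
        design = SimDesign()
        bundle, _ = simulate_cohort(design, seed=3)
        cfg = RunConfig()
        m, _ = preprocess_cohort(bundle, cfg)
        met = [a for a in m.values.columns if a.startswith("M")]
        sub = m.subset_analytes(met)
        out = finalize(sub)
        miss = sub.missing_mask.to_numpy()
        assert miss.any()
        imputed = out.values.to_numpy()[miss]
        mins = np.nanmin(sub.values.to_numpy(), axis=0)
        cols = np.nonzero(miss)[1]
        np.testing.assert_allclose(imputed, mins[cols])


class TestHarmonize:
    def _named(self, cols):
        vals = np.arange(4 * len(cols), dtype=float).reshape(4, len(cols))
        m = make_matrix(vals)
        m.values.columns = cols
        m.meta.index = pd.Index(cols, name="analyte_id")
        return m

    def test_intersection(self):
        a = self._named(["p1", "p2", "p3"])
        b = self._named(["p2", "p3", "p4"])
        ha, hb = harmonize(a, b)
        assert list(ha.values.columns) == ["p2", "p3"]
        assert list(hb.values.columns) == ["p2", "p3"]

    def test_symmetry(self):
        a = self._named(["p1", "p2", "p3"])
        b = self._named(["p3", "p2", "p4"])
        ha, hb = harmonize(a, b)
        hb2, ha2 = harmonize(b, a)
        assert set(ha.values.columns) == set(ha2.values.columns)

    def test_identical_panels_unchanged(self):
        a = self._named(["p1", "p2"])
        b = self._named(["p1", "p2"])
        ha, hb = harmonize(a, b)
        assert list(ha.values.columns) == ["p1", "p2"]

    def test_empty_intersection_raises(self):
        a = self._named(["p1"])
        b = self._named(["q1"])
        with pytest.raises(OmodError):
            harmonize(a, b)
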