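"""Module PC aggregation: fitting, merging, export rule, standardization."""

import math

import numpy as np
import pandas as pd
import pytest

from omod import (
    CovariateProfile,
    ModulePartition,
    OmodError,
    SimDesign,
    fit_module_pcs,
    merge_correlated,
    select_exported_pcs,
    simulate_cohort,
    standardize_scores,
)
from omod.datatypes import ModuleModel, ModulePCs
from conftest import make_matrix

_LN2 = math.log(2.0)


def _one_module_partition(analytes, module_id=1):
    return ModulePartition(
        assignment=pd.Series(module_id, index=pd.Index(analytes, name="analyte_id"))
    )


class TestFitModulePCs:
    def test_identical_columns_analytic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        m = make_matrix(np.column_stack([x, x]))
        model, scores = fit_module_pcs(m, _one_module_partition(["A1", "A2"]))
        pcs = model.modules[1]
        assert pcs.var_fractions[0] == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(pcs.loadings[:, 0]), 1 / math.sqrt(2))

    def test_variance_fractions_conserved(self, pipeline):
        for pcs in pipeline["model"].modules.values():
            assert pcs.var_fractions.sum() == pytest.approx(1.0)
            assert (np.diff(pcs.var_fractions) <= 1e-10).all()

    def test_loadings_orthonormal(self, pipeline):
        for pcs in pipeline["model"].modules.values():
            G = pcs.loadings.T @ pcs.loadings
            np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-10)

    def test_pc1_orientation_positive_mean_correlation(self, pipeline):
        from omod.scores import _colwise_spearman

        m = pipeline["m_d"]
        for mid, pcs in pipeline["model"].modules.items():
            X = m.values[pcs.analytes].to_numpy()
            pc1 = ((X - pcs.means) / pcs.sds) @ pcs.loadings[:, 0]
            assert _colwise_spearman(X, pc1).mean() >= 0

    def test_scores_equal_projection(self, pipeline):
        """Scores from the SVD fit equal z-matrix @ loadings (internal oracle)."""
        m = pipeline["m_d"]
        model, scores = pipeline["model"], pipeline["scores"]
        for mid, pcs in model.modules.items():
            X = m.values[pcs.analytes].to_numpy()
            Z = (X - pcs.means) / pcs.sds
            proj = Z @ pcs.loadings[:, : pcs.n_exported] / pcs.pc_sds[: pcs.n_exported]
            for c in range(pcs.n_exported):
                got = scores.scores[f"m{mid}_pc{c + 1}"].to_numpy()
                assert np.abs(got - proj[:, c]).max() < 1e-8

    def test_sign_flip_of_one_analyte_flips_its_loading_only(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=300)
        vals = np.column_stack([z + 0.5 * rng.normal(size=300) for _ in range(4)])
        m1 = make_matrix(vals)
        flipped = vals.copy()
        flipped[:, 2] *= -1
        m2 = make_matrix(flipped)
        part = _one_module_partition(["A1", "A2", "A3", "A4"])
        l1 = fit_module_pcs(m1, part)[0].modules[1].loadings[:, 0]
        l2 = fit_module_pcs(m2, part)[0].modules[1].loadings[:, 0]
        np.testing.assert_allclose(l2[[0, 1, 3]], l1[[0, 1, 3]], atol=1e-10)
        np.testing.assert_allclose(l2[2], -l1[2], atol=1e-10)

    def test_zero_variance_column_raises(self):
        m = make_matrix(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(OmodError):
            fit_module_pcs(m, _one_module_partition(["A1", "A2"]))

    def test_pc1_variance_fraction_moment_oracle(self):
        """One-factor module: PC1 variance fraction ~ (1+(k-1)r)/k where r is
        the within-module correlation lambda^2/(lambda^2+sigma^2)."""
        lam, sigma, k = 0.8, 0.6, 10
        d = SimDesign(
            n_factors=1, proteins_per_factor=k, metabolites_per_factor=0,
            loadings=lam, noise_sd=sigma, n_background_proteins=0,
            n_background_metabolites=0, xenobiotic_fraction=0.0,
            high_cv_fraction=0.0, n_duplicate_pairs=2,
            trait_couplings={}, survival_betas={},
            profile=CovariateProfile(n_samples=2000),
        )
        bundle, truth = simulate_cohort(d, seed=9)
        vals = np.log2(bundle.abundances.values.iloc[:2000].to_numpy())
        m = make_matrix(vals)
        model, _ = fit_module_pcs(m, _one_module_partition(m.values.columns))
        sigma_eff2 = sigma**2 + (d.duplicate_cv / _LN2) ** 2
        r = lam**2 / (lam**2 + sigma_eff2)
        expected = (1 + (k - 1) * r) / k
        assert model.modules[1].var_fractions[0] == pytest.approx(expected, abs=0.03)


class TestMergeCorrelated:
    def _split_factor_fixture(self, seed=2, n=600):
        """One latent factor split across two 'modules' -> must merge."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        w = rng.normal(size=n)
        cols = [z + 0.4 * rng.normal(size=n) for _ in range(4)] + [
            w + 0.4 * rng.normal(size=n) for _ in range(2)
        ]
        m = make_matrix(np.column_stack(cols))
        assignment = pd.Series(
            [1, 1, 2, 2, 3, 3],
            index=pd.Index([f"A{j + 1}" for j in range(6)], name="analyte_id"),
        )
        return m, ModulePartition(assignment=assignment)

    def test_same_factor_modules_merge(self):
        m, part = self._split_factor_fixture()
        model, scores = fit_module_pcs(m, part)
        part2, model2, scores2 = merge_correlated(model, scores, part, m, 0.9)
        assert sorted(model2.modules) == [1, 3]
        assert sorted(model2.modules[1].analytes) == ["A1", "A2", "A3", "A4"]
        assert part2.assignment["A3"] == 1
        assert model2.modules[1].merged_from == [1, 2]
        assert part2.merge_history[0]["merged"] == [1, 2]

    def test_independent_modules_unchanged(self, pipeline):
        """Fixed point: after merging, no pair of first PCs correlates above
        the threshold."""
        model, scores = pipeline["model"], pipeline["scores"]
        ids = model.module_ids()
        mat = np.column_stack(
            [scores.scores[f"m{i}_pc1"].to_numpy() for i in ids]
        )
        corr = np.corrcoef(mat, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9

    def test_merge_refits_pcs(self):
        m, part = self._split_factor_fixture()
        model, scores = fit_module_pcs(m, part)
        _, model2, scores2 = merge_correlated(model, scores, part, m, 0.9)
        pcs = model2.modules[1]
        assert len(pcs.analytes) == 4
        assert pcs.loadings.shape[0] == 4
        # refit scores present and internally consistent
        X = m.values[pcs.analytes].to_numpy()
        proj = ((X - pcs.means) / pcs.sds) @ pcs.loadings[:, 0]
        np.testing.assert_allclose(
            scores2.scores["m1_pc1"].to_numpy(), proj, atol=1e-10
        )


class TestSelectExportedPCs:
    def _model(self, var_fractions, n_loadings=None):
        vf = np.asarray(var_fractions, dtype=float)
        k = n_loadings or min(3, len(vf))
        p = len(vf)
        pcs = ModulePCs(
            module_id=1, analytes=[f"A{j}" for j in range(p)],
            means=np.zeros(p), sds=np.ones(p),
            loadings=np.eye(p)[:, :k], var_fractions=vf,
            pc_sds=np.ones(k), n_exported=k,
        )
        return ModuleModel(modules={1: pcs})

    def test_single_pc_suffices(self):
        out = select_exported_pcs(self._model([0.6, 0.3, 0.1]))
        assert out.modules[1].n_exported == 1

    def test_cap_at_three(self):
        out = select_exported_pcs(self._model([0.30, 0.15, 0.10, 0.09, 0.36]))
        assert out.modules[1].n_exported == 3

    def test_two_analyte_module_capped_by_dimension(self):
        out = select_exported_pcs(self._model([0.3, 0.7][:2], n_loadings=2))
        assert out.modules[1].n_exported == 2

    def test_exact_boundary_counts(self):
        out = select_exported_pcs(self._model([0.5, 0.3, 0.2]))
        assert out.modules[1].n_exported == 1


class TestStandardizeScores:
    def test_discovery_scores_have_unit_sd(self, pipeline):
        scores = pipeline["scores"]
        assert scores.standardized
        sds = scores.scores.std(axis=0, ddof=1)
        np.testing.assert_allclose(sds, 1.0, atol=1e-10)

    def test_affine_rescaling_invariance(self):
        """Scaling an analyte's column (e.g. raw x10, a log2 shift) leaves
        z-scored PCs, hence standardized scores, unchanged."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=200)
        vals = np.column_stack([z + 0.5 * rng.normal(size=200) for _ in range(3)])
        part = _one_module_partition(["A1", "A2", "A3"])
        m1 = make_matrix(vals)
        shifted = vals.copy()
        shifted[:, 1] = shifted[:, 1] * 10 + math.log2(10)
        m2 = make_matrix(shifted)
        s1 = standardize_scores(*reversed(fit_module_pcs(m1, part)))
        s2 = standardize_scores(*reversed(fit_module_pcs(m2, part)))
        pd.testing.assert_frame_equal(s1.scores, s2.scores, atol=1e-10, rtol=0)

    def test_missing_sd_raises(self, pipeline):
        from omod.datatypes import ScoreMatrix

        bad = ScoreMatrix(
            pipeline["scores"].scores.rename(columns=lambda c: "m9999_pc1"),
            standardized=False,
        )
        with pytest.raises(OmodError):
            standardize_scores(
                ScoreMatrix(bad.scores.iloc[:, [0]], standardized=False),
                pipeline["model"],
            )

    def test_exported_pc_count_consistency(self, pipeline):
        model = pipeline["model"]
        total = sum(p.n_exported for p in model.modules.values())
        assert total == len(model.score_columns())
        assert list(pipeline["scores"].scores.columns) == model.score_columns()
        assert all(1 <= p.n_exported <= 3 for p in model.modules.values())
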