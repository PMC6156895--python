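import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from globalp import (KinshipMatrix, fit_probe_lmm, fit_probe_ols, run_ewas,
                     kinship_from_pedigree)
from globalp.ewas import reml_neg_loglik
from globalp.simulate import SimulationConfig, simulate_study, _build_kinship
from globalp.preprocess import beta_to_m

from conftest import make_meth, make_samples


def _random_dataset(rng, n=60, with_cov=True):
    y = rng.normal(size=n)
    cov = {"age": rng.normal(50, 10, n), "sex": rng.choice(["F", "M"], n)} if with_cov else {}
    samples = make_samples(y, covariates=cov)
    m = 0.3 * y + rng.normal(scale=0.8, size=n)
    return m, samples


class TestOls:
    def test_matches_statsmodels(self, rng):
        m, samples = _random_dataset(rng)
        rec = fit_probe_ols(m, samples)
        X = samples.design_matrix().to_numpy()
        ref = sm.OLS(m, X).fit()
        assert rec.beta_hat == pytest.approx(ref.params[1], rel=1e-10)
        assert rec.se == pytest.approx(ref.bse[1], rel=1e-10)

    def test_hand_computed_normal_equations(self):
        # n = 4, no covariates: b = Sxy/Sxx on centered data
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = np.array([0.5, 0.4, 0.9, 1.0])
        samples = make_samples(y)
        rec = fit_probe_ols(m, samples)
        xc, mc = y - y.mean(), m - m.mean()
        b = float(xc @ mc / (xc @ xc))
        resid = mc - b * xc
        s2 = float(resid @ resid) / (4 - 2)
        se = np.sqrt(s2 / (xc @ xc))
        assert rec.beta_hat == pytest.approx(b, rel=1e-12)
        assert rec.se == pytest.approx(se, rel=1e-12)

    def test_perfect_fit_guarded(self):
        y = np.arange(10, dtype=float)
        samples = make_samples(y)
        with pytest.raises(ValueError, match="perfect fit"):
            fit_probe_ols(y.copy(), samples)  # M equals phenotype exactly

    def test_rank_deficient_names_columns(self, rng):
        n = 30
        y = rng.normal(size=n)
        samples = make_samples(y, covariates={"a": y.copy(), "b": 2 * y})
        with pytest.raises(ValueError, match="collinear"):
            fit_probe_ols(rng.normal(size=n), samples)

    def test_type_one_error_in_binomial_band(self, rng):
        # independent M and phenotype: rejection rate at 0.05 should sit in
        # the 99.9% binomial band for 600 fits
        hits = 0
        n_reps = 600
        for _ in range(n_reps):
            y = rng.normal(size=80)
            m = rng.normal(size=80)
            hits += fit_probe_ols(m, make_samples(y)).p_value < 0.05
        half = 3.3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= hits / n_reps <= 0.05 + half


class TestLmm:
    def test_identity_kinship_reproduces_ols(self, rng):
        for _ in range(10):
            m, samples = _random_dataset(rng)
            kin = KinshipMatrix.identity(list(samples.sample_ids))
            lmm = fit_probe_lmm(m, samples, kin)
            ols = fit_probe_ols(m, samples)
            assert lmm.beta_hat == pytest.approx(ols.beta_hat, rel=1e-6)
            assert lmm.se == pytest.approx(ols.se, rel=1e-6)
            assert lmm.p_value == pytest.approx(ols.p_value, rel=1e-6)

    @staticmethod
    def _heritable_probe(noise_sd=0.3):
        # a probe with a strong genuine polygenic component, so the REML
        # variance-ratio optimum is comfortably interior
        cfg = SimulationConfig(seed=42, n_families=120, family_structure="trio",
                               n_regions=1, probes_per_region=1, h2=0.0)
        kin, _, _ = _build_kinship(cfg)
        study = simulate_study(cfg, kinship=kin)
        rng = np.random.default_rng(1)
        A = kin.relationship
        L = np.linalg.cholesky(A + 1e-10 * np.eye(A.shape[0]))
        g = L @ rng.standard_normal(A.shape[0])
        m = g + noise_sd * rng.standard_normal(A.shape[0])
        return m, study.samples, kin

    def test_reml_optimum_gradient_vanishes(self):
        m, samples, kin = self._heritable_probe()
        rec = fit_probe_lmm(m, samples, kin)
        assert rec.converged
        assert -10 < rec.log_delta < 10  # interior
        X = samples.design_matrix().to_numpy()
        d, U = kin.eig()
        h = 1e-4
        grad = (reml_neg_loglik(rec.log_delta + h, m, X, d, U)
                - reml_neg_loglik(rec.log_delta - h, m, X, d, U)) / (2 * h)
        assert abs(grad) < 1e-4

    def test_rotated_reml_matches_dense_oracle(self):
        # the eigenbasis profile must equal the textbook dense-matrix REML
        m, samples, kin = self._heritable_probe()
        X = samples.design_matrix().to_numpy()
        A = kin.relationship
        n, p = X.shape
        d, U = kin.eig()

        def dense_nll(ld):
            V = np.exp(ld) * A + np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            b = np.linalg.solve(XtViX, X.T @ Vi @ m)
            r = m - X @ b
            s2 = (r @ Vi @ r) / (n - p)
            sld = np.linalg.slogdet
            return 0.5 * ((n - p) * np.log(s2) + sld(V)[1] + sld(XtViX)[1] + (n - p))

        for ld in (-2.0, 0.0, 1.5, 3.0):
            assert reml_neg_loglik(ld, m, X, d, U) == pytest.approx(dense_nll(ld),
                                                                    rel=1e-10)

    def test_null_calibration_on_family_data(self):
        # permutation-style null: phenotype independent of methylation
        cfg = SimulationConfig(seed=9, n_families=80, family_structure="trio",
                               n_regions=1, probes_per_region=1, h2=0.4)
        kin, _, _ = _build_kinship(cfg)
        hits, n_reps = 0, 300
        from globalp.simulate import _child_seeds
        for s in _child_seeds(9, n_reps):
            study = simulate_study(cfg.replace(seed=s), kinship=kin)
            m = beta_to_m(study.meth.values, clamp=True)[0]
            hits += fit_probe_lmm(m, study.samples, kin).p_value < 0.05
        half = 3.3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half <= hits / n_reps <= 0.05 + half

    def test_zero_variance_probe_rejected(self, tiny_samples):
        kin = KinshipMatrix.identity(list(tiny_samples.sample_ids))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_probe_lmm(np.zeros(40), tiny_samples, kin)


class TestRunEwas:
    def _study(self, rng, n=50, n_probes=6):
        y = rng.normal(size=n)
        samples = make_samples(y)
        M = rng.normal(size=(n_probes, n))
        betas = 1 / (1 + np.exp2(-M))
        return make_meth(betas), samples

    def test_zero_variance_probes_flagged_not_fatal(self, rng):
        meth, samples = self._study(rng)
        meth.data.iloc[1] = 0.5  # constant probe
        meth.data.iloc[4] = 0.9
        table = run_ewas(meth, samples, model="ols")
        assert len(table) == 6
        assert table["converged"].sum() == 4
        assert not table.loc[[1, 4], "converged"].any()

    def test_ols_with_kinship_warns_and_ignores(self, rng):
        meth, samples = self._study(rng)
        kin = KinshipMatrix.identity(list(samples.sample_ids))
        with pytest.warns(UserWarning, match="ignores"):
            t1 = run_ewas(meth, samples, kin, model="ols")
        t2 = run_ewas(meth, samples, model="ols")
        pd.testing.assert_frame_equal(t1, t2)

    def test_bitwise_determinism(self, rng):
        meth, samples = self._study(rng)
        t1 = run_ewas(meth, samples, model="ols")
        t2 = run_ewas(meth, samples, model="ols")
        pd.testing.assert_frame_equal(t1, t2)

    def test_z_p_relation_all_records(self, rng):
        meth, samples = self._study(rng)
        table = run_ewas(meth, samples, model="ols")
        ok = table[table["converged"]]
        np.testing.assert_allclose(ok["z"], ok["beta_hat"] / ok["se"], rtol=1e-12)
        np.testing.assert_allclose(ok["p_value"], 2 * sps.norm.sf(np.abs(ok["z"])),
                                   rtol=1e-12)

    def test_batch_and_single_probe_paths_agree(self, rng):
        meth, samples = self._study(rng)
        batch = run_ewas(meth, samples, model="ols")
        single = [fit_probe_ols(beta_to_m(meth.values, clamp=True)[i], samples,
                                probe_id=str(p))
                  for i, p in enumerate(meth.probe_ids)]
        for row, rec in zip(batch.itertuples(), single):
            assert row.beta_hat == pytest.approx(rec.beta_hat, rel=1e-10)
            assert row.se == pytest.approx(rec.se, rel=1e-10)

    def test_lmm_on_pedigree_kinship(self, rng):
        # smoke: mixed model runs on a real pedigree-derived kinship
        ped = pd.DataFrame(
            [(f"f{i}", "", "") for i in range(10)]
            + [(f"m{i}", "", "") for i in range(10)]
            + [(f"c{i}", f"f{i}", f"m{i}") for i in range(10)],
            columns=["id", "father", "mother"])
        kin = kinship_from_pedigree(ped)
        n = len(kin.sample_ids)
        samples = make_samples(rng.normal(size=n), ids=list(kin.sample_ids))
        M = rng.normal(size=(3, n))
        meth = make_meth(1 / (1 + np.exp2(-M)), sample_ids=list(kin.sample_ids))
        table = run_ewas(meth, samples, kin, model="lmm")
        assert table["converged"].all()
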