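import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from globalp import (bh_fdr, partial_correlation, region_chi2, run_globalp,
                     run_ewas, build_gene_regions, build_island_regions,
                     attach_regions)
from globalp.io import ProbeManifest

from conftest import make_meth, make_samples


def random_corr(rng, m, extra=20):
    """Well-conditioned random correlation matrix (Wishart-based)."""
    A = rng.standard_normal((m, m + extra))
    S = A @ A.T
    dinv = 1.0 / np.sqrt(np.diag(S))
    return dinv[:, None] * S * dinv[None, :]


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        M = rng.standard_normal((4, 50))
        pc = partial_correlation(M)
        np.testing.assert_allclose(pc.sigma, np.corrcoef(M), atol=1e-12)

    def test_duplicated_probe_collinear(self, rng):
        base = rng.standard_normal(30)
        M = np.vstack([base, base, rng.standard_normal(30)])
        pc = partial_correlation(M)
        assert pc.sigma[0, 1] == pytest.approx(1.0)
        assert pc.rank == 2  # m - 1

    def test_toy_covariate_case_matches_residual_oracle(self):
        # n = 6, m = 2, one numeric covariate: regress each probe on the
        # covariate independently and correlate the residuals
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        M = np.array([[0.3, 0.1, 0.5, 0.9, 0.2, 0.8],
                      [1.0, 0.4, 0.6, 0.2, 0.9, 0.3]])
        samples = make_samples(np.zeros(6), covariates={"x": cov})
        pc = partial_correlation(M, samples)

        X = np.column_stack([np.ones(6), cov])
        resid = []
        for row in M:
            beta = np.linalg.solve(X.T @ X, X.T @ row)
            resid.append(row - X @ beta)
        expected = np.corrcoef(np.vstack(resid))
        np.testing.assert_allclose(pc.sigma, expected, atol=1e-12)

    def test_phenotype_not_residualized(self, rng):
        # Sigma is the null covariance of z: only covariates are removed
        y = rng.standard_normal(50)
        M = np.vstack([y + 0.1 * rng.standard_normal(50),
                       y + 0.1 * rng.standard_normal(50)])
        samples = make_samples(y)
        pc = partial_correlation(M, samples)
        assert pc.sigma[0, 1] > 0.9

    def test_zero_residual_variance_names_probe(self):
        M = np.vstack([np.zeros(10), np.arange(10.0)])
        df = pd.DataFrame(M, index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            partial_correlation(df)

    def test_small_sample_warns(self, rng):
        M = rng.standard_normal((5, 6))
        with pytest.warns(UserWarning, match="complete-case"):
            partial_correlation(M)


# ---------------------------------------------------------------------------
# quadratic form
# ---------------------------------------------------------------------------

class TestRegionChi2:
    def test_zero_z_gives_p_one(self):
        stat, df, p = region_chi2(np.zeros(3), np.eye(3))
        assert (stat, df, p) == (0.0, 3, 1.0)

    def test_single_probe_equals_two_sided_normal(self):
        z = 1.96
        stat, df, p = region_chi2([z], np.eye(1))
        assert stat == pytest.approx(z ** 2, rel=1e-12)
        assert df == 1
        assert p == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)

    def test_worked_two_probe_case(self):
        # explicit 2x2 inverse: (z1^2 - 2 rho z1 z2 + z2^2) / (1 - rho^2)
        stat, df, p = region_chi2([1.0, 1.0], [[1.0, 0.5], [0.5, 1.0]])
        assert stat == pytest.approx(4.0 / 3.0, rel=1e-12)
        assert df == 2
        assert p == pytest.approx(np.exp(-2.0 / 3.0), rel=1e-12)  # chi2_2 sf

    def test_identity_sigma_reduces_to_sum_of_squares(self, rng):
        z = rng.standard_normal(6)
        stat, df, _ = region_chi2(z, np.eye(6))
        assert stat == pytest.approx(float(z @ z), rel=1e-12)
        assert df == 6

    def test_matches_direct_inverse_on_random_instances(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 11))
            S = random_corr(rng, m)
            z = rng.standard_normal(m)
            stat, df, _ = region_chi2(z, S)
            direct = float(z @ np.linalg.solve(S, z))
            assert df == m
            assert stat == pytest.approx(direct, rel=1e-8)

    def test_permutation_invariance(self, rng):
        m = 5
        S = random_corr(rng, m)
        z = rng.standard_normal(m)
        perm = rng.permutation(m)
        s1, _, p1 = region_chi2(z, S)
        s2, _, p2 = region_chi2(z[perm], S[np.ix_(perm, perm)])
        assert s1 == pytest.approx(s2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_rank_truncation_reduces_df(self, rng):
        base = rng.standard_normal(40)
        M = np.vstack([base, base, rng.standard_normal(40)])
        pc = partial_correlation(M)
        z = np.array([1.0, 1.0, 0.5])
        _, df, _ = region_chi2(z, pc)
        assert df == 2  # one eigenvalue clipped => df drops by exactly one

    def test_null_p_values_uniform(self, rng):
        # z ~ MVN(0, Sigma) with Sigma known: p is exactly Uniform(0,1)
        m = 4
        S = random_corr(rng, m)
        L = np.linalg.cholesky(S)
        pvals = np.empty(10_000)
        draws = L @ rng.standard_normal((m, 10_000))
        for i in range(10_000):
            _, _, pvals[i] = region_chi2(draws[:, i], S)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_dimension_mismatch_and_rank_zero(self):
        with pytest.raises(ValueError, match="length"):
            region_chi2([1.0, 2.0], np.eye(3))
        with pytest.raises(ValueError, match="rank 0"):
            region_chi2([1.0, 1.0], np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_bruteforce(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * K / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    K = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(K)
    for rank_i in range(K):
        cands = [p[order[j]] * K / (j + 1) for j in range(rank_i, K)]
        q[order[rank_i]] = min(1.0, min(cands))
    return q


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    @pytest.mark.parametrize("p, expected", [
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ])
    def test_hand_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_matches_bruteforce_and_statsmodels(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 40))
            p = rng.uniform(size=K)
            q = bh_fdr(p)
            np.testing.assert_array_equal(q, bh_bruteforce(p))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, rtol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_ties_stable(self):
        q = bh_fdr([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# run_globalp end-to-end on constructed studies
# ---------------------------------------------------------------------------

def _study_with_signal(rng, n=300, n_null_regions=20):
    """Two overlapping annotations (gene 5'UTR + island N_Shore) share the
    same two signal probes; plus null 3-probe gene regions."""
    y = rng.standard_normal(n)
    probes, rows, man_rows = [], [], []
    for name, pos in (("sig1", 100), ("sig2", 300)):
        probes.append(name)
        rows.append(0.5 * y + rng.standard_normal(n))
        man_rows.append({"probe_id": name, "chrom": "11", "pos": pos,
                         "gene_names": ("CPT1A",), "gene_groups": ("5'UTR",),
                         "island_relation": "N_Shore", "island_name": "isl11"})
    for r in range(n_null_regions):
        for i in range(3):
            pid = f"null{r}_{i}"
            probes.append(pid)
            rows.append(rng.standard_normal(n))
            man_rows.append({"probe_id": pid, "chrom": "1",
                             "pos": 10_000 * (r + 1) + i * 100,
                             "gene_names": (f"NULL{r}",), "gene_groups": ("Body",),
                             "island_relation": "none", "island_name": ""})
    M = np.vstack(rows)
    betas = 1 / (1 + np.exp2(-M))
    meth = make_meth(betas, probe_ids=probes)
    samples = make_samples(y, ids=list(meth.sample_ids))
    manifest = ProbeManifest(pd.DataFrame(man_rows).set_index("probe_id"))
    return meth, samples, manifest


class TestRunGlobalp:
    def _run(self, rng, **kw):
        meth, samples, manifest = _study_with_signal(rng, **kw)
        ewas = run_ewas(meth, samples, model="ols")
        gene, _ = build_gene_regions(manifest)
        island, _ = build_island_regions(manifest)
        regions, _ = attach_regions(gene, island, min_probes=2)
        table, audit = run_globalp(ewas, regions, meth, samples)
        return table, audit

    def test_planted_region_attains_smallest_q(self, rng):
        table, _ = self._run(rng)
        assert table.iloc[0]["region_id"] in ("CPT1A:5'UTR", "isl11:N_Shore")
        assert table.iloc[0]["q_value"] == table["q_value"].min()

    def test_overlapping_annotations_both_fire(self, rng):
        # both regions are driven by the two probes they share
        table, _ = self._run(rng)
        sig = table.set_index("region_id").loc[["CPT1A:5'UTR", "isl11:N_Shore"]]
        assert sig["significant"].all()
        assert (sig["n_probes"] == 2).all()

    def test_all_null_regions_calibrated(self, rng):
        # a single large null study: fraction of regions with p < 0.05
        # inside the 99.9% binomial band
        meth, samples, manifest = _study_with_signal(rng, n=200, n_null_regions=500)
        ewas = run_ewas(meth, samples, model="ols")
        gene, _ = build_gene_regions(manifest)
        null_ids = [rid for rid in gene.sorted_ids() if rid.startswith("NULL")]
        from globalp.regions import RegionSet
        nulls = RegionSet([gene[rid] for rid in null_ids])
        table, _ = run_globalp(ewas, nulls, meth, samples)
        rate = float((table["p_value"] < 0.05).mean())
        half = 3.3 * np.sqrt(0.05 * 0.95 / len(table))
        assert 0.05 - half <= rate <= 0.05 + half

    def test_unconverged_probes_dropped_with_audit(self, rng):
        meth, samples, manifest = _study_with_signal(rng, n_null_regions=3)
        meth.data.loc["null0_0"] = 0.5  # constant -> flagged in EWAS
        ewas = run_ewas(meth, samples, model="ols")
        gene, _ = build_gene_regions(manifest)
        island, _ = build_island_regions(manifest)
        regions, _ = attach_regions(gene, island, min_probes=2)
        table, audit = run_globalp(ewas, regions, meth, samples, min_probes=2)
        assert audit["n_probes_dropped"] == 1
        assert table.set_index("region_id").loc["NULL0:Body", "n_probes"] == 2

    def test_region_below_min_probes_skipped(self, rng):
        meth, samples, manifest = _study_with_signal(rng, n_null_regions=1)
        meth.data.loc["null0_0"] = 0.5
        meth.data.loc["null0_1"] = 0.5
        ewas = run_ewas(meth, samples, model="ols")
        gene, _ = build_gene_regions(manifest)
        island, _ = build_island_regions(manifest)
        regions, _ = attach_regions(gene, island, min_probes=2)
        table, audit = run_globalp(ewas, regions, meth, samples, min_probes=2)
        assert "NULL0:Body" not in set(table["region_id"])
        assert audit["n_skipped_small"] == 1

    def test_single_probe_region_p_matches_ewas(self, rng):
        meth, samples, manifest = _study_with_signal(rng, n_null_regions=2)
        ewas = run_ewas(meth, samples, model="ols")
        gene, _ = build_gene_regions(manifest)
        from globalp.regions import RegionSet, AnnotationRegion
        r = gene["NULL0:Body"]
        single = AnnotationRegion("solo:Body", "solo", "Body", r.chrom, r.start,
                                  r.start, (r.probe_ids[0],), (r.start,))
        table, _ = run_globalp(ewas, RegionSet([single]), meth, samples,
                               min_probes=1)
        probe_p = float(ewas.set_index("probe_id").loc[r.probe_ids[0], "p_value"])
        assert table.iloc[0]["p_value"] == pytest.approx(probe_p, rel=1e-12)
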