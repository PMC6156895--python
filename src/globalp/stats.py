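"""The region test: quadratic-form chi-square on correlated z-scores.

Under the null of no association, the vector of per-probe z-scores in a
region with m probes is multivariate normal with mean 0 and covariance
Sigma, where Sigma is the correlation matrix between the probes' M-values
in the study sample — the *partial* correlation matrix (correlation of
covariate-residualized M-values) when covariates are in the model.  It
follows that

    z_m^T Sigma^{-1} z_m  ~  chi^2 with m degrees of freedom.

Sigma is estimated per region from individual-level data.  Duplicate or
near-duplicate probes make Sigma singular, so the quadratic form is
computed through an eigenvalue-truncated pseudo-inverse: eigenvalues
below ``tol * lambda_max`` are clipped to zero and the degrees of
freedom become the retained rank, preserving the chi-square reference on
the retained subspace.

Because annotation regions overlap (a probe can sit in a gene body and
on an island shore), Bonferroni across regions is too conservative; the
region family is corrected with the Benjamini–Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MethylationMatrix, SampleTable, RESULT_COLUMNS
from .preprocess import beta_to_m
from .regions import RegionSet

__all__ = ["PartialCorrMatrix", "partial_correlation", "region_chi2",
           "bh_fdr", "run_globalp", "DEFAULT_EIG_TOL"]

#: relative eigenvalue threshold below which Sigma directions are truncated
DEFAULT_EIG_TOL = 1e-8


@dataclass
class PartialCorrMatrix:
    """Estimated inter-probe (partial) correlation for one region.

    ``sigma`` is symmetric with unit diagonal; ``eigvals``/``eigvecs``
    hold its eigendecomposition with eigenvalues below ``tol * max``
    clipped to zero, and ``rank`` counts the survivors.  ``n_eff`` is the
    number of complete-case samples the estimate used.
    """

    probe_ids: tuple
    sigma: np.ndarray
    n_eff: int
    rank: int
    eigvals: np.ndarray
    eigvecs: np.ndarray
    tol: float = DEFAULT_EIG_TOL


def _truncated_eig(sigma: np.ndarray, tol: float):
    vals, vecs = np.linalg.eigh(sigma)
    vals = np.where(vals < tol * max(vals.max(), 0.0), 0.0, vals)
    return vals, vecs


def partial_correlation(m_values, samples: SampleTable | None = None,
                        tol: float = DEFAULT_EIG_TOL) -> PartialCorrMatrix:
    """Partial correlation of region probes, given the model covariates.

    ``m_values`` is the probe x sample M-value sub-matrix (DataFrame or
    array).  Each probe is residualized on intercept + covariates (the
    phenotype is *not* regressed out — Sigma is the null covariance of
    the z-scores) by least squares, and the residual vectors are Pearson
    correlated.  With no covariates this reduces to the plain correlation
    of the M-values.  Samples with any missing probe in the region are
    dropped (complete-case per region).
    """
    if isinstance(m_values, pd.DataFrame):
        probe_ids = tuple(map(str, m_values.index))
        M = m_values.to_numpy(dtype=float)
    else:
        M = np.asarray(m_values, dtype=float)
        probe_ids = tuple(f"p{i}" for i in range(M.shape[0]))
    if M.ndim != 2:
        raise ValueError("m_values must be a probe x sample matrix")
    m = M.shape[0]

    if samples is not None:
        X = samples.design_matrix(include_phenotype=False).to_numpy(dtype=float)
        if X.shape[0] != M.shape[1]:
            raise ValueError("sample table does not match m_values columns")
    else:
        X = np.ones((M.shape[1], 1))

    keep = np.isfinite(M).all(axis=0) & np.isfinite(X).all(axis=1)
    M, X = M[:, keep], X[keep]
    n = M.shape[1]
    if n < m + X.shape[1] + 2:
        warnings.warn(
            f"only {n} complete-case samples for {m} probes and {X.shape[1]} "
            "design columns; Sigma may be rank-deficient (truncation applies)",
            UserWarning, stacklevel=2)
    if n <= X.shape[1]:
        raise ValueError(f"too few complete-case samples ({n}) to residualize "
                         f"on {X.shape[1]} design columns")

    coef, *_ = np.linalg.lstsq(X, M.T, rcond=None)
    resid = M.T - X @ coef                       # n x m
    sd = resid.std(axis=0, ddof=0)
    dead = np.nonzero(sd <= 0)[0]
    if dead.size:
        raise ValueError(f"probe {probe_ids[dead[0]]!r} has zero residual variance")
    sigma = np.corrcoef(resid.T) if m > 1 else np.ones((1, 1))
    sigma = np.clip((sigma + sigma.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sigma, 1.0)
    vals, vecs = _truncated_eig(sigma, tol)
    return PartialCorrMatrix(probe_ids=probe_ids, sigma=sigma, n_eff=int(n),
                             rank=int(np.count_nonzero(vals)), eigvals=vals,
                             eigvecs=vecs, tol=tol)


def region_chi2(z, sigma, tol: float = DEFAULT_EIG_TOL) -> tuple[float, int, float]:
    """Quadratic-form region statistic z^T Sigma^+ z.

    ``sigma`` may be a :class:`PartialCorrMatrix` (its truncated
    eigendecomposition is reused) or a plain symmetric matrix (truncated
    here at ``tol``).  Returns ``(statistic, df, p_value)`` with df the
    retained rank and the p-value the upper chi-square tail.
    """
    z = np.asarray(z, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    if isinstance(sigma, PartialCorrMatrix):
        vals, vecs = sigma.eigvals, sigma.eigvecs
        dim = sigma.sigma.shape[0]
    else:
        S = np.asarray(sigma, dtype=float)
        if S.ndim == 0:
            S = S.reshape(1, 1)
        dim = S.shape[0]
        vals, vecs = _truncated_eig(S, tol)
    if z.shape[0] != dim:
        raise ValueError(f"z has length {z.shape[0]} but Sigma is {dim}x{dim}")
    kept = vals > 0
    df = int(np.count_nonzero(kept))
    if df == 0:
        raise ValueError("Sigma has rank 0 after eigenvalue truncation")
    u = vecs.T @ z
    statistic = float(np.sum(u[kept] ** 2 / vals[kept]))
    p_value = float(sps.chi2.sf(statistic, df))
    return statistic, df, p_value


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Sort ascending, set q_(i) = min_{j >= i} p_(j) * K / j capped at 1,
    and map back to the input order; ties are handled stably.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    K = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * K / np.arange(1, K + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def run_globalp(ewas: pd.DataFrame, regions: RegionSet, meth: MethylationMatrix,
                samples: SampleTable, alpha: float = 0.05, min_probes: int = 2,
                eig_tol: float = DEFAULT_EIG_TOL,
                values_are_m: bool = False) -> tuple[pd.DataFrame, dict]:
    """Test every region and FDR-correct across the whole region family.

    Per region: assemble the member probes' z-scores in genomic-position
    order, estimate the partial correlation from the region's M-value
    sub-matrix (covariate-residualized, complete-case per region), form
    the quadratic-form statistic and its chi-square p-value.  Probes with
    missing, unconverged or non-finite EWAS records are dropped with an
    audit count; a region reduced below ``min_probes`` is skipped.  BH is
    applied jointly over gene and island regions (one family).

    Returns ``(table, audit)``; the table has one row per tested region
    with q-values and a ``significant`` flag at ``alpha``, sorted by
    p-value.  Reported start/stop are the min/max positions of the
    probes actually tested.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    by_probe = ewas.set_index(ewas["probe_id"].astype(str))
    usable = by_probe[(by_probe["converged"].astype(bool))
                      & np.isfinite(by_probe["z"].astype(float))]
    z_of = usable["z"].astype(float)
    have_meth = set(map(str, meth.probe_ids))

    M_all = meth.data if values_are_m else pd.DataFrame(
        beta_to_m(meth.values, clamp=True), index=meth.data.index,
        columns=meth.data.columns)

    rows = []
    audit = {"n_regions_in": len(regions), "n_tested": 0, "n_skipped_small": 0,
             "n_probes_dropped": 0, "n_regions_failed": 0}
    # region positions come from build-time ordering; keep an id-sorted walk
    for rid in regions.sorted_ids():
        region = regions[rid]
        used = [p for p in region.probe_ids if p in z_of.index and p in have_meth]
        audit["n_probes_dropped"] += region.m - len(used)
        if len(used) < max(min_probes, 1):
            audit["n_skipped_small"] += 1
            continue
        z = z_of.loc[used].to_numpy()
        sub = M_all.loc[used, list(map(str, samples.sample_ids))]
        try:
            sigma = partial_correlation(sub, samples, tol=eig_tol)
            statistic, df, p = region_chi2(z, sigma)
        except ValueError as exc:
            audit["n_regions_failed"] += 1
            warnings.warn(f"region {rid!r} failed: {exc}", UserWarning, stacklevel=2)
            continue
        positions = region.probe_positions(used)
        rows.append({
            "chromosome": region.chrom, "start": int(min(positions)),
            "stop": int(max(positions)), "n_probes": len(used),
            "statistic": statistic, "df": df, "p_value": p,
            "region_id": rid, "category": region.category,
        })
    audit["n_tested"] = len(rows)
    table = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "q_value"])
    if len(table):
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < alpha
        table = table[RESULT_COLUMNS + ["significant"]]
        table = table.sort_values(["p_value", "region_id"],
                                  kind="stable").reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=RESULT_COLUMNS + ["significant"])
    audit["n_significant"] = int(table["significant"].sum()) if len(table) else 0
    return table, audit
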