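"""Per-probe association models: methylation M on phenotype, with kinship.

The EWAS stage regresses each probe's M-values on the phenotype plus
covariates.  For family samples the model is a linear mixed model

    M = X b + g + e,    g ~ N(0, sg^2 * 2*phi),   e ~ N(0, se^2 * I),

where ``2*phi`` is the additive relationship matrix from the pedigree.
The variance components are estimated by restricted maximum likelihood:
after a one-time eigendecomposition ``2*phi = U D U^T`` the model is
rotated into the eigenbasis, where the covariance is diagonal,
``se^2 (delta*D + I)`` with ``delta = sg^2/se^2``; the REML criterion is
then profiled down to a one-dimensional search over ``log delta`` on
[-10, 10] (bounded Brent), with ``se^2`` and the fixed effects solved by
generalized least squares at each step.

Each fit reports the phenotype coefficient ``beta_hat``, its standard
error, the Wald z-score ``z = beta_hat/se`` and the two-sided normal
p-value ``2*(1 - Phi(|z|))`` — the normal reference is used (not t)
because the region test downstream consumes z-scores directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import KinshipMatrix, MethylationMatrix, SampleTable
from .preprocess import beta_to_m

__all__ = ["EwasRecord", "kinship_from_pedigree", "fit_probe_lmm",
           "fit_probe_ols", "run_ewas", "EWAS_COLUMNS"]

_LOG_DELTA_BOUNDS = (-10.0, 10.0)


@dataclass
class EwasRecord:
    """Per-probe association summary: effect, SE, z = effect/SE, normal p."""

    probe_id: str
    beta_hat: float
    se: float
    z: float
    p_value: float
    n_used: int
    converged: bool
    log_delta: float = float("nan")  # log variance ratio sg^2/se^2 (LMM only)
    message: str = ""


EWAS_COLUMNS = ["probe_id", "beta_hat", "se", "z", "p_value", "n_used",
                "converged", "log_delta", "message"]


# ---------------------------------------------------------------------------
# kinship from pedigree
# ---------------------------------------------------------------------------

def kinship_from_pedigree(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Recursive kinship coefficients from a pedigree table.

    Expects columns ``id``, ``father``, ``mother`` (empty/'' = founder;
    a ``family`` column is permitted and ignored — relationships follow
    from the parent links alone).  Parents referenced but not listed as
    rows are treated as unrelated founders.  The recursion, applied in
    an order where parents precede children:

    * founders: phi(i, i) = 1/2, phi(i, j) = 0 to anyone processed earlier;
    * phi(i, i) = (1 + phi(father_i, mother_i)) / 2;
    * phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2 for earlier j.

    Raises if the parent links contain a cycle (an individual its own
    ancestor).  Returns kinship for the listed ids, in listed order.
    """
    ped = pedigree.copy()
    ped["id"] = ped["id"].astype(str)
    for col in ("father", "mother"):
        ped[col] = ped[col].fillna("").astype(str).replace({"0": "", ".": "", "NA": ""})
    listed = list(ped["id"])
    if len(set(listed)) != len(listed):
        raise ValueError("duplicate individual ids in pedigree")
    parents = {row.id: (row.father or None, row.mother or None)
               for row in ped.itertuples()}
    # implicit founders: parents that have no row of their own
    everyone = list(listed)
    for fa, mo in list(parents.values()):
        for p in (fa, mo):
            if p and p not in parents:
                parents[p] = (None, None)
                everyone.append(p)

    # Kahn topological sort over parent -> child edges
    n_par = {i: sum(p is not None for p in parents[i]) for i in everyone}
    children: dict[str, list[str]] = {i: [] for i in everyone}
    for i, (fa, mo) in parents.items():
        for p in (fa, mo):
            if p:
                children[p].append(i)
    order, queue = [], sorted(i for i in everyone if n_par[i] == 0)
    while queue:
        i = queue.pop(0)
        order.append(i)
        for c in children[i]:
            n_par[c] -= 1
            if n_par[c] == 0:
                queue.append(c)
    if len(order) != len(everyone):
        cyclic = sorted(set(everyone) - set(order))
        raise ValueError(f"pedigree contains a cycle (individual listed as its "
                         f"own ancestor): {cyclic[:5]}")

    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, ind in enumerate(order):
        fa, mo = parents[ind]
        fi = idx[fa] if fa else None
        mi = idx[mo] if mo else None
        phi[k, k] = 0.5 * (1.0 + (phi[fi, mi] if fi is not None and mi is not None else 0.0))
        for j in range(k):
            val = 0.5 * ((phi[fi, j] if fi is not None else 0.0)
                         + (phi[mi, j] if mi is not None else 0.0))
            phi[k, j] = phi[j, k] = val
    keep = np.array([idx[i] for i in listed])
    return KinshipMatrix(tuple(listed), phi[np.ix_(keep, keep)], check=False)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _complete_cases(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.isfinite(y) & np.isfinite(X).all(axis=1)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few complete cases ({n}) for {p} fixed-effect columns")
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _wald(beta: float, se: float) -> tuple[float, float]:
    z = beta / se
    return z, 2.0 * stats.norm.sf(abs(z))


def _reml_profile(log_delta: float, yt: np.ndarray, Xt: np.ndarray,
                  d: np.ndarray):
    """Profiled REML pieces at a fixed variance ratio.

    Returns (negative restricted log-likelihood, GLS coefficients,
    coefficient covariance, residual variance se^2).
    """
    n, p = Xt.shape
    delta = np.exp(log_delta)
    v = delta * d + 1.0            # eigenvalues of V / se^2
    w = 1.0 / v
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW                 # X^T V^-1 X (in units of 1/se^2)
    Ay = XtW.T @ yt
    b = np.linalg.solve(A, Ay)
    r = yt - Xt @ b
    rss = float(np.dot(r * w, r))
    sigma2 = rss / (n - p)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0 or not np.isfinite(logdet_A):
        return np.inf, b, None, sigma2
    nll = 0.5 * ((n - p) * np.log(sigma2) + np.log(v).sum() + logdet_A + (n - p))
    cov = sigma2 * np.linalg.inv(A)
    return nll, b, cov, sigma2


def reml_neg_loglik(log_delta: float, y: np.ndarray, X: np.ndarray,
                    d: np.ndarray, U: np.ndarray) -> float:
    """Negative restricted log-likelihood at a given log variance ratio.

    Exposed so the optimum can be verified (e.g. by a finite-difference
    gradient check); ``d, U`` is the eigendecomposition of 2*phi.
    """
    return _reml_profile(log_delta, U.T @ y, U.T @ X, d)[0]


def fit_probe_lmm(m_values, samples: SampleTable, kinship: KinshipMatrix,
                  probe_id: str = "") -> EwasRecord:
    """REML linear mixed model for one probe; see the module docstring.

    ``m_values`` is the per-sample M vector aligned to ``samples`` /
    ``kinship``.  Complete cases only; ``n_used`` is recorded.  A
    variance-ratio optimum on the search boundary is accepted (delta -> 0
    degenerates gracefully to OLS) and still flagged converged; only an
    optimizer failure clears the flag.
    """
    y = np.asarray(m_values, dtype=float)
    design = samples.design_matrix(include_phenotype=True)
    names = list(design.columns)
    X_all = design.to_numpy(dtype=float)
    if y.shape[0] != X_all.shape[0]:
        raise ValueError("m_values length does not match sample table")
    if list(map(str, samples.sample_ids)) != list(kinship.sample_ids):
        raise ValueError("kinship sample ids are not aligned to the sample table")
    mask = _complete_cases(y, X_all)
    y, X = y[mask], X_all[mask]
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(f"too few complete cases ({X.shape[0]}) to fit "
                         f"{X.shape[1]} fixed effects plus variance components")
    if np.ptp(y) == 0.0:
        raise ValueError(f"probe {probe_id or '<unnamed>'}: zero-variance M vector")
    _check_design(X, names)

    if mask.all():
        d, U = kinship.eig()
    else:
        sub = kinship.subset(np.asarray(kinship.sample_ids)[mask])
        d, U = np.linalg.eigh(sub.relationship)
        d = np.clip(d, 0.0, None)
    yt, Xt = U.T @ y, U.T @ X

    res = optimize.minimize_scalar(
        lambda ld: _reml_profile(ld, yt, Xt, d)[0],
        bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    nll, b, cov, _ = _reml_profile(log_delta, yt, Xt, d)
    converged = bool(res.success) and np.isfinite(nll) and cov is not None
    j = names.index(samples.phenotype)
    beta_hat = float(b[j])
    se = float(np.sqrt(cov[j, j])) if cov is not None else float("nan")
    z, p = _wald(beta_hat, se) if se > 0 else (float("nan"), float("nan"))
    return EwasRecord(probe_id=str(probe_id), beta_hat=beta_hat, se=se, z=z,
                      p_value=p, n_used=int(X.shape[0]), converged=converged,
                      log_delta=log_delta,
                      message="" if converged else "REML optimizer failed")


def fit_probe_ols(m_values, samples: SampleTable, probe_id: str = "") -> EwasRecord:
    """Ordinary least squares with classical SEs; same record contract.

    Degenerate path for unrelated designs (the mixed model with
    phi = 0.5 I collapses to exactly this fit).
    """
    y = np.asarray(m_values, dtype=float)
    design = samples.design_matrix(include_phenotype=True)
    names = list(design.columns)
    X_all = design.to_numpy(dtype=float)
    if y.shape[0] != X_all.shape[0]:
        raise ValueError("m_values length does not match sample table")
    mask = _complete_cases(y, X_all)
    y, X = y[mask], X_all[mask]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few complete cases ({n}) for {p} fixed-effect columns")
    if np.ptp(y) == 0.0:
        raise ValueError(f"probe {probe_id or '<unnamed>'}: zero-variance M vector")
    _check_design(X, names)
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    r = y - X @ b
    rss = float(r @ r)
    if rss <= 1e-12 * float(y @ y):
        raise ValueError(f"probe {probe_id or '<unnamed>'}: perfect fit "
                         "(zero residual variance), standard errors undefined")
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    j = names.index(samples.phenotype)
    beta_hat = float(b[j])
    se = float(np.sqrt(cov[j, j]))
    z, pval = _wald(beta_hat, se)
    return EwasRecord(probe_id=str(probe_id), beta_hat=beta_hat, se=se, z=z,
                      p_value=pval, n_used=int(n), converged=True)


def _ols_batch(Y: np.ndarray, X: np.ndarray, j: int):
    """Vectorized OLS over probes (rows of Y) sharing a complete design.

    Returns (beta, se, ok) for the j-th design column; probes with zero
    variance or a perfect fit are flagged not-ok rather than raising.
    """
    n, p = X.shape
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y.T)
    R = Y.T - X @ B
    rss = np.einsum("ij,ij->j", R, R)
    yss = np.einsum("ij,ij->i", Y, Y)
    ok = (np.ptp(Y, axis=1) > 0) & (rss > 1e-12 * np.maximum(yss, np.finfo(float).tiny))
    sigma2 = rss / (n - p)
    cjj = np.linalg.inv(XtX)[j, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * cjj)
        beta = B[j]
    return beta, se, ok


def run_ewas(meth: MethylationMatrix, samples: SampleTable,
             kinship: KinshipMatrix | None = None, model: str = "lmm",
             values_are_m: bool = False) -> pd.DataFrame:
    """Fit every probe and return one summary row per probe.

    ``meth`` holds beta values by default and is converted to M-values
    (clamped at 1e-6); pass ``values_are_m=True`` if it already holds
    M-values.  Per-probe failures (zero variance, perfect fit, too few
    complete cases) become flagged rows (``converged=False``) rather than
    aborting the run.  Deterministic given identical inputs.
    """
    if model not in ("lmm", "ols"):
        raise ValueError(f"unknown model {model!r}")
    if model == "ols" and kinship is not None:
        warnings.warn("model='ols' ignores the supplied kinship matrix",
                      UserWarning, stacklevel=2)
        kinship = None
    if model == "lmm" and kinship is None:
        raise ValueError("model='lmm' requires a kinship matrix")
    if list(map(str, meth.sample_ids)) != list(map(str, samples.sample_ids)):
        raise ValueError("methylation and sample table are not aligned; "
                         "call align_samples first")

    M = meth.values if values_are_m else beta_to_m(meth.values, clamp=True)
    design = samples.design_matrix(include_phenotype=True)
    names = list(design.columns)
    X = design.to_numpy(dtype=float)
    j = names.index(samples.phenotype)

    records: list[EwasRecord] = []
    design_ok = np.isfinite(X).all()
    if model == "ols" and design_ok and np.isfinite(M).all() and X.shape[0] > X.shape[1]:
        _check_design(X, names)
        beta, se, ok = _ols_batch(M, X, j)
        for i, pid in enumerate(meth.probe_ids):
            if ok[i] and np.isfinite(se[i]) and se[i] > 0:
                z, p = _wald(float(beta[i]), float(se[i]))
                records.append(EwasRecord(str(pid), float(beta[i]), float(se[i]),
                                          z, p, X.shape[0], True))
            else:
                records.append(_failed(str(pid), X.shape[0],
                                       "zero-variance or perfect-fit probe"))
    else:
        fit = fit_probe_ols if model == "ols" else fit_probe_lmm
        for i, pid in enumerate(meth.probe_ids):
            try:
                if model == "ols":
                    rec = fit(M[i], samples, probe_id=str(pid))
                else:
                    rec = fit(M[i], samples, kinship, probe_id=str(pid))
            except (ValueError, np.linalg.LinAlgError) as exc:
                rec = _failed(str(pid), int(np.isfinite(M[i]).sum()), str(exc))
            records.append(rec)
    return pd.DataFrame([asdict(r) for r in records], columns=EWAS_COLUMNS)


def _failed(probe_id: str, n_used: int, message: str) -> EwasRecord:
    nan = float("nan")
    return EwasRecord(probe_id, nan, nan, nan, nan, n_used, False, nan, message)
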