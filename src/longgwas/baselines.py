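"""Pseudo-phenotype GWAS baselines: accumulated EBVs, DRPs, residuals.

These are the traditional single-value strategies the time-varied scans are
compared against.  From a reduced random-regression fit, each phenotyped
individual is collapsed to one number:

* accumulated EBV:  EBV_i = Q_c' a_hat_i, the predicted genetic trajectory
  summed over the integer recording grid (Q_c the accumulation vector);
* DRP: a deregressed proof removing the parent-average part of the EBV,
  DRP_i = PA_i + (EBV_i - PA_i) / r^2_i, with reliability r^2_i from the
  prediction error variance;
* averaged estimated residual (GRAMMAR-style).

The pseudo-phenotype is then regressed on each SNP dosage, either with a
polygenic term u ~ N(0, A sigma_a^2) (the "-P" models, variance ratio by
REML) or by ordinary least squares (the "-NP" models and the residual
scan); each SNP is tested on 1 degree of freedom.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import GenotypeMatrix
from .model import RRMResults
from .scan import accumulation_vector

__all__ = [
    "accumulate_ebv",
    "reliabilities",
    "deregress",
    "average_residuals",
    "scan_single_value",
]


def accumulate_ebv(results: RRMResults, include_ancestors: bool = False) -> pd.Series:
    """Accumulated EBV per individual: EBV_i = Q_c' a_hat_i.

    By default returns the phenotyped individuals (data order); with
    ``include_ancestors`` every pedigree member gets a value.
    """
    model = results.model
    qc = accumulation_vector(model.spec.nr1, model.domain)
    if include_ancestors:
        ids = model.random_ids
        vals = results.a @ qc
    else:
        ids = model.data.individuals
        vals = results.a_phenotyped @ qc
    return pd.Series(vals, index=ids, name="ebv")


def reliabilities(results: RRMResults, r2_floor: float = 0.0) -> pd.Series:
    """Reliability of each phenotyped individual's accumulated EBV.

    r^2_i = 1 - PEV_i / (Q_c' G Q_c), with PEV_i = Q_c' C^{aa}_i Q_c taken
    from the prediction error covariance of the additive coefficients
    (the corresponding diagonal block of the inverse MME coefficient
    matrix).  Clipped to [0, 1).  Balanced data uses the rotated-kernel
    closed form; otherwise the MME coefficient matrix is inverted directly
    (desk scale only).
    """
    model = results.model
    qc = accumulation_vector(model.spec.nr1, model.domain)
    denom = float(qc @ results.vc.G @ qc)
    if denom <= 0:
        raise ValueError("non-positive genetic variance of the accumulated EBV")
    if model.data.is_balanced():
        kern = model.kernel()
        pev_blocks = kern.pev_additive(results.vc, [kern.mean_group()])
    else:
        pev_blocks = _pev_via_mme(results)
    pev = np.einsum("a,iab,b->i", qc, pev_blocks, qc)
    r2 = np.clip(1.0 - pev / denom, 0.0, 1.0 - 1e-12)
    return pd.Series(np.maximum(r2, r2_floor), index=model.data.individuals, name="r2")


def _pev_via_mme(results: RRMResults) -> np.ndarray:
    """Additive-coefficient PEV blocks from the dense inverse of the MME
    coefficient matrix (phenotyped individuals only)."""
    from scipy import sparse as sp

    from .model import build_design

    model = results.model
    design = build_design(model.data, model.spec, model.domain, model.random_ids)
    ainv, _ = model._a_inverse_logdet()
    X, Q, Z = design.X, design.Q, design.Z
    se2 = results.vc.sigma_e2
    Ginv = linalg.inv(results.vc.G)
    Pinv = linalg.inv(results.vc.P)
    W = sp.hstack([sp.csr_matrix(X), Q, Z], format="csr")
    C = (W.T @ W).toarray()
    p_fix = X.shape[1]
    nq = Q.shape[1]
    C[p_fix:p_fix + nq, p_fix:p_fix + nq] += sp.kron(ainv, Ginv).toarray() * se2
    n_phen = len(design.phenotyped_ids)
    C[p_fix + nq:, p_fix + nq:] += np.kron(np.eye(n_phen), Pinv) * se2
    if C.shape[0] > 8000:
        raise ValueError("MME too large for dense PEV extraction")
    Cinv = linalg.inv(C)
    k1 = model.spec.k1
    idx_in_random = (model.pedigree.index_of(model.data.individuals)
                     if model.pedigree is not None
                     else np.arange(n_phen))
    blocks = np.empty((n_phen, k1, k1))
    for j, ri in enumerate(idx_in_random):
        lo = p_fix + ri * k1
        blocks[j] = Cinv[lo:lo + k1, lo:lo + k1] * se2
    return blocks


def deregress(
    ebv: pd.Series,
    ped,
    r2: pd.Series,
    r2_floor: float = 0.1,
    ebv_all: pd.Series | None = None,
) -> pd.Series:
    """Deregressed proofs: remove the parent average, expand the Mendelian
    sampling deviation by the reliability.

    DRP_i = PA_i + (EBV_i - PA_i) / max(r^2_i, r2_floor), with
    PA_i = (EBV_sire + EBV_dam)/2 and an unknown parent contributing 0.
    This is a single-step parent-average-removal deregression; reliabilities
    are floored to cap variance inflation.

    Parameters
    ----------
    ebv : Series indexed by individual id (the phenotyped cohort).
    ped : Pedigree or None (no pedigree means PA = 0 for everyone).
    r2 : Series of reliabilities in [0, 1).
    ebv_all : Series covering ancestors too; defaults to ``ebv``.
    """
    r2v = r2.reindex(ebv.index)
    if bool((r2v.fillna(0.0) < r2_floor).all()):
        raise ValueError("all reliabilities below the deregression floor")
    if ebv_all is None:
        ebv_all = ebv
    out = {}
    for ind in ebv.index:
        pa = 0.0
        if ped is not None:
            i = int(ped.index_of([ind])[0])
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0:
                pa += 0.5 * float(ebv_all.get(ped.ids[s], 0.0))
            if d >= 0:
                pa += 0.5 * float(ebv_all.get(ped.ids[d], 0.0))
        r2i = max(float(r2v.get(ind, 0.0)), r2_floor)
        out[ind] = pa + (float(ebv[ind]) - pa) / r2i
    return pd.Series(out, name="drp").reindex(ebv.index)


def average_residuals(results: RRMResults) -> pd.Series:
    """Per-individual mean of the estimated residuals from the reduced fit."""
    model = results.model
    df = pd.DataFrame({"id": model.data.ids, "e": results.residuals})
    means = df.groupby("id", sort=False)["e"].mean()
    return means.reindex(model.data.individuals).rename("residual")


def _reml_variance_ratio(y: np.ndarray, X: np.ndarray, A: np.ndarray):
    """Single-component REML on the eigenbasis of A (EMMA-style).

    Returns (sigma_a2, sigma_e2, U, d) maximizing the residual likelihood of
    y = X beta + u + e, var(u) = A sigma_a2.
    """
    d, U = linalg.eigh(A)
    d = np.maximum(d, 1e-10)
    yr, Xr = U.T @ y, U.T @ X
    n, p = X.shape

    def profile_negloglik(log_lam):
        lam = np.exp(log_lam)  # sigma_a2 / sigma_e2
        w = 1.0 / (lam * d + 1.0)
        XVX = (Xr * w[:, None]).T @ Xr
        XVy = (Xr * w[:, None]).T @ yr
        cf = linalg.cho_factor(XVX)
        beta = linalg.cho_solve(cf, XVy)
        r = yr - Xr @ beta
        yPy = float(r @ (w * r))
        se2 = yPy / (n - p)
        logdet_V = float(np.sum(np.log(lam * d + 1.0))) + (n - p) * np.log(se2)
        logdet_XVX = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) + 0.0
        return 0.5 * (logdet_V + logdet_XVX + (n - p))

    res = optimize.minimize_scalar(
        profile_negloglik, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    w = 1.0 / (lam * d + 1.0)
    XVX = (Xr * w[:, None]).T @ Xr
    XVy = (Xr * w[:, None]).T @ yr
    beta = linalg.solve(XVX, XVy, assume_a="pos")
    r = yr - Xr @ beta
    se2 = float(r @ (w * r)) / (n - p)
    return lam * se2, se2, U, d


def scan_single_value(
    y: pd.Series,
    geno: GenotypeMatrix,
    results: RRMResults | None = None,
    fit_polygenic: bool = False,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Single-value association scan of a pseudo-phenotype on each SNP.

    With ``fit_polygenic`` a polygenic term u ~ N(0, A sigma_a^2) is
    included (A over the pseudo-phenotyped individuals, variance ratio
    estimated once by REML under the no-SNP model and plugged in);
    otherwise plain least squares.  Each SNP is tested by a 1-df Wald
    chi-square.  Returns a table with columns snp, coef, W, df, p.
    """
    ids = y.index.to_numpy(dtype=object)
    geno = geno.subset_individuals(ids)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    ones = np.ones((n, 1))

    if fit_polygenic:
        if results is None:
            raise ValueError("fit_polygenic requires the fitted reduced model")
        model = results.model
        idx = model.pedigree.index_of(ids) if model.pedigree is not None else np.arange(n)
        A = model.A[np.ix_(idx, idx)]
        sa2, se2, U, d = _reml_variance_ratio(yv, ones, A)
        w = 1.0 / (sa2 * d + se2)
        yr = U.T @ yv
        onesr = U.T @ ones.ravel()
    rows = []
    freqs = geno.freq
    for s in range(geno.n_snps):
        x = geno.values[s].astype(float).copy()
        nanmask = np.isnan(x)
        if nanmask.any():
            x[nanmask] = np.nanmean(x)
        p_freq = freqs[s]
        maf = min(p_freq, 1 - p_freq) if np.isfinite(p_freq) else 0.0
        rec = {"snp": geno.snp_ids[s],
               "chrom": geno.chrom[s] if geno.chrom is not None else "",
               "pos": geno.pos[s] if geno.pos is not None else 0}
        if maf < maf_min or np.std(x) == 0:
            rows.append({**rec, "coef": np.nan, "W": 0.0, "df": 0, "p": 1.0,
                         "testable": False})
            continue
        if fit_polygenic:
            Xr = np.column_stack([onesr, U.T @ x])
            XVX = (Xr * w[:, None]).T @ Xr
            XVy = (Xr * w[:, None]).T @ yr
            beta = linalg.solve(XVX, XVy, assume_a="pos")
            covb = linalg.inv(XVX)
            W = float(beta[1] ** 2 / covb[1, 1])
        else:
            X = np.column_stack([np.ones(n), x])
            XtX = X.T @ X
            beta = linalg.solve(XtX, X.T @ yv, assume_a="pos")
            resid = yv - X @ beta
            s2 = float(resid @ resid) / (n - 2)
            covb = s2 * linalg.inv(XtX)
            W = float(beta[1] ** 2 / covb[1, 1])
        pval = float(stats.chi2.sf(W, 1))
        rows.append({**rec, "coef": float(beta[1]), "W": W, "df": 1, "p": pval,
                     "testable": True})
    return pd.DataFrame(rows)
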