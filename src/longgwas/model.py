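"""Random regression model for longitudinal traits (Model/Results API).

The model for individual *i* at time *t* is

    y_i(t) = mu(t) + a_i(t) + p_i(t) + e_it,

with mu(t), a_i(t) and p_i(t) regressions on normalized Legendre polynomials
of orders ``nf``, ``nr1`` and ``nr2``.  Stacking records gives

    y = X b + Q a + Z p + e,
    var(a) = A (x) G,   var(p) = I (x) P,   var(e) = I sigma_e^2,

where A is the pedigree numerator relationship matrix, G and P are the
coefficient covariance matrices, and (x) is the Kronecker product.
Variance components are estimated by REML; with them plugged in, fixed
effects (BLUE) and random-effect predictions (BLUP) solve Henderson's mixed
model equations.

Two computational backends are used:

* a *balanced kernel* for data where every individual shares one recording
  grid — the eigendecomposition A = U D U' rotates the model into
  independent per-individual blocks, making each REML likelihood evaluation
  O(n T^2) (EMMA-style);
* a general sparse *MME backend* for arbitrary record patterns, with the
  REML log-likelihood computed from the factorization of the MME
  coefficient matrix.

On balanced data both backends agree to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse
from scipy.sparse.linalg import splu

from .basis import TimeDomain, legendre_matrix
from .data import LongitudinalData
from .pedigree import Pedigree, a_inverse, numerator_relationship_matrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "DesignSet",
    "MMEFit",
    "build_design",
    "solve_mme",
    "RandomRegressionModel",
    "RRMResults",
    "information_criteria",
    "select_orders",
]

VARIANCE_FLOOR_FRAC = 1e-8  # relative to phenotypic variance


@dataclass(frozen=True)
class ModelSpec:
    """Basis orders: nf for mu(t) (and SNP curves), nr1 additive, nr2 PE."""

    nf: int
    nr1: int
    nr2: int

    def __post_init__(self) -> None:
        if min(self.nf, self.nr1, self.nr2) < 0:
            raise ValueError(f"basis orders must be >= 0: {self}")

    @property
    def k1(self) -> int:
        return self.nr1 + 1

    @property
    def k2(self) -> int:
        return self.nr2 + 1

    def n_variance_params(self) -> int:
        """Free (co)variance parameters: triangles of G and P plus sigma_e^2."""
        return self.k1 * (self.k1 + 1) // 2 + self.k2 * (self.k2 + 1) // 2 + 1

    def validate_against(self, data: LongitudinalData) -> None:
        max_m = int(data.record_counts().max())
        if self.k1 > max_m or self.k2 > max_m:
            raise ValueError(
                f"orders {self} not identifiable: need max records per individual "
                f">= max(nr1, nr2) + 1, got {max_m}"
            )


@dataclass
class VarianceComponents:
    """Covariance of additive (G) and PE (P) coefficients plus sigma_e^2."""

    G: np.ndarray
    P: np.ndarray
    sigma_e2: float

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        for name, M in (("G", self.G), ("P", self.P)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
        if not self.sigma_e2 > 0:
            raise ValueError("sigma_e2 must be > 0")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G.copy(), self.P.copy(), float(self.sigma_e2))


# ---------------------------------------------------------------------------
# Design matrices and the mixed model equations (general backend)
# ---------------------------------------------------------------------------


@dataclass
class DesignSet:
    """Stacked design matrices for y = X b + Q a + Z p + e.

    Q spans ``random_ids`` (typically all pedigree members, so ancestors get
    breeding values too); Z spans the phenotyped individuals only.
    """

    X: np.ndarray
    Q: sparse.csr_matrix
    Z: sparse.csr_matrix
    y: np.ndarray
    random_ids: np.ndarray
    phenotyped_ids: np.ndarray
    x_names: list

    @property
    def n_records(self) -> int:
        return len(self.y)


def build_design(
    data: LongitudinalData,
    spec: ModelSpec,
    domain: TimeDomain,
    random_ids=None,
    extra_fixed: dict | None = None,
) -> DesignSet:
    """Assemble X, Q, Z for the random regression model.

    Record r for (individual i, time t) has X row [phi_0(t)..phi_nf(t)]
    (plus any extra fixed covariate columns), the same-order basis row in
    individual i's block of Q (order nr1) and of Z (order nr2), zeros
    elsewhere.
    """
    spec.validate_against(data)
    phen_ids = data.individuals
    if random_ids is None:
        random_ids = phen_ids
    random_ids = np.asarray(random_ids, dtype=object)

    phi_f = legendre_matrix(spec.nf, data.times, domain)
    phi_a = legendre_matrix(spec.nr1, data.times, domain)
    phi_p = legendre_matrix(spec.nr2, data.times, domain)

    X = phi_f
    x_names = [f"mu_{k}" for k in range(spec.nf + 1)]
    if extra_fixed:
        for name, col in extra_fixed.items():
            X = np.column_stack([X, np.asarray(col, dtype=float)])
            x_names.append(name)

    m = data.n_records
    rand_pos = {v: i for i, v in enumerate(random_ids)}
    phen_pos = {v: i for i, v in enumerate(phen_ids)}
    rec_rand = np.array([rand_pos[v] for v in data.ids])
    rec_phen = np.array([phen_pos[v] for v in data.ids])

    def block_matrix(rec_idx, phi, n_ind):
        k = phi.shape[1]
        rows = np.repeat(np.arange(m), k)
        cols = (rec_idx[:, None] * k + np.arange(k)[None, :]).ravel()
        return sparse.csr_matrix((phi.ravel(), (rows, cols)), shape=(m, n_ind * k))

    Q = block_matrix(rec_rand, phi_a, len(random_ids))
    Z = block_matrix(rec_phen, phi_p, len(phen_ids))
    return DesignSet(X, Q, Z, data.values.copy(), random_ids, phen_ids, x_names)


@dataclass
class MMEFit:
    """Solution of the mixed model equations at fixed variance components."""

    b: np.ndarray
    a: np.ndarray          # (n_random, nr1+1) additive coefficient BLUPs
    p: np.ndarray          # (n_phenotyped, nr2+1) PE coefficient BLUPs
    residuals: np.ndarray
    rss: float             # reduction in sums of squares R(model)
    logdet_C: float
    spec: ModelSpec | None = None
    x_names: list | None = None


def solve_mme(
    design: DesignSet,
    vc: VarianceComponents,
    a_inv: sparse.spmatrix | np.ndarray,
    spec: ModelSpec | None = None,
) -> MMEFit:
    """Solve Henderson's mixed model equations at the given components.

    The coefficient matrix couples X'X, Q'Q + A^{-1} (x) G^{-1} sigma_e^2 and
    Z'Z + I (x) P^{-1} sigma_e^2 (the system is scaled by sigma_e^2, which
    cancels from the solutions).  Returns BLUE/BLUP solutions, residuals and
    the reduction in sums of squares R(model) = b'X'y + a'Q'y + p'Z'y.
    """
    X, Q, Z, y = design.X, design.Q, design.Z, design.y
    k1 = Q.shape[1] // len(design.random_ids)
    k2 = Z.shape[1] // len(design.phenotyped_ids)
    se2 = vc.sigma_e2

    Ginv = linalg.inv(_regularized(vc.G))
    Pinv = linalg.inv(_regularized(vc.P))
    a_inv = sparse.csr_matrix(a_inv)

    Xs = sparse.csr_matrix(X)
    W = sparse.hstack([Xs, Q, Z], format="csr")
    p_fix = X.shape[1]
    nq = Q.shape[1]
    # shrinkage blocks, scaled by sigma_e^2 since C is built from W'W (R = I se2)
    GA = sparse.kron(a_inv, Ginv, format="csr") * se2
    PI = sparse.kron(sparse.identity(len(design.phenotyped_ids)), Pinv,
                     format="csr") * se2
    shrink = sparse.block_diag(
        [sparse.csr_matrix((p_fix, p_fix)), GA, PI], format="csr"
    )
    C = (W.T @ W + shrink).tocsr()
    rhs = W.T @ y

    # rank check on the fixed block via dense QR of X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"fixed-effect design is rank deficient (columns {design.x_names})"
        )

    n_eq = C.shape[0]
    if n_eq <= 5000:
        Cd = C.toarray()
        try:
            cf = linalg.cho_factor(Cd, lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"MME coefficient matrix not PD: {exc}")
        sol = linalg.cho_solve(cf, rhs)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    else:
        lu = splu(C.tocsc())
        sol = lu.solve(rhs)
        logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    b = sol[:p_fix]
    a = sol[p_fix:p_fix + nq].reshape(len(design.random_ids), k1)
    p = sol[p_fix + nq:].reshape(len(design.phenotyped_ids), k2)
    fitted = X @ b + Q @ sol[p_fix:p_fix + nq] + Z @ sol[p_fix + nq:]
    rss = float(sol @ rhs)
    # logdet of the R^-1-scaled system of Eq. (4): C_eq4 = C / se2
    logdet_C_eq4 = logdet_C - n_eq * np.log(se2)
    return MMEFit(b, a, p, y - fitted, rss, logdet_C_eq4, spec, design.x_names)


def _regularized(M: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Lift a PSD matrix onto the PD cone by flooring its eigenvalues."""
    w, V = linalg.eigh(M)
    scale = max(np.max(np.abs(w)), 1.0)
    w = np.maximum(w, eps * scale)
    return (V * w) @ V.T


# ---------------------------------------------------------------------------
# Balanced kernel: eigen-rotation of A into independent blocks
# ---------------------------------------------------------------------------


class FixedGroup:
    """A fixed time-varied term: per-individual weight times a basis curve.

    The population mean is weight 1 for everyone; an fGWAS-C SNP term has
    weight x_i (dosage); an fGWAS-F genotype-class term has an indicator
    weight.  Columns of the stacked design are w_i * phi_k(t).
    """

    def __init__(self, name: str, weights: np.ndarray, phi: np.ndarray):
        self.name = name
        self.weights = np.asarray(weights, dtype=float)
        self.phi = np.asarray(phi, dtype=float)  # (T, p) basis on record grid

    @property
    def n_cols(self) -> int:
        return self.phi.shape[1]


class BalancedKernel:
    """REML/GLS/BLUP engine for one shared recording grid per individual.

    With A = U D U', the rotation (U' (x) I_T) turns the stacked model into n
    independent T-dimensional blocks with covariance
    Sigma_i = d_i Phi_a G Phi_a' + Phi_p P Phi_p' + sigma_e^2 I.
    A generalized eigendecomposition of the two T x T kernels then reduces
    every likelihood evaluation to elementwise work on an (n, T) array.
    """

    def __init__(
        self,
        Y: np.ndarray,                # (n, T) records per individual
        rec_times: np.ndarray,        # (T,) shared recording times
        spec: ModelSpec,
        domain: TimeDomain,
        A_pp: np.ndarray | None = None,
    ):
        self.Y = np.asarray(Y, dtype=float)
        self.n, self.T = self.Y.shape
        self.rec_times = np.asarray(rec_times, dtype=float)
        self.spec = spec
        self.domain = domain
        self.phi_f = legendre_matrix(spec.nf, rec_times, domain)
        self.phi_a = legendre_matrix(spec.nr1, rec_times, domain)
        self.phi_p = legendre_matrix(spec.nr2, rec_times, domain)
        if A_pp is None:
            A_pp = np.eye(self.n)
        dvals, U = linalg.eigh(A_pp)
        self.d = np.maximum(dvals, 1e-10)
        self.U = U
        self.Yrot = U.T @ self.Y
        self.yy = float(np.sum(self.Y**2))

    def mean_group(self) -> FixedGroup:
        return FixedGroup("mu", np.ones(self.n), self.phi_f)

    # -- core linear algebra ------------------------------------------------

    def _prepare(self, vc: VarianceComponents):
        """Per-component context reusable across many GLS solves (scans)."""
        B1 = self.phi_a @ vc.G @ self.phi_a.T
        B2 = self.phi_p @ vc.P @ self.phi_p.T + vc.sigma_e2 * np.eye(self.T)
        lam, Vg = linalg.eigh(B1, B2)
        lam = np.maximum(lam, 0.0)
        sign, logdet_B2 = np.linalg.slogdet(B2)
        Ystar = self.Yrot @ Vg
        invD = 1.0 / (1.0 + np.outer(self.d, lam))
        return lam, Vg, logdet_B2, Ystar, invD

    def gls(self, vc: VarianceComponents, groups: list, want_blups: bool = False,
            ctx=None):
        """GLS fixed-effect fit (and optional BLUPs) at known components.

        Returns a dict with beta, cov (GLS covariance of beta), rss
        (reduction in sums of squares), logL (REML), and, when requested,
        additive/PE coefficient BLUPs and per-record residuals.  Pass a
        precomputed ``ctx = _prepare(vc)`` when solving many designs at the
        same components (per-SNP scans).
        """
        lam, Vg, logdet_B2, Ystar, invD = ctx if ctx is not None else self._prepare(vc)
        U, d = self.U, self.d

        Fs = [Vg.T @ g.phi for g in groups]          # star-space bases
        ws = [U.T @ g.weights for g in groups]       # rotated weights
        p_tot = sum(g.n_cols for g in groups)
        XVX = np.zeros((p_tot, p_tot))
        XVy = np.zeros(p_tot)
        offs = np.cumsum([0] + [g.n_cols for g in groups])
        for gi in range(len(groups)):
            wj_y = np.einsum("i,ij,ij->j", ws[gi], invD, Ystar)
            XVy[offs[gi]:offs[gi + 1]] = Fs[gi].T @ wj_y
            for hi in range(gi, len(groups)):
                wj = np.einsum("i,i,ij->j", ws[gi], ws[hi], invD)
                blk = np.einsum("j,ja,jb->ab", wj, Fs[gi], Fs[hi])
                XVX[offs[gi]:offs[gi + 1], offs[hi]:offs[hi + 1]] = blk
                if hi != gi:
                    XVX[offs[hi]:offs[hi + 1], offs[gi]:offs[gi + 1]] = blk.T
        yVy = float(np.einsum("ij,ij->", invD, Ystar**2))

        try:
            cf = linalg.cho_factor(XVX)
        except linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "fixed-effect design is rank deficient (collinear columns among "
                + ", ".join(g.name for g in groups)
                + ")"
            )
        beta = linalg.cho_solve(cf, XVy)
        cov = linalg.cho_solve(cf, np.eye(p_tot))
        logdet_XVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = yVy - float(beta @ XVy)
        logdet_V = self.n * logdet_B2 + float(np.sum(np.log1p(np.outer(self.d, lam))))
        m = self.n * self.T
        logL = -0.5 * ((m - p_tot) * np.log(2 * np.pi) + logdet_V + logdet_XVX + yPy)
        rss = self.yy - vc.sigma_e2 * yPy
        out = {
            "beta": beta, "cov": cov, "rss": rss, "logL": logL,
            "offsets": offs, "yPy": yPy,
        }
        if want_blups:
            fitted_star = np.zeros_like(Ystar)
            for gi, g in enumerate(groups):
                bg = beta[offs[gi]:offs[gi + 1]]
                fitted_star += np.outer(ws[gi], Fs[gi] @ bg)
            Sstar = invD * (Ystar - fitted_star)
            Stil = Sstar @ Vg.T          # rotated V^{-1} residual, time coords
            S = U @ Stil                 # back-rotated: rows = individuals
            omega = S @ self.phi_a       # (n, nr1+1): Q' V^{-1} (y - X beta)
            # additive BLUP carries the relationship matrix: in rotated
            # coordinates a~_i = d_i G Phi_a' Sigma_i^{-1} r~_i
            a_hat = (U @ (self.d[:, None] * (Stil @ self.phi_a))) @ vc.G
            p_hat = (S @ self.phi_p) @ vc.P
            resid = vc.sigma_e2 * S      # e_hat = sigma_e^2 V^{-1}(y - X b - ...)
            out.update({
                "a_hat": a_hat, "p_hat": p_hat, "resid_matrix": resid,
                "omega": omega,
            })
        return out

    def reml_loglik(self, vc: VarianceComponents, groups: list) -> float:
        return self.gls(vc, groups)["logL"]

    def pev_additive(self, vc: VarianceComponents, groups: list) -> np.ndarray:
        """Prediction error covariance of each individual's additive
        coefficients, var(a_hat_i - a_i), including the fixed-effect
        contribution; equals the corresponding diagonal blocks of the
        inverse MME coefficient matrix."""
        lam, Vg, _, Ystar, invD = self._prepare(vc)
        U, d, G = self.U, self.d, vc.G
        k = self.spec.k1
        Fa = Vg.T @ self.phi_a  # (T, k)

        # M_i = Phi_a' Sigma_i^{-1} Phi_a in star coords
        # term1_j = sum_i U_ji^2 d_i^2 (G M_i G)
        M = np.einsum("ij,ja,jb->iab", invD, Fa, Fa)        # (n, k, k)
        GMG = np.einsum("ab,ibc,cd->iad", G, M, G)
        term1 = np.einsum("ji,i,iab->jab", U**2, d**2, GMG)

        # fixed-effect correction: H_i = d_i G Phi_a' Sigma_i^{-1} X_i
        Fs = [Vg.T @ g.phi for g in groups]
        ws = [U.T @ g.weights for g in groups]
        p_tot = sum(g.n_cols for g in groups)
        offs = np.cumsum([0] + [g.n_cols for g in groups])
        XVX = np.zeros((p_tot, p_tot))
        N = np.zeros((self.n, k, p_tot))
        for gi, g in enumerate(groups):
            # Phi_a' D_i^{-1} F_g scaled by w_gi
            Ng = np.einsum("ij,ja,jb->iab", invD, Fa, Fs[gi])
            N[:, :, offs[gi]:offs[gi + 1]] = Ng * ws[gi][:, None, None]
            for hi in range(gi, len(groups)):
                wj = np.einsum("i,i,ij->j", ws[gi], ws[hi], invD)
                blk = np.einsum("j,ja,jb->ab", wj, Fs[gi], Fs[hi])
                XVX[offs[gi]:offs[gi + 1], offs[hi]:offs[hi + 1]] = blk
                if hi != gi:
                    XVX[offs[hi]:offs[hi + 1], offs[gi]:offs[gi + 1]] = blk.T
        H = np.einsum("i,ab,ibp->iap", d, G, N)            # (n, k, p_tot)
        Hbar = np.einsum("ji,iap->jap", U, H)
        Cx_inv = linalg.inv(XVX)
        corr = np.einsum("jap,pq,jbq->jab", Hbar, Cx_inv, Hbar)

        A_diag = np.einsum("ji,i,ji->j", U, d, U)          # diag of A_pp
        prior = A_diag[:, None, None] * G[None, :, :]
        return prior - term1 + corr


# ---------------------------------------------------------------------------
# REML driver
# ---------------------------------------------------------------------------


def _pack(vc: VarianceComponents) -> np.ndarray:
    def chol_params(M):
        L = linalg.cholesky(_regularized(M), lower=True)
        k = M.shape[0]
        out = []
        for i in range(k):
            for j in range(i + 1):
                out.append(np.log(L[i, j]) if i == j else L[i, j])
        return out

    return np.array(
        chol_params(vc.G) + chol_params(vc.P) + [np.log(vc.sigma_e2)], dtype=float
    )


def _unpack(theta: np.ndarray, spec: ModelSpec) -> VarianceComponents:
    def take_chol(vals, k):
        L = np.zeros((k, k))
        it = iter(vals)
        for i in range(k):
            for j in range(i + 1):
                v = next(it)
                L[i, j] = np.exp(v) if i == j else v
        return L @ L.T

    k1, k2 = spec.k1, spec.k2
    n1 = k1 * (k1 + 1) // 2
    n2 = k2 * (k2 + 1) // 2
    G = take_chol(theta[:n1], k1)
    P = take_chol(theta[n1:n1 + n2], k2)
    return VarianceComponents(G, P, float(np.exp(theta[n1 + n2])))


def _initial_vc(data: LongitudinalData, spec: ModelSpec, domain: TimeDomain) -> VarianceComponents:
    """Scale-aware start: half the phenotypic variance to the residual, the
    rest split evenly between diagonal G and P."""
    var_y = float(np.var(data.values))
    grid = domain.grid.astype(float)

    def diag_for(order, share):
        phi = legendre_matrix(order, grid, domain)
        mean_sq = np.mean(phi**2, axis=0)
        k = order + 1
        return np.diag(share * var_y / (k * mean_sq))

    return VarianceComponents(
        diag_for(spec.nr1, 0.25), diag_for(spec.nr2, 0.25), 0.5 * var_y
    )


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


def _maximize_reml(objective, theta0, var_y):
    """Maximize the REML log-likelihood over packed covariance parameters.

    Quasi-Newton (L-BFGS-B) with a log-Cholesky parameterization keeps every
    iterate inside the parameter space; diagonal log-variances are bounded
    below at the variance floor.  Falls back to Nelder-Mead if the gradient
    path stalls below the starting likelihood.
    """
    trace = []

    def neg(theta):
        try:
            val = -objective(theta)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        trace.append(val)
        return val

    res = optimize.minimize(
        neg, theta0, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    f0 = neg(theta0)
    if not np.isfinite(res.fun) or res.fun > f0 + 1e-6:
        res = optimize.minimize(
            neg, theta0, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-7},
        )
    if res.fun > f0 + 1e-6:
        raise ConvergenceError(
            f"REML failed to improve on the initial likelihood ({-f0:.4f})",
            trace=trace,
        )
    return res.x, -res.fun


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class RandomRegressionModel:
    """Random regression model for longitudinal phenotypes.

    Parameters
    ----------
    data : LongitudinalData
        Long-format records (id, time, value).
    spec : ModelSpec
        Basis orders (nf, nr1, nr2).
    pedigree : Pedigree, optional
        Pedigree for the numerator relationship matrix; omit for A = I.
        Individuals with records that are missing from the pedigree are
        appended as founders (with a warning).
    domain : TimeDomain, optional
        Standardization domain; defaults to the data's min/max time.

    Examples
    --------
    >>> model = RandomRegressionModel(data, ModelSpec(2, 2, 2), pedigree=ped)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(
        self,
        data: LongitudinalData,
        spec: ModelSpec,
        pedigree: Pedigree | None = None,
        domain: TimeDomain | None = None,
    ):
        spec.validate_against(data)
        self.data = data
        self.spec = spec
        self.domain = domain if domain is not None else data.domain()
        self.pedigree = self._reconcile_pedigree(pedigree)
        self._A_full = None
        self._kernel = None

    def _reconcile_pedigree(self, ped: Pedigree | None) -> Pedigree | None:
        if ped is None:
            return None
        known = set(ped.ids)
        missing = [v for v in self.data.individuals if v not in known]
        if missing:
            warnings.warn(
                f"{len(missing)} phenotyped individual(s) absent from the "
                "pedigree; added as founders"
            )
            recs = [
                (ped.ids[i],
                 ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None,
                 ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else None)
                for i in range(len(ped))
            ] + [(v, None, None) for v in missing]
            ped = Pedigree.from_records(recs)
        return ped

    # -- relationship matrices ---------------------------------------------

    @property
    def A(self) -> np.ndarray:
        """Numerator relationship matrix over all pedigree individuals
        (identity when no pedigree was given)."""
        if self._A_full is None:
            if self.pedigree is None:
                self._A_full = np.eye(self.data.n_individuals)
            else:
                self._A_full = numerator_relationship_matrix(self.pedigree)
        return self._A_full

    @property
    def random_ids(self) -> np.ndarray:
        if self.pedigree is None:
            return self.data.individuals
        return self.pedigree.ids

    def _phen_index_in_random(self) -> np.ndarray:
        if self.pedigree is None:
            return np.arange(self.data.n_individuals)
        return self.pedigree.index_of(self.data.individuals)

    @property
    def A_pp(self) -> np.ndarray:
        """A restricted to phenotyped individuals (data order)."""
        idx = self._phen_index_in_random()
        return self.A[np.ix_(idx, idx)]

    # -- balanced kernel ----------------------------------------------------

    def kernel(self) -> BalancedKernel:
        if self._kernel is None:
            if not self.data.is_balanced():
                raise ValueError("balanced kernel requires one shared recording grid")
            df = self.data.to_frame()
            wide = df.pivot_table(index="id", columns="time", values="value", sort=False)
            wide = wide.loc[self.data.individuals]
            self._kernel = BalancedKernel(
                wide.to_numpy(), wide.columns.to_numpy(dtype=float),
                self.spec, self.domain, self.A_pp,
            )
        return self._kernel

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        init: VarianceComponents | None = None,
        method: str = "auto",
    ) -> "RRMResults":
        """Estimate (G, P, sigma_e^2) by REML and solve for BLUE/BLUP.

        method: 'auto' uses the fast balanced kernel when the data share one
        recording grid, otherwise the sparse MME likelihood.
        """
        vc0 = init if init is not None else _initial_vc(self.data, self.spec, self.domain)
        var_y = float(np.var(self.data.values))
        theta0 = _pack(vc0)

        if method == "auto":
            method = "balanced" if self.data.is_balanced() else "mme"

        if method == "balanced":
            kern = self.kernel()
            groups = [kern.mean_group()]

            def objective(theta):
                return kern.reml_loglik(_unpack(theta, self.spec), groups)

        elif method == "mme":
            design = build_design(self.data, self.spec, self.domain, self.random_ids)
            a_inv, logdet_A = self._a_inverse_logdet()

            def objective(theta):
                vc = _unpack(theta, self.spec)
                return _mme_reml_loglik(design, vc, a_inv, logdet_A, self.spec)

        else:
            raise ValueError(f"unknown fit method {method!r}")

        theta_hat, logL = _maximize_reml(objective, theta0, var_y)
        vc_hat = _unpack(theta_hat, self.spec)
        vc_hat = _apply_floor(vc_hat, var_y)
        return self.fit_given(vc_hat, logL=logL, reml=True)

    def fit_given(
        self, vc: VarianceComponents, logL: float | None = None, reml: bool = False
    ) -> "RRMResults":
        """Solve for fixed effects and BLUPs at known variance components."""
        if self.data.is_balanced():
            kern = self.kernel()
            groups = [kern.mean_group()]
            out = kern.gls(vc, groups, want_blups=True)
            phen_a = out["a_hat"]
            # extend additive BLUPs to non-phenotyped pedigree members
            a_all = self._extend_blups(out["omega"], vc)
            resid = self._records_from_matrix(out["resid_matrix"])
            return RRMResults(
                self, vc, b=out["beta"], a=a_all, a_phenotyped=phen_a,
                p=out["p_hat"], residuals=resid, rss=out["rss"],
                logL=out["logL"] if logL is None else logL, reml=reml,
            )
        design = build_design(self.data, self.spec, self.domain, self.random_ids)
        a_inv, logdet_A = self._a_inverse_logdet()
        fit = solve_mme(design, vc, a_inv, self.spec)
        if logL is None:
            logL = _mme_reml_loglik(design, vc, a_inv, logdet_A, self.spec, fit=fit)
        idx = self._phen_index_in_random()
        return RRMResults(
            self, vc, b=fit.b, a=fit.a, a_phenotyped=fit.a[idx],
            p=fit.p, residuals=fit.residuals, rss=fit.rss, logL=logL, reml=reml,
        )

    def _extend_blups(self, omega: np.ndarray, vc: VarianceComponents) -> np.ndarray:
        """BLUPs for every pedigree member: a_hat = (A_{.,phen} (x) G) Q'V^{-1} r."""
        if self.pedigree is None:
            return omega @ vc.G
        idx = self._phen_index_in_random()
        A_all_p = self.A[:, idx]
        return (A_all_p @ omega) @ vc.G

    def _records_from_matrix(self, mat: np.ndarray) -> np.ndarray:
        """Flatten an (individual, grid-time) matrix back to record order."""
        df = self.data.to_frame()
        wide = df.pivot_table(index="id", columns="time", values="value", sort=False)
        wide = wide.loc[self.data.individuals]
        pos_i = {v: i for i, v in enumerate(wide.index)}
        pos_t = {t: j for j, t in enumerate(wide.columns)}
        ii = np.array([pos_i[v] for v in df["id"]])
        jj = np.array([pos_t[t] for t in df["time"]])
        return mat[ii, jj]

    def _a_inverse_logdet(self):
        if self.pedigree is None:
            n = self.data.n_individuals
            return sparse.identity(n, format="csr"), 0.0
        from .pedigree import inbreeding

        F = inbreeding(self.pedigree)
        ainv = a_inverse(self.pedigree, F)
        # |A| = prod of Mendelian sampling variances d_i
        dvals = np.ones(len(self.pedigree))
        for i in range(len(self.pedigree)):
            s, d = self.pedigree.sire[i], self.pedigree.dam[i]
            if s >= 0:
                dvals[i] -= 0.25 * (1 + F[s])
            if d >= 0:
                dvals[i] -= 0.25 * (1 + F[d])
        return ainv, float(np.sum(np.log(dvals)))


def _apply_floor(vc: VarianceComponents, var_y: float) -> VarianceComponents:
    floor = VARIANCE_FLOOR_FRAC * var_y
    vc = vc.copy()
    for M in (vc.G, vc.P):
        d = np.diag(M)
        low = d < floor
        if np.any(low):
            warnings.warn("variance component at boundary; fixed at the floor")
            np.fill_diagonal(M, np.maximum(d, floor))
    vc.sigma_e2 = max(vc.sigma_e2, floor)
    return vc


def _mme_reml_loglik(design, vc, a_inv, logdet_A, spec, fit=None):
    """REML log-likelihood from the MME factorization:
    log|V| + log|X'V^{-1}X| = log|C| + log|R| + log|A (x) G| + log|I (x) P|."""
    if fit is None:
        fit = solve_mme(design, vc, a_inv, spec)
    m = design.n_records
    p = design.X.shape[1]
    n_rand = len(design.random_ids)
    n_phen = len(design.phenotyped_ids)
    se2 = vc.sigma_e2
    sG = np.linalg.slogdet(_regularized(vc.G))[1]
    sP = np.linalg.slogdet(_regularized(vc.P))[1]
    logdet_Gstar = spec.k1 * logdet_A + n_rand * sG + n_phen * sP
    yPy = (float(design.y @ design.y) - fit.rss) / se2
    logdet_V_XVX = fit.logdet_C + m * np.log(se2) + logdet_Gstar
    return -0.5 * ((m - p) * np.log(2 * np.pi) + logdet_V_XVX + yPy)


class RRMResults:
    """Fitted random regression model: estimates, BLUPs and diagnostics.

    Attributes
    ----------
    vc : VarianceComponents
        (REML) estimates of G, P and sigma_e^2.
    b : ndarray
        Fixed regression coefficients of the population mean curve.
    a : ndarray, (n_pedigree, nr1+1)
        Additive coefficient BLUPs for every pedigree member.
    p : ndarray, (n_phenotyped, nr2+1)
        Permanent-environment coefficient BLUPs.
    residuals : ndarray
        Per-record estimated residuals e_hat.
    rss : float
        Reduction in sums of squares R(model).
    logL : float
        Residual log-likelihood at the estimates.
    """

    def __init__(self, model, vc, b, a, a_phenotyped, p, residuals, rss, logL, reml):
        self.model = model
        self.vc = vc
        self.b = b
        self.a = a
        self.a_phenotyped = a_phenotyped
        self.p = p
        self.residuals = residuals
        self.rss = rss
        self.logL = logL
        self.reml = reml

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def aic(self) -> float:
        return information_criteria(self)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self)[1]

    def mean_curve(self, times) -> np.ndarray:
        phi = legendre_matrix(self.spec.nf, times, self.model.domain)
        return phi @ self.b

    def genetic_curves(self, times, ids=None) -> np.ndarray:
        """Predicted additive genetic trajectories a_i(t)."""
        phi = legendre_matrix(self.spec.nr1, times, self.model.domain)
        a = self.a if ids is None else self.a[self.model.pedigree.index_of(ids)]
        return a @ phi.T

    # hooks implemented in sibling modules (kept here so that the results
    # object is the single user-facing surface)
    def scan(self, genotypes, model="fgwas-c", **kw):
        from .scan import scan_fgwas_c, scan_fgwas_f

        fn = {"fgwas-c": scan_fgwas_c, "fgwas-f": scan_fgwas_f}[model]
        return fn(self, genotypes, **kw)

    def accumulated_ebv(self):
        from .baselines import accumulate_ebv

        return accumulate_ebv(self)

    def average_residuals(self):
        from .baselines import average_residuals

        return average_residuals(self)

    def reliabilities(self):
        from .baselines import reliabilities

        return reliabilities(self)

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Random Regression Model (REML)" if self.reml else "Random Regression Model",
            "=" * 46,
            f"records: {self.model.data.n_records}   individuals: {self.model.data.n_individuals}",
            f"orders: mean nf={spec.nf}, additive nr1={spec.nr1}, permanent nr2={spec.nr2}",
            f"logL: {self.logL:.4f}   AIC: {self.aic:.2f}   BIC: {self.bic:.2f}",
            f"sigma_e^2: {self.vc.sigma_e2:.6g}",
            "G (additive coefficient covariance):",
            _fmt_matrix(self.vc.G),
            "P (permanent environmental covariance):",
            _fmt_matrix(self.vc.P),
            "mean curve coefficients b:",
            "  " + "  ".join(f"{v:.6g}" for v in self.b),
        ]
        return "\n".join(lines)


def _fmt_matrix(M) -> str:
    return "\n".join("  " + "  ".join(f"{v:12.6g}" for v in row) for row in np.atleast_2d(M))


def information_criteria(fit: RRMResults) -> tuple:
    """AIC and BIC from the residual log-likelihood.

    k counts the free variance parameters only (the REML convention):
    k = (nr1+1)(nr1+2)/2 + (nr2+1)(nr2+2)/2 + 1.
    """
    k = fit.spec.n_variance_params()
    m = fit.model.data.n_records
    aic = -2.0 * fit.logL + 2.0 * k
    bic = -2.0 * fit.logL + k * np.log(m)
    return float(aic), float(bic)


def select_orders(
    data: LongitudinalData,
    pedigree: Pedigree | None,
    grid: list,
    domain: TimeDomain | None = None,
) -> tuple:
    """Fit every spec in the grid by REML and pick the smallest BIC.

    Ties (within 1e-6) break toward the model with fewer variance
    parameters.  Specs that fail to converge are skipped with a warning;
    if all fail a ConvergenceError is raised.  Returns (best_spec, table).
    """
    if not grid:
        raise ValueError("empty model grid")
    rows = []
    for spec in grid:
        try:
            res = RandomRegressionModel(data, spec, pedigree, domain).fit()
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"spec {spec} skipped: {exc}")
            continue
        rows.append({
            "nf": spec.nf, "nr1": spec.nr1, "nr2": spec.nr2,
            "k": spec.n_variance_params(), "logL": res.logL,
            "aic": res.aic, "bic": res.bic,
        })
    if not rows:
        raise ConvergenceError("no model in the grid converged")
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    cand = table[table["bic"] <= best_bic + 1e-6].sort_values(["k", "bic"])
    row = cand.iloc[0]
    return ModelSpec(int(row["nf"]), int(row["nr1"]), int(row["nr2"])), table
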