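"""Shared fixtures: tiny simulated datasets and a dense GLS/BLUP oracle."""

import numpy as np
import pytest

from longgwas.basis import TimeDomain, legendre_matrix
from longgwas.model import ModelSpec, RandomRegressionModel, VarianceComponents
from longgwas.pedigree import numerator_relationship_matrix
from longgwas.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-scale config small enough for oracle comparisons."""
    return SimConfig.desk(
        40, n_snps=12, n_background=10, n_historical_generations=5
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return simulate_dataset(tiny_cfg, seed=11)


@pytest.fixture(scope="session")
def small_cfg():
    """Mid-size config for statistical checks (fast REML)."""
    return SimConfig.desk(200, n_snps=52, n_background=50,
                          n_historical_generations=20)


class DenseOracle:
    """Brute-force GLS/BLUP on the explicit covariance matrix V.

    Builds V = Q (A_pp (x) G) Q' + Z (I (x) P) Z' + I sigma_e^2 over the
    phenotyped individuals and solves everything densely.  Only feasible at
    tiny n; used as the independent reference for the MME and kernel paths.
    """

    def __init__(self, data, spec, domain, pedigree, vc):
        self.data, self.spec, self.domain, self.vc = data, spec, domain, vc
        ids = data.individuals
        n, m = len(ids), data.n_records
        pos = {v: i for i, v in enumerate(ids)}
        phi_a = legendre_matrix(spec.nr1, data.times, domain)
        phi_p = legendre_matrix(spec.nr2, data.times, domain)
        Q = np.zeros((m, n * spec.k1))
        Z = np.zeros((m, n * spec.k2))
        for r, v in enumerate(data.ids):
            i = pos[v]
            Q[r, i * spec.k1:(i + 1) * spec.k1] = phi_a[r]
            Z[r, i * spec.k2:(i + 1) * spec.k2] = phi_p[r]
        if pedigree is not None:
            A = numerator_relationship_matrix(pedigree)
            idx = pedigree.index_of(ids)
            App = A[np.ix_(idx, idx)]
        else:
            App = np.eye(n)
        self.App, self.Q, self.Z = App, Q, Z
        self.Gfull = np.kron(App, vc.G)
        self.V = (Q @ self.Gfull @ Q.T + Z @ np.kron(np.eye(n), vc.P) @ Z.T
                  + vc.sigma_e2 * np.eye(m))
        self.Vi = np.linalg.inv(self.V)

    def gls(self, X):
        """Returns (beta, cov_beta, rss, logL) for fixed design X."""
        y = self.data.values
        XVX = X.T @ self.Vi @ X
        beta = np.linalg.solve(XVX, X.T @ self.Vi @ y)
        cov = np.linalg.inv(XVX)
        r = y - X @ beta
        yPy = float(r @ self.Vi @ r)
        rss = float(y @ y) - self.vc.sigma_e2 * yPy
        m, p = X.shape
        logL = -0.5 * (
            (m - p) * np.log(2 * np.pi)
            + np.linalg.slogdet(self.V)[1]
            + np.linalg.slogdet(XVX)[1]
            + yPy
        )
        return beta, cov, rss, logL

    def blup(self, X):
        beta, *_ = self.gls(X)
        r = self.data.values - X @ beta
        a = (self.Gfull @ self.Q.T @ self.Vi @ r).reshape(-1, self.spec.k1)
        n = len(self.data.individuals)
        p = (np.kron(np.eye(n), self.vc.P) @ self.Z.T @ self.Vi @ r).reshape(
            -1, self.spec.k2
        )
        return beta, a, p


@pytest.fixture
def dense_oracle():
    return DenseOracle


@pytest.fixture(scope="session")
def example_vc():
    return VarianceComponents(
        np.array([[2.0, 0.2], [0.2, 1.0]]),
        np.array([[1.5, -0.1], [-0.1, 0.8]]),
        3.0,
    )
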