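"""Time-varied SNP scans: Wald statistics, decomposition, cumulative effects."""

import numpy as np
import pytest
from scipy import stats

from longgwas.basis import TimeDomain, legendre_matrix
from longgwas.data import GenotypeMatrix
from longgwas.model import ModelSpec, RandomRegressionModel
from longgwas.scan import (SnpEffectCurves, accumulation_vector,
                           cumulative_effect, decompose_fgwas_f,
                           wald_incremental)


class TestWaldIncremental:
    def test_no_improvement(self):
        W, p = wald_incremental(10.0, 10.0, 2.0, 3)
        assert W == 0.0 and p == 1.0

    def test_chi2_quantile_df1(self):
        W, p = wald_incremental(3.841459, 0.0, 1.0, 1)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_chi2_survival_df4(self):
        W, p = wald_incremental(10.0, 0.0, 1.0, 4)
        assert p == pytest.approx(0.040428, abs=1e-6)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            wald_incremental(1.0, 0.0, 1.0, 0)

    def test_small_negative_clipped(self):
        with pytest.warns(UserWarning):
            W, p = wald_incremental(0.0, 1.0, 1.0, 2)
        assert W == 0.0 and p == 1.0


class TestCumulativeEffect:
    dom = TimeDomain(0.0, 9.0)  # 10 integer grid points

    def test_constant_curve(self):
        # order-0 coefficient c gives height c*sqrt(1/2) at every point
        c = 4.0
        expected = c * np.sqrt(0.5) * 10
        assert cumulative_effect([c], self.dom) == pytest.approx(expected)

    def test_odd_component_cancels_on_symmetric_grid(self):
        val = cumulative_effect([0.0, 5.0], self.dom)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_matches_pointwise_loop(self):
        rng = np.random.default_rng(3)
        coefs = rng.normal(size=4)
        total = 0.0
        for t in self.dom.grid:
            total += float(legendre_matrix(3, [float(t)], self.dom)[0] @ coefs)
        assert cumulative_effect(coefs, self.dom) == pytest.approx(total)

    def test_accumulation_vector_is_row_sum(self):
        qc = accumulation_vector(2, self.dom)
        phi = legendre_matrix(2, self.dom.grid.astype(float), self.dom)
        np.testing.assert_allclose(qc, phi.sum(axis=0))


class TestDecomposition:
    dom = TimeDomain(0.0, 4.0)

    def curves_from_values(self, aa, Aa, AA):
        """Build class curves whose order-0 value is constant per class."""
        c = 1 / np.sqrt(0.5)
        return SnpEffectCurves(0, self.dom, lambdas={
            0: np.array([aa * c]), 1: np.array([Aa * c]), 2: np.array([AA * c]),
        })

    def test_symmetric_homozygotes(self):
        curves = self.curves_from_values(-2.0, 0.0, 2.0)
        add, dom, var = decompose_fgwas_f(curves, 0.3, self.dom)
        np.testing.assert_allclose(add, 2.0)
        np.testing.assert_allclose(dom, 0.0, atol=1e-12)

    def test_variance_at_half_frequency(self):
        curves = self.curves_from_values(-1.0, 0.7, 1.0)
        add, dom, var = decompose_fgwas_f(curves, 0.5, self.dom)
        # q - p = 0 kills the dominance term: var = 2*0.25*add^2
        np.testing.assert_allclose(var, 0.5 * add**2)

    def test_literal_formula_on_random_curves(self):
        rng = np.random.default_rng(9)
        lam = {g: rng.normal(size=3) for g in (0, 1, 2)}
        curves = SnpEffectCurves(2, self.dom, lambdas=lam)
        p = 0.37
        add, dom, var = decompose_fgwas_f(curves, p, self.dom)
        t = self.dom.grid.astype(float)
        phi = legendre_matrix(2, t, self.dom)
        s_aa, s_Aa, s_AA = (phi @ lam[g] for g in (0, 1, 2))
        add2 = (s_AA - s_aa) / 2
        dom2 = s_Aa - (s_AA + s_aa) / 2
        q = 1 - p
        var2 = 2 * p * q * (add2 + dom2 * (q - p)) ** 2
        np.testing.assert_allclose(add, add2, atol=1e-12)
        np.testing.assert_allclose(dom, dom2, atol=1e-12)
        np.testing.assert_allclose(var, var2, atol=1e-12)

    def test_printed_convention_differs_only_by_reference(self):
        # with the low-homozygote curve identically zero (reference coding)
        # the printed and midpoint conventions coincide
        curves = SnpEffectCurves(0, self.dom, lambdas={
            0: np.zeros(1), 1: np.array([1.3]), 2: np.array([2.0]),
        })
        t = self.dom.grid.astype(float)
        np.testing.assert_allclose(
            curves.dom_curve(t, "printed"), curves.dom_curve(t, "midpoint")
        )

    def test_monomorphic_frequency_rejected(self):
        curves = self.curves_from_values(-1, 0, 1)
        with pytest.raises(ValueError):
            decompose_fgwas_f(curves, 1.0, self.dom)


def _geno(ids, rows, snp_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    snp_ids = snp_ids or [f"s{i}" for i in range(rows.shape[0])]
    return GenotypeMatrix(np.asarray(snp_ids, dtype=object),
                          np.asarray(ids, dtype=object), rows)


@pytest.fixture(scope="module")
def fitted(tiny_dataset, tiny_cfg):
    ped, gm, data, truth = tiny_dataset
    model = RandomRegressionModel(data, ModelSpec(2, 1, 1), ped, tiny_cfg.domain)
    return model.fit(), gm


class TestScans:
    def test_monomorphic_untestable(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        g = _geno(ids, np.ones(len(ids)))
        tab = res.scan(g, model="fgwas-c").table
        assert tab.loc[0, "W"] == 0.0 and tab.loc[0, "p"] == 1.0
        assert not tab.loc[0, "testable"]

    def test_dosage_accepted_by_c(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        rng = np.random.default_rng(1)
        g = _geno(ids, rng.uniform(0, 2, len(ids)))
        tab = res.scan(g, model="fgwas-c").table
        assert np.isfinite(tab.loc[0, "W"]) and tab.loc[0, "testable"]
        assert tab.loc[0, "df"] == res.spec.nf + 1

    def test_dosage_rejected_by_f(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        rng = np.random.default_rng(1)
        g = _geno(ids, rng.uniform(0, 2, len(ids)))
        with pytest.raises(ValueError, match="fGWAS-C"):
            res.scan(g, model="fgwas-f")

    def test_scale_invariance_of_wald(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, len(ids)).astype(float)
        t1 = res.scan(_geno(ids, x), model="fgwas-c").table
        t2 = res.scan(_geno(ids, x / 2.0), model="fgwas-c").table
        assert t1.loc[0, "W"] == pytest.approx(t2.loc[0, "W"], rel=1e-8)

    def test_two_class_snp_df(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        rng = np.random.default_rng(3)
        x = rng.choice([0.0, 2.0], len(ids))
        tab = res.scan(_geno(ids, x), model="fgwas-f").table
        assert tab.loc[0, "df"] == res.spec.nf + 1

    def test_three_class_snp_df(self, fitted):
        res, gm = fitted
        tab = res.scan(gm, model="fgwas-f").table
        row = tab[tab["snp"] == "QTN"].iloc[0]
        if row["testable"] and row["df"] > 0:
            assert row["df"] in (res.spec.nf + 1, 2 * (res.spec.nf + 1))

    def test_missing_calls_dropped_for_f(self, fitted):
        res, gm = fitted
        ids = res.model.data.individuals
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, len(ids)).astype(float)
        x[:3] = np.nan
        tab = res.scan(_geno(ids, x), model="fgwas-f").table
        assert np.isfinite(tab.loc[0, "W"]) and tab.loc[0, "p"] <= 1.0

    def test_wald_matches_dense_oracle_orders_zero(self, tiny_dataset, tiny_cfg,
                                                   dense_oracle, example_vc):
        """With all orders 0 the scan is a single-coefficient mixed-model
        association; W must equal the squared effect over its GLS sampling
        variance computed from the dense covariance matrix."""
        from longgwas.model import VarianceComponents

        ped, gm, data, truth = tiny_dataset
        spec = ModelSpec(0, 0, 0)
        vc = VarianceComponents([[2.0]], [[1.5]], 3.0)
        model = RandomRegressionModel(data, spec, ped, tiny_cfg.domain)
        res = model.fit_given(vc)
        tab = res.scan(gm, model="fgwas-c").table

        oracle = dense_oracle(data, spec, tiny_cfg.domain, ped, vc)
        ids = data.individuals
        pos = {v: i for i, v in enumerate(ids)}
        xsub = gm.subset_individuals(ids)
        phi = legendre_matrix(0, data.times, tiny_cfg.domain)
        for s in range(2):
            xcol = np.array([xsub.values[s][pos[v]] for v in data.ids])
            X = np.column_stack([phi, xcol * phi[:, 0]])
            beta, cov, *_ = oracle.gls(X)
            W_oracle = beta[1] ** 2 / cov[1, 1]
            assert tab.loc[s, "W"] == pytest.approx(W_oracle, abs=1e-6)

    def test_fgwas_f_dominance_near_zero_for_additive_qtn(self, small_cfg):
        """The simulated QTN is purely additive, so the fGWAS-F cumulative
        dominance estimate should be centred at zero."""
        import warnings

        from longgwas.simulate import simulate_dataset

        doms, cums = [], []
        for seed in range(61, 67):
            ped, gm, data, truth = simulate_dataset(small_cfg, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = RandomRegressionModel(data, ModelSpec(2, 2, 2), ped,
                                            small_cfg.domain).fit()
            tab = res.scan(gm, model="fgwas-f").table
            doms.append(tab.loc[0, "cumulative_dom"])
            cums.append(tab.loc[0, "cumulative_add"])
        doms = np.asarray(doms)
        se = doms.std(ddof=1) / np.sqrt(len(doms))
        assert abs(doms.mean()) < 3 * se

    def test_c_and_f_pvalues_agree(self, fitted):
        res, gm = fitted
        tc = res.scan(gm, model="fgwas-c").table
        tf = res.scan(gm, model="fgwas-f").table
        # same ordering of evidence on the same SNPs
        assert (tc.loc[0, "p"] < tc.loc[1, "p"]) == (tf.loc[0, "p"] < tf.loc[1, "p"])
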