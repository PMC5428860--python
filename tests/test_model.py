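"""Design assembly, MME solving, REML estimation and model selection."""

import warnings

import numpy as np
import pytest

from longgwas.basis import TimeDomain, legendre_matrix
from longgwas.data import LongitudinalData
from longgwas.model import (ModelSpec, RandomRegressionModel, VarianceComponents,
                            build_design, information_criteria, select_orders,
                            solve_mme)
from longgwas.pedigree import Pedigree, a_inverse


def make_data(n, times, seed=0, ids=None):
    rng = np.random.default_rng(seed)
    ids = ids if ids is not None else [f"i{k}" for k in range(n)]
    rid = np.repeat(np.asarray(ids, dtype=object), len(times))
    t = np.tile(times, n)
    y = rng.normal(size=len(rid))
    return LongitudinalData(rid, t, y)


class TestBuildDesign:
    def test_orders_zero_single_record(self):
        data = LongitudinalData(np.array(["a"], dtype=object), [3.0], [1.0])
        dom = TimeDomain(0, 10)
        ds = build_design(data, ModelSpec(0, 0, 0), dom)
        for M in (ds.X, ds.Q.toarray(), ds.Z.toarray()):
            np.testing.assert_allclose(np.asarray(M), [[np.sqrt(0.5)]])

    def test_q_block_diagonal(self):
        data = make_data(2, [1.0, 5.0, 9.0])
        ds = build_design(data, ModelSpec(1, 1, 1), TimeDomain(0, 10))
        Q = ds.Q.toarray()
        assert np.all(Q[:3, 2:] == 0) and np.all(Q[3:, :2] == 0)

    def test_x_matches_basis_matrix(self):
        times = [0.0, 2.0, 4.0, 6.0, 8.0]
        data = make_data(1, times)
        dom = TimeDomain(0, 10)
        ds = build_design(data, ModelSpec(2, 0, 0), dom)
        assert ds.X.shape == (5, 3)
        np.testing.assert_allclose(ds.X, legendre_matrix(2, times, dom))

    def test_record_outside_domain(self):
        data = make_data(1, [1.0, 20.0])
        with pytest.raises(ValueError, match="outside domain"):
            build_design(data, ModelSpec(0, 0, 0), TimeDomain(0, 10))

    def test_identifiability_guard(self):
        data = make_data(3, [1.0, 2.0])
        with pytest.raises(ValueError, match="identifiable"):
            ModelSpec(0, 2, 0).validate_against(data)


class TestSolveMME:
    def test_matches_dense_oracle_unbalanced(self, dense_oracle, example_vc):
        # 3 individuals with different record counts exercise the general path
        rng = np.random.default_rng(5)
        ids = np.array(["a"] * 2 + ["b"] * 5 + ["c"] * 3, dtype=object)
        times = np.concatenate([[1, 9], [1, 3, 5, 7, 9], [2, 5, 8]]).astype(float)
        data = LongitudinalData(ids, times, rng.normal(size=10))
        dom = TimeDomain(0, 10)
        spec = ModelSpec(1, 1, 1)
        ped = Pedigree.from_records(
            [("a", None, None), ("b", None, None), ("c", "a", "b")]
        )
        ds = build_design(data, spec, dom, ped.ids)
        fit = solve_mme(ds, example_vc, a_inverse(ped), spec)
        oracle = dense_oracle(data, spec, dom, ped, example_vc)
        beta, a, p = oracle.blup(ds.X)
        np.testing.assert_allclose(fit.b, beta, atol=1e-8)
        idx = ped.index_of(data.individuals)
        np.testing.assert_allclose(fit.a[idx], a, atol=1e-8)
        np.testing.assert_allclose(fit.p, p, atol=1e-8)
        _, _, rss, _ = oracle.gls(ds.X)
        assert fit.rss == pytest.approx(rss, abs=1e-7)

    def test_ols_limit_with_huge_priors(self):
        data = make_data(4, [1.0, 4.0, 7.0, 10.0], seed=1)
        dom = TimeDomain(0, 10)
        spec = ModelSpec(1, 0, 0)
        vc = VarianceComponents(np.array([[1e8]]), np.array([[1e8]]), 1.0)
        ds = build_design(data, spec, dom)
        fit = solve_mme(ds, vc, np.eye(4), spec)
        # with vanishing shrinkage the fit approaches unpenalized least
        # squares on the combined design [X Q Z]
        W = np.column_stack([ds.X, ds.Q.toarray(), ds.Z.toarray()])
        proj = W @ np.linalg.lstsq(W, data.values, rcond=None)[0]
        np.testing.assert_allclose(data.values - fit.residuals, proj, atol=1e-5)

    def test_normal_equations_satisfied(self, example_vc):
        data = make_data(5, [0.0, 2.5, 5.0, 7.5, 10.0], seed=2)
        dom = TimeDomain(0, 10)
        spec = ModelSpec(2, 1, 1)
        ds = build_design(data, spec, dom)
        fit = solve_mme(ds, example_vc, np.eye(5), spec)
        # first-order condition for the fixed block: X'e = 0 at the solution
        resid = fit.residuals
        np.testing.assert_allclose(ds.X.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_fixed_block(self):
        data = make_data(3, [1.0, 5.0, 9.0], seed=3)
        dom = TimeDomain(0, 10)
        spec = ModelSpec(1, 0, 0)
        dup = np.ones(data.n_records)
        ds = build_design(data, spec, dom, extra_fixed={"c1": dup, "c2": dup})
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            solve_mme(ds, VarianceComponents([[1.0]], [[1.0]], 1.0), np.eye(3), spec)


class TestBalancedKernelEquivalence:
    def test_kernel_equals_mme(self, tiny_dataset, tiny_cfg, example_vc):
        ped, gm, data, truth = tiny_dataset
        spec = ModelSpec(2, 1, 1)
        model = RandomRegressionModel(data, spec, ped, tiny_cfg.domain)
        res = model.fit_given(example_vc)
        ds = build_design(data, spec, tiny_cfg.domain, model.random_ids)
        fit = solve_mme(ds, example_vc, a_inverse(ped), spec)
        np.testing.assert_allclose(res.b, fit.b, atol=1e-8)
        np.testing.assert_allclose(res.a, fit.a, atol=1e-8)
        np.testing.assert_allclose(res.p, fit.p, atol=1e-8)
        assert res.rss == pytest.approx(fit.rss, rel=1e-10)

    def test_kernel_logl_equals_dense(self, tiny_dataset, tiny_cfg, example_vc,
                                      dense_oracle):
        ped, gm, data, truth = tiny_dataset
        spec = ModelSpec(2, 1, 1)
        model = RandomRegressionModel(data, spec, ped, tiny_cfg.domain)
        res = model.fit_given(example_vc)
        oracle = dense_oracle(data, spec, tiny_cfg.domain, ped, example_vc)
        X = legendre_matrix(spec.nf, data.times, tiny_cfg.domain)
        *_, logL = oracle.gls(X)
        assert res.logL == pytest.approx(logL, abs=1e-6)


class TestREML:
    def test_pure_noise_recovers_unit_residual(self):
        rng = np.random.default_rng(42)
        n, T = 250, 8
        times = np.linspace(0, 10, T)
        ids = np.repeat([f"i{k}" for k in range(n)], T).astype(object)
        data = LongitudinalData(ids, np.tile(times, n), rng.normal(size=n * T))
        res = RandomRegressionModel(data, ModelSpec(0, 0, 0)).fit()
        assert res.vc.sigma_e2 == pytest.approx(1.0, abs=0.1)
        assert res.vc.G[0, 0] < 0.1
        assert res.vc.P[0, 0] < 0.1

    def test_logl_improves_on_init(self, small_cfg):
        from longgwas.simulate import simulate_dataset

        ped, gm, data, truth = simulate_dataset(small_cfg, 21)
        model = RandomRegressionModel(data, ModelSpec(2, 1, 1), ped, small_cfg.domain)
        init = VarianceComponents(np.eye(2), np.eye(2), float(np.var(data.values)))
        res = model.fit(init=init)
        logL_init = model.fit_given(init).logL
        assert res.logL >= logL_init - 1e-6

    def test_nested_orders_increase_logl(self, small_cfg):
        from longgwas.simulate import simulate_dataset

        ped, gm, data, truth = simulate_dataset(small_cfg, 22)
        model_small = RandomRegressionModel(data, ModelSpec(2, 0, 1), ped,
                                            small_cfg.domain)
        model_large = RandomRegressionModel(data, ModelSpec(2, 1, 1), ped,
                                            small_cfg.domain)
        assert model_large.fit().logL >= model_small.fit().logL - 1e-4


class TestInformationCriteria:
    def test_formula(self, tiny_dataset, tiny_cfg, example_vc):
        ped, gm, data, truth = tiny_dataset
        model = RandomRegressionModel(data, ModelSpec(2, 1, 1), ped, tiny_cfg.domain)
        res = model.fit_given(example_vc)
        k = 3 + 3 + 1
        m = data.n_records
        aic, bic = information_criteria(res)
        assert aic == pytest.approx(-2 * res.logL + 2 * k)
        assert bic == pytest.approx(-2 * res.logL + k * np.log(m))

    def test_parameter_count(self):
        assert ModelSpec(1, 3, 5).n_variance_params() == 10 + 21 + 1

    def test_hand_example(self):
        # logL = -100, k = 4, m = 1000
        assert -2 * (-100.0) + 2 * 4 == pytest.approx(208.0)
        assert -2 * (-100.0) + 4 * np.log(1000) == pytest.approx(227.6310, abs=1e-3)


class TestSelectOrders:
    def test_single_spec_grid(self, tiny_dataset, tiny_cfg):
        ped, gm, data, truth = tiny_dataset
        spec, table = select_orders(data, ped, [ModelSpec(1, 1, 1)],
                                    tiny_cfg.domain)
        assert spec == ModelSpec(1, 1, 1)
        assert len(table) == 1

    def test_tie_breaks_to_fewer_parameters(self, monkeypatch, tiny_dataset,
                                            tiny_cfg):
        ped, gm, data, truth = tiny_dataset
        import longgwas.model as M

        class FakeRes:
            logL = -100.0
            aic = 1.0
            bic = 1.0

        def fake_fit(self, *a, **k):
            r = FakeRes()
            r.aic, r.bic = 200.0, 200.0
            return r

        monkeypatch.setattr(M.RandomRegressionModel, "fit", fake_fit)
        spec, _ = select_orders(data, ped, [ModelSpec(2, 2, 2), ModelSpec(1, 1, 1)],
                                tiny_cfg.domain)
        assert spec == ModelSpec(1, 1, 1)

    def test_recovers_quadratic_genetic_order(self):
        """Data generated with quadratic genetic curves should mostly select
        an additive order of at least 2."""
        from longgwas.simulate import SimConfig, simulate_dataset

        cfg = SimConfig.desk(300, n_snps=52, n_background=50,
                             n_historical_generations=20,
                             polygenic_profile=(0.5, 0.5, 1.0))
        hits = 0
        grid = [ModelSpec(2, 0, 2), ModelSpec(2, 1, 2), ModelSpec(2, 2, 2)]
        for seed in [31, 32, 33, 34, 35]:
            ped, gm, data, truth = simulate_dataset(cfg, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec, _ = select_orders(data, ped, grid, cfg.domain)
            hits += spec.nr1 >= 2
        assert hits >= 4
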