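"""Screening, ridge/GCV against a dense-algebra oracle, projection
contracts, adaptive-LASSO closed forms, and the 2SLS equivalence of the
full per-gene fit."""

import numpy as np
import pytest

from ivgrn import FitConfig, fit_network, simulate_dataset
from ivgrn.iv_discovery import IvInstrument, IvMap
from ivgrn.synthetic_data import (
    make_gene_annotation,
    simulate_expression,
    simulate_genotypes,
    simulate_network,
)
from ivgrn.twostage import (
    adaptive_lasso,
    fit_gene,
    isis_screen,
    make_projection,
    ridge_gcv,
    stage1_predict,
)


def _true_ivmap(params, X):
    """IvMap wired directly from the planted cis assignment."""
    ivmap = IvMap()
    for g, cols in params.iv_assignment.items():
        ivmap.entries[g] = [
            IvInstrument(
                name=f"v{j}", column=X[:, j], members=[int(j)],
                stratum="common", p_value=0.0, position=int(j),
            )
            for j in cols
        ]
    return ivmap


class TestIsisScreen:
    def test_perfect_column_ranked_first(self, rng):
        pool = rng.normal(size=(100, 10))
        kept = isis_screen(pool[:, 3], pool, target_size=1)
        assert kept.tolist() == [3]

    def test_small_pool_returned_whole(self, rng):
        pool = rng.normal(size=(50, 5))
        assert isis_screen(rng.normal(size=50), pool, 10).tolist() == list(range(5))

    def test_iteration_recovers_masked_predictor(self, rng):
        # classic construction: x2 = w - x1 and y = x1 + 0.5*x2 makes
        # cov(y, x2) = 0, so one-pass marginal screening cannot see x2;
        # after x1 enters and the residual is formed, x2 dominates
        n = 2000
        x1 = rng.normal(size=n)
        w = rng.normal(size=n)
        x2 = w - x1
        y = x1 + 0.5 * x2 + 0.01 * rng.normal(size=n)
        decoys = rng.normal(size=(n, 20))
        pool = np.column_stack([x1, x2, decoys])
        one_pass = isis_screen(y, pool, target_size=2, batch=2, max_iter=1)
        iterative = isis_screen(y, pool, target_size=2, batch=1)
        assert 1 not in one_pass
        assert iterative.tolist() == [0, 1]


class TestRidgeGcv:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        fit = ridge_gcv(y, X, lambda_grid=np.array([0.0]))
        D = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(fit.coef, beta[1:], atol=1e-8)

    def test_heavy_shrinkage_limit(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fit = ridge_gcv(y, X, lambda_grid=np.array([1e12]))
        assert np.max(np.abs(fit.coef)) < 1e-6
        assert np.allclose(fit.fitted, y.mean(), atol=1e-6)

    def test_gcv_curve_matches_dense_oracle(self, rng):
        # oracle: explicit smoother S = Xc (Xc'Xc + lam I)^-1 Xc'
        n, m = 50, 10
        X = rng.normal(size=(n, m))
        y = rng.normal(size=n)
        grid = np.geomspace(0.1, 100, 8)
        fit = ridge_gcv(y, X, lambda_grid=grid)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        for lam in grid:
            S = Xc @ np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T)
            rss = float(((yc - S @ yc) ** 2).sum())
            df = 1.0 + float(np.trace(S))
            assert fit.gcv[float(lam)] == pytest.approx(
                n * rss / (n - df) ** 2, rel=1e-8
            )

    def test_selects_grid_minimizer(self, rng):
        X = rng.normal(size=(60, 8))
        y = X[:, 0] + rng.normal(size=60)
        fit = ridge_gcv(y, X)
        assert fit.lam == min(fit.gcv, key=lambda k: (fit.gcv[k], k))


class TestProjection:
    def test_contracts_on_random_block(self, rng):
        X = rng.normal(size=(50, 4))
        H = make_projection(X)
        # annihilation
        assert np.max(np.abs(H.apply(X))) < 1e-8
        v = rng.normal(size=50)
        # idempotence and symmetry (via inner products)
        assert np.allclose(H.apply(H.apply(v)), H.apply(v), atol=1e-10)
        u = rng.normal(size=50)
        assert u @ H.apply(v) == pytest.approx(H.apply(u) @ v)

    def test_empty_block_is_identity(self, rng):
        H = make_projection(None)
        v = rng.normal(size=20)
        assert np.array_equal(H.apply(v), v)
        assert H.rank == 0

    def test_collinear_columns_pruned(self, rng):
        x = rng.normal(size=(30, 1))
        H = make_projection(np.hstack([x, 2 * x, x + 1e-14]))
        assert H.rank == 1
        assert np.max(np.abs(H.apply(x))) < 1e-8


class TestAdaptiveLasso:
    def test_sparse_support_recovery(self):
        hits = 0
        n_trials = 60
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 50))
            beta = np.zeros(50)
            beta[[7, 23]] = 1.0
            y = X @ beta + 0.5 * rng.normal(size=300)
            coef = adaptive_lasso(y, X, FitConfig(seed=seed))
            if set(np.nonzero(coef)[0]) == {7, 23}:
                hits += 1
        assert hits >= 0.95 * n_trials

    def test_null_response_stays_empty(self):
        fps = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 1000)
            X = rng.normal(size=(200, 30))
            y = rng.normal(size=200)
            fps.append(np.count_nonzero(adaptive_lasso(y, X, FitConfig(seed=seed))))
        assert np.median(fps) <= 1

    def test_orthogonal_design_soft_threshold_closed_form(self, rng):
        # with exactly orthogonal standardized columns the weighted problem
        # decouples: alpha_j = soft(c_j, n*lam) / g_j on the weighted design
        n, m = 64, 4
        raw = np.column_stack([np.ones(n), rng.normal(size=(n, m))])
        Q, _ = np.linalg.qr(raw)
        X = Q[:, 1:] * np.sqrt(n)  # mean 0, sd 1, mutually orthogonal exactly
        y = X @ np.array([1.0, -0.5, 0.0, 0.2]) + 0.1 * rng.normal(size=n)
        lam = 0.05
        cfg = FitConfig(lasso_lambda=lam)
        coef = adaptive_lasso(y, X, cfg)
        yc = y - y.mean()
        init = ridge_gcv(yc, X).coef
        expected = np.zeros(m)
        for j in range(m):
            if abs(init[j]) < 1e-10:
                continue
            xw = X[:, j] * abs(init[j])
            g = xw @ xw
            c = xw @ yc
            a = np.sign(c) * max(abs(c) - n * lam, 0.0) / g
            expected[j] = a * abs(init[j])
        assert np.allclose(coef, expected, atol=1e-5)

    def test_lambda_zero_is_weighted_ols(self, rng):
        X = rng.normal(size=(80, 3))
        y = X @ np.array([0.5, -1.0, 0.2]) + 0.1 * rng.normal(size=80)
        coef = adaptive_lasso(y, X, FitConfig(lasso_lambda=0.0))
        D = np.column_stack([np.ones(80), X])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.allclose(coef, beta[1:], atol=1e-8)


class TestStage1:
    def test_null_network_prediction_near_oracle(self):
        # Gamma = 0: expression = X Psi + eps; on a held-out half, the
        # ridge prediction trained on the other half must come within 0.1
        # of the realized-signal (best possible) R^2
        rng = np.random.default_rng(0)
        p, n = 8, 1200
        params = simulate_network(
            p, n_edges=0, reciprocal_pairs=0, seed=1, cis_effect_range=(0.8, 1.2)
        )
        genes = make_gene_annotation(p)
        X, _ = simulate_genotypes(
            n, rng.uniform(0.2, 0.4, params.variant_count), seed=2,
            gene_annotation=genes, iv_assignment=params.iv_assignment,
        )
        Y, _ = simulate_expression(params, X, seed=3)
        half = n // 2
        signal = X @ params.psi
        for j in range(p):
            # refit the same screened ridge on the train half, apply to test
            train_fit = ridge_gcv(Y[:half, j], X[:half])
            pred_test = X[half:] @ train_fit.coef + train_fit.intercept
            y_test = Y[half:, j]
            var = np.var(y_test)
            r2_fit = 1 - np.var(y_test - pred_test) / var
            r2_oracle = 1 - np.var(y_test - signal[half:, j]) / var
            assert r2_fit >= r2_oracle - 0.1

    def test_prediction_in_span_of_screened_ivs(self, benchmark_dataset,
                                                benchmark_ivmap, benchmark_stage1):
        ds, ivmap, s1 = benchmark_dataset, benchmark_ivmap, benchmark_stage1
        pool, _ = ivmap.pooled_matrix()
        for j in (0, 7, 19):
            cols = pool[:, s1.screened[j]]
            D = np.column_stack([np.ones(len(cols)), cols])
            proj = D @ np.linalg.lstsq(D, s1.predicted[:, j], rcond=None)[0]
            assert np.allclose(proj, s1.predicted[:, j], atol=1e-6)

    def test_worker_count_invariance(self, benchmark_dataset, benchmark_ivmap,
                                     benchmark_stage1):
        fit2 = stage1_predict(
            benchmark_dataset.expression, benchmark_ivmap,
            FitConfig(seed=0, n_jobs=2),
        )
        assert np.array_equal(fit2.predicted, benchmark_stage1.predicted)


class TestFitGene:
    def test_gene_never_its_own_candidate(self, benchmark_dataset,
                                          benchmark_ivmap, benchmark_stage1):
        fit = fit_gene(
            4, benchmark_dataset.expression, benchmark_stage1, benchmark_ivmap,
            FitConfig(seed=0),
        )
        assert 4 not in fit.candidates
        assert fit.gamma[4] == 0

    def test_two_stage_least_squares_equivalence(self):
        # single candidate regulator + lambda -> 0 must reproduce the
        # textbook 2SLS slope exactly
        worst = 0.0
        for seed in range(20):
            n = 300
            params = simulate_network(2, n_edges=1, seed=seed, allow_cycles=False)
            genes = make_gene_annotation(2)
            X, _ = simulate_genotypes(
                n, [0.3] * params.variant_count, seed=seed + 1,
                gene_annotation=genes, iv_assignment=params.iv_assignment,
            )
            Y, _ = simulate_expression(params, X, seed=seed + 2)
            ivmap = _true_ivmap(params, X)
            (r, t), = params.edge_set()
            cfg = FitConfig(ridge_grid=np.array([0.0]), lasso_lambda=0.0, seed=seed)
            s1 = stage1_predict(Y, ivmap, cfg)
            est = fit_gene(t, Y, s1, ivmap, cfg).gamma[r]
            Z = np.column_stack([np.ones(n), X])
            b1, *_ = np.linalg.lstsq(Z, Y[:, r], rcond=None)
            W = np.column_stack([np.ones(n), Z @ b1, X[:, params.iv_assignment[t]]])
            b2, *_ = np.linalg.lstsq(W, Y[:, t], rcond=None)
            worst = max(worst, abs(b2[1] - est))
        assert worst < 1e-6


class TestFitNetwork:
    def test_null_truth_nearly_empty_estimate(self):
        rng = np.random.default_rng(2)
        p, n = 30, 500
        params = simulate_network(p, n_edges=0, reciprocal_pairs=0, seed=3)
        genes = make_gene_annotation(p)
        X, _ = simulate_genotypes(
            n, rng.uniform(0.1, 0.45, params.variant_count), seed=4,
            gene_annotation=genes, iv_assignment=params.iv_assignment,
        )
        Y, _ = simulate_expression(params, X, seed=5)
        C = fit_network(Y, _true_ivmap(params, X), FitConfig(seed=0))
        assert len(C.edge_set()) <= 0.005 * p * (p - 1)

    def test_row_permutation_invariance(self, benchmark_dataset, benchmark_ivmap,
                                        benchmark_network):
        ds = benchmark_dataset
        perm = np.random.default_rng(99).permutation(ds.n_samples)
        ivmap2 = IvMap()
        for g, entry in benchmark_ivmap.entries.items():
            ivmap2.entries[g] = [
                IvInstrument(
                    name=iv.name, column=iv.column[perm], members=iv.members,
                    stratum=iv.stratum, p_value=iv.p_value, position=iv.position,
                )
                for iv in entry
            ]
        C2 = fit_network(ds.expression[perm], ivmap2, FitConfig(seed=0))
        assert C2.edge_set() == benchmark_network.edge_set()

    def test_support_recovery_improves_with_n(self):
        # median edge F1 at n=1200 >= F1 at n=150 over seeds
        def f1(n, seed):
            ds = simulate_dataset(
                n=n, p=10, n_edges=8, reciprocal_pairs=1, seed=seed
            )
            C = fit_network(
                ds.expression, _true_ivmap(ds.truth, ds.genotypes),
                FitConfig(seed=seed),
            )
            est, true = C.edge_set(), ds.truth.edge_set()
            tp = len(est & true)
            prec = tp / max(len(est), 1)
            rec = tp / len(true)
            return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

        small = np.median([f1(150, s) for s in range(3)])
        large = np.median([f1(1200, s) for s in range(3)])
        assert large >= small
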