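"""VIF selection, Hellinger/PCoA, partial RDA, selection, robust regression."""

import numpy as np
import pandas as pd
import pytest

from alpzone import ordination as od


def _frame(arr, prefix="x"):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])],
        index=[f"s{i}" for i in range(arr.shape[0])],
    )


class TestVIF:
    def test_independent_columns_kept_with_unit_vif(self):
        rng = np.random.default_rng(0)
        env = _frame(rng.standard_normal((1000, 2)))
        kept, trace = od.vif_select(env, ["x0", "x1"])
        assert kept == ["x0", "x1"] and trace.empty
        assert (od.vif_values(env, ["x0", "x1"]) < 1.1).all()

    def test_duplicated_column_removed_once(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        env = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)})
        kept, trace = od.vif_select(env, ["a", "b", "c"])
        assert len(trace) == 1 and trace["removed"].iloc[0] in ("a", "b")
        assert "c" in kept and len(kept) == 2
        assert np.isinf(trace["vif"].iloc[0])

    def test_matches_inverse_correlation_oracle(self):
        # VIFs equal the diagonal of the inverse correlation matrix
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(np.array(
            [[1.0, 0.9, 0.9], [0.9, 1.0, 0.9], [0.9, 0.9, 1.0]]
        ))
        env = _frame(rng.standard_normal((200, 3)) @ L.T)
        vifs = od.vif_values(env, ["x0", "x1", "x2"])
        R = np.corrcoef(env.to_numpy(), rowvar=False)
        oracle = np.diag(np.linalg.inv(R))
        assert np.allclose(vifs.to_numpy(), oracle, atol=1e-9)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((120, 3))
        base[:, 1] = base[:, 0] * 0.97 + 0.1 * base[:, 1]
        env = _frame(base)
        kept_a, _ = od.vif_select(env, ["x0", "x1", "x2"])
        kept_b, _ = od.vif_select(env, ["x2", "x1", "x0"])
        assert set(kept_a) == set(kept_b)


class TestHellinger:
    def test_hand_example(self):
        out = od.hellinger(np.array([[9.0, 16.0]]))
        assert np.allclose(out, [[0.6, 0.8]])

    def test_rows_have_unit_norm_and_bounded_distance(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 50, size=(10, 6)).astype(float)
        M[0] += 1  # ensure no zero row
        H = od.hellinger(M + 1)
        assert np.allclose((H**2).sum(axis=1), 1.0)
        d = np.linalg.norm(H[:, None, :] - H[None, :, :], axis=-1)
        assert d.max() <= np.sqrt(2) + 1e-12

    def test_double_application_differs(self):
        M = np.array([[1.0, 3.0], [2.0, 2.0]])
        once = od.hellinger(M)
        twice = od.hellinger(once)
        assert not np.allclose(once, twice)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            od.hellinger(np.array([[1.0, -1.0]]))

    def test_zero_row_warns_and_stays_zero(self):
        with pytest.warns(UserWarning):
            out = od.hellinger(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(out[0], 0.0)


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        pos = np.array([0.0, 1.0, 3.0])
        D = np.abs(pos[:, None] - pos[None, :])
        coords, eigvals = od.pcoa(D)
        axis1 = coords.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(axis1))
        assert np.allclose(np.sort(gaps), [1.0, 2.0], atol=1e-8)
        assert eigvals[1] == pytest.approx(0.0, abs=1e-8)

    def test_identical_points_give_no_positive_axes(self):
        D = np.zeros((4, 4))
        coords, eigvals = od.pcoa(D)
        assert coords.shape[1] == 0 or np.allclose(coords, 0.0)

    def test_matches_pca_oracle_on_euclidean_distances(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        H = od.hellinger(rng.integers(1, 40, size=(8, 5)).astype(float))
        D = np.linalg.norm(H[:, None, :] - H[None, :, :], axis=-1)
        coords, eigvals = od.pcoa(D)
        scores = PCA(n_components=coords.shape[1]).fit_transform(H)
        for j in range(coords.shape[1]):
            c = coords.iloc[:, j].to_numpy()
            assert np.allclose(c, scores[:, j], atol=1e-8) or np.allclose(
                c, -scores[:, j], atol=1e-8
            )

    @pytest.mark.parametrize(
        "D,msg",
        [
            (np.array([[0.0, 1.0], [2.0, 0.0]]), "symmetric"),
            (np.array([[1.0, 1.0], [1.0, 0.0]]), "diagonal"),
        ],
    )
    def test_invalid_matrices_rejected(self, D, msg):
        with pytest.raises(ValueError, match=msg):
            od.pcoa(D)


def _random_instance(seed, n=6, p=4, m=2):
    rng = np.random.default_rng(seed)
    Y = _frame(rng.standard_normal((n, p)), prefix="m")
    env = _frame(rng.standard_normal((n, m)))
    return Y, env


class TestRDA:
    def test_exact_linear_community_has_unit_r2(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        Y = _frame(np.outer(x, [1.0, -2.0, 0.5]), prefix="m")
        env = pd.DataFrame({"x0": x}, index=Y.index)
        res = od.rda(Y, env, ["x0"], condition=(), n_perm=0)
        assert res.constrained_R2 == pytest.approx(1.0)

    def test_noise_community_has_near_zero_adjusted_r2(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            Y = _frame(rng.standard_normal((50, 5)), prefix="m")
            env = _frame(rng.standard_normal((50, 2)))
            res = od.rda(Y, env, ["x0", "x1"], condition=(), n_perm=0)
            vals.append(res.adjusted_R2)
        assert abs(np.mean(vals)) < 0.05

    def test_matches_brute_force_least_squares_oracle(self):
        # 6 samples x 4 MOTUs x 2 predictors, no conditioning
        Y, env = _random_instance(5)
        res = od.rda(Y, env, ["x0", "x1"], condition=(), n_perm=0)
        # oracle: explicit hat-matrix multivariate regression + eigh
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        X = env.to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        F = H @ Yc
        eig = np.linalg.eigvalsh(F.T @ F / (len(Y) - 1))[::-1]
        n_pos = (eig > 1e-10).sum()
        assert np.allclose(res.eigenvalues[:n_pos], eig[:n_pos], atol=1e-10)
        # fitted values from scores: axes @ axes^+ reproduces F's column space
        r2_oracle = (F**2).sum() / (Yc**2).sum()
        assert res.constrained_R2 == pytest.approx(r2_oracle, abs=1e-12)
        recon = res.axes.to_numpy()
        assert np.allclose(recon @ recon.T, F @ F.T, atol=1e-8)

    def test_eigenvalue_sum_equals_fitted_variance(self):
        Y, env = _random_instance(6, n=12, p=5, m=3)
        res = od.rda(Y, env, ["x0", "x1", "x2"], condition=(), n_perm=0)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        assert res.eigenvalues.sum() == pytest.approx(
            res.constrained_R2 * (Yc**2).sum() / (len(Y) - 1)
        )

    def test_conditioned_variable_is_aliased(self):
        rng = np.random.default_rng(7)
        site = np.repeat(["A", "B", "C"], 4)
        env = pd.DataFrame(
            {
                "Site": site,
                # constant within site -> aliased once Site is conditioned out
                "x0": np.repeat([1.0, 2.0, 3.0], 4),
                "x1": rng.standard_normal(12),
            },
            index=[f"s{i}" for i in range(12)],
        )
        Y = _frame(rng.standard_normal((12, 3)), prefix="m")
        with pytest.raises(ValueError, match="aliased.*x0"):
            od.rda(Y, env, ["x0", "x1"], condition=("Site",), n_perm=0)

    def test_partial_rda_removes_condition_signal(self):
        # community driven entirely by Site: conditioning absorbs it
        rng = np.random.default_rng(8)
        site = np.repeat(["A", "B"], 10)
        base = np.where(site == "A", 1.0, -1.0)
        Y = _frame(np.outer(base, [1, 2, 3]) + 0.01 * rng.standard_normal((20, 3)), "m")
        env = pd.DataFrame(
            {"Site": site, "x0": rng.standard_normal(20)}, index=Y.index
        )
        res = od.rda(Y, env, ["x0"], condition=("Site",), n_perm=99, seed=0)
        assert res.constrained_R2 < 0.2
        # the Site signal itself is absorbed: fitted variance after
        # conditioning is a tiny fraction of the raw community variance
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        assert res.eigenvalues.sum() * (len(Y) - 1) < 0.01 * (Yc**2).sum()


class TestStepwise:
    def _dataset(self, seed, effect=2.0, n=60, noise_vars=3):
        rng = np.random.default_rng(seed)
        env = _frame(rng.standard_normal((n, 1 + noise_vars)))
        signal = env["x0"].to_numpy()
        Y = _frame(
            np.outer(signal * effect, [1.0, -1.0, 0.5, 0.2]) + rng.standard_normal((n, 4)),
            prefix="m",
        )
        return Y, env

    def test_true_variable_found_in_seeded_runs(self):
        hits = 0
        runs = 15
        for seed in range(runs):
            Y, env = self._dataset(seed)
            sel, _ = od.stepwise_select(
                Y, env, list(env.columns), condition=(), n_perm=99, seed=seed
            )
            hits += "x0" in sel
        assert hits >= 13  # >= ~95% with binomial slack at 15 runs

    def test_all_noise_mostly_selects_nothing(self):
        # two independent noise candidates: family-wise add rate ~ 1-(1-a)^2,
        # so >= 90% empty; assert with binomial slack over 30 runs
        empty = 0
        runs = 30
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            Y = _frame(rng.standard_normal((40, 4)), prefix="m")
            env = _frame(rng.standard_normal((40, 2)))
            sel, _ = od.stepwise_select(
                Y, env, ["x0", "x1"], condition=(), n_perm=99, seed=seed
            )
            empty += not sel
        assert empty >= 24

    def test_single_perfect_predictor_selected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        Y = _frame(np.outer(x, [1.0, 2.0]), prefix="m")
        env = pd.DataFrame({"x0": x}, index=Y.index)
        sel, trace = od.stepwise_select(Y, env, ["x0"], condition=(), n_perm=199, seed=0)
        assert sel == ["x0"]


class TestVariancePartition:
    def test_orthogonal_predictors_partials_match_construction(self):
        rng = np.random.default_rng(3)
        n = 400
        x0, x1 = rng.standard_normal(n), rng.standard_normal(n)
        # community variance: ~50% from x0, ~25% from x1, rest noise
        Y = _frame(
            np.column_stack(
                [
                    np.sqrt(2.0) * x0 + 0.1 * rng.standard_normal(n),
                    x1 + 0.1 * rng.standard_normal(n),
                    rng.standard_normal(n),
                ]
            ),
            prefix="m",
        )
        env = pd.DataFrame({"x0": x0, "x1": x1}, index=Y.index)
        parts = od.variance_partition(Y, env, ["x0", "x1"], condition=())
        var_tot = Y.to_numpy().var(axis=0, ddof=0).sum()
        expect0 = 2.0 / var_tot
        expect1 = 1.0 / var_tot
        assert parts["x0"] == pytest.approx(expect0, abs=0.02)
        assert parts["x1"] == pytest.approx(expect1, abs=0.02)

    def test_near_duplicate_variable_has_zero_partial(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        env = pd.DataFrame(
            {"x0": x, "dup": x + 1e-3 * rng.standard_normal(50)},
            index=[f"s{i}" for i in range(50)],
        )
        Y = _frame(np.outer(x, [1.0, -1.0]) + 0.1 * rng.standard_normal((50, 2)), "m")
        parts = od.variance_partition(Y, env, ["x0", "dup"], condition=())
        assert abs(parts["dup"]) < 0.01

    def test_single_predictor_partial_equals_global(self):
        Y, env = _random_instance(9, n=30, p=4, m=1)
        parts = od.variance_partition(Y, env, ["x0"], condition=())
        res = od.rda(Y, env, ["x0"], condition=(), n_perm=0)
        assert parts["x0"] == pytest.approx(res.adjusted_R2)


class TestIRLS:
    def test_exact_line_recovered_with_unit_weights(self):
        x = np.linspace(0, 10, 25)
        y = 2.5 * x - 1.0
        fit = od.irls_fit(x, y)
        assert fit.slope == pytest.approx(2.5, abs=1e-10)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-10)
        assert np.allclose(fit.weights, 1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_gross_outliers_downweighted(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 22)
        y = 1.5 * x + 2.0 + 0.05 * rng.standard_normal(22)
        y[3] += 40.0
        y[17] -= 35.0
        fit = od.irls_fit(x, y)
        assert abs(fit.slope - 1.5) / 1.5 < 0.05
        assert fit.weights[3] < 0.05 and fit.weights[17] < 0.05

    def test_agrees_with_ols_under_gaussian_noise(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 100)
        y = 0.8 * x + 1.0 + 0.3 * rng.standard_normal(100)
        fit = od.irls_fit(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(fit.slope - ols.params[1]) < ols.bse[1]
        assert abs(fit.intercept - ols.params[0]) < ols.bse[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            od.irls_fit([1.0, 2.0], [1.0, 2.0])

    def test_marker_regression_excludes_zero_frequencies(self):
        fx = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        fy = np.array([0.05, 0.0, 0.21, 0.33, 0.38, 0.52])
        fit = od.marker_regression(fx, fy)
        assert fit.n_excluded == 2
        assert fit.slope > 0
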