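"""MFA, adequacy diagnostics, varimax and retention against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swaykit.mfa import (
    MFA,
    bartlett_sphericity,
    dimension_group_test,
    group_variance_share,
    horn_parallel,
    interpret_loadings,
    kmo,
    varimax,
)


def _blocked_frame(X, n_blocks=4):
    p = X.shape[1]
    per = p // n_blocks
    cols = [f"v{j % per}@B{j // per}" for j in range(p)]
    return pd.DataFrame(X, columns=cols)


def _random_frame(rng, n=150, p=24):
    # correlated data: latent factors + noise
    F = rng.standard_normal((n, 3))
    W = rng.standard_normal((3, p))
    return _blocked_frame(F @ W + 0.8 * rng.standard_normal((n, p)))


# ---------------------------------------------------------------------------
# KMO / Bartlett
# ---------------------------------------------------------------------------

def _kmo_bruteforce(X):
    """Independent KMO: explicit anti-image partial correlations."""
    R = np.corrcoef(X, rowvar=False)
    Rinv = np.linalg.inv(R)
    p = R.shape[0]
    num = den_q = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            q_ij = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
            num += R[i, j] ** 2
            den_q += q_ij**2
    return num / (num + den_q)


def test_kmo_matches_bruteforce_on_equicorrelated_sample(rng):
    L = np.linalg.cholesky(0.5 * np.ones((3, 3)) + 0.5 * np.eye(3))
    X = rng.standard_normal((10_000, 3)) @ L.T
    _, overall = kmo(pd.DataFrame(X, columns=list("abc")))
    assert overall == pytest.approx(_kmo_bruteforce(X), abs=1e-6)


def test_kmo_low_for_duplicated_pairs(rng):
    a = rng.standard_normal(2000)
    b = rng.standard_normal(2000)
    X = np.column_stack([a, a + 0.01 * rng.standard_normal(2000),
                         b, b + 0.01 * rng.standard_normal(2000)])
    per_var, overall = kmo(pd.DataFrame(X, columns=list("wxyz")))
    assert overall == pytest.approx(_kmo_bruteforce(X), abs=1e-6)
    assert overall < 0.6  # partials dominate: poor factorability
    assert ((per_var >= 0) & (per_var <= 1)).all()


def test_kmo_in_unit_interval_on_random_data(rng):
    X = rng.standard_normal((50, 6))
    per_var, overall = kmo(pd.DataFrame(X))
    assert 0.0 <= overall <= 1.0
    assert ((per_var >= 0) & (per_var <= 1)).all()


def test_bartlett_identity_correlation_is_null():
    n, p = 200, 5
    # orthogonal, mean-zero columns -> sample correlation R = I -> ln det = 0
    X = np.random.default_rng(0).standard_normal((n, p))
    q, _ = np.linalg.qr(X - X.mean(axis=0))
    chi2, df, pval = bartlett_sphericity(pd.DataFrame(q))
    assert chi2 == pytest.approx(0.0, abs=1e-8)
    assert pval == pytest.approx(1.0)
    assert df == p * (p - 1) // 2


def test_bartlett_df_for_24_variables(rng):
    X = _random_frame(rng)
    _, df, _ = bartlett_sphericity(X)
    assert df == 276


def test_bartlett_matches_direct_formula(rng):
    X = rng.standard_normal((120, 6)) @ rng.standard_normal((6, 6))
    df_frame = pd.DataFrame(X)
    chi2, df, pval = bartlett_sphericity(df_frame)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    want = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(R))
    assert chi2 == pytest.approx(want, abs=1e-8)
    assert pval == pytest.approx(stats.chi2.sf(want, p * (p - 1) // 2), abs=1e-12)


# ---------------------------------------------------------------------------
# the MFA fit vs an independent SVD oracle
# ---------------------------------------------------------------------------

def test_mfa_equals_direct_svd_oracle(rng):
    """Eigenvalues to 1e-8 and loadings up to sign, on random matrices."""
    for _ in range(10):
        df = _random_frame(rng)
        res = MFA(df, n_dims=2, diagnostics=False).fit()
        # oracle: rebuild the weighted matrix from scratch and SVD it
        X = df.to_numpy(float)
        n = X.shape[0]
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        Zw = Z.copy()
        for b in range(4):
            cols = np.arange(6 * b, 6 * b + 6)
            lam1 = np.linalg.svd(Z[:, cols], compute_uv=False)[0] ** 2 / (n - 1)
            Zw[:, cols] /= np.sqrt(lam1)
        s = np.linalg.svd(Zw, compute_uv=False)
        np.testing.assert_allclose(res.eigenvalues, s**2 / (n - 1), atol=1e-8)
        # loadings: correlations of variables with scores, up to column sign
        for k in range(2):
            want = np.array(
                [np.corrcoef(Z[:, j], res.scores.iloc[:, k])[0, 1]
                 for j in range(24)]
            )
            got = res.loadings.iloc[:, k].to_numpy()
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )


def test_weighted_block_first_eigenvalue_is_one(rng):
    df = _random_frame(rng)
    res = MFA(df, n_dims=2, diagnostics=False).fit()
    X = df.to_numpy(float)
    n = X.shape[0]
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    for name, w in res.block_weights.items():
        cols = [list(df.columns).index(c) for c in res.model.blocks[name]]
        Zb = Z[:, cols] * np.sqrt(w)
        lam1 = np.linalg.svd(Zb, compute_uv=False)[0] ** 2 / (n - 1)
        assert lam1 == pytest.approx(1.0, abs=1e-8)


def test_rank_one_blocks_put_all_inertia_on_dim1(rng):
    """Four identical rank-1 blocks: Dimension 1 carries ~100% of inertia."""
    f = rng.standard_normal(80)
    cols = {}
    for b in range(4):
        for j in range(6):
            cols[f"v{j}@B{b}"] = f * (j + 1) + 1e-8 * rng.standard_normal(80)
    res = MFA(pd.DataFrame(cols), n_dims=2, diagnostics=False).fit()
    assert res.variance_explained.iloc[0] == pytest.approx(100.0, abs=1e-3)


def test_participant_permutation_equivariance(rng):
    df = _random_frame(rng, n=60)
    perm = rng.permutation(60)
    res1 = MFA(df, n_dims=2, diagnostics=False).fit()
    res2 = MFA(df.iloc[perm].reset_index(drop=True), n_dims=2, diagnostics=False).fit()
    np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-8)
    np.testing.assert_allclose(
        np.abs(res1.loadings.to_numpy()), np.abs(res2.loadings.to_numpy()), atol=1e-8
    )
    np.testing.assert_allclose(
        np.abs(res1.scores.to_numpy()[perm]), np.abs(res2.scores.to_numpy()), atol=1e-8
    )


def test_contrib_sums_to_100_per_dimension(rng):
    res = MFA(_random_frame(rng), n_dims=2, diagnostics=False).fit()
    np.testing.assert_allclose(res.contrib.sum(axis=0), 100.0, atol=1e-8)


def test_zero_variance_variable_named_in_error(rng):
    df = _random_frame(rng)
    df["v0@B0"] = 3.0
    with pytest.raises(ValueError, match="v0@B0"):
        MFA(df, n_dims=2, diagnostics=False).fit()


# ---------------------------------------------------------------------------
# varimax
# ---------------------------------------------------------------------------

def _varimax_criterion(L):
    L2 = L**2
    return np.sum(L2**2) - np.sum(L2.sum(axis=0) ** 2) / L.shape[0]


def test_varimax_fixed_point_on_simple_structure():
    L = np.zeros((6, 2))
    L[:3, 0] = [0.9, 0.8, 0.85]
    L[3:, 1] = [0.7, 0.75, 0.9]
    rotated, _ = varimax(L)
    # already perfectly simple: unchanged up to column sign/permutation
    assert np.allclose(np.sort(np.abs(rotated).max(axis=0)),
                       np.sort(np.abs(L).max(axis=0)), atol=1e-8)
    np.testing.assert_allclose(np.abs(rotated), np.abs(L), atol=1e-6)


def test_varimax_preserves_communalities(rng):
    L = rng.standard_normal((24, 3)) * 0.4
    rotated, R = varimax(L)
    np.testing.assert_allclose(
        (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-10
    )
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)


def test_varimax_2d_angle_matches_grid_search(rng):
    """Planted 2-factor loadings: rotation matches a 0.01-degree grid scan."""
    base = np.zeros((10, 2))
    base[:5, 0] = rng.uniform(0.6, 0.9, 5)
    base[5:, 1] = rng.uniform(0.6, 0.9, 5)
    theta_true = np.deg2rad(27.0)
    Rot = np.array(
        [[np.cos(theta_true), -np.sin(theta_true)],
         [np.sin(theta_true), np.cos(theta_true)]]
    )
    L = base @ Rot  # mix the simple structure by a known angle
    # grid-search oracle over rotation angle (Kaiser-normalised criterion)
    h = np.sqrt((L**2).sum(axis=1))
    Ln = L / h[:, None]
    best_theta, best_val = None, -np.inf
    for deg in np.arange(0.0, 90.0, 0.01):
        th = np.deg2rad(deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        val = _varimax_criterion(Ln @ R)
        if val > best_val:
            best_val, best_theta = val, th
    rotated, _ = varimax(L, kaiser_normalize=True)
    got_val = _varimax_criterion(rotated / h[:, None])
    # criterion at our optimum >= grid optimum within the 0.01-deg resolution
    assert got_val >= best_val - 1e-9
    # and the recovered angle agrees with the grid to 0.05 degrees
    Rn = np.linalg.lstsq(Ln, rotated / h[:, None], rcond=None)[0]
    got_theta = np.arctan2(Rn[1, 0], Rn[0, 0]) % (np.pi / 2)
    assert np.rad2deg(abs(got_theta - best_theta)) % 90 < 0.05


def test_varimax_agrees_with_statsmodels(rng):
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L = rng.standard_normal((24, 2)) * 0.5
    ours, _ = varimax(L, kaiser_normalize=False)
    theirs, _ = rotate_factors(L, "varimax")
    # same solution up to column sign/permutation and each method's
    # convergence tolerance; our criterion is at least as good
    got = np.sort(np.abs(ours), axis=None)
    want = np.sort(np.abs(theirs), axis=None)
    np.testing.assert_allclose(got, want, atol=1e-3)
    assert _varimax_criterion(ours) >= _varimax_criterion(theirs) - 1e-6


def test_varimax_single_column_identity():
    L = np.array([[0.5], [0.7]])
    rotated, R = varimax(L)
    np.testing.assert_array_equal(rotated, L)
    np.testing.assert_array_equal(R, np.eye(1))


# ---------------------------------------------------------------------------
# Horn's parallel analysis
# ---------------------------------------------------------------------------

def test_horn_pure_noise_retains_nothing(rng):
    X = pd.DataFrame(rng.standard_normal((150, 12)))
    retained, thresholds = horn_parallel(X, n_iter=200, seed=0)
    assert retained == 0
    assert len(thresholds) == 12


def test_horn_two_planted_factors_retained(rng):
    n = 150
    F = rng.standard_normal((n, 2))
    W = rng.standard_normal((2, 12)) * 5.0  # SNR 5
    X = pd.DataFrame(F @ W + rng.standard_normal((n, 12)))
    retained, _ = horn_parallel(X, n_iter=200, seed=0)
    assert retained == 2


def test_horn_deterministic_under_seed(rng):
    X = pd.DataFrame(rng.standard_normal((80, 8)))
    r1, t1 = horn_parallel(X, n_iter=150, seed=42)
    r2, t2 = horn_parallel(X, n_iter=150, seed=42)
    assert r1 == r2
    np.testing.assert_array_equal(t1, t2)


def test_horn_rejects_too_few_iterations(rng):
    with pytest.raises(ValueError):
        horn_parallel(pd.DataFrame(rng.standard_normal((50, 5))), n_iter=10)


# ---------------------------------------------------------------------------
# interpretation + group comparisons
# ---------------------------------------------------------------------------

def test_interpret_loadings_thresholds():
    L = pd.DataFrame(
        [[0.85, 0.05], [0.45, -0.35], [0.30, 0.20]],
        index=["strong", "crossing", "weak"],
        columns=["Dim1", "Dim2"],
    )
    out = interpret_loadings(L)
    assert out.loc["strong", "label"] == "substantial"
    assert out.loc["strong", "substantial_dims"] == "Dim1"
    assert not out.loc["strong", "cross_loading"]
    assert out.loc["crossing", "label"] == "substantial"
    assert out.loc["crossing", "cross_loading"]
    assert out.loc["weak", "label"] == "negligible"


def test_interpret_rejects_bad_thresholds():
    L = pd.DataFrame([[0.5, 0.1]], columns=["Dim1", "Dim2"])
    with pytest.raises(ValueError):
        interpret_loadings(L, substantial=1.4)


def test_group_share_exchangeable_halves(rng):
    df = _random_frame(rng, n=120)
    groups = pd.Series(["X"] * 60 + ["Y"] * 60, index=df.index)
    shares = group_variance_share(df, groups, n_dims=2).set_index("group")
    assert shares.loc["X", "dim1_share"] == pytest.approx(
        shares.loc["Y", "dim1_share"], abs=8.0
    )


def test_dimension_group_test_matches_f_oneway(rng):
    scores = pd.Series(rng.standard_normal(100))
    groups = pd.Series(["a"] * 40 + ["b"] * 60)
    out = dimension_group_test(scores, groups)
    F, p = stats.f_oneway(scores[:40], scores[40:])
    assert out["F"] == pytest.approx(F, rel=1e-10)
    assert out["p"] == pytest.approx(p, rel=1e-10)
    assert 0 <= out["eta2"] <= 1


def test_dimension_group_test_equal_groups_is_null():
    scores = pd.Series(np.tile([1.0, 2.0, 3.0], 2))
    groups = pd.Series(["a"] * 3 + ["b"] * 3)
    out = dimension_group_test(scores, groups)
    assert out["F"] == 0.0
    assert out["p"] == 1.0


def test_dimension_group_test_permutation_close_to_parametric(rng):
    scores = pd.Series(np.concatenate([rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)]))
    groups = pd.Series(["a"] * 40 + ["b"] * 40)
    par = dimension_group_test(scores, groups)
    perm = dimension_group_test(scores, groups, method="permutation",
                                n_perm=4000, seed=1)
    assert perm["p"] == pytest.approx(par["p"], abs=0.02)


def test_dimension_group_test_permutation_null_uniform(rng):
    """With shuffled labels the permutation p-value is ~uniform."""
    pvals = []
    for seed in range(60):
        r = np.random.default_rng(seed)
        scores = pd.Series(r.standard_normal(40))
        groups = pd.Series(r.permutation(["a"] * 20 + ["b"] * 20))
        pvals.append(dimension_group_test(scores, groups)["p"])
    _, ks_p = stats.kstest(pvals, "uniform")
    assert ks_p > 0.01
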