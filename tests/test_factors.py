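import numpy as np
import pytest

from nmlsa.factors import (ModuleFactorModel, ProjectionProfile,
                           extract_module_factors, interactive_pair,
                           module_eigenvectors, oblique_rotate,
                           projection_lengths, select_interacting_set)


def make_orthonormal(n, k, rng):
    """k orthonormal mean-zero n-vectors."""
    A = rng.standard_normal((n, k + 1))
    A[:, 0] = 1.0  # force factors orthogonal to the constant
    Q, _ = np.linalg.qr(A)
    return Q[:, 1:].T


def test_rank_one_module():
    rng = np.random.default_rng(1)
    pattern = rng.standard_normal(50)
    X = np.outer(rng.uniform(0.5, 2.0, 20), pattern)
    vecs, fracs = module_eigenvectors(X)
    assert len(vecs) == 1
    np.testing.assert_allclose(fracs[0], 1.0, atol=1e-12)


def test_two_balanced_factors():
    rng = np.random.default_rng(2)
    v = make_orthonormal(80, 2, rng)
    X = np.vstack([np.outer(np.ones(50), v[0]),
                   np.outer(np.ones(50), v[1])])
    vecs, fracs = module_eigenvectors(X)
    assert len(vecs) == 2
    np.testing.assert_allclose(fracs.sum(), 1.0, atol=1e-9)
    np.testing.assert_allclose(sorted(fracs), [0.5, 0.5], atol=1e-9)


def test_retention_matches_svd_oracle(rng):
    X = rng.standard_normal((100, 100))
    vecs, fracs = module_eigenvectors(X, variance_fraction=0.05)
    Xc = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(Xc, compute_uv=False)
    expected = max(1, int(np.sum(s ** 2 / np.sum(s ** 2) >= 0.05)))
    assert len(vecs) == expected
    np.testing.assert_allclose(fracs, (s ** 2 / np.sum(s ** 2))[:expected],
                               atol=1e-9)


def test_rank_zero_rejected():
    with pytest.raises(ValueError, match="rank 0"):
        module_eigenvectors(np.ones((5, 10)))


def test_projection_lengths_orthonormality(rng):
    v = make_orthonormal(40, 2, rng)
    X = np.vstack([3.0 * v[0], -2.0 * v[1], rng.standard_normal(40)])
    prof = projection_lengths(X, v)
    np.testing.assert_allclose(prof.lengths[0], [3.0, 0.0], atol=1e-9)
    np.testing.assert_allclose(prof.lengths[1], [2.0, 0.0][::-1], atol=1e-9)
    assert (prof.lengths >= 0).all()


def test_projection_lengths_match_brute_force(rng):
    X = rng.standard_normal((30, 50))
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    prof = projection_lengths(X, vt[:4])
    np.testing.assert_allclose(prof.lengths, np.abs(Xc @ vt[:4].T),
                               atol=1e-9)


def test_projection_dimension_mismatch(rng):
    with pytest.raises(ValueError, match="mismatch"):
        projection_lengths(rng.standard_normal((5, 10)),
                           rng.standard_normal((2, 8)))


def test_interactive_identical_columns():
    lengths = np.abs(np.random.default_rng(3).standard_normal((50, 2)))
    lengths[:, 1] = lengths[:, 0]
    prof = ProjectionProfile(lengths=lengths)
    assert interactive_pair(prof, 0, 1, alpha=1e-6)


def test_interactive_constant_column():
    lengths = np.ones((50, 2))
    lengths[:, 0] = np.abs(np.random.default_rng(4).standard_normal(50))
    assert not interactive_pair(ProjectionProfile(lengths=lengths), 0, 1)


def test_interactive_type_one_error_calibration():
    """Independent projection-length columns should test significant at
    about the nominal 5% rate."""
    rng = np.random.default_rng(5)
    hits = 0
    reps = 1000
    for _ in range(reps):
        lengths = np.abs(rng.standard_normal((100, 2)))
        if interactive_pair(ProjectionProfile(lengths=lengths), 0, 1, 0.05):
            hits += 1
    assert 0.03 <= hits / reps <= 0.08


def test_interactive_block_design_negative_correlation():
    """Genes loading exclusively one of two factors give anti-correlated
    projection lengths; the two-sided test must flag the pair."""
    rng = np.random.default_rng(6)
    n = 60
    v = make_orthonormal(n, 2, rng)
    X = np.vstack([np.outer(rng.uniform(1, 2, 50), v[0]),
                   np.outer(rng.uniform(1, 2, 50), v[1])])
    X += 0.05 * rng.standard_normal(X.shape)
    prof = projection_lengths(X, v)
    r = np.corrcoef(prof.lengths[:, 0], prof.lengths[:, 1])[0, 1]
    assert r < 0
    assert interactive_pair(prof, 0, 1, alpha=0.05)


def test_select_single_eigenvector():
    prof = ProjectionProfile(
        lengths=np.abs(np.random.default_rng(7).standard_normal((20, 1))))
    assert select_interacting_set(prof) == [0]


def test_select_stop_rule_is_literal():
    """If eigenvector 2 is not interactive with 1, selection stops even
    when eigenvector 3 would have been interactive with 1."""
    rng = np.random.default_rng(8)
    a = np.abs(rng.standard_normal(200))
    b = np.abs(rng.standard_normal(200))          # independent of a
    c = a + 0.01 * np.abs(rng.standard_normal(200))  # strongly tied to a
    prof = ProjectionProfile(lengths=np.column_stack([a, b, c]))
    assert interactive_pair(prof, 0, 2)            # 3 would interact ...
    assert select_interacting_set(prof) == [0]     # ... but is never seen


def test_select_adds_interacting_chain():
    rng = np.random.default_rng(9)
    a = np.abs(rng.standard_normal(200))
    b = a + 0.05 * np.abs(rng.standard_normal(200))
    c = b + 0.05 * np.abs(rng.standard_normal(200))
    prof = ProjectionProfile(lengths=np.column_stack([a, b, c]))
    assert select_interacting_set(prof) == [0, 1, 2]


def test_oblique_single_factor(rng):
    v = make_orthonormal(60, 1, rng)
    loadings = rng.uniform(-2, 2, 40)
    X = np.outer(loadings, v[0]) + 0.01 * rng.standard_normal((40, 60))
    vecs, _ = module_eigenvectors(X)
    model = oblique_rotate(X, vecs, [0])
    f = model.factor_scores[0]
    np.testing.assert_allclose(f.std(), 1.0, atol=1e-9)
    corr = np.corrcoef(f, v[0])[0, 1]
    assert abs(corr) > 0.999


def test_exact_model_zero_residual(rng):
    """With both eigenvectors of an exact two-factor module selected, the
    rotated model reproduces it: E ~= 0. (The interactivity screen is a
    separate concern; independent random loadings legitimately fail it.)"""
    v = make_orthonormal(50, 2, rng)
    L = rng.standard_normal((30, 2))
    X = L @ v
    vecs, _ = module_eigenvectors(X)
    model = oblique_rotate(X, vecs)
    assert np.abs(model.residuals).max() < 1e-6


def test_rotation_recovers_simple_structure():
    """Two factors with disjoint supporting genes, observed through the
    mixing that PCA induces: rotated loadings must re-separate them."""
    rng = np.random.default_rng(10)
    n = 100
    v = make_orthonormal(n, 2, rng)
    F = np.vstack([v[0], 0.6 * v[0] + 0.8 * v[1]])  # correlated factors
    L = np.zeros((100, 2))
    L[:50, 0] = rng.uniform(0.8, 1.2, 50)
    L[50:, 1] = rng.uniform(0.8, 1.2, 50)
    X = L @ F + 0.05 * rng.standard_normal((100, n))
    model = extract_module_factors(X)
    assert model.n_factors == 2
    Lr = np.abs(model.loadings)
    main = Lr.max(axis=1)
    cross = Lr.min(axis=1)
    assert np.mean(cross) < 0.1 * np.mean(main)


def test_reconstruction_and_ordering(rng):
    X = rng.standard_normal((40, 60))
    model = extract_module_factors(X)
    recon = model.loadings @ model.factor_scores + model.residuals
    Xc = X - X.mean(axis=1, keepdims=True)
    assert np.abs(recon - Xc).max() < 1e-9
    assert (np.diff(model.variance_explained) <= 1e-9).all()
    # sign convention: the top-loading feature of each factor is positive
    for k in range(model.n_factors):
        top = np.argmax(np.abs(model.loadings[:, k]))
        assert model.loadings[top, k] > 0


def test_planted_factor_recovery():
    """Modules with 1-3 planted factors at SNR 2: regression of each true
    factor on the recovered set gives R^2 >= 0.9 in >= 90% of runs."""
    rng = np.random.default_rng(11)
    ok = total = 0
    for rep in range(30):
        r = 1 + rep % 3
        F = np.vstack([rng.standard_normal(100) for _ in range(r)])
        F = (F - F.mean(axis=1, keepdims=True)) / F.std(axis=1, keepdims=True)
        cuts = np.sort(rng.random((100, r - 1)), axis=1) if r > 1 else None
        L = (np.diff(np.c_[np.zeros(100), cuts, np.ones(100)], axis=1)
             if r > 1 else np.ones((100, 1)))
        L *= rng.choice([-1, 1], size=L.shape)
        X = L @ F
        X += rng.standard_normal(X.shape) * (X.std(axis=1, keepdims=True) / 2)
        model = extract_module_factors(X)
        G = model.factor_scores
        for j in range(r):
            y = F[j] - F[j].mean()
            beta, *_ = np.linalg.lstsq(G.T, y, rcond=None)
            resid = y - G.T @ beta
            r2 = 1 - (resid @ resid) / (y @ y)
            ok += r2 >= 0.9
            total += 1
    assert ok / total >= 0.9
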