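"""Chi-square distance, initial clustering, spatial augmentation, lambda tuning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sltp.ltp import (augment_ltps, chi2_cdist, chi2_distance, compute_W,
                      init_ltps, tune_lambda)


# ---------------------------------------------------------------------------
# chi-square distance

def test_chi2_known_values():
    assert chi2_distance([0.5, 0.5], [0.5, 0.5]) == 0.0
    assert chi2_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
    assert chi2_distance([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.0667, abs=1e-4)
    assert chi2_distance([0.0, 1.0], [0.0, 1.0]) == 0.0  # empty bins contribute 0


def test_chi2_input_validation():
    with pytest.raises(ValueError):
        chi2_distance([0.5, 0.5], [1.0])
    with pytest.raises(ValueError):
        chi2_distance([-0.1, 1.1], [0.5, 0.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
       st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4))
def test_chi2_symmetry_and_nonnegativity(p, q):
    p, q = np.array(p), np.array(q)
    d = chi2_distance(p, q)
    assert d >= 0.0
    assert d == pytest.approx(chi2_distance(q, p))
    assert chi2_distance(p, p) == 0.0


def test_chi2_cdist_matches_scalar():
    rng = np.random.default_rng(0)
    P = rng.dirichlet(np.ones(6), 5)
    Q = rng.dirichlet(np.ones(6), 3)
    D = chi2_cdist(P, Q)
    for i in range(5):
        for j in range(3):
            assert D[i, j] == pytest.approx(chi2_distance(P[i], Q[j]))


# ---------------------------------------------------------------------------
# initial clustering

def test_each_roi_its_own_ltp_gives_zero_ssw():
    rng = np.random.default_rng(1)
    FT = rng.dirichlet(np.ones(8), 12)
    model = init_ltps(FT, n_ltp=12, seed=0)
    assert model.k == 12
    assert model.ssw_t == pytest.approx(0.0, abs=1e-12)


def test_separated_textures_recovered():
    rng = np.random.default_rng(2)
    a = np.tile([0.9, 0.1, 0.0, 0.0], (30, 1)) + rng.uniform(0, 0.02, (30, 4))
    b = np.tile([0.0, 0.0, 0.1, 0.9], (30, 1)) + rng.uniform(0, 0.02, (30, 4))
    FT = np.vstack([a, b])
    FT /= FT.sum(1, keepdims=True)
    model = init_ltps(FT, n_ltp=2, seed=0)
    from sklearn.metrics import adjusted_rand_score

    truth = np.repeat([0, 1], 30)
    assert adjusted_rand_score(truth, model.labels) == 1.0


def test_init_deterministic_and_validates_size():
    rng = np.random.default_rng(3)
    FT = rng.dirichlet(np.ones(10), 40)
    m1 = init_ltps(FT, 5, seed=9)
    m2 = init_ltps(FT, 5, seed=9)
    np.testing.assert_array_equal(m1.labels, m2.labels)
    with pytest.raises(ValueError):
        init_ltps(FT, 41, seed=0)


def test_model_invariants_centroids_and_p95(train_result, train_table):
    """Centroids and P95 thresholds are re-derivable from the assignments."""
    model = train_result.model
    FT = train_table.ft
    for j in range(model.k):
        members = model.labels == j
        np.testing.assert_allclose(model.ft_centroids[j], FT[members].mean(0),
                                   atol=1e-9)
        d = chi2_cdist(FT[members], model.ft_centroids[j][None])[:, 0]
        assert model.p95[j] == pytest.approx(np.percentile(d, 95))
        assert model.max_intra[j] == pytest.approx(d.max())
    # assignments partition the training set
    assert np.isin(model.labels, np.arange(model.k)).all()


# ---------------------------------------------------------------------------
# W scaling

def test_w_zero_when_textures_identical():
    FT = np.tile([0.5, 0.5], (4, 1))
    FS = np.eye(4)
    assert compute_W(FT, FS) == 0.0


def test_w_two_roi_toy_matches_brute_force():
    FT = np.array([[1.0, 0.0], [0.0, 1.0]])
    FS = np.array([[1.0, 0.0], [0.0, 1.0]])
    # SST_T = 2 * chi2((1,0),(.5,.5)) = 2 * 1/3; SST_S = 2 * 0.5 = 1
    brute_t = sum(chi2_distance(f, FT.mean(0)) for f in FT)
    brute_s = sum(((f - FS.mean(0)) ** 2).sum() for f in FS)
    assert compute_W(FT, FS) == pytest.approx(brute_t / brute_s)
    assert compute_W(FT, FS) == pytest.approx(2.0 / 3.0)


def test_w_invariant_under_duplication():
    rng = np.random.default_rng(4)
    FT = rng.dirichlet(np.ones(6), 10)
    FS = np.eye(6)[rng.integers(0, 6, 10)]
    w = compute_W(FT, FS)
    assert compute_W(np.vstack([FT, FT]), np.vstack([FS, FS])) == pytest.approx(w)


def test_w_errors_when_single_subregion():
    FT = np.random.default_rng(5).dirichlet(np.ones(4), 6)
    FS = np.tile(np.eye(6)[0], (6, 1))
    with pytest.raises(ValueError):
        compute_W(FT, FS)


# ---------------------------------------------------------------------------
# augmentation

def test_lambda_zero_penalty_off_is_chi2_kmeans_fixed_point(train_result, train_table):
    init = train_result.init_model
    out = augment_ltps(train_table.ft, train_table.fs, init, 0.0,
                       train_result.w, penalty=False)
    np.testing.assert_array_equal(out.labels, init.labels)
    assert out.ssw_t == pytest.approx(init.ssw_t, abs=1e-12)


def test_large_lambda_splits_spatially_disjoint_duplicates():
    """One texture planted in two disjoint sub-regions splits spatially."""
    rng = np.random.default_rng(6)
    FT = rng.dirichlet(50 * np.ones(5), 60)           # one tight texture cloud
    FS = np.zeros((60, 4))
    FS[:30, 0] = 1.0                                   # region A
    FS[30:, 3] = 1.0                                   # region B
    other = rng.dirichlet(np.ones(5) * [50, 1, 1, 1, 1], 30)
    FT = np.vstack([FT, other])
    FS = np.vstack([FS, np.tile([0, 1.0, 0, 0], (30, 1))])
    init = init_ltps(FT, 3, seed=1)
    w = compute_W(FT, FS)

    def spatial_scatter(model):
        tot = 0.0
        for j in range(model.k):
            sel = model.labels == j
            tot += ((FS[sel] - FS[sel].mean(0)) ** 2).sum()
        return tot

    free = augment_ltps(FT, FS, init, 0.0, w, penalty=False)
    reg = augment_ltps(FT, FS, init, 2.0, w, penalty=False)
    assert spatial_scatter(reg) < spatial_scatter(free)
    # the duplicated texture ends in >= 2 spatially concentrated patterns
    groups = {tuple(np.flatnonzero(FS[reg.labels == j].sum(0) > 0))
              for j in range(reg.k)}
    assert any(g == (0,) for g in groups) and any(g == (3,) for g in groups)


def test_penalty_falls_back_to_texture_argmin():
    """A ROI texturally beyond every P95 goes to the min-chi2 pattern."""
    FT = np.vstack([np.tile([1.0, 0, 0, 0], (10, 1)),
                    np.tile([0, 0, 0, 1.0], (10, 1))])
    FS = np.vstack([np.tile([1.0, 0], (10, 1)), np.tile([0, 1.0], (10, 1))])
    outlier_ft = np.array([[0.0, 0.35, 0.65, 0.0]])    # far from both patterns
    outlier_fs = np.array([[0.0, 1.0]])                # spatially with pattern 2
    init = init_ltps(np.vstack([FT, outlier_ft]), 2, seed=0)
    out = augment_ltps(np.vstack([FT, outlier_ft]), np.vstack([FS, outlier_fs]),
                       init, 5.0, 1.0, penalty=True)
    d = chi2_cdist(outlier_ft, out.ft_centroids)[0]
    assert out.labels[-1] == np.argmin(d)


def test_objective_trace_monotone(train_result, train_table):
    for lam in (0.5, 1.0, 2.0):
        model = augment_ltps(train_table.ft, train_table.fs,
                             train_result.init_model, lam, train_result.w,
                             penalty=True)
        t = np.array(model.objective_trace)
        if len(t) > 1:
            assert np.all(np.diff(t) <= 1e-6 * np.abs(t[:-1]))


# ---------------------------------------------------------------------------
# lambda tuning

def test_constant_spatial_term_selects_grid_max():
    """With all ROIs in one sub-region the spatial term is constant."""
    rng = np.random.default_rng(7)
    FT = rng.dirichlet(np.ones(6), 40)
    FS = np.tile(np.eye(4)[2], (40, 1))
    init = init_ltps(FT, 4, seed=0)
    lam, trace = tune_lambda(FT, FS, init, w=1.0, grid=[0.0, 1.0, 2.0], l_t=1.0)
    assert lam == 2.0
    assert all(d == pytest.approx(0.0, abs=1e-9) for _, d in trace)


def test_lambda_star_is_last_grid_point_below_loss(monkeypatch):
    """Monotone loss crossing L_T between grid points a < b selects a."""
    import sltp.ltp as ltp_mod

    losses = {0.0: 0.0, 0.5: 0.4, 1.0: 0.9, 1.5: 1.4, 2.0: 3.0}

    class Stub:
        def __init__(self, ssw):
            self.ssw_t = ssw

    init = Stub(100.0)
    init.labels = np.zeros(1, dtype=int)

    def fake_augment(FT, FS, init_, lam, w, penalty=True):
        return Stub(100.0 * (1 + losses[lam] / 100.0))

    monkeypatch.setattr(ltp_mod, "augment_ltps", fake_augment)
    lam, trace = ltp_mod.tune_lambda(None, None, init, w=1.0,
                                     grid=sorted(losses), l_t=1.0)
    assert lam == 1.0
    assert dict(trace)[0.0] == pytest.approx(0.0)


def test_phantom_trace_starts_near_zero_loss(train_result):
    """Delta-SSW_T(0) is ~0: with the textural penalty active, only the few
    ROIs beyond their own cluster's P95 threshold can move at lambda = 0."""
    trace = dict(train_result.lambda_trace)
    assert abs(trace[0.0]) < 0.2  # well below the 1% tuning tolerance
    assert 0.0 <= train_result.lam_star <= 2.0
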