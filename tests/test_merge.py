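"""Replacement-ratio graph, map-equation partitioning, sLTP finalization."""

import numpy as np
import pytest

from sltp.ltp import LtpModel, chi2_cdist
from sltp.merge import (build_graph, finalize_sltps, map_equation, merge_ltps,
                        partition_graph, partition_graph_exhaustive,
                        replacement_ratio)


def make_model(FT, FS, labels, lam=0.0, w=1.0):
    labels = np.asarray(labels)
    k = labels.max() + 1
    ft_c = np.vstack([FT[labels == j].mean(0) for j in range(k)])
    fs_c = np.vstack([FS[labels == j].mean(0) for j in range(k)])
    max_intra = np.array([chi2_cdist(FT[labels == j], ft_c[j][None])[:, 0].max()
                          for j in range(k)])
    return LtpModel(ft_centroids=ft_c, fs_centroids=fs_c, labels=labels,
                    lam=lam, w=w, p95=max_intra.copy(), max_intra=max_intra)


# ---------------------------------------------------------------------------
# replacement ratios

def test_duplicate_patterns_fully_replace_each_other():
    rng = np.random.default_rng(0)
    base = rng.dirichlet(np.ones(6), 10)
    FT = np.vstack([base, base])  # two patterns with identical member sets
    FS = np.tile([1.0, 0.0], (20, 1))
    model = make_model(FT, FS, np.repeat([0, 1], 10))
    assert replacement_ratio(0, FT, FS, model)[1] == 1.0
    assert replacement_ratio(1, FT, FS, model)[0] == 1.0


def test_texturally_disjoint_pattern_absorbs_nothing():
    FT = np.vstack([np.tile([1.0, 0, 0], (8, 1)) ,
                    np.tile([0, 0, 1.0], (8, 1))])
    FT[:8] += np.random.default_rng(1).uniform(0, 0.05, (8, 3))
    FT /= FT.sum(1, keepdims=True)
    FS = np.tile([1.0, 0.0], (16, 1))
    model = make_model(FT, FS, np.repeat([0, 1], 8))
    ratios = replacement_ratio(0, FT, FS, model)
    assert ratios[1] == 0.0  # every ROI of pattern 0 is beyond pattern 1's max-intra


def test_three_pattern_toy_matches_brute_force():
    rng = np.random.default_rng(2)
    FT = np.vstack([rng.dirichlet([20, 2, 2], 10),
                    rng.dirichlet([2, 20, 2], 10),
                    rng.dirichlet([8, 8, 2], 10)])
    FS = np.vstack([np.tile([1.0, 0], (10, 1)), np.tile([0, 1.0], (10, 1)),
                    np.tile([0.5, 0.5], (10, 1))])
    model = make_model(FT, FS, np.repeat([0, 1, 2], 10), lam=0.7, w=1.3)
    for i in range(3):
        got = replacement_ratio(i, FT, FS, model)
        # brute force: relabel each member by hand
        counts = np.zeros(3)
        members = np.flatnonzero(model.labels == i)
        for x in members:
            best, best_cost = None, np.inf
            for k in range(3):
                if k == i:
                    continue
                d_t = chi2_cdist(FT[x][None], model.ft_centroids[k][None])[0, 0]
                if d_t > model.max_intra[k]:
                    continue
                cost = d_t + 0.7 * 1.3 * ((FS[x] - model.fs_centroids[k])**2).sum()
                if cost < best_cost:
                    best, best_cost = k, cost
            if best is not None:
                counts[best] += 1
        np.testing.assert_allclose(got, counts / members.size)


def test_edge_threshold_is_strict_below(monkeypatch):
    import sltp.merge as mg

    FT = np.random.default_rng(3).dirichlet(np.ones(4), 12)
    FS = np.eye(2)[np.random.default_rng(4).integers(0, 2, 12)]
    model = make_model(FT, FS, np.repeat([0, 1], 6))

    for pair, kept in [((0.60, 0.44), True), ((0.48, 0.50), False),
                       ((0.50, 0.50), True)]:
        def fake_ratio(i, FT_, FS_, m):
            out = np.zeros(2)
            out[1 - i] = pair[i]
            return out

        monkeypatch.setattr(mg, "replacement_ratio", fake_ratio)
        g = mg.build_graph(model, FT, FS, threshold=0.5)
        assert g.has_edge(0, 1) == kept


def test_graph_weights_symmetric_and_bounded(train_result, train_table,
                                             study_config):
    g = build_graph(train_result.model, train_table.ft, train_table.fs,
                    threshold=0.0)
    for i, j, w in g.edges(data="weight"):
        assert 0.0 <= w <= 1.0
    ratios = np.stack([replacement_ratio(i, train_table.ft, train_table.fs,
                                         train_result.model)
                       for i in range(train_result.model.k)])
    assert np.all(ratios >= 0) and np.all(ratios <= 1)


# ---------------------------------------------------------------------------
# map equation

from _graphs import ORACLE_GRAPHS


def test_merging_a_single_edge_pair_wins():
    g = ORACLE_GRAPHS["single-edge-pair"]
    together = map_equation(g, {0: 0, 1: 0})
    apart = map_equation(g, {0: 0, 1: 1})
    assert together == pytest.approx(1.0)  # H of two equal visit rates
    assert apart == pytest.approx(3.0)     # 1 bit index + 2x1 bit modules
    part = partition_graph(g, seed=0)
    assert len(set(part["communities"].values())) == 1


def test_two_bridged_cliques_split_into_two_communities():
    part = partition_graph(ORACLE_GRAPHS["two-4cliques-bridged"], seed=0)
    comm = part["communities"]
    assert len({comm[i] for i in range(4)}) == 1
    assert len({comm[i] for i in range(4, 8)}) == 1
    assert comm[0] != comm[4]


def test_edgeless_graph_gives_singletons():
    part = partition_graph(ORACLE_GRAPHS["edgeless-5"], seed=0)
    assert sorted(part["communities"].values()) == list(range(5))


@pytest.mark.parametrize("name", sorted(ORACLE_GRAPHS))
def test_greedy_matches_exhaustive_oracle(name):
    """Greedy description length equals the exhaustive optimum on <= 8 nodes."""
    g = ORACLE_GRAPHS[name]
    greedy = partition_graph(g, seed=0)
    exact = partition_graph_exhaustive(g)
    assert greedy["codelength"] == pytest.approx(exact["codelength"], abs=1e-9)


def test_partition_deterministic():
    g = ORACLE_GRAPHS["triangle-plus-tail"]
    p1 = partition_graph(g, seed=3)
    p2 = partition_graph(g, seed=3)
    assert p1["communities"] == p2["communities"]


# ---------------------------------------------------------------------------
# finalization

def test_singleton_communities_keep_ltp_centroids():
    rng = np.random.default_rng(5)
    FT = rng.dirichlet(np.ones(5), 12)
    FS = np.eye(3)[rng.integers(0, 3, 12)]
    hu = rng.uniform(-980, -850, 12)
    model = make_model(FT, FS, np.repeat([0, 1, 2], 4))
    sltp = finalize_sltps({0: 0, 1: 1, 2: 2}, model, FT, FS, hu)
    assert sltp.n_sltp == 3
    # ordering follows ascending mean attenuation, centroids preserved per LTP
    order = np.argsort([hu[model.labels == j].mean() for j in range(3)])
    for rank, j in enumerate(order):
        np.testing.assert_allclose(sltp.ft_centroids[rank],
                                   model.ft_centroids[j], atol=1e-12)
        assert sltp.member_ltps[rank] == [j]
    assert np.all(np.diff(sltp.mean_hu) >= 0)


def test_merging_equal_size_ltps_averages_centroids():
    rng = np.random.default_rng(6)
    FT = rng.dirichlet(np.ones(4), 8)
    FS = np.eye(2)[rng.integers(0, 2, 8)]
    hu = rng.uniform(-950, -900, 8)
    model = make_model(FT, FS, np.repeat([0, 1], 4))
    sltp = finalize_sltps({0: 0, 1: 0}, model, FT, FS, hu)
    assert sltp.n_sltp == 1
    np.testing.assert_allclose(sltp.ft_centroids[0],
                               0.5 * (model.ft_centroids[0] + model.ft_centroids[1]),
                               atol=1e-12)


def test_cohort_merge_compresses_and_covers(reference_model, train_result,
                                            train_table):
    sltp = reference_model["sltp"]
    assert sltp.n_sltp <= train_result.model.k
    assert np.isin(sltp.labels, np.arange(1, sltp.n_sltp + 1)).all()
    assert len(sltp.labels) == len(train_table)
    # centroids re-derivable as means over member ROIs
    for k in range(1, sltp.n_sltp + 1):
        sel = sltp.labels == k
        np.testing.assert_allclose(sltp.ft_centroids[k - 1],
                                   train_table.ft[sel].mean(0), atol=1e-9)


def test_merge_idempotent_when_patterns_are_distinct(reference_model,
                                                     train_table, study_config):
    """Re-merging the merged model changes nothing when no edge survives."""
    sltp = reference_model["sltp"]
    relabeled = sltp.labels - 1
    model = make_model(train_table.ft, train_table.fs, relabeled,
                       lam=sltp.lam, w=sltp.w)
    g = build_graph(model, train_table.ft, train_table.fs,
                    threshold=study_config.edge_threshold)
    if g.number_of_edges() == 0:
        again, _, _ = merge_ltps(model, train_table.ft, train_table.fs,
                                 train_table.mean_hu,
                                 threshold=study_config.edge_threshold, seed=0)
        assert again.n_sltp == sltp.n_sltp
        np.testing.assert_array_equal(again.labels, sltp.labels)
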