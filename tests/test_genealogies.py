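"""Local-tree extraction, breakpoints and TMRCA behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bacsim import (GenomeMap, IntervalSet, LocalTree, Parameters, TreeNode,
                    breakpoints, local_tree, segment_trees, simulate_arg,
                    tmrca)


def test_local_trees_equal_clonal_frame_without_recombination():
    g = GenomeMap.whole(50)
    arg, frame, _ = simulate_arg(Parameters(n=5, genome=g, seed=2))
    for site in (0, 10, 49):
        assert local_tree(arg, site).signature() == frame.signature()
    assert breakpoints(arg) == []
    assert len(segment_trees(arg)) == 1


def test_gap_site_is_an_error():
    g = GenomeMap(((20, 10), (20, 0)), circular=True)
    arg, _, _ = simulate_arg(Parameters(n=3, genome=g, seed=4))
    with pytest.raises(ValueError, match="gap"):
        local_tree(arg, 25)


def test_tmrca_examples():
    left = TreeNode(time=0.0, label="sample_1")
    right = TreeNode(time=0.0, label="sample_2")
    tree = LocalTree(root=TreeNode(time=0.7, children=[left, right]), n=2)
    assert tmrca(tree) == pytest.approx(0.7)
    imported = LocalTree(
        root=TreeNode(time=0.5, children=[left, right], import_div=0.2), n=2)
    with pytest.raises(ValueError):
        tmrca(imported)


@pytest.mark.parametrize("params", [
    dict(rho_int=0.03, delta_int=12),
    dict(rho_int=0.02, delta_int=15, rho_ext=0.02, delta_ext=10,
         div_min=0.1, div_max=0.3),
])
@pytest.mark.parametrize("seed", [1, 7, 23])
def test_segment_partition_matches_per_site_tree_classes(params, seed):
    g = GenomeMap.whole(120)
    arg, _, events = simulate_arg(Parameters(n=4, genome=g, seed=seed,
                                             **params))
    segs = segment_trees(arg)
    sigs = [local_tree(arg, s).signature() for s in range(120)]
    classes = [key for key, _ in itertools.groupby(sigs)]
    assert len(classes) == len(segs)
    for (start, end), tree in segs:
        span = IntervalSet([(start, end)]) & g.seq_intervals()
        for s in span.sites():
            assert sigs[s] == tree.signature()
    # boundaries come from recorded tract endpoints
    endpoint_pool = {0, 120}
    for ev in events:
        for s, e in ev.tract:
            endpoint_pool.update((s, e))
    assert set(breakpoints(arg)) <= endpoint_pool


def test_single_within_event_bounds_breakpoints():
    # find a replicate with exactly one within event; its tract endpoints
    # are the only possible segment boundaries
    g = GenomeMap.whole(200, circular=False)
    for seed in range(200):
        arg, frame, events = simulate_arg(
            Parameters(n=4, genome=g, rho_int=0.004, delta_int=20,
                       seed=seed))
        if len(events) == 1:
            break
    else:  # pragma: no cover
        pytest.fail("no single-event replicate found")
    (s0, e0), = [(iv[0][0], iv[-1][1])
                 for iv in [events[0].tract.intervals]]
    assert set(breakpoints(arg)) <= {s0, e0}
    # outside the tract the local tree is the clonal frame
    for site in (0, 199):
        if not events[0].tract.contains(site):
            assert local_tree(arg, site).signature() == frame.signature()


def test_local_trees_are_ultrametric_with_labelled_leaves():
    g = GenomeMap.whole(150)
    arg, _, _ = simulate_arg(Parameters(n=5, genome=g, rho_int=0.03,
                                        delta_int=10, seed=9))
    for site in (0, 75, 149):
        tree = local_tree(arg, site)
        assert tree.leaf_labels() == frozenset(
            f"sample_{i}" for i in range(1, 6))
        for leaf in tree.root.leaves():
            assert leaf.time == 0.0


def test_pairwise_site_tmrca_mean_is_one(rng):
    g = GenomeMap.whole(30)
    vals = []
    for _ in range(3000):
        arg, _, _ = simulate_arg(Parameters(n=2, genome=g), rng)
        vals.append(local_tree(arg, 3).tmrca)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 1.0) < 3 * se


def test_import_clades_carry_divergence_annotations():
    g = GenomeMap.whole(200)
    p = Parameters(n=4, genome=g, rho_ext=0.05, delta_ext=40,
                   div_min=0.2, div_max=0.5, seed=12)
    arg, _, events = simulate_arg(p)
    assert any(e.kind == "external" for e in events)
    found = False
    for (start, _end), tree in segment_trees(arg):
        for node in tree.root.postorder():
            if node.import_div is not None:
                assert 0.2 <= node.import_div <= 0.5
                found = True
    assert found


def test_newick_units_and_import_grafts():
    g = GenomeMap.whole(120)
    p = Parameters(n=4, genome=g, theta=0.02, rho_ext=0.05, delta_ext=40,
                   div_min=0.3, div_max=0.3, seed=12)
    arg, frame, events = simulate_arg(p)
    assert any(e.kind == "external" for e in events)
    tagged = [t for _, t in segment_trees(arg)
              if any(n.import_div is not None
                     for n in t.root.postorder())]
    assert tagged
    nwk = tagged[0].newick(theta=p.theta)
    # import edge: branch length 2d/theta, comment-tagged
    assert "[&import,d=0.3]" in nwk
    assert f"{2 * 0.3 / p.theta:.10g}" in nwk
    # substitution units scale everything by theta/2
    coal = frame.newick(theta=p.theta, substitution_units=True)
    t_sub = float(coal.rsplit(":", 1)[1].rstrip(");\n"))
    assert t_sub < 1.0  # theta/2 = 0.01 shrinks coalescent-unit lengths


def test_tmrca_correlation_decays_with_distance(rng):
    g = GenomeMap.whole(3000, circular=False)
    p = Parameters(n=2, genome=g, rho_int=0.01, delta_int=100)
    near, far = [], []
    base = []
    for _ in range(1500):
        arg, _, _ = simulate_arg(p, rng)
        base.append(local_tree(arg, 0).tmrca)
        near.append(local_tree(arg, 20).tmrca)
        far.append(local_tree(arg, 2800).tmrca)
    r_near = stats.pearsonr(base, near).statistic
    r_far = stats.pearsonr(base, far).statistic
    assert r_near > r_far


def test_circular_tmrca_correlation_is_rotation_symmetric(rng):
    # distance k and G-k are equivalent on a circle
    g = GenomeMap.whole(400, circular=True)
    p = Parameters(n=2, genome=g, rho_int=0.02, delta_int=40)
    base, at_k, at_gk = [], [], []
    for _ in range(1500):
        arg, _, _ = simulate_arg(p, rng)
        base.append(local_tree(arg, 0).tmrca)
        at_k.append(local_tree(arg, 100).tmrca)
        at_gk.append(local_tree(arg, 300).tmrca)
    r1 = np.arctanh(stats.pearsonr(base, at_k).statistic)
    r2 = np.arctanh(stats.pearsonr(base, at_gk).statistic)
    se = 2.0 / np.sqrt(len(base) - 3)   # two Fisher-z draws
    assert abs(r1 - r2) < 3.5 * se
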