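"""Backward-in-time ARG simulation: structure, rates and distributions."""

import numpy as np
import pytest
from scipy import stats

from bacsim import (GenomeMap, IntervalSet, Parameters, clonal_frame,
                    simulate_arg)
from bacsim.argsim import _sample_within
from bacsim.oracle import coalescent_expectations, rejection_simulate_arg


def test_no_recombination_gives_plain_coalescent_tree():
    g = GenomeMap.whole(100)
    arg, frame, events = simulate_arg(Parameters(n=7, genome=g, seed=1))
    assert len(events) == 0
    assert len(arg.nodes) == 2 * 7 - 1
    kinds = [nd.kind for nd in arg.nodes]
    assert kinds.count("leaf") == 7
    assert kinds.count("coalescence") + kinds.count("root") == 6
    assert frame.leaf_labels() == frozenset(
        f"sample_{i}" for i in range(1, 8))


def test_leaves_have_time_zero_and_full_material():
    g = GenomeMap(((40, 10), (30, 20)), circular=True)
    arg, _, _ = simulate_arg(Parameters(n=4, genome=g, rho_int=0.05,
                                        delta_int=8, seed=3))
    for i in range(4):
        node = arg.nodes[i]
        assert node.kind == "leaf"
        assert node.time == 0.0
        assert node.material == g.seq_intervals()


def test_times_increase_rootward_and_splits_partition_material():
    g = GenomeMap.whole(300)
    arg, _, events = simulate_arg(Parameters(n=5, genome=g, rho_int=0.05,
                                             delta_int=20, seed=11))
    assert len(events) > 0
    for node in arg.nodes:
        for child_id, _role in node.children:
            assert node.time > arg.nodes[child_id].time
        if node.kind == "recomb_split":
            donor = node.donor_material
            recip = node.recipient_material
            assert donor and recip
            assert (donor & recip).is_empty
            assert donor | recip == node.material


def test_event_times_are_chronological_and_tracts_touch_material():
    g = GenomeMap.whole(300)
    arg, _, events = simulate_arg(
        Parameters(n=5, genome=g, rho_int=0.03, delta_int=20, rho_ext=0.02,
                   delta_ext=15, div_min=0.1, div_max=0.4, seed=5))
    times = [ev.time for ev in events]
    assert times == sorted(times)
    for ev in events:
        node = arg.nodes[ev.lineage]
        # tract overlapped the recipient's material when the event fired
        assert ev.tract & (node.material if node.material is not None
                           else g.seq_intervals())
        if ev.kind == "external":
            assert 0.1 <= ev.divergence <= 0.4
        else:
            assert ev.divergence is None


def test_fixed_seed_reproduces_identical_run():
    g = GenomeMap.whole(500)
    p = Parameters(n=6, genome=g, theta=0.02, rho_int=0.04, delta_int=25,
                   rho_ext=0.01, delta_ext=30, div_min=0.0, div_max=0.3,
                   seed=42)
    arg1, frame1, ev1 = simulate_arg(p)
    arg2, frame2, ev2 = simulate_arg(p)
    assert frame1.newick(theta=p.theta) == frame2.newick(theta=p.theta)
    assert [(e.kind, e.time, e.lineage, e.tract, e.divergence)
            for e in ev1] == \
        [(e.kind, e.time, e.lineage, e.tract, e.divergence) for e in ev2]


def test_clonal_tmrca_mean_matches_coalescent(rng):
    e_tmrca, _ = coalescent_expectations(10)
    g = GenomeMap.whole(50)
    vals = [simulate_arg(Parameters(n=10, genome=g), rng)[1].tmrca
            for _ in range(3000)]
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - e_tmrca) < 3 * se


def test_high_recombination_leaves_clonal_frame_law_unchanged(rng):
    # splits never remove the clonal lineage, so the clonal genealogy stays
    # a plain n-coalescent whatever R is
    g = GenomeMap.whole(400)
    t_rec, t_none = [], []
    for _ in range(2500):
        _, f, _ = simulate_arg(Parameters(n=5, genome=g, rho_int=0.05,
                                          delta_int=30), rng)
        t_rec.append(f.tmrca)
        _, f, _ = simulate_arg(Parameters(n=5, genome=g), rng)
        t_none.append(f.tmrca)
    assert stats.ks_2samp(t_rec, t_none).pvalue > 0.001


def test_crossover_limit_of_huge_tracts(rng):
    # delta -> infinity on a linear genome degenerates gene conversion
    # toward a crossover at s: the tract runs to the end of the genome
    g = GenomeMap.whole(200, circular=False)
    material = IntervalSet([(0, 200)])
    for _ in range(300):
        s, l, tract = _sample_within(material, g, 1e12, rng)
        if s > 0:
            assert tract.intervals[-1][1] == 200


def test_rate_convention_raw_initiation_count(rng):
    # raw within-candidates are Poisson with mean (R/2) * G * (integrated
    # lineage time) -- this pins the R/2-per-site-per-lineage convention
    R, G = 0.01, 200
    g = GenomeMap.whole(G, circular=False)
    p = Parameters(n=2, genome=g, rho_int=R, delta_int=5)
    raw_total, time_total = 0, 0.0
    for _ in range(3000):
        _, _, _, st_ = rejection_simulate_arg(p, rng)
        raw_total += st_.raw_within
        time_total += st_.lineage_time
    expected = 0.5 * R * G * time_total
    assert abs(raw_total - expected) < 3 * np.sqrt(expected)


def test_external_event_count_and_raw_lengths(rng):
    # R=0, R_e>0: expected import count is (R_e/2) * G * E[L_total] with
    # near-full material (delta_e=1 keeps removals negligible), and raw
    # tract lengths are geometric with mean delta_e
    G, Re = 2000, 1e-3
    g = GenomeMap.whole(G)
    p = Parameters(n=2, genome=g, rho_ext=Re, delta_ext=1.0)
    counts = []
    for _ in range(3000):
        _, _, ev = simulate_arg(p, rng)
        counts.append(len(ev))
    expected = 0.5 * Re * G * 2.0   # (R_e/2) * G * E[L_total], E[L_total]=2
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 3 * se

    pgeo = Parameters(n=2, genome=GenomeMap.whole(5000), rho_ext=2e-4,
                      delta_ext=6.0)
    lengths = []
    while len(lengths) < 2000:
        _, _, ev = simulate_arg(pgeo, rng)
        lengths.extend(e.raw_length for e in ev)
    lengths = np.array(lengths)
    kmax = 25
    obs = np.bincount(np.minimum(lengths, kmax), minlength=kmax + 1)[1:]
    pk = np.array([(1 / 6.0) * (5 / 6.0) ** (k - 1)
                   for k in range(1, kmax)] + [(5 / 6.0) ** (kmax - 1)])
    p_val = stats.chisquare(obs, pk * len(lengths)).pvalue
    assert p_val > 0.001


def test_event_cap_raises():
    g = GenomeMap.whole(2000)
    p = Parameters(n=10, genome=g, rho_int=0.1, delta_int=100, seed=0)
    with pytest.raises(RuntimeError, match="event cap"):
        simulate_arg(p, max_events=10)


def test_clonal_frame_function_matches_simulator_output():
    g = GenomeMap.whole(400)
    p = Parameters(n=6, genome=g, rho_int=0.04, delta_int=25, seed=8)
    arg, frame, _ = simulate_arg(p)
    assert clonal_frame(arg).signature() == frame.signature()
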