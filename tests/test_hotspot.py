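"""hotspot: candidate enumeration, bootstrap null, p-values, BH, track.

The independent oracles here are exhaustive: interval membership by direct
counting, the null distribution by enumerating all L^m equally likely
draws, and BH by literal evaluation of the min-over-j step-up formula.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nupvar.hotspot import (
    Candidate,
    bh_adjust,
    build_null,
    call_hotspots,
    cluster_pvalue,
    enumerate_candidate_clusters,
)


def _oracle_candidates(positions):
    distinct = sorted(set(positions))
    out = []
    for start, end in itertools.combinations_with_replacement(distinct, 2):
        n = sum(1 for p in positions if start <= p <= end)
        out.append((start, end, n))
    return out


class TestEnumerate:
    def test_single_position(self):
        assert enumerate_candidate_clusters([5]) == [Candidate(5, 5, 1)]

    def test_two_positions(self):
        assert enumerate_candidate_clusters([3, 10]) == [
            Candidate(3, 3, 1),
            Candidate(3, 10, 2),
            Candidate(10, 10, 1),
        ]

    def test_empty(self):
        assert enumerate_candidate_clusters([]) == []

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=8))
    def test_matches_brute_force(self, positions):
        candidates = enumerate_candidate_clusters(positions)
        expected = _oracle_candidates(positions)
        assert sorted((c.start, c.end, c.n_variants) for c in candidates) == sorted(expected)
        d = len(set(positions))
        assert len(candidates) == d * (d + 1) // 2


def _oracle_min_width(draw, c):
    s = sorted(draw)
    return min(s[j + c - 1] - s[j] + 1 for j in range(len(s) - c + 1))


def _exact_tail(m, L, c, span):
    """P(min window span containing c of m uniform draws <= span), exactly."""
    hits = sum(
        1
        for draw in itertools.product(range(1, L + 1), repeat=m)
        if _oracle_min_width(draw, c) <= span
    )
    return hits / L**m


class TestNullModel:
    def test_singletons_have_width_one(self):
        null = build_null(m=1, L=50, B=20, seed=1)
        assert (null.min_width_table[:, 0] == 1).all()

    def test_m2_L2_outcome_set(self):
        null = build_null(m=2, L=2, B=200, seed=1)
        assert set(null.min_width_table[:, 1]) <= {1, 2}

    def test_min_width_nondecreasing_in_count(self):
        null = build_null(m=6, L=100, B=50, seed=2)
        assert (np.diff(null.min_width_table, axis=1) >= 0).all()

    def test_reproducible_per_seed(self):
        a = build_null(m=5, L=100, B=30, seed=7)
        b = build_null(m=5, L=100, B=30, seed=7)
        assert (a.min_width_table == b.min_width_table).all()

    def test_pair_width_distribution_matches_exact_enumeration(self):
        # m=2, L=10: 100 equally likely draws; compare empirical frequencies
        m, L, B = 2, 10, 10_000
        null = build_null(m=m, L=L, B=B, seed=5)
        for width in (1, 3, 6):
            exact = _exact_tail(m, L, 2, width)
            empirical = np.mean(null.min_width_table[:, 1] <= width)
            se = math.sqrt(exact * (1 - exact) / B) or 1 / B
            assert abs(empirical - exact) <= 3 * se


class TestClusterPvalue:
    def test_singleton_always_p_one(self):
        null = build_null(m=4, L=100, B=99, seed=3)
        assert cluster_pvalue(Candidate(10, 10, 1), null) == 1.0

    def test_whole_protein_always_p_one(self):
        null = build_null(m=4, L=100, B=99, seed=3)
        assert cluster_pvalue(Candidate(1, 100, 4), null) == 1.0

    def test_oversized_candidate_rejected(self):
        null = build_null(m=2, L=100, B=10, seed=3)
        with pytest.raises(ValueError):
            cluster_pvalue(Candidate(1, 10, 3), null)

    @pytest.mark.parametrize("m,L", [(2, 8), (3, 6), (3, 10)])
    def test_matches_exhaustive_enumeration(self, m, L):
        B = 4000
        null = build_null(m=m, L=L, B=B, seed=11)
        for c in range(2, m + 1):
            for span in range(1, L + 1, max(1, L // 4)):
                exact = _exact_tail(m, L, c, span)
                p = cluster_pvalue(Candidate(1, span, c), null)
                se = math.sqrt(max(exact * (1 - exact), 1e-9) / B)
                assert abs(p - exact) <= 3 * se + 2 / (B + 1)

    def test_monotone_in_span_and_count(self):
        null = build_null(m=8, L=200, B=500, seed=13)
        spans = [1, 5, 20, 80, 200]
        for n in (2, 5, 8):
            ps = [cluster_pvalue(Candidate(1, s, n), null) for s in spans]
            assert ps == sorted(ps)
        for s in (5, 40):
            ps = [cluster_pvalue(Candidate(1, s, n), null) for n in range(2, 9)]
            assert ps == sorted(ps, reverse=True)


def _oracle_bh(p):
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(p[j] * n / (rank_pos_j) for rank_pos_j, j in enumerate(order, 1) if rank_pos_j >= rank_pos),
            1.0,
        )
    return q


class TestBH:
    def test_all_equal(self):
        q, sig = bh_adjust([0.03] * 5)
        assert np.allclose(q, 0.03) and sig.all()

    def test_hand_derived_example(self):
        q, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    def test_empty(self):
        q, sig = bh_adjust([])
        assert q.size == 0 and sig.size == 0

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force(self, p):
        q, sig = bh_adjust(p, alpha=0.05)
        expected = _oracle_bh(p)
        assert np.allclose(q, expected)
        assert (sig == (q <= 0.05)).all()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1, size=40)
        q, _ = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)


class TestCallHotspots:
    def test_no_signal_gives_zero_track(self):
        calls, track = call_hotspots([5, 400, 801, 1200], L=1391, B=100, seed=1)
        if not any(c.significant for c in calls):
            assert (track.counts == 0).all()

    def test_track_conservation(self):
        rng = np.random.default_rng(3)
        pos = list(rng.integers(650, 680, size=12)) + list(rng.integers(1, 1392, size=12))
        calls, track = call_hotspots(pos, L=1391, B=300, seed=9)
        sig_span_sum = sum(c.span for c in calls if c.significant)
        assert track.counts.sum() == sig_span_sum

    def test_deterministic_per_seed(self):
        pos = [10, 12, 14, 500, 900]
        a = call_hotspots(pos, L=1000, B=150, seed=21)
        b = call_hotspots(pos, L=1000, B=150, seed=21)
        assert a[0] == b[0]
        assert (a[1].counts == b[1].counts).all()

    def test_position_bounds_checked(self):
        with pytest.raises(ValueError):
            call_hotspots([5, 2000], L=1391, B=10, seed=0)
        with pytest.raises(ValueError):
            call_hotspots([], L=1391, B=10, seed=0)

    def test_planted_cluster_recovered(self):
        """12 of 24 variants packed into a 100-residue window are flagged in
        >= 90% of seeded runs (bootstrap at the default size)."""
        hits = 0
        for run in range(50):
            rng = np.random.default_rng(100 + run)
            win = int(rng.integers(1, 1391 - 99))
            pos = list(rng.integers(win, win + 100, size=12)) + list(
                rng.integers(1, 1392, size=12)
            )
            calls, _ = call_hotspots(pos, L=1391, B=1000, alpha=0.05, seed=300 + run)
            hits += any(
                c.significant and c.start <= win + 99 and c.end >= win for c in calls
            )
        assert hits >= 45

    def test_uniform_null_false_discovery_controlled(self):
        """Mean false-discovery proportion under the uniform null stays
        below 0.10 (m=24, L=1391, B=200, alpha=0.05, 50 runs)."""
        fdp = []
        for run in range(50):
            rng = np.random.default_rng(700 + run)
            pos = list(rng.integers(1, 1392, size=24))
            calls, _ = call_hotspots(pos, L=1391, B=200, alpha=0.05, seed=900 + run)
            n_sig = sum(c.significant for c in calls)
            fdp.append(1.0 if n_sig else 0.0)  # every call is false here
        assert float(np.mean(fdp)) <= 0.10
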