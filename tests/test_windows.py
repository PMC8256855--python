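"""Sliding-window genotyping: painting, smoothing, blocks, bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bluebin as bb
from bluebin.core import MISSING, STATE_A, STATE_B, SnpMatrix
from bluebin.windows import (blocks_from_states, call_window, correct_track,
                             smooth_states)

A, B, M = STATE_A, STATE_B, MISSING


def _track_matrix(parent_rows, progeny_rows, marker_types):
    """Single-scaffold SnpMatrix from explicit calls and marker types."""
    calls = np.array([list(p) + list(k) for p, k in
                      zip(parent_rows, progeny_rows)], dtype=np.int8)
    n = calls.shape[0]
    sites = pd.DataFrame({
        "scaffold": ["scf1"] * n, "pos": np.arange(1, n + 1) * 10,
        "ref": ["A"] * n, "alt": ["C"] * n,
        "qual": [90.0] * n, "mean_depth": [20.0] * n,
        "marker_type": marker_types,
    })
    samples = ["P1", "P2"] + [f"K{i}" for i in range(calls.shape[1] - 2)]
    return SnpMatrix(sites=sites, calls=calls, samples=samples, parents=("P1", "P2"))


class TestPainting:
    def test_painting_rules(self):
        AB, AA, BB, NA = bb.AB, bb.AA, bb.BB, bb.MISSING
        m = _track_matrix(
            parent_rows=[(AA, AB), (AA, AB), (AA, AB), (AB, AA), (AB, AB),
                         (AB, AB), (AB, AB)],
            progeny_rows=[(AA,), (AB,), (BB,), (BB,), (AA,), (AB,), (BB,)],
            marker_types=["P2HET"] * 3 + ["P1HET"] + ["BOTHHET"] * 3,
        )
        tracks = bb.paint_transmitted_alleles(m)
        p2 = tracks["P2"]["scf1"]
        # P2HET sites: AA->A, AB->B, BB->Mendelian error (missing)
        assert list(p2.states[:3, 0]) == [A, B, M]
        p1 = tracks["P1"]["scf1"]
        # P1HET site with BB progeny is impossible -> missing + flagged
        assert p1.states[list(p1.site_rows).index(3), 0] == M
        assert p1.n_mendel_errors >= 1
        # BOTHHET: AA -> (A, A), AB -> missing on both, BB -> (B, B)
        r1 = [list(p1.site_rows).index(i) for i in (4, 5, 6)]
        r2 = [list(p2.site_rows).index(i) for i in (4, 5, 6)]
        assert list(p1.states[r1, 0]) == [A, M, B]
        assert list(p2.states[r2, 0]) == [A, M, B]

    def test_informative_sites_per_track(self):
        m = _track_matrix(
            parent_rows=[(bb.AB, bb.AA), (bb.AA, bb.AB), (bb.AB, bb.AB)],
            progeny_rows=[(bb.AA,)] * 3,
            marker_types=["P1HET", "P2HET", "BOTHHET"],
        )
        tracks = bb.paint_transmitted_alleles(m)
        assert list(tracks["P1"]["scf1"].site_rows) == [0, 2]
        assert list(tracks["P2"]["scf1"].site_rows) == [1, 2]


class TestCallWindow:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([B] * 9 + [A] * 4 + [M] * 2, B),  # strict majority
            ([A] * 6 + [B] * 6 + [M] * 3, M),  # tie
            ([M] * 15, M),                      # all missing
            ([A] * 4 + [M] * 11, M),            # below minimum support
            ([A] * 5 + [M] * 10, A),            # exactly at minimum support
        ],
    )
    def test_dominant_rule(self, states, expected):
        assert call_window(states, 15) == expected


class TestSlide:
    def test_constant_track_single_block(self):
        sm = smooth_states(np.full(30, A, dtype=np.int8))
        assert blocks_from_states(sm) == [(0, 29, A)]

    def test_clean_transition_two_blocks(self):
        track = np.array([A] * 20 + [B] * 20, dtype=np.int8)
        sm = smooth_states(track)
        assert blocks_from_states(sm) == [(0, 19, A), (20, 39, B)]

    def test_singleton_error_smoothed_away(self):
        track = np.array([A] * 20 + [B] + [A] * 19, dtype=np.int8)
        sm = smooth_states(track)
        assert blocks_from_states(sm) == [(0, 39, A)]

    def test_smoothing_idempotent_on_block_constant_tracks(self):
        track = np.array([A] * 25 + [B] * 25, dtype=np.int8)
        once = smooth_states(track)
        twice = smooth_states(once)
        assert np.array_equal(once, twice)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from([A, B, M]), min_size=1, max_size=80))
    def test_smoothed_output_states_valid_and_idempotent(self, states):
        track = np.array(states, dtype=np.int8)
        sm = smooth_states(track)
        assert set(np.unique(sm)) <= {A, B, M}
        runs = blocks_from_states(sm)
        for (s1, e1, v1), (s2, e2, v2) in zip(runs, runs[1:]):
            assert s1 <= e1 < s2 <= e2
            assert v1 != v2  # adjacent blocks differ in state


class TestBreakpoints:
    def test_clean_boundary_breakpoint(self):
        m = _track_matrix(
            parent_rows=[(bb.AB, bb.AA)] * 40,
            progeny_rows=[(bb.AA,)] * 20 + [(bb.AB,)] * 20,
            marker_types=["P1HET"] * 40,
        )
        tracks, corrected, bps = bb.genotype_population(m)
        assert len(bps) == 1
        assert (bps[0].left_site, bps[0].right_site) == (19, 20)
        assert bps[0].midpoint_bp == pytest.approx((200 + 210) / 2)

    def test_single_block_no_breakpoints(self):
        m = _track_matrix(
            parent_rows=[(bb.AB, bb.AA)] * 30,
            progeny_rows=[(bb.AA,)] * 30,
            marker_types=["P1HET"] * 30,
        )
        _, _, bps = bb.genotype_population(m)
        assert bps == []

    def test_recovery_on_simulated_population(self, pop):
        # sanity bound at the small shared-fixture scale; the stringent
        # check runs at full population scale in the acceptance suite
        rec = bb.score_breakpoint_recovery(pop.truth, pop.filtered,
                                           pop.tracks, pop.breakpoints)
        assert rec["recovery_rate"] >= 0.7
        assert rec["false_positive_rate"] < 0.1


class TestBins:
    def test_enumerated_profile_changes(self):
        # 4 individuals; profile changes at sites 10 and 25 of 40 -> 3 bins
        AB, AA = bb.AB, bb.AA
        prog = np.zeros((40, 4), dtype=np.int8)
        prog[:, :] = AA
        prog[10:, 0] = AB   # individual 0 switches at site 10
        prog[25:, 1] = AB   # individual 1 switches at site 25
        m = _track_matrix(
            parent_rows=[(AB, AA)] * 40,
            progeny_rows=[tuple(r) for r in prog],
            marker_types=["P1HET"] * 40,
        )
        tracks, corrected, _ = bb.genotype_population(m, window_size=5)
        bs = bb.deduce_bins(m, tracks, corrected)
        assert bs.n_bins == 3
        assert list(bs.bins["n_snps"]) == [10, 15, 15]

    def test_no_crossovers_one_bin_per_scaffold(self):
        m = _track_matrix(
            parent_rows=[(bb.AB, bb.AA)] * 30,
            progeny_rows=[(bb.AA, bb.AB)] * 30,
            marker_types=["P1HET"] * 30,
        )
        tracks, corrected, _ = bb.genotype_population(m)
        bs = bb.deduce_bins(m, tracks, corrected)
        assert bs.n_bins == 1

    def test_snp_conservation(self, pop):
        # bins tile scaffolds: per-scaffold bin SNPs equal filtered sites
        per_scaffold = pop.binset.bins.groupby("scaffold")["n_snps"].sum()
        expected = pop.filtered.sites.groupby("scaffold").size()
        assert per_scaffold.sort_index().equals(expected.sort_index())


class TestWindowLadder:
    def test_noise_free_parents_select_smallest(self):
        tracks = [np.full(200, bb.AB, dtype=np.int8)]
        chosen, curve = bb.select_window_size(tracks)
        assert chosen == 5
        assert (curve["score"] == 1.0).all()

    def test_score_plateaus_with_window_size_on_noisy_data(self):
        rng = np.random.default_rng(31)
        tracks = []
        for _ in range(20):
            t = np.full(400, bb.AB, dtype=np.int8)
            # low-coverage miscalls: het read as hom a few % of the time
            miss = rng.random(400) < 0.05
            t[miss] = rng.choice([bb.AA, bb.BB], size=miss.sum())
            tracks.append(t)
        chosen, curve = bb.select_window_size(tracks)
        scores = curve["score"].to_numpy()
        # non-decreasing up to its plateau (tiny wiggle tolerance)
        assert (np.diff(scores) >= -0.005).all()
        assert scores[-1] >= scores[0]

    def test_override_skips_ladder(self):
        chosen, _ = bb.select_window_size([], override=15)
        assert chosen == 15

    def test_empty_ladder_rejected(self):
        with pytest.raises(ValueError):
            bb.select_window_size([np.full(10, bb.AB, np.int8)], ladder=())


class TestCorrection:
    def test_corrected_track_fills_breakpoint_gap(self):
        # A-block, ambiguous gap, B-block: correction assigns every site
        track = np.array([A] * 18 + [M] * 4 + [B] * 18, dtype=np.int8)
        m = _track_matrix(
            parent_rows=[(bb.AB, bb.AA)] * 40,
            progeny_rows=[({A: bb.AA, B: bb.AB, M: bb.MISSING}[s],) for s in track],
            marker_types=["P1HET"] * 40,
        )
        tracks, corrected, bps = bb.genotype_population(m)
        corr = corrected["P1"]["scf1"][:, 0]
        assert (corr != M).all()
        assert len(bps) == 1
        changes = np.flatnonzero(np.diff(corr))
        assert len(changes) == 1
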