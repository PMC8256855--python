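"""Interval mapping: conditional probabilities, LOD scans, thresholds,
support intervals, variance explained, multi-year reporting."""

import math

import numpy as np
import pandas as pd
import pytest

import bluebin as bb
from bluebin.core import MISSING
from bluebin.qtl import (QtlPeak, ScanConfig, ScanEngine, _r2_from_lod,
                         qtl_interval, variance_explained)


def _states(rows):
    return np.asarray(rows, dtype=np.int8)


class TestGenotypeProbabilities:
    def test_at_bin_is_indicator(self):
        pos = np.array([0.0, 10.0])
        s = _states([[1, 0], [0, 0]])
        p = bb.genotype_probabilities(0.0, pos, s, np.full_like(s, MISSING))
        assert p[0, 0] == pytest.approx(1.0)
        assert p[1, 0] == pytest.approx(0.0)

    def test_midpoint_between_opposite_flanks_is_half(self):
        pos = np.array([0.0, 10.0])
        s = _states([[0], [1]])
        p = bb.genotype_probabilities(5.0, pos, s, np.full_like(s, MISSING))
        assert p[0, 0] == pytest.approx(0.5)

    def test_asymmetric_position_matches_enumeration_oracle(self):
        # 2 cM from an A flank, 8 cM from a B flank: enumerate the four
        # (recombination in left interval) x (right interval) outcomes
        pos = np.array([0.0, 10.0])
        s = _states([[0], [1]])
        p = bb.genotype_probabilities(2.0, pos, s, np.full_like(s, MISSING))
        rl, rr = bb.kosambi_inverse(2.0), bb.kosambi_inverse(8.0)
        num = {0: 0.0, 1: 0.0}
        for rec_l in (0, 1):
            for rec_r in (0, 1):
                w = (rl if rec_l else 1 - rl) * (rr if rec_r else 1 - rr)
                x = rec_l  # state at test position given left flank A
                right = x ^ rec_r
                if right == 1:  # condition on observed right flank B
                    num[x] += w
        expected = num[1] / (num[0] + num[1])
        assert p[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_missing_flank_falls_back_to_single_flank(self):
        pos = np.array([0.0, 10.0])
        s = _states([[0], [MISSING]])
        p = bb.genotype_probabilities(8.0, pos, s, np.full_like(s, MISSING))
        assert p[0, 0] == pytest.approx(bb.kosambi_inverse(8.0))

    def test_no_information_is_half(self):
        pos = np.array([0.0])
        s = _states([[MISSING]])
        p = bb.genotype_probabilities(0.0, pos, s, s.copy())
        assert p[0, 0] == pytest.approx(0.5)


def _toy_mapped_binset(seed=0, n_ind=50):
    """Hand-built three-bin map with complete (no-missing) states."""
    from bluebin.windows import BinSet
    rng = np.random.default_rng(seed)
    s1 = rng.integers(0, 2, size=(3, n_ind)).astype(np.int8)
    s2 = rng.integers(0, 2, size=(3, n_ind)).astype(np.int8)
    bins = pd.DataFrame({
        "bin_id": ["bin0", "bin1", "bin2"], "scaffold": ["s"] * 3,
        "start_local": range(3), "end_local": range(3),
        "start_row": range(3), "end_row": range(3),
        "start_bp": [1, 100, 200], "end_bp": [50, 150, 250],
        "n_snps": [5, 5, 5],
    })
    binset = BinSet(bins=bins, states_p1=s1, states_p2=s2,
                    individuals=[f"K{i}" for i in range(n_ind)])
    table = pd.DataFrame({
        "lg": [1, 1, 1], "order": [0, 1, 2],
        "bin_id": bins["bin_id"], "bin_index": [0, 1, 2],
        "position_cm": [0.0, 5.0, 10.0], "scaffold": ["s"] * 3,
        "start_bp": bins["start_bp"], "end_bp": bins["end_bp"],
        "n_snps": bins["n_snps"],
    })
    return binset, bb.GeneticMap(table=table, unplaced=np.empty(0, int))


class TestScan:
    def test_perfect_signal_peaks_at_bin_with_r2_one(self, mapped_pop):
        pop, gmap = mapped_pop
        bi = int(gmap.table["bin_index"].iloc[len(gmap.table) // 2])
        lg = int(gmap.table.set_index("bin_index").loc[bi, "lg"])
        states = pop.binset.states_p1[bi]
        ok = states != MISSING
        y = pd.Series(states[ok].astype(float),
                      index=np.array(pop.binset.individuals)[ok])
        cfg = ScanConfig(n_permutations=0, min_n=10)
        res = bb.scan_trait(gmap, pop.binset, y, cfg, threshold=3.0)
        assert res.peaks
        top = max(res.peaks, key=lambda p: p.peak_lod)
        assert top.lg == lg
        want = float(gmap.table.set_index("bin_index").loc[bi, "position_cm"])
        assert abs(top.peak_cm - want) < 1.0
        assert top.r_squared > 0.95

    def test_lod_invariant_to_affine_phenotype_transform(self, mapped_pop):
        pop, gmap = mapped_pop
        rng = np.random.default_rng(1)
        inds = pop.binset.individuals
        y = pd.Series(rng.normal(size=len(inds)), index=inds)
        eng = ScanEngine(gmap, pop.binset, individuals=inds)
        l1 = eng.lod_profile(y.to_numpy())
        l2 = eng.lod_profile(3.5 * y.to_numpy() - 11.0)
        assert np.allclose(l1, l2, atol=1e-8)

    def test_profile_at_bin_equals_single_marker_regression(self):
        # at a bin position the design is the bin's 0/1 indicators, so
        # the scan LOD must equal an explicit least-squares regression
        binset, gmap = _toy_mapped_binset(seed=2)
        n = len(binset.individuals)
        rng = np.random.default_rng(21)
        y = binset.states_p1[1] + 0.5 * binset.states_p2[1] + rng.normal(0, 1, n)
        eng = ScanEngine(gmap, binset)
        gi = int(np.argmin(np.abs(eng.grid["position_cm"].to_numpy() - 5.0)))
        assert eng.grid["position_cm"].iat[gi] == 5.0
        lod_scan = eng.lod_profile(y)[gi, 0]
        X = np.column_stack([np.ones(n), binset.states_p1[1], binset.states_p2[1]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ beta) ** 2).sum()
        rss0 = ((y - y.mean()) ** 2).sum()
        lod_reg = n / 2 * math.log10(rss0 / rss1)
        assert lod_scan == pytest.approx(lod_reg, abs=1e-8)

    def test_constant_phenotype_rejected(self, mapped_pop):
        pop, gmap = mapped_pop
        y = pd.Series(1.0, index=pop.binset.individuals)
        with pytest.raises(ValueError, match="constant"):
            bb.scan_trait(gmap, pop.binset, y, ScanConfig(n_permutations=0))


class TestPermutations:
    def test_same_seed_same_cutoff(self, mapped_pop):
        pop, gmap = mapped_pop
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(pop.binset.individuals))
        eng = ScanEngine(gmap, pop.binset)
        cfg = ScanConfig(n_permutations=120, seed=77)
        c1, _ = bb.permutation_threshold(eng, y, cfg)
        c2, _ = bb.permutation_threshold(eng, y, cfg)
        assert c1 == c2

    def test_alpha_one_gives_minimum_of_maxima(self, mapped_pop):
        pop, gmap = mapped_pop
        rng = np.random.default_rng(4)
        y = rng.normal(size=len(pop.binset.individuals))
        eng = ScanEngine(gmap, pop.binset)
        cfg = ScanConfig(n_permutations=120, seed=5, alpha=1.0)
        cutoff, maxima = bb.permutation_threshold(eng, y, cfg)
        assert cutoff == maxima.min()


class TestInterval:
    def test_triangular_profile_hand_computed(self):
        # peak 10 at 50 cM, slope 0.5/cM: LOD-1 drop points at 48 and 52
        pos = np.arange(40.0, 60.5, 0.5)
        lods = 10.0 - 0.5 * np.abs(pos - 50.0)
        bins = np.arange(40.0, 61.0, 1.0)
        peak = int(np.argmax(lods))
        (ci, first, last, tl, tr) = qtl_interval(pos, lods, peak, bins)
        assert ci == (48.0, 52.0)
        assert not tl and not tr

    def test_peak_at_edge_flagged_truncated(self):
        pos = np.arange(0.0, 10.5, 0.5)
        lods = 10.0 - 0.5 * pos
        bins = np.arange(0.0, 11.0, 1.0)
        (_, _, _, tl, tr) = qtl_interval(pos, lods, 0, bins)
        assert tl and not tr

    def test_flat_profile_below_threshold_yields_no_peak(self, mapped_pop):
        pop, gmap = mapped_pop
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=len(pop.binset.individuals)),
                      index=pop.binset.individuals)
        res = bb.scan_trait(gmap, pop.binset, y, ScanConfig(n_permutations=0),
                            threshold=1e9)
        assert res.peaks == []


class TestVarianceExplained:
    @pytest.mark.parametrize("r2,h2,expected", [(0.30, 0.86, 0.35),
                                                (0.44, 0.67, 0.66),
                                                (0.0, 0.9, 0.0)])
    def test_ratio_values(self, r2, h2, expected):
        got_r2, ratio, capped = variance_explained(1.0, 1.0 - r2, h2)
        assert got_r2 == pytest.approx(r2)
        assert round(ratio, 2) == expected
        assert not capped

    def test_ratio_capped_at_one(self):
        # mirrors a published row where R2 exceeds H2 (0.63 vs 0.47)
        _, ratio, capped = variance_explained(1.0, 1.0 - 0.63, 0.47)
        assert ratio == 1.0 and capped

    def test_r2_without_h2(self):
        r2, ratio, capped = variance_explained(10.0, 5.0)
        assert r2 == pytest.approx(0.5)
        assert ratio is None

    def test_r2_from_lod_consistency(self):
        n = 117
        for r2 in (0.1, 0.3, 0.6):
            lod = n / 2 * math.log10(1 / (1 - r2))
            assert _r2_from_lod(lod, n) == pytest.approx(r2)


class TestReport:
    def test_reference_chilling_and_coldhard_means(self):
        ref = bb.load_reference_qtl_summary()
        supported, _ = bb.qtl_report(ref)
        chill = supported[supported["trait"] == "ChillReq"].iloc[0]
        assert round(chill["mean_peak_lod"], 1) == 37.5
        assert round(100 * chill["mean_r2"], 1) == 33.3
        assert round(100 * chill["mean_r2_over_h2"], 1) == 39.0
        cold = supported[supported["trait"] == "ColdHard"].iloc[0]
        assert round(cold["mean_peak_lod"], 1) == 19.6
        assert round(100 * cold["mean_r2"], 1) == 24.5

    def test_single_year_qtl_listed_separately(self):
        rec = pd.DataFrame([
            {"trait": "t", "year": 2012, "lg": 1, "bin_first": 5, "bin_last": 9,
             "peak_lod": 11.0, "r2": 0.2, "h2": 0.8, "r2_over_h2": 0.25},
            {"trait": "t", "year": 2013, "lg": 1, "bin_first": 7, "bin_last": 12,
             "peak_lod": 13.0, "r2": 0.3, "h2": 0.8, "r2_over_h2": 0.375},
            {"trait": "t", "year": 2013, "lg": 2, "bin_first": 1, "bin_last": 2,
             "peak_lod": 9.0, "r2": 0.1, "h2": 0.8, "r2_over_h2": 0.125},
        ])
        supported, single = bb.qtl_report(rec)
        assert len(supported) == 1
        assert supported["mean_peak_lod"].iloc[0] == pytest.approx(12.0)
        assert supported["bin_first"].iloc[0] == 5
        assert supported["bin_last"].iloc[0] == 12
        assert len(single) == 1
        assert single["lg"].iloc[0] == 2

    def test_non_overlapping_same_lg_not_merged(self):
        rec = pd.DataFrame([
            {"trait": "t", "year": 2012, "lg": 1, "bin_first": 1, "bin_last": 3,
             "peak_lod": 11.0, "r2": 0.2, "h2": 0.8, "r2_over_h2": 0.25},
            {"trait": "t", "year": 2013, "lg": 1, "bin_first": 20, "bin_last": 25,
             "peak_lod": 13.0, "r2": 0.3, "h2": 0.8, "r2_over_h2": 0.375},
        ])
        supported, single = bb.qtl_report(rec)
        assert len(supported) == 0 and len(single) == 2
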