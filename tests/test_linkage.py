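"""Two-point estimation, grouping, ordering, Kosambi, map summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bluebin as bb
from bluebin.core import MISSING
from bluebin.linkage import linkage_lod, map_summary, pairwise_rf
from bluebin.windows import BinSet


def _binset(states_p1, states_p2=None, n_snps=None):
    s1 = np.asarray(states_p1, dtype=np.int8)
    s2 = (np.asarray(states_p2, dtype=np.int8) if states_p2 is not None
          else np.full_like(s1, MISSING))
    nb = s1.shape[0]
    bins = pd.DataFrame({
        "bin_id": [f"bin{i:05d}" for i in range(nb)],
        "scaffold": ["scf1"] * nb,
        "start_local": range(nb), "end_local": range(nb),
        "start_row": range(nb), "end_row": range(nb),
        "start_bp": np.arange(nb) * 1000 + 1,
        "end_bp": np.arange(nb) * 1000 + 500,
        "n_snps": n_snps if n_snps is not None else [10] * nb,
    })
    inds = [f"K{i}" for i in range(s1.shape[1])]
    return BinSet(bins=bins, states_p1=s1, states_p2=s2, individuals=inds)


class TestKosambi:
    @pytest.mark.parametrize("r,cm", [(0.0, 0.0), (0.2, 21.18), (0.35, 43.37)])
    def test_closed_form_values(self, r, cm):
        assert bb.kosambi(r) == pytest.approx(cm, abs=0.005)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            bb.kosambi(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.49))
    def test_roundtrip_to_1e10(self, r):
        assert bb.kosambi_inverse(bb.kosambi(r)) == pytest.approx(r, abs=1e-10)


class TestTwoPoint:
    def test_testcross_closed_form(self):
        # 10 recombinants of 100 meioses
        a = np.zeros((2, 100), dtype=np.int8)
        a[1, :10] = 1
        bs = _binset(a)
        est = bb.two_point_rf(bs, 0, 1)
        assert est.rf == pytest.approx(0.10)
        assert est.lod == pytest.approx(15.99, abs=0.01)
        assert est.phase["P1"] == "coupling"

    def test_identical_bins_limit(self):
        a = np.zeros((2, 80), dtype=np.int8)
        bs = _binset(a)
        est = bb.two_point_rf(bs, 0, 1)
        assert est.rf == 0.0
        assert est.lod == pytest.approx(80 * math.log10(2))

    def test_disjoint_parent_pairs_uninformative(self):
        s1 = np.array([[0] * 50, [MISSING] * 50], dtype=np.int8)
        s2 = np.array([[MISSING] * 50, [0] * 50], dtype=np.int8)
        bs = _binset(s1, s2)
        est = bb.two_point_rf(bs, 0, 1)
        assert (est.rf, est.lod, est.usable) == (0.5, 0.0, False)

    def test_repulsion_phase_detected(self):
        a = np.zeros((2, 100), dtype=np.int8)
        a[1] = 1
        a[1, :5] = 0  # 95 mismatches = 5 recombinants in repulsion
        est = bb.two_point_rf(_binset(a), 0, 1)
        assert est.phase["P1"] == "repulsion"
        assert est.rf == pytest.approx(0.05)

    def test_pairwise_matches_single_pair(self, pop):
        est = pairwise_rf(pop.binset)
        for i, j in [(0, 1), (0, min(5, pop.binset.n_bins - 1))]:
            single = bb.two_point_rf(pop.binset, i, j)
            assert est.rf[i, j] == pytest.approx(single.rf, abs=1e-6)
            assert est.lod[i, j] == pytest.approx(single.lod, abs=1e-3)

    def test_rf_estimator_unbiased(self):
        # mean rf-hat within 2 MC standard errors of truth at n=117
        rng = np.random.default_rng(7)
        n, reps = 117, 400
        for r in (0.05, 0.1, 0.2, 0.3):
            ests = []
            for _ in range(reps):
                a = np.zeros((2, n), dtype=np.int8)
                a[0] = rng.integers(0, 2, n)
                rec = rng.random(n) < r
                a[1] = np.where(rec, 1 - a[0], a[0])
                ests.append(bb.two_point_rf(_binset(a), 0, 1).rf)
            se = np.std(ests) / math.sqrt(reps)
            assert np.mean(ests) == pytest.approx(r, abs=2 * se + 1e-9)

    def test_unphased_ml_estimator_recovers_rf(self):
        rng = np.random.default_rng(11)
        n, r = 400, 0.15
        g1 = np.empty(n, dtype=np.int8)
        g2 = np.empty(n, dtype=np.int8)
        for k in range(n):
            a1, b1 = rng.integers(0, 2), rng.integers(0, 2)
            a2 = 1 - a1 if rng.random() < r else a1
            b2 = 1 - b1 if rng.random() < r else b1
            g1[k], g2[k] = a1 + b1, a2 + b2
        rf, lod, phase = bb.rf_from_unphased_genotypes(g1, g2)
        assert rf == pytest.approx(r, abs=0.04)
        assert lod > 10
        assert phase == "coupling/coupling"


class TestGrouping:
    def test_linked_pair_groups_unlinked_bin_stays_out(self):
        rng = np.random.default_rng(3)
        n = 200
        base = rng.integers(0, 2, n).astype(np.int8)
        linked = np.where(rng.random(n) < 0.02, 1 - base, base)
        unlinked = rng.integers(0, 2, n)
        s = np.vstack([base, linked, unlinked]).astype(np.int8)
        bs = _binset(s)
        est = pairwise_rf(bs)
        groups, unplaced = bb.group_bins(est, bs.bins["n_snps"].to_numpy())
        assert any(set(g) >= {0, 1} for g in groups)
        assert 2 in unplaced

    def test_low_lod_separates_despite_low_rf(self):
        # few informative meioses: rf small but LOD < 12 -> no edge
        a = np.full((2, 40), MISSING, dtype=np.int8)
        a[:, :25] = 0
        bs = _binset(a)
        est = pairwise_rf(bs)
        assert est.lod[0, 1] < 12
        groups, unplaced = bb.group_bins(est, bs.bins["n_snps"].to_numpy())
        assert len(groups) == 0 and set(unplaced) == {0, 1}

    def test_group_order_invariant_to_input_order(self, pop):
        est = pairwise_rf(pop.binset)
        n_snps = pop.binset.bins["n_snps"].to_numpy()
        groups1, _ = bb.group_bins(est, n_snps)
        perm = np.random.default_rng(5).permutation(pop.binset.n_bins)
        est2 = bb.linkage.PairwiseEstimates(
            rf=est.rf[np.ix_(perm, perm)], lod=est.lod[np.ix_(perm, perm)],
            n=est.n[np.ix_(perm, perm)])
        groups2, _ = bb.group_bins(est2, n_snps[perm])
        sets1 = {frozenset(g.tolist()) for g in groups1}
        sets2 = {frozenset(perm[g].tolist()) for g in groups2}
        assert sets1 == sets2


class TestOrdering:
    def test_three_bins_exhaustive(self):
        # rf(0,1)=0.05, rf(1,2)=0.05, rf(0,2)=0.10 -> order 0-1-2
        rng = np.random.default_rng(13)
        n = 400
        a = np.zeros((3, n), dtype=np.int8)
        a[0] = rng.integers(0, 2, n)
        a[1] = np.where(rng.random(n) < 0.05, 1 - a[0], a[0])
        a[2] = np.where(rng.random(n) < 0.05, 1 - a[1], a[1])
        bs = _binset(a)
        est = pairwise_rf(bs)
        order = bb.order_bins(np.array([0, 1, 2]), est)
        assert list(order) in ([0, 1, 2], [2, 1, 0])
        # exhaustive check: chosen order minimises the SARF criterion
        def sarf(o):
            return est.rf[o[0], o[1]] + est.rf[o[1], o[2]]
        best = min(itertools.permutations([0, 1, 2]), key=sarf)
        assert sarf(list(order)) == pytest.approx(sarf(best))

    def test_two_bins_trivial(self, pop):
        est = pairwise_rf(pop.binset)
        assert list(bb.order_bins(np.array([0, 1]), est)) == [0, 1]

    def test_order_matches_truth_on_simulation(self, mapped_pop):
        pop, gmap = mapped_pop
        from scipy.stats import kendalltau
        scaff2start = dict(zip(pop.genome.scaffolds["scaffold"],
                               pop.genome.scaffolds["start_bp"]))
        for lg, sub in gmap.table.groupby("lg"):
            truebp = (sub["scaffold"].map(scaff2start).to_numpy()
                      + sub["start_bp"].to_numpy())
            tau = abs(kendalltau(np.arange(len(sub)), truebp).statistic)
            assert tau >= 0.95


class TestMapSummary:
    def test_reference_totals(self):
        ref = bb.load_reference_map_summary()
        totals = map_summary(ref)
        assert totals["total_snps"] == 17486
        assert totals["total_bins"] == 922
        assert totals["total_length_cm"] == 1539.4

    def test_single_lg_gap_count(self):
        lg = pd.DataFrame([{"lg": 1, "n_bins": 3, "n_snps": 30,
                            "length_cm": 20.0, "n_gaps_gt10": 1}])
        assert map_summary(lg)["total_gaps_gt10"] == 1

    def test_gap_detection_from_positions(self, mapped_pop):
        _, gmap = mapped_pop
        summ = gmap.lg_summary()
        for _, row in summ.iterrows():
            sub = gmap.table[gmap.table["lg"] == row["lg"]]
            gaps = (np.diff(sub["position_cm"].to_numpy()) > 10).sum()
            assert row["n_gaps_gt10"] == gaps

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            map_summary(pd.DataFrame())


class TestLodFunction:
    def test_lod_zero_at_half(self):
        assert linkage_lod(50, 100) == pytest.approx(0.0)

    def test_lod_monotone_in_linkage(self):
        lods = [linkage_lod(r, 100) for r in (0, 10, 25, 40, 50)]
        assert lods == sorted(lods, reverse=True)
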