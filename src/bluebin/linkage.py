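"""Linkage-map construction from marker bins.

Two-point recombination fractions are counted directly on the painted
parental meioses (each bin carries a phased state per parent track, so
a recombinant between two bins is simply a state mismatch, up to the
linkage phase chosen per track by maximum likelihood).  Bins are
grouped by the conjunction rf <= rf_max and LOD >= lod_min, ordered
within groups by greedy seriation plus 2-opt refinement of the sum of
adjacent recombination fractions, and placed on a centimorgan scale by
the Kosambi mapping function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse import csgraph

from .core import MISSING
from .windows import BinSet

DEFAULT_RF_MAX = 0.35
DEFAULT_LOD_MIN = 12.0
DEFAULT_MIN_INFORMATIVE = 20
DEFAULT_RF_CEILING = 0.49


# ----------------------------------------------------------------------
def kosambi(rf) -> np.ndarray | float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgan."""
    r = np.asarray(rf, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if np.isscalar(rf) else d


def kosambi_inverse(cm) -> np.ndarray | float:
    """Inverse Kosambi: r = tanh(d/50)/2."""
    d = np.asarray(cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if np.isscalar(cm) else r


def linkage_lod(n_recombinant: float, n_informative: float) -> float:
    """log10 likelihood ratio of the ML recombination fraction vs 0.5."""
    n, r_count = float(n_informative), float(n_recombinant)
    if n <= 0:
        return 0.0
    r = r_count / n
    lod = n * math.log10(2.0)
    if 0 < r_count:
        lod += r_count * math.log10(r)
    if r_count < n:
        lod += (n - r_count) * math.log10(1.0 - r)
    return lod


# ----------------------------------------------------------------------
@dataclass
class TwoPointEstimate:
    bin_i: str
    bin_j: str
    rf: float
    lod: float
    phase: dict[str, str]  # per track: "coupling" | "repulsion"
    informative_n: int
    usable: bool


@dataclass
class PairwiseEstimates:
    """Dense pairwise rf/LOD/informative-meioses matrices over bins."""

    rf: np.ndarray
    lod: np.ndarray
    n: np.ndarray


def pairwise_rf(binset: BinSet, min_informative: int = DEFAULT_MIN_INFORMATIVE) -> PairwiseEstimates:
    """All-pairs two-point estimates via matrix products.

    Per parent track, for each bin pair, the number of co-informative
    meioses and state mismatches is counted; the phase minimising the
    recombinant count (maximising the likelihood) is chosen per track,
    and the two tracks' meioses are pooled.  Pairs with fewer than
    ``min_informative`` pooled meioses are unusable (rf 0.5, LOD 0);
    so are pairs informative through disjoint parents only.
    """
    N = None
    R = None
    for states in (binset.states_p1, binset.states_p2):
        x = np.where(states == MISSING, 0.0, 2.0 * states - 1.0).astype(np.float32)
        m = (states != MISSING).astype(np.float32)
        n_t = m @ m.T
        agree = x @ x.T  # matches minus mismatches
        mismatch = (n_t - agree) / 2.0
        r_t = np.minimum(mismatch, n_t - mismatch)  # ML phase per pair
        if N is None:
            N, R = n_t, r_t
        else:
            N, R = N + n_t, R + r_t
    N = np.asarray(np.rint(N), dtype=np.int32)
    R = np.asarray(np.rint(R), dtype=np.float32)
    usable = N >= min_informative
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(usable, R / np.maximum(N, 1), 0.5).astype(np.float32)
        r_safe = np.clip(rf, 1e-9, 1 - 1e-9)
        lod = np.where(
            usable,
            R * np.log10(r_safe) + (N - R) * np.log10(1 - r_safe) + N * np.log10(2.0),
            0.0,
        ).astype(np.float32)
    lod[R == 0] = np.where(usable[R == 0], N[R == 0] * np.log10(2.0), 0.0)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(lod, 0.0)
    return PairwiseEstimates(rf=rf, lod=lod, n=N)


def two_point_rf(
    binset: BinSet,
    i: int,
    j: int,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> TwoPointEstimate:
    """Two-point estimate for one bin pair, with per-track phase."""
    n_tot, r_tot = 0, 0
    phase = {}
    for parent, states in (("P1", binset.states_p1), ("P2", binset.states_p2)):
        a, b = states[i], states[j]
        ok = (a != MISSING) & (b != MISSING)
        n_t = int(ok.sum())
        if n_t == 0:
            continue
        mism = int((a[ok] != b[ok]).sum())
        if mism <= n_t - mism:
            phase[parent] = "coupling"
            r_t = mism
        else:
            phase[parent] = "repulsion"
            r_t = n_t - mism
        n_tot += n_t
        r_tot += r_t
    usable = n_tot >= min_informative
    if not usable:
        return TwoPointEstimate(binset.bins["bin_id"].iat[i], binset.bins["bin_id"].iat[j],
                                0.5, 0.0, phase, n_tot, False)
    return TwoPointEstimate(
        binset.bins["bin_id"].iat[i], binset.bins["bin_id"].iat[j],
        r_tot / n_tot, linkage_lod(r_tot, n_tot), phase, n_tot, True,
    )


# ----------------------------------------------------------------------
def rf_from_unphased_genotypes(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, str]:
    """ML recombination fraction for two unphased 1:2:1 markers.

    Both parents heterozygous at both markers, linkage phase unknown:
    the likelihood of the observed 3x3 joint genotype table is
    maximised over r for each of the four phase configurations
    (coupling/repulsion per parent); the best configuration wins, ties
    broken toward coupling.  Returns (rf, lod, phase_label).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    counts = np.zeros((3, 3))
    for a, b in zip(g1[ok], g2[ok]):
        counts[a, b] += 1

    def joint(r: float, c1: bool, c2: bool) -> np.ndarray:
        out = np.zeros((3, 3))
        for pmatch1 in [(1 - r) if c1 else r]:
            for pmatch2 in [(1 - r) if c2 else r]:
                t1 = 0.5 * np.array([[pmatch1, 1 - pmatch1], [1 - pmatch1, pmatch1]])
                t2 = 0.5 * np.array([[pmatch2, 1 - pmatch2], [1 - pmatch2, pmatch2]])
                for a1 in (0, 1):
                    for a2 in (0, 1):
                        for b1 in (0, 1):
                            for b2 in (0, 1):
                                out[a1 + b1, a2 + b2] += t1[a1, a2] * t2[b1, b2]
        return out

    def nll(r, c1, c2):
        p = np.clip(joint(r, c1, c2), 1e-300, None)
        return -float((counts * np.log(p)).sum())

    best = None
    labels = {(True, True): "coupling/coupling", (True, False): "coupling/repulsion",
              (False, True): "repulsion/coupling", (False, False): "repulsion/repulsion"}
    for c1, c2 in [(True, True), (True, False), (False, True), (False, False)]:
        res = optimize.minimize_scalar(nll, bounds=(1e-6, 0.5), args=(c1, c2),
                                       method="bounded")
        cand = (res.fun, not (c1 and c2), res.x, labels[(c1, c2)])
        if best is None or cand[:2] < best[:2]:
            best = cand
    null = nll(0.5, True, True)
    lod = (null - best[0]) / math.log(10.0)
    return float(best[2]), float(max(lod, 0.0)), best[3]


# ----------------------------------------------------------------------
def group_bins(
    est: PairwiseEstimates,
    n_snps: np.ndarray,
    rf_max: float = DEFAULT_RF_MAX,
    lod_min: float = DEFAULT_LOD_MIN,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Connected components of the (rf <= rf_max AND lod >= lod_min) graph.

    Groups are numbered by descending total SNP content; singletons are
    returned separately as unplaced bins.
    """
    adj = (est.rf <= rf_max) & (est.lod >= lod_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = csgraph.connected_components(sparse.csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == k) for k in range(n_comp)]
    placed = [g for g in groups if g.size > 1]
    unplaced = np.concatenate([g for g in groups if g.size == 1]) if any(
        g.size == 1 for g in groups) else np.empty(0, dtype=int)
    order = np.argsort([-int(n_snps[g].sum()) for g in placed], kind="stable")
    return [placed[i] for i in order], unplaced


def _sarf(order: np.ndarray, rf: np.ndarray) -> float:
    return float(rf[order[:-1], order[1:]].sum())


def order_bins(group: np.ndarray, est: PairwiseEstimates) -> np.ndarray:
    """Order bins within a group by the SARF criterion.

    Greedy seriation from the strongest-linkage pair, extending the
    chain at whichever end offers the smallest rf, then 2-opt segment
    reversals until no move reduces the sum of adjacent rf.
    Deterministic: ties break on (rf, lod, bin index).
    """
    group = np.asarray(group)
    k = group.size
    if k <= 2:
        return group.copy()
    rf = est.rf[np.ix_(group, group)].astype(float)
    lod = est.lod[np.ix_(group, group)].astype(float)

    iu = np.triu_indices(k, 1)
    seed_flat = np.lexsort((iu[1], iu[0], rf[iu], -lod[iu]))[0]
    i0, j0 = iu[0][seed_flat], iu[1][seed_flat]
    chain = [int(i0), int(j0)]
    remaining = [i for i in range(k) if i not in chain]
    while remaining:
        rem = np.array(remaining)
        d_head = rf[chain[0], rem]
        d_tail = rf[chain[-1], rem]
        bi_head = np.lexsort((rem, -lod[chain[0], rem], d_head))[0]
        bi_tail = np.lexsort((rem, -lod[chain[-1], rem], d_tail))[0]
        if d_head[bi_head] < d_tail[bi_tail]:
            chain.insert(0, int(rem[bi_head]))
            remaining.remove(int(rem[bi_head]))
        else:
            chain.append(int(rem[bi_tail]))
            remaining.remove(int(rem[bi_tail]))

    order = np.array(chain)
    improved = True
    n_pass = 0
    while improved and n_pass < 50:
        improved = False
        n_pass += 1
        for i in range(k - 1):
            for j in range(i + 1, k):
                left = rf[order[i - 1], order[i]] if i > 0 else 0.0
                right = rf[order[j], order[j + 1]] if j < k - 1 else 0.0
                new_left = rf[order[i - 1], order[j]] if i > 0 else 0.0
                new_right = rf[order[i], order[j + 1]] if j < k - 1 else 0.0
                if new_left + new_right < left + right - 1e-12:
                    order[i: j + 1] = order[i: j + 1][::-1]
                    improved = True
    return group[order]


# ----------------------------------------------------------------------
@dataclass
class GeneticMap:
    """Ordered marker bins in linkage groups with Kosambi cM positions."""

    table: pd.DataFrame  # lg, order, bin_id, bin_index, position_cm, scaffold, bp span, n_snps
    unplaced: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.table["lg"].nunique())

    def lg_summary(self) -> pd.DataFrame:
        rows = []
        for lg, sub in self.table.groupby("lg", sort=True):
            pos = sub["position_cm"].to_numpy()
            rows.append(
                {
                    "lg": lg,
                    "n_bins": len(sub),
                    "n_snps": int(sub["n_snps"].sum()),
                    "length_cm": float(pos.max()),
                    "n_gaps_gt10": int((np.diff(pos) > 10.0).sum()),
                }
            )
        return pd.DataFrame(rows)

    def positions(self, lg: int) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg].reset_index(drop=True)


def build_map(
    binset: BinSet,
    rf_max: float = DEFAULT_RF_MAX,
    lod_min: float = DEFAULT_LOD_MIN,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    rf_ceiling: float = DEFAULT_RF_CEILING,
    est: PairwiseEstimates | None = None,
) -> GeneticMap:
    """Group, order and place marker bins on the centimorgan scale.

    Adjacent-bin rf values above ``rf_ceiling`` are clamped before the
    Kosambi transform.  Group orientation follows the scaffold
    coordinate of the first bin (cosmetic, deterministic).
    """
    est = est or pairwise_rf(binset, min_informative=min_informative)
    n_snps = binset.bins["n_snps"].to_numpy()
    groups, unplaced = group_bins(est, n_snps, rf_max=rf_max, lod_min=lod_min)
    rows = []
    for lg_num, g in enumerate(groups, start=1):
        ordered = order_bins(g, est)
        first = binset.bins.iloc[ordered[0]]
        last = binset.bins.iloc[ordered[-1]]
        if (last["scaffold"], last["start_bp"]) < (first["scaffold"], first["start_bp"]):
            ordered = ordered[::-1]
        adj_rf = np.clip(est.rf[ordered[:-1], ordered[1:]], 0.0, rf_ceiling)
        pos = np.concatenate([[0.0], np.cumsum(kosambi(adj_rf))])
        for o, (bi, p) in enumerate(zip(ordered, pos)):
            b = binset.bins.iloc[bi]
            rows.append(
                {
                    "lg": lg_num,
                    "order": o,
                    "bin_id": b["bin_id"],
                    "bin_index": int(bi),
                    "position_cm": float(p),
                    "scaffold": b["scaffold"],
                    "start_bp": int(b["start_bp"]),
                    "end_bp": int(b["end_bp"]),
                    "n_snps": int(b["n_snps"]),
                }
            )
    table = pd.DataFrame(rows)
    return GeneticMap(table=table, unplaced=unplaced)


# ----------------------------------------------------------------------
def map_summary(lg_table: pd.DataFrame) -> dict[str, float]:
    """Whole-map totals from a per-LG summary table.

    Expects columns ``n_bins, n_snps, length_cm, n_gaps_gt10``; lengths
    and means are rounded to one decimal as conventionally printed.
    """
    if lg_table.empty:
        raise ValueError("empty map")
    return {
        "n_groups": int(len(lg_table)),
        "total_bins": int(lg_table["n_bins"].sum()),
        "total_snps": int(lg_table["n_snps"].sum()),
        "total_length_cm": round(float(lg_table["length_cm"].sum()), 1),
        "mean_lg_length_cm": round(float(lg_table["length_cm"].mean()), 1),
        "mean_snps_per_lg": round(float(lg_table["n_snps"].mean()), 1),
        "total_gaps_gt10": int(lg_table["n_gaps_gt10"].sum()),
    }
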