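"""Parent-dependent sliding-window genotyping.

Noisy progeny calls are decomposed into two transmitted-allele tracks
per individual — one for each parent's meiosis — using the marker type
of every site.  A window of ``window_size`` consecutive informative
SNPs slides along each scaffold at a step of one SNP; the window state
is the dominant (strict-majority) allele among non-missing entries,
subject to a minimum support count, else MISSING.  Runs of identical
window states collapse into genotype blocks, adjacent blocks of
different state define recombination breakpoints, and population-wide
marker bins are the maximal runs of sites sharing one genotypic
profile across all individuals and both tracks.

Painting rules (B = alternate allele):

========  ============  =====================================
type      progeny call  painted state
========  ============  =====================================
P1HET     AA / AB / BB  P1 track: A / B / Mendelian error
P2HET     AA / AB / BB  P2 track: A / B / Mendelian error
BOTHHET   AA / BB / AB  both tracks: (A,A) / (B,B) / MISSING
========  ============  =====================================

(BOTHHET heterozygotes are phase-ambiguous and contribute nothing; the
window smoother fills them in from their neighbours.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (AA, AB, BB, MISSING, BOTHHET, P1HET, P2HET,
                   STATE_A, STATE_B, SnpMatrix)

DEFAULT_WINDOW_SIZE = 15
DEFAULT_LADDER = tuple(range(5, 20))


@dataclass
class TransmissionTrack:
    """Per-scaffold transmitted-allele states for one parent's meioses.

    ``states`` has one row per informative site (in scaffold order) and
    one column per progeny individual; entries are A/B/MISSING codes.
    """

    parent: str
    scaffold: str
    site_rows: np.ndarray  # global row indices into the SnpMatrix
    local_rows: np.ndarray  # row indices within this scaffold's site list
    pos_bp: np.ndarray
    states: np.ndarray
    n_mendel_errors: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.site_rows)


def _paint_parent(matrix: SnpMatrix, parent: str) -> dict[str, TransmissionTrack]:
    """All per-scaffold tracks for one parent."""
    het_type = P1HET if parent == "P1" else P2HET
    other = {"P1": 1, "P2": 0}[parent]
    mtype = matrix.sites["marker_type"].to_numpy()
    prog = matrix.progeny_calls()
    p_calls = matrix.parent_calls()
    hom_parent = p_calls[other]

    informative = (mtype == het_type) | (mtype == BOTHHET)
    n_prog = prog.shape[1]
    states = np.full(matrix.calls.shape[:1] + (n_prog,), MISSING, dtype=np.int8)

    tc = mtype == het_type
    # testcross sites: subtract the homozygous parent's allele contribution
    h = np.where(hom_parent == BB, 1, 0)[:, None]
    s = prog - h
    valid = (prog != MISSING) & ((s == STATE_A) | (s == STATE_B))
    mask_tc = tc[:, None] & valid
    states[mask_tc] = s[mask_tc].astype(np.int8)
    n_err = int((tc[:, None] & (prog != MISSING) & ~valid).sum())

    bh = mtype == BOTHHET
    states[bh[:, None] & (prog == AA)] = STATE_A
    states[bh[:, None] & (prog == BB)] = STATE_B

    out: dict[str, TransmissionTrack] = {}
    scaff = matrix.sites["scaffold"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for s_name, rows in matrix.scaffold_groups().items():
        inf_rows = rows[informative[rows]]
        out[s_name] = TransmissionTrack(
            parent=parent,
            scaffold=s_name,
            site_rows=inf_rows,
            local_rows=np.searchsorted(rows, inf_rows),
            pos_bp=pos[inf_rows],
            states=states[inf_rows],
            n_mendel_errors=n_err,
        )
    return out


def paint_transmitted_alleles(matrix: SnpMatrix) -> dict[str, dict[str, TransmissionTrack]]:
    """Decompose progeny calls into per-parent transmission tracks.

    Mendelian-impossible calls (a BB progeny at an AB x AA site) are
    painted MISSING and counted on the track.
    """
    return {p: _paint_parent(matrix, p) for p in ("P1", "P2")}


# ----------------------------------------------------------------------
def _min_support(width: int) -> int:
    return math.ceil(width / 3)


def call_window(states, window_size: int | None = None) -> int:
    """Dominant state of one window: strict majority of non-missing
    entries with minimum support, ties or thin support -> MISSING."""
    s = np.asarray(states)
    w = len(s) if window_size is None else window_size
    a = int((s == STATE_A).sum())
    b = int((s == STATE_B).sum())
    if a + b < _min_support(w):
        return MISSING
    if a > b:
        return STATE_A
    if b > a:
        return STATE_B
    return MISSING


def smooth_states(states: np.ndarray, window_size: int = DEFAULT_WINDOW_SIZE) -> np.ndarray:
    """Window-smooth a (n_sites, n_individuals) state array.

    Stage 1 assigns each window (one start index per site, stride 1,
    truncated at the scaffold tail) its dominant state; stage 2 assigns
    each site the majority state over the windows covering it.  Both
    stages run vectorised over all individuals at once.
    """
    arr = np.asarray(states, dtype=np.int8)
    one_d = arr.ndim == 1
    s = arr[:, None] if one_d else arr
    n = s.shape[0]
    if n == 0:
        return arr.copy()
    w = min(window_size, n)

    ca = np.cumsum(np.concatenate([np.zeros((1, s.shape[1]), int), s == STATE_A]), axis=0)
    cb = np.cumsum(np.concatenate([np.zeros((1, s.shape[1]), int), s == STATE_B]), axis=0)
    starts = np.arange(n)
    ends = np.minimum(starts + w, n)
    widths = ends - starts
    a = ca[ends] - ca[starts]
    b = cb[ends] - cb[starts]
    support = a + b >= np.ceil(widths / 3)[:, None]
    win = np.full(s.shape, MISSING, dtype=np.int8)
    win[(a > b) & support] = STATE_A
    win[(b > a) & support] = STATE_B

    wa = np.cumsum(np.concatenate([np.zeros((1, s.shape[1]), int), win == STATE_A]), axis=0)
    wb = np.cumsum(np.concatenate([np.zeros((1, s.shape[1]), int), win == STATE_B]), axis=0)
    sites = np.arange(n)
    lo = np.maximum(sites - w + 1, 0)
    hi = sites + 1
    va = wa[hi] - wa[lo]
    vb = wb[hi] - wb[lo]
    out = np.full(s.shape, MISSING, dtype=np.int8)
    out[va > vb] = STATE_A
    out[vb > va] = STATE_B
    return out[:, 0] if one_d else out


@dataclass
class GenotypeBlock:
    """A maximal run of same-state smoothed sites on one track."""

    individual: str
    parent: str
    scaffold: str
    start_site: int  # track-local index of first non-missing site
    end_site: int  # track-local index of last non-missing site (inclusive)
    state: int


def blocks_from_states(smoothed: np.ndarray) -> list[tuple[int, int, int]]:
    """Collapse a smoothed 1-D state vector into (start, end, state) runs.

    Missing stretches interior to two same-state runs are absorbed;
    leading/trailing missing sites belong to no block.
    """
    nz = np.flatnonzero(np.asarray(smoothed) != MISSING)
    if nz.size == 0:
        return []
    vals = np.asarray(smoothed)[nz]
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [nz.size - 1]])
    return [(int(nz[s]), int(nz[e]), int(vals[s])) for s, e in zip(starts, ends)]


def slide_track(
    track: TransmissionTrack,
    window_size: int = DEFAULT_WINDOW_SIZE,
    individuals: list[str] | None = None,
) -> tuple[np.ndarray, list[GenotypeBlock]]:
    """Smooth one track and extract genotype blocks for every individual."""
    smoothed = smooth_states(track.states, window_size)
    names = individuals or [f"I{j}" for j in range(smoothed.shape[1])]
    blocks = [
        GenotypeBlock(individual=names[j], parent=track.parent,
                      scaffold=track.scaffold, start_site=s, end_site=e, state=v)
        for j in range(smoothed.shape[1])
        for s, e, v in blocks_from_states(smoothed[:, j])
    ]
    return smoothed, blocks


# ----------------------------------------------------------------------
@dataclass
class Breakpoint:
    """A recombination breakpoint between two adjacent genotype blocks."""

    individual: str
    parent: str
    scaffold: str
    left_site: int  # track-local index of last site of the left block
    right_site: int  # track-local index of first site of the right block
    left_bp: int
    right_bp: int

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.left_bp + self.right_bp)

    @property
    def midpoint_site(self) -> float:
        return 0.5 * (self.left_site + self.right_site)


def _refine_cut(raw: np.ndarray, lo: int, hi: int, v_left: int, v_right: int) -> int:
    """Best cut k in [lo, hi+1] splitting raw[lo:k] / raw[k:hi+1].

    Minimises raw-state mismatches (left side should read ``v_left``,
    right side ``v_right``); among ties, the middle cut is taken.
    Returns k: the boundary lies between local sites k-1 and k.
    """
    seg = raw[lo: hi + 1]
    wrong_left = np.concatenate([[0], np.cumsum(seg == v_right)])
    wrong_right_total = int((seg == v_left).sum())
    right_wrong = wrong_right_total - np.concatenate([[0], np.cumsum(seg == v_left)])
    cost = wrong_left + right_wrong
    best = np.flatnonzero(cost == cost.min())
    return lo + int(best[(len(best) - 1) // 2])


def correct_track(
    track: TransmissionTrack,
    smoothed: np.ndarray,
    individuals: list[str],
    refine_margin: int = DEFAULT_WINDOW_SIZE,
) -> tuple[np.ndarray, list[Breakpoint]]:
    """Correct a smoothed track to block consensus and refine breakpoints.

    The window-smoothed block boundary only localises a crossover to a
    few sites; each boundary is refined against the raw track states,
    choosing the cut that minimises raw-state mismatches within
    ``refine_margin`` sites of the smoothed boundary.  Every site
    between the first and last block is then assigned its block's
    state (the population-correction step); the breakpoint record
    keeps the uncertainty interval, running from the last raw site
    supporting the left state to the first supporting the right.
    """
    corrected = np.full_like(smoothed, MISSING)
    out: list[Breakpoint] = []
    for j in range(smoothed.shape[1]):
        raw = track.states[:, j]
        runs = blocks_from_states(smoothed[:, j])
        if not runs:
            continue
        cuts = []
        for (s1, e1, v1), (s2, e2, v2) in zip(runs, runs[1:]):
            lo = max(s1, e1 - refine_margin + 1)
            hi = min(e2, s2 + refine_margin - 1)
            k = _refine_cut(raw, lo, hi, v1, v2)
            if cuts:
                k = max(k, cuts[-1])  # keep cuts monotone for tiny blocks
            cuts.append(k)
            left_cands = np.flatnonzero(raw[s1:k] == v1)
            left = s1 + int(left_cands[-1]) if left_cands.size else max(k - 1, s1)
            right_cands = np.flatnonzero(raw[k: e2 + 1] == v2)
            right = k + int(right_cands[0]) if right_cands.size else min(k, e2)
            if right <= left:
                left, right = max(k - 1, s1), min(k, e2)
            out.append(
                Breakpoint(
                    individual=individuals[j], parent=track.parent,
                    scaffold=track.scaffold, left_site=left, right_site=right,
                    left_bp=int(track.pos_bp[left]), right_bp=int(track.pos_bp[right]),
                )
            )
        bounds = [runs[0][0]] + cuts + [runs[-1][1] + 1]
        for (a, b), (_, _, v) in zip(zip(bounds[:-1], bounds[1:]), runs):
            corrected[a:b, j] = v
    return corrected, out


def detect_breakpoints(
    track: TransmissionTrack,
    smoothed: np.ndarray,
    individuals: list[str],
    refine_margin: int = DEFAULT_WINDOW_SIZE,
) -> list[Breakpoint]:
    """One refined breakpoint per adjacent block pair with differing states."""
    _, out = correct_track(track, smoothed, individuals, refine_margin)
    return out


# ----------------------------------------------------------------------
@dataclass
class BinSet:
    """Population-wide marker bins with their genotype profiles.

    ``states_p1``/``states_p2`` are (n_bins, n_progeny) arrays of the
    per-track state of every individual within each bin.
    """

    bins: pd.DataFrame  # bin_id, scaffold, start/end local row, bp span, n_snps
    states_p1: np.ndarray
    states_p2: np.ndarray
    individuals: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def genotype_table(self) -> pd.DataFrame:
        labels = np.array(["NA", "A", "B"])
        cols = {}
        for ind_j, ind in enumerate(self.individuals):
            cols[f"{ind}.P1"] = labels[self.states_p1[:, ind_j] + 1]
            cols[f"{ind}.P2"] = labels[self.states_p2[:, ind_j] + 1]
        out = self.bins[["bin_id", "scaffold", "start_bp", "end_bp", "n_snps"]].copy()
        return pd.concat([out, pd.DataFrame(cols)], axis=1)


def genotype_population(
    matrix: SnpMatrix,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> tuple[dict[str, dict[str, TransmissionTrack]],
           dict[str, dict[str, np.ndarray]],
           list[Breakpoint]]:
    """Paint, smooth, correct and call breakpoints for the population.

    Returns the painted tracks, the block-corrected per-site states
    (per parent, per scaffold) and all refined breakpoints.
    """
    tracks = paint_transmitted_alleles(matrix)
    individuals = matrix.progeny
    corrected: dict[str, dict[str, np.ndarray]] = {"P1": {}, "P2": {}}
    breakpoints: list[Breakpoint] = []
    for parent in ("P1", "P2"):
        for s_name, track in tracks[parent].items():
            sm = smooth_states(track.states, window_size)
            corr, bps = correct_track(track, sm, individuals)
            corrected[parent][s_name] = corr
            breakpoints.extend(bps)
    return tracks, corrected, breakpoints


def deduce_bins(
    matrix: SnpMatrix,
    tracks: dict[str, dict[str, TransmissionTrack]],
    corrected: dict[str, dict[str, np.ndarray]],
) -> BinSet:
    """Partition every scaffold into maximal same-profile marker bins.

    The profile of a site is the vector of corrected (block-level)
    states of every individual on both tracks; each corrected run
    extends over all scaffold sites up to the next informative site of
    its track, so a single crossover changes the profile at exactly
    one site boundary.  Bins tile each scaffold completely, so bin SNP
    counts sum to the filtered site count.
    """
    individuals = matrix.progeny
    n_prog = len(individuals)
    scaff_rows = matrix.scaffold_groups()
    pos = matrix.sites["pos"].to_numpy()

    bin_rows = []
    sp1, sp2 = [], []
    for s_name, rows in scaff_rows.items():
        n_s = rows.size
        profile = np.full((n_s, 2 * n_prog), MISSING, dtype=np.int8)
        for pi, parent in enumerate(("P1", "P2")):
            track = tracks[parent][s_name]
            corr = corrected[parent][s_name]
            local = track.local_rows
            for j in range(n_prog):
                runs = blocks_from_states(corr[:, j])
                for ri, (a, b, v) in enumerate(runs):
                    end_row = (local[runs[ri + 1][0]] - 1 if ri + 1 < len(runs)
                               else local[b])
                    profile[local[a]: end_row + 1, pi * n_prog + j] = v
        change = np.flatnonzero(np.any(profile[1:] != profile[:-1], axis=1)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change - 1, [n_s - 1]])
        for s0, e0 in zip(starts, ends):
            bin_rows.append(
                {
                    "scaffold": s_name,
                    "start_local": int(s0),
                    "end_local": int(e0),
                    "start_row": int(rows[s0]),
                    "end_row": int(rows[e0]),
                    "start_bp": int(pos[rows[s0]]),
                    "end_bp": int(pos[rows[e0]]),
                    "n_snps": int(e0 - s0 + 1),
                }
            )
            sp1.append(profile[s0, :n_prog])
            sp2.append(profile[s0, n_prog:])
    bins = pd.DataFrame(bin_rows)
    bins.insert(0, "bin_id", [f"bin{i:05d}" for i in range(len(bins))])
    return BinSet(
        bins=bins,
        states_p1=np.vstack(sp1) if sp1 else np.empty((0, n_prog), np.int8),
        states_p2=np.vstack(sp2) if sp2 else np.empty((0, n_prog), np.int8),
        individuals=individuals,
    )


# ----------------------------------------------------------------------
def select_window_size(
    parent_call_tracks: list[np.ndarray],
    ladder: tuple[int, ...] = DEFAULT_LADDER,
    tol: float = 1e-3,
    override: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the window size that best preserves parental heterozygosity.

    Each track is the sequence of a parent's own genotype calls along a
    scaffold at sites where that parent's true constitution is
    heterozygous.  For every ladder size the score is the fraction of
    windows whose dominant call is AB; the smallest size within *tol*
    of the maximum score wins.  ``override`` short-circuits the ladder
    (for configurations that pin the window size).
    """
    if override is not None:
        return override, pd.DataFrame({"window_size": [override], "score": [np.nan]})
    ladder = tuple(ladder)
    if not ladder:
        raise ValueError("empty window-size ladder")
    scores = []
    for w in ladder:
        n_windows = 0
        n_het = 0
        for track in parent_call_tracks:
            t = np.asarray(track)
            n = t.size
            if n == 0:
                continue
            ww = min(w, n)
            counts = {}
            for code in (AA, AB, BB):
                c = np.cumsum(np.concatenate([[0], t == code]))
                starts = np.arange(n)
                ends = np.minimum(starts + ww, n)
                counts[code] = c[ends] - c[starts]
            widths = np.minimum(np.arange(n) + ww, n) - np.arange(n)
            support = counts[AA] + counts[AB] + counts[BB] >= np.ceil(widths / 3)
            dom_ab = (support & (counts[AB] > counts[AA]) & (counts[AB] > counts[BB]))
            n_windows += n
            n_het += int(dom_ab.sum())
        scores.append(n_het / n_windows if n_windows else 0.0)
    curve = pd.DataFrame({"window_size": ladder, "score": scores})
    best = max(scores)
    chosen = next(w for w, s in zip(ladder, scores) if s >= best - tol)
    return chosen, curve


# ----------------------------------------------------------------------
def score_breakpoint_recovery(
    truth,
    matrix: SnpMatrix,
    tracks: dict[str, dict[str, TransmissionTrack]],
    breakpoints: list[Breakpoint],
    tol_sites: float = 2.0,
) -> dict[str, float]:
    """Match detected breakpoints against simulated crossover truth.

    A true crossover is recovered when a detected breakpoint on the
    same individual/parent/scaffold has its interval midpoint within
    ``tol_sites`` informative sites of the crossover's true position
    (matching is greedy one-to-one).  Detected breakpoints left
    unmatched count as false positives.
    """
    genome = truth.genome
    scaff = genome.scaffolds
    detected: dict[tuple, list[float]] = {}
    for b in breakpoints:
        detected.setdefault((b.individual, b.parent, b.scaffold), []).append(b.midpoint_site)

    n_true = 0
    n_recovered = 0
    xo = truth.crossover_table()
    bp_per_cm = genome.bp_per_cm()
    used: dict[tuple, set[int]] = {}
    for _, row in xo.iterrows():
        n_true += 1
        chrom_bp = row["cm"] * bp_per_cm
        cand = scaff[(scaff["chrom"] == row["chrom"])
                     & (scaff["start_bp"] <= chrom_bp)
                     & (scaff["end_bp"] >= chrom_bp)]
        if cand.empty:
            continue
        s_name = cand["scaffold"].iloc[0]
        track = tracks[row["parent"]].get(s_name)
        if track is None or track.n_sites < 2:
            continue
        local_bp = chrom_bp - float(cand["start_bp"].iloc[0]) + 1
        k = np.searchsorted(track.pos_bp, local_bp)
        true_mid = k - 0.5
        key = (row["individual"], row["parent"], s_name)
        mids = detected.get(key, [])
        taken = used.setdefault(key, set())
        best_i, best_d = -1, np.inf
        for i, m in enumerate(mids):
            if i in taken:
                continue
            d = abs(m - true_mid)
            if d < best_d:
                best_i, best_d = i, d
        if best_i >= 0 and best_d <= tol_sites:
            taken.add(best_i)
            n_recovered += 1
    n_detected = sum(len(v) for v in detected.values())
    n_matched = sum(len(v) for v in used.values())
    return {
        "n_true": n_true,
        "n_detected": n_detected,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_true if n_true else float("nan"),
        "false_positive_rate": (n_detected - n_matched) / n_true if n_true else float("nan"),
    }
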