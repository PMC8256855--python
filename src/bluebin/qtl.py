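"""Interval-mapping QTL scans over the bin map.

Regression-based (Haley-Knott) interval mapping: at every grid
position the phenotype is regressed on the expected transmitted-allele
indicators of the two parental meioses, computed from the flanking bin
states by the standard no-interference conditional formula with
Kosambi-inverse recombination fractions to the flanks.  The LOD is
(n/2) log10(RSS0/RSS1).  Genome-wide significance thresholds come from
permutations of the phenotype vector, QTL support intervals from the
LOD 1-drop rule extended outward to the nearest bin boundaries, and
variance explained is reported both as R^2 and as R^2/H^2 (capped at
one when it exceeds the trait heritability).

An optional composite-mapping mode conditions the scan on
forward-selected bin cofactors, excluding any cofactor within a
configurable window of the test position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING
from .linkage import GeneticMap, kosambi_inverse
from .windows import BinSet

DEFAULT_STEP_CM = 0.5
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_COFACTOR_WINDOW_CM = 10.0


@dataclass
class ScanConfig:
    step_cm: float = DEFAULT_STEP_CM
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    mode: str = "im"  # "im" | "cim"
    cofactor_window_cm: float = DEFAULT_COFACTOR_WINDOW_CM
    max_cofactors: int = 5
    min_n: int = 30

    def validate(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step_cm must be positive")
        if not (0 < self.alpha < 1) and self.alpha != 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations and self.n_permutations < 100:
            raise ValueError("need >= 100 permutations for threshold estimation")


# ----------------------------------------------------------------------
def _fill_indices(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest non-missing bin index at-or-before / at-or-after each bin."""
    m, n = states.shape
    rows = np.arange(m)[:, None]
    valid = states != MISSING
    fwd = np.maximum.accumulate(np.where(valid, rows, -1), axis=0)
    bwd = np.minimum.accumulate(np.where(valid, rows, m)[::-1], axis=0)[::-1]
    return fwd, bwd


def _track_prob(pos, states, fwd, bwd, x: float) -> np.ndarray:
    """P(transmitted state = B at x) per individual for one track."""
    m, n = states.shape
    kl = int(np.searchsorted(pos, x, side="right")) - 1
    kr = int(np.searchsorted(pos, x, side="left"))
    li = fwd[kl] if kl >= 0 else np.full(n, -1)
    ri = bwd[kr] if kr < m else np.full(n, m)
    has_l, has_r = li >= 0, ri < m
    lc = np.clip(li, 0, m - 1)
    rc = np.clip(ri, 0, m - 1)
    rl = kosambi_inverse(np.maximum(x - pos[lc], 0.0))
    rr = kosambi_inverse(np.maximum(pos[rc] - x, 0.0))
    sl = states[lc, np.arange(n)]
    sr = states[rc, np.arange(n)]
    a_b = np.where(sl == 1, 1.0 - rl, rl)  # P(X=B | left flank)
    pr_b = np.where(sr == 1, 1.0 - rr, rr)  # P(right flank | X=B)
    pr_a = np.where(sr == 1, rr, 1.0 - rr)
    num_b = a_b * pr_b
    denom = np.maximum(num_b + (1.0 - a_b) * pr_a, 1e-300)
    p = np.where(
        has_l & has_r, num_b / denom,
        np.where(has_l, a_b, np.where(has_r, pr_b, 0.5)),
    )
    return p


def genotype_probabilities(
    position_cm: float,
    positions: np.ndarray,
    states_p1: np.ndarray,
    states_p2: np.ndarray,
) -> np.ndarray:
    """Expected B-transmission indicators (n_individuals, 2) at a position.

    ``positions`` are the cM positions of the LG's bins; state arrays
    are (n_bins, n_individuals).  At a bin with a non-missing state the
    indicator is exactly 0/1; between bins it is the conditional
    probability given the nearest non-missing flanking states.
    """
    out = np.empty((states_p1.shape[1], 2))
    for t, s in enumerate((states_p1, states_p2)):
        fwd, bwd = _fill_indices(s)
        out[:, t] = _track_prob(positions, s, fwd, bwd, position_cm)
    return out


# ----------------------------------------------------------------------
class ScanEngine:
    """Precomputed design matrices for fast repeated LOD profiles.

    Builds, for every grid position, the centred Haley-Knott design
    (two track indicators) and its orthonormal basis, so that LOD
    profiles for many phenotype vectors (permutations, many traits)
    reduce to a single matrix product.
    """

    def __init__(
        self,
        gmap: GeneticMap,
        binset: BinSet,
        individuals: list[str] | None = None,
        step_cm: float = DEFAULT_STEP_CM,
    ):
        all_inds = binset.individuals
        self.individuals = list(individuals) if individuals is not None else list(all_inds)
        idx = np.array([all_inds.index(i) for i in self.individuals])
        self.n = len(idx)

        grid_rows = []
        xs = []
        self.bin_positions: dict[int, np.ndarray] = {}
        self.bin_order_index: dict[int, np.ndarray] = {}
        for lg in sorted(gmap.table["lg"].unique()):
            sub = gmap.positions(lg)
            pos = sub["position_cm"].to_numpy()
            bidx = sub["bin_index"].to_numpy()
            self.bin_positions[int(lg)] = pos
            self.bin_order_index[int(lg)] = bidx
            s1 = binset.states_p1[bidx][:, idx]
            s2 = binset.states_p2[bidx][:, idx]
            f1, b1 = _fill_indices(s1)
            f2, b2 = _fill_indices(s2)
            top = float(pos.max())
            grid = np.unique(np.round(
                np.concatenate([np.arange(0.0, top, step_cm), [top]]), 9))
            for x in grid:
                grid_rows.append((int(lg), float(x)))
                x1 = _track_prob(pos, s1, f1, b1, x)
                x2 = _track_prob(pos, s2, f2, b2, x)
                xs.append(np.column_stack([x1, x2]))
        self.grid = pd.DataFrame(grid_rows, columns=["lg", "position_cm"])
        X = np.stack(xs)  # (G, n, 2)
        Xc = X - X.mean(axis=1, keepdims=True)
        # orthonormal basis of each centred design, zero-padded to rank 2
        G = X.shape[0]
        U = np.zeros_like(Xc)
        for g in range(G):
            u, sv, _ = np.linalg.svd(Xc[g], full_matrices=False)
            keep = sv > max(1e-10, 1e-10 * (sv[0] if sv.size else 1.0))
            r = int(keep.sum())
            U[g, :, :r] = u[:, :r]
        self.X = X
        self._ustack = U.transpose(0, 2, 1).reshape(G * 2, self.n)

    @property
    def n_grid(self) -> int:
        return len(self.grid)

    def lod_profile(self, Y: np.ndarray) -> np.ndarray:
        """LOD at every grid position for each phenotype column.

        *Y* is (n, k); returns (n_grid, k).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Yc = Y - Y.mean(axis=0, keepdims=True)
        rss0 = (Yc**2).sum(axis=0)
        proj = self._ustack @ Yc  # (G*2, k)
        expl = (proj**2).reshape(self.n_grid, 2, -1).sum(axis=1)
        rss1 = np.maximum(rss0[None, :] - expl, rss0[None, :] * 1e-12)
        return (self.n / 2.0) * np.log10(rss0[None, :] / rss1)


# ----------------------------------------------------------------------
def permutation_threshold(
    engine: ScanEngine,
    y: np.ndarray,
    config: ScanConfig,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD cutoff from phenotype permutations.

    Permutes the phenotype rows jointly against the genotype matrix
    (preserving genotype LD), takes the genome-wide maximum LOD of
    each permutation and returns its empirical (1 - alpha) quantile.
    """
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=float)
    perms = np.stack([y[rng.permutation(y.size)] for _ in range(config.n_permutations)], axis=1)
    maxima = engine.lod_profile(perms).max(axis=0)
    cutoff = float(np.quantile(maxima, 1.0 - config.alpha, method="higher"))
    return cutoff, maxima


# ----------------------------------------------------------------------
@dataclass
class QtlPeak:
    lg: int
    peak_cm: float
    peak_lod: float
    interval_cm: tuple[float, float]
    first_bin: int  # order index of the bounding bin within the LG
    last_bin: int
    truncated_left: bool
    truncated_right: bool
    r_squared: float
    r2_over_h2: float | None = None
    r2_capped: bool = False


@dataclass
class QtlScanResult:
    trait: str
    year: str
    profile: pd.DataFrame  # lg, position_cm, lod
    threshold: float | None
    peaks: list[QtlPeak]
    h2: float | None = None
    n: int = 0
    dropped: list[str] = field(default_factory=list)


def qtl_interval(
    positions: np.ndarray,
    lods: np.ndarray,
    peak_idx: int,
    bin_positions: np.ndarray,
) -> tuple[tuple[float, float], int, int, bool, bool]:
    """LOD 1-drop interval snapped outward to the nearest bin boundaries.

    Walks from the peak until the LOD falls more than one unit below
    the peak on each side, then extends outward to the nearest bin
    positions.  Returns the cM interval, the order indices of the
    bounding bins, and truncation flags for drops never reached before
    the LG ends.
    """
    peak_lod = lods[peak_idx]
    lo = peak_idx
    while lo > 0 and lods[lo - 1] >= peak_lod - 1.0:
        lo -= 1
    hi = peak_idx
    while hi < len(lods) - 1 and lods[hi + 1] >= peak_lod - 1.0:
        hi += 1
    truncated_left = lo == 0 and lods[lo] >= peak_lod - 1.0
    truncated_right = hi == len(lods) - 1 and lods[hi] >= peak_lod - 1.0

    drop_lo, drop_hi = positions[lo], positions[hi]
    first = int(np.searchsorted(bin_positions, drop_lo, side="right")) - 1
    first = max(first, 0)
    last = int(np.searchsorted(bin_positions, drop_hi, side="left"))
    last = min(last, len(bin_positions) - 1)
    return ((float(bin_positions[first]), float(bin_positions[last])),
            first, last, truncated_left, truncated_right)


def variance_explained(rss0: float, rss1: float, h2: float | None = None
                       ) -> tuple[float, float | None, bool]:
    """R^2 = 1 - RSS1/RSS0 and its ratio to the trait heritability.

    The ratio R^2/H^2 is capped at 1.0 (flagged) when the QTL appears
    to explain more than the heritable variance.
    """
    r2 = 1.0 - rss1 / rss0
    if h2 is None:
        return r2, None, False
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    ratio = r2 / h2
    capped = ratio > 1.0
    return r2, min(ratio, 1.0), capped


def _r2_from_lod(lod: float, n: int) -> float:
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def scan_trait(
    gmap: GeneticMap,
    binset: BinSet,
    phenotype: pd.Series,
    config: ScanConfig | None = None,
    trait: str = "trait",
    year: str = "Y1",
    h2: float | None = None,
    engine: ScanEngine | None = None,
    threshold: float | None = None,
) -> QtlScanResult:
    """Interval-mapping scan of one trait-year phenotype.

    *phenotype* is indexed by individual; individuals absent from the
    genotyped population are dropped (and reported).  The genome-wide
    threshold is taken from permutations unless supplied.
    """
    config = config or ScanConfig()
    config.validate()
    pheno = phenotype.dropna()
    genotyped = set(binset.individuals)
    dropped = [i for i in pheno.index if i not in genotyped]
    pheno = pheno[pheno.index.isin(genotyped)]
    if pheno.size < config.min_n:
        raise ValueError(f"only {pheno.size} phenotyped+genotyped individuals")
    y = pheno.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")

    if engine is None:
        engine = ScanEngine(gmap, binset, individuals=list(pheno.index),
                            step_cm=config.step_cm)
    lods = engine.lod_profile(y)[:, 0]
    profile = engine.grid.copy()
    profile["lod"] = lods

    if threshold is None and config.n_permutations:
        threshold, _ = permutation_threshold(engine, y, config)

    peaks: list[QtlPeak] = []
    if threshold is not None:
        n = engine.n
        for lg, sub in profile.groupby("lg", sort=True):
            pos = sub["position_cm"].to_numpy()
            lg_lods = sub["lod"].to_numpy()
            above = lg_lods >= threshold
            if not above.any():
                continue
            # contiguous super-threshold segments -> one peak each
            segs = []
            in_seg = False
            for i, flag in enumerate(above):
                if flag and not in_seg:
                    seg_start = i
                    in_seg = True
                if in_seg and (not flag or i == len(above) - 1):
                    seg_end = i if flag else i - 1
                    segs.append((seg_start, seg_end))
                    in_seg = False
            bin_pos = engine.bin_positions[int(lg)]
            for s0, s1 in segs:
                pk = s0 + int(np.argmax(lg_lods[s0: s1 + 1]))
                (ci, first, last, tl, tr) = qtl_interval(pos, lg_lods, pk, bin_pos)
                r2 = _r2_from_lod(lg_lods[pk], n)
                ratio, capped = None, False
                if h2 is not None:
                    _, ratio, capped = variance_explained(1.0, 1.0 - r2, h2)
                peaks.append(
                    QtlPeak(lg=int(lg), peak_cm=float(pos[pk]),
                            peak_lod=float(lg_lods[pk]), interval_cm=ci,
                            first_bin=first, last_bin=last,
                            truncated_left=tl, truncated_right=tr,
                            r_squared=r2, r2_over_h2=ratio, r2_capped=capped)
                )
    return QtlScanResult(trait=trait, year=year, profile=profile,
                         threshold=threshold, peaks=peaks, h2=h2,
                         n=engine.n, dropped=dropped)


# ----------------------------------------------------------------------
def scan_trait_cim(
    gmap: GeneticMap,
    binset: BinSet,
    phenotype: pd.Series,
    config: ScanConfig,
    h2: float | None = None,
) -> QtlScanResult:
    """Composite interval mapping: scan conditioned on bin cofactors.

    Cofactor bins are forward-selected by residual sum of squares
    (up to ``max_cofactors``, partial F p < 0.01); at each test
    position cofactors within ``cofactor_window_cm`` of the position
    on the same LG are excluded from the conditioning set.
    """
    from scipy import stats

    pheno = phenotype.dropna()
    pheno = pheno[pheno.index.isin(set(binset.individuals))]
    y = pheno.to_numpy(dtype=float)
    inds = list(pheno.index)
    engine = ScanEngine(gmap, binset, individuals=inds, step_cm=config.step_cm)
    n = engine.n

    # candidate cofactor columns: expected indicators at every bin
    tab = gmap.table
    cof_cols = []
    cof_meta = []
    for _, row in tab.iterrows():
        p = genotype_probabilities(
            row["position_cm"], engine.bin_positions[int(row["lg"])],
            binset.states_p1[engine.bin_order_index[int(row["lg"])]][
                :, [binset.individuals.index(i) for i in inds]],
            binset.states_p2[engine.bin_order_index[int(row["lg"])]][
                :, [binset.individuals.index(i) for i in inds]],
        )
        cof_cols.append(p)
        cof_meta.append((int(row["lg"]), float(row["position_cm"])))

    def rss_of(Xcols: list[np.ndarray]) -> float:
        X = np.column_stack([np.ones(n)] + Xcols) if Xcols else np.ones((n, 1))
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float((resid**2).sum())

    selected: list[int] = []
    rss_cur = rss_of([])
    while len(selected) < config.max_cofactors:
        best_i, best_rss = -1, rss_cur
        for i in range(len(cof_cols)):
            if i in selected:
                continue
            r = rss_of([cof_cols[j][:, k] for j in selected + [i] for k in (0, 1)])
            if r < best_rss:
                best_i, best_rss = i, r
        if best_i < 0:
            break
        df2 = n - 2 * (len(selected) + 1) - 1
        f = (rss_cur - best_rss) / 2.0 / (best_rss / df2)
        if stats.f.sf(f, 2, df2) >= 0.01:
            break
        selected.append(best_i)
        rss_cur = best_rss

    lods = np.empty(engine.n_grid)
    for g in range(engine.n_grid):
        lg = int(engine.grid["lg"].iat[g])
        x = float(engine.grid["position_cm"].iat[g])
        keep = [j for j in selected
                if not (cof_meta[j][0] == lg
                        and abs(cof_meta[j][1] - x) <= config.cofactor_window_cm)]
        base_cols = [cof_cols[j][:, k] for j in keep for k in (0, 1)]
        rss0 = rss_of(base_cols)
        rss1 = rss_of(base_cols + [engine.X[g][:, 0], engine.X[g][:, 1]])
        lods[g] = (n / 2.0) * math.log10(rss0 / max(rss1, rss0 * 1e-12))
    profile = engine.grid.copy()
    profile["lod"] = lods
    return QtlScanResult(trait="trait", year="Y1", profile=profile,
                         threshold=None, peaks=[], h2=h2, n=n, dropped=[])


# ----------------------------------------------------------------------
def qtl_report(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-year QTL summary: co-locating QTLs supported by >= 2 years.

    *records* has one row per detected QTL with columns
    ``trait, year, lg, bin_first, bin_last, peak_lod, r2, h2,
    r2_over_h2``.  QTLs of the same trait on the same LG whose bin
    intervals overlap (transitively) across at least two distinct
    years are flagged supported; per-QTL means of peak LOD, R^2 and
    R^2/H^2 are taken across the supporting years.  Returns
    (supported table, single-year table).
    """
    supported_rows, single_rows = [], []
    for (trait, lg), sub in records.groupby(["trait", "lg"], sort=True):
        sub = sub.sort_values(["bin_first", "year"]).reset_index(drop=True)
        # cluster transitively overlapping [bin_first, bin_last] intervals
        cluster_id = np.zeros(len(sub), dtype=int)
        cur, hi = 0, sub["bin_last"].iat[0]
        for i in range(1, len(sub)):
            if sub["bin_first"].iat[i] > hi:
                cur += 1
                hi = sub["bin_last"].iat[i]
            else:
                hi = max(hi, sub["bin_last"].iat[i])
            cluster_id[i] = cur
        for cid in np.unique(cluster_id):
            grp = sub[cluster_id == cid]
            years = sorted(grp["year"].unique())
            row = {
                "trait": trait,
                "lg": lg,
                "years": ",".join(str(y) for y in years),
                "n_years": len(years),
                "bin_first": int(grp["bin_first"].min()),
                "bin_last": int(grp["bin_last"].max()),
                "mean_peak_lod": float(grp["peak_lod"].mean()),
                "mean_r2": float(grp["r2"].mean()),
                "mean_r2_over_h2": (float(grp["r2_over_h2"].mean())
                                    if grp["r2_over_h2"].notna().all() else np.nan),
            }
            (supported_rows if len(years) >= 2 else single_rows).append(row)
    cols = ["trait", "lg", "years", "n_years", "bin_first", "bin_last",
            "mean_peak_lod", "mean_r2", "mean_r2_over_h2"]
    return (pd.DataFrame(supported_rows, columns=cols),
            pd.DataFrame(single_rows, columns=cols))
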