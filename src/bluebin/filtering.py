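"""Site-level, parental and segregation filters for a multi-sample VCF.

Filter chain (fixed order, each rule's removals counted in a report):

1. biallelic sites only
2. site quality >= 30 (per-call GQ < 30 is set MISSING first)
3. mean aligned depth within [3, 750]
4. parental criteria: both parents called, at least one heterozygous
5. progeny missingness <= 50%
6. chi-square segregation test against 1:1 (testcross types, df=1) or
   1:2:1 (both-parents-heterozygous type, df=2) at alpha = 0.05

Critical chi-square values are computed from the distribution quantile
function, not hard-coded (they round to 3.84 and 5.99).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .core import (AA, AB, BB, MISSING, BOTHHET, P1HET, P2HET,
                   FilterReport, SnpMatrix)

log = logging.getLogger(__name__)

DEFAULT_MIN_QUALITY = 30.0
DEFAULT_DEPTH_RANGE = (3.0, 750.0)
DEFAULT_MAX_MISSING = 0.5
DEFAULT_SEG_ALPHA = 0.05
DEFAULT_MIN_SCORED = 20  # minimum scored progeny for a segregation test


def chi2_critical(df: int, alpha: float = DEFAULT_SEG_ALPHA) -> float:
    """Upper-tail chi-square critical value at significance *alpha*."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def read_vcf(path, parent_ids: tuple[str, str]) -> SnpMatrix:
    """Load a multi-sample VCF into a raw :class:`SnpMatrix`.

    All records are loaded with GT/DP/GQ; records with more than one
    ALT allele are kept but flagged non-biallelic so that
    :func:`filter_sites` removes them with an accounted reason.
    Malformed records are skipped with a logged count.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for p in parent_ids:
        if p not in samples:
            raise ValueError(f"parent sample {p!r} not present in VCF")

    rows, call_rows, dp_rows, gq_rows = [], [], [], []
    n_bad = 0
    for rec in vf:
        try:
            alts = rec.alts or ()
            biallelic = len(alts) == 1
            calls = np.empty(len(samples), dtype=np.int8)
            dps = np.zeros(len(samples), dtype=np.int32)
            gqs = np.zeros(len(samples), dtype=np.int16)
            for j, s in enumerate(samples):
                sd = rec.samples[s]
                gt = sd.get("GT")
                if gt is None or any(a is None for a in gt):
                    calls[j] = MISSING
                else:
                    calls[j] = int(sum(1 for a in gt if a != 0) if biallelic else MISSING)
                    if calls[j] > 2:
                        calls[j] = MISSING
                dps[j] = sd.get("DP") or 0
                gqs[j] = sd.get("GQ") or 0
            rows.append(
                {
                    "scaffold": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alts[0] if alts else ".",
                    "qual": float(rec.qual) if rec.qual is not None else 0.0,
                    "mean_depth": float(dps.mean()),
                    "biallelic": biallelic,
                }
            )
            call_rows.append(calls)
            dp_rows.append(dps)
            gq_rows.append(gqs)
        except (ValueError, KeyError, TypeError):
            n_bad += 1
    if n_bad:
        log.warning("skipped %d malformed VCF records", n_bad)
    sites = pd.DataFrame(rows)
    m = SnpMatrix(
        sites=sites,
        calls=np.vstack(call_rows) if call_rows else np.empty((0, len(samples)), np.int8),
        samples=samples,
        parents=tuple(parent_ids),
        depth=np.vstack(dp_rows) if dp_rows else None,
        gq=np.vstack(gq_rows) if gq_rows else None,
    )
    return m.sort_sites()


def classify_marker_type(p1_call: int, p2_call: int) -> str | None:
    """Marker segregation type from the two parental calls.

    Returns P1HET/P2HET/BOTHHET, or None when the site is rejected
    (missing parent or no heterozygous parent).
    """
    if p1_call == MISSING or p2_call == MISSING:
        return None
    p1_het, p2_het = p1_call == AB, p2_call == AB
    if p1_het and p2_het:
        return BOTHHET
    if p1_het:
        return P1HET
    if p2_het:
        return P2HET
    return None


def _classify_all(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    out = np.full(p1.shape, "", dtype=object)
    out[(p1 == AB) & (p2 == AB)] = BOTHHET
    out[(p1 == AB) & (p2 != AB) & (p2 != MISSING)] = P1HET
    out[(p2 == AB) & (p1 != AB) & (p1 != MISSING)] = P2HET
    return out


def filter_sites(
    matrix: SnpMatrix,
    min_quality: float = DEFAULT_MIN_QUALITY,
    depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE,
    max_missing: float = DEFAULT_MAX_MISSING,
    min_gq: float | None = None,
) -> tuple[SnpMatrix, FilterReport]:
    """Apply site-level and parental filters; classify marker types.

    ``min_gq`` defaults to ``min_quality``: calls with genotype quality
    below it are set MISSING before the parental and missingness rules
    run (the strictest consistent reading of a joint site/genotype
    quality threshold).
    """
    report = FilterReport()
    m = matrix
    calls = m.calls.copy()
    if m.gq is not None:
        calls[m.gq < (min_quality if min_gq is None else min_gq)] = MISSING
    m = SnpMatrix(sites=m.sites.copy(), calls=calls, samples=list(m.samples),
                  parents=m.parents, depth=m.depth, gq=m.gq)

    def apply(mask: np.ndarray, rule: str) -> None:
        nonlocal m
        report.add(rule, int((~mask).sum()))
        m = m.subset_sites(np.asarray(mask))

    if "biallelic" in m.sites.columns:
        apply(m.sites["biallelic"].to_numpy(dtype=bool), "not_biallelic")
    apply(m.sites["qual"].to_numpy(dtype=float) >= min_quality, "low_quality")
    md = m.sites["mean_depth"].to_numpy(dtype=float)
    apply(md >= depth_range[0], "depth_below_min")
    md = m.sites["mean_depth"].to_numpy(dtype=float)
    apply(md <= depth_range[1], "depth_above_max")

    p1, p2 = m.parent_calls()
    apply((p1 != MISSING) & (p2 != MISSING), "parent_missing")
    p1, p2 = m.parent_calls()
    mtype = _classify_all(p1, p2)
    apply(mtype != "", "no_het_parent")

    prog = m.progeny_calls()
    miss_frac = (prog == MISSING).mean(axis=1) if prog.shape[1] else np.zeros(m.n_sites)
    apply(miss_frac <= max_missing, "too_missing")

    p1, p2 = m.parent_calls()
    sites = m.sites.copy()
    sites["marker_type"] = _classify_all(p1, p2)
    m = SnpMatrix(sites=sites, calls=m.calls, samples=list(m.samples),
                  parents=m.parents, depth=m.depth, gq=m.gq)
    if m.n_sites == 0:
        log.warning("no sites survived filtering")
    return m, report


@dataclass
class SegregationTest:
    """Chi-square goodness-of-fit of progeny genotype counts against
    the Mendelian expectation for the site's marker type."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    chi2: float
    df: int
    critical: float
    passed: bool
    n_scored: int


def segregation_test(
    observed: np.ndarray | tuple,
    marker_type: str,
    alpha: float = DEFAULT_SEG_ALPHA,
    min_scored: int = DEFAULT_MIN_SCORED,
) -> SegregationTest:
    """Test observed genotype-class counts against 1:1 or 1:2:1.

    For testcross types *observed* is (n_class1, n_class2); for
    BOTHHET it is (n_AA, n_AB, n_BB).  Missing and Mendelian-impossible
    calls must already be excluded from the counts.
    """
    obs = np.asarray(observed, dtype=float)
    if marker_type in (P1HET, P2HET):
        ratio = (1, 1)
        df = 1
    elif marker_type == BOTHHET:
        ratio = (1, 2, 1)
        df = 2
    else:
        raise ValueError(f"unknown marker type {marker_type!r}")
    if len(obs) != len(ratio):
        raise ValueError("observed counts do not match the marker type classes")
    n = obs.sum()
    crit = chi2_critical(df, alpha)
    if n < min_scored:
        return SegregationTest(tuple(int(x) for x in obs), ratio, float("nan"),
                               df, crit, False, int(n))
    exp = n * np.asarray(ratio, dtype=float) / sum(ratio)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return SegregationTest(tuple(int(x) for x in obs), ratio, chi2, df,
                           crit, chi2 <= crit, int(n))


def segregation_filter(
    matrix: SnpMatrix,
    alpha: float = DEFAULT_SEG_ALPHA,
    min_scored: int = DEFAULT_MIN_SCORED,
) -> tuple[SnpMatrix, pd.DataFrame]:
    """Remove sites with distorted segregation among progeny.

    Mendelian-impossible progeny calls (e.g. BB at a testcross site
    where only AA/AB can occur) are treated as genotyping errors: they
    are excluded from the counts and tallied in the per-site table
    rather than failing the site outright.  Returns the filtered
    matrix and a table (scaffold, pos, marker_type, chi2, df, n_scored,
    n_impossible, pass).
    """
    if "marker_type" not in matrix.sites.columns:
        raise ValueError("marker types not assigned; run filter_sites first")
    prog = matrix.progeny_calls()
    mtype = matrix.sites["marker_type"].to_numpy()
    n_aa = (prog == AA).sum(axis=1).astype(float)
    n_ab = (prog == AB).sum(axis=1).astype(float)
    n_bb = (prog == BB).sum(axis=1).astype(float)

    both = mtype == BOTHHET
    df = np.where(both, 2, 1)
    n_impossible = np.where(both, 0, n_bb).astype(int)
    n_scored = np.where(both, n_aa + n_ab + n_bb, n_aa + n_ab)

    chi2 = np.full(matrix.n_sites, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 1:1 expectation for testcross types
        chi2_tc = (n_aa - n_ab) ** 2 / (n_aa + n_ab)
        # 1:2:1 expectation for both-heterozygous sites
        n = n_aa + n_ab + n_bb
        e1, e2 = n / 4.0, n / 2.0
        chi2_bh = ((n_aa - e1) ** 2 / e1 + (n_ab - e2) ** 2 / e2
                   + (n_bb - e1) ** 2 / e1)
    chi2[~both] = chi2_tc[~both]
    chi2[both] = chi2_bh[both]

    crit = np.where(both, chi2_critical(2, alpha), chi2_critical(1, alpha))
    enough = n_scored >= min_scored
    passed = enough & (chi2 <= crit)
    chi2[~enough] = np.nan

    table = pd.DataFrame(
        {
            "scaffold": matrix.sites["scaffold"].to_numpy(),
            "pos": matrix.sites["pos"].to_numpy(),
            "marker_type": mtype,
            "chi2": chi2,
            "df": df,
            "n_scored": n_scored.astype(int),
            "n_impossible": n_impossible,
            "pass": passed,
        }
    )
    return matrix.subset_sites(passed), table


def full_filter(
    matrix: SnpMatrix,
    min_quality: float = DEFAULT_MIN_QUALITY,
    depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE,
    max_missing: float = DEFAULT_MAX_MISSING,
    seg_alpha: float = DEFAULT_SEG_ALPHA,
    min_scored: int = DEFAULT_MIN_SCORED,
) -> tuple[SnpMatrix, FilterReport, pd.DataFrame]:
    """The complete filter chain: site filters then segregation test."""
    m, report = filter_sites(matrix, min_quality=min_quality,
                             depth_range=depth_range, max_missing=max_missing)
    m, seg_table = segregation_filter(m, alpha=seg_alpha, min_scored=min_scored)
    report.add("distorted_segregation", int((~seg_table["pass"]).sum()))
    return m, report, seg_table
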