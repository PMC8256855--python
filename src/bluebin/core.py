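"""Shared containers and genotype/state codes.

Genotype calls are encoded as small integers throughout the package:
``AA=0, AB=1, BB=2, MISSING=-1``.  Transmitted-allele states on a
per-parent track are ``A=0, B=1, MISSING=-1`` where ``A`` is the
reference allele of the site (founder haplotype 0 in the simulator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype call codes
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

# transmitted-allele state codes
STATE_A: int = 0
STATE_B: int = 1

# marker segregation types of a biallelic site in an outcross:
# P1HET : P1 = AB, P2 = AA  (testcross through parent 1)
# P2HET : P1 = AA, P2 = AB  (testcross through parent 2)
# BOTHHET : P1 = AB, P2 = AB (intercross-like, segregates 1:2:1)
P1HET = "P1HET"
P2HET = "P2HET"
BOTHHET = "BOTHHET"
MARKER_TYPES = (P1HET, P2HET, BOTHHET)

CALL_LABELS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
CALL_CODES = {v: k for k, v in CALL_LABELS.items()}


@dataclass
class SnpMatrix:
    """Biallelic SNP sites x individuals with calls, depth and quality.

    Parameters
    ----------
    sites
        One row per site, ordered by (scaffold, pos).  Required columns:
        ``scaffold, pos, ref, alt, qual, mean_depth``.  Optional columns
        added by downstream stages: ``biallelic``, ``marker_type``,
        ``chi2``, ``seg_pass``.
    calls
        ``int8`` array of shape (n_sites, n_samples) with codes
        AA/AB/BB/MISSING.
    samples
        Sample identifiers, one per calls column.
    parents
        The two parental sample IDs ``(p1, p2)``; must be in *samples*.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: list[str]
    parents: tuple[str, str]
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape does not match sites x samples")
        p1, p2 = self.parents
        for p in (p1, p2):
            if p not in self.samples:
                raise ValueError(f"parent sample {p!r} missing from samples")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def parent_indices(self) -> tuple[int, int]:
        return self.samples.index(self.parents[0]), self.samples.index(self.parents[1])

    @property
    def progeny(self) -> list[str]:
        pset = set(self.parents)
        return [s for s in self.samples if s not in pset]

    @property
    def progeny_indices(self) -> np.ndarray:
        pset = set(self.parent_indices)
        return np.array([i for i in range(self.n_samples) if i not in pset], dtype=int)

    def parent_calls(self) -> tuple[np.ndarray, np.ndarray]:
        i1, i2 = self.parent_indices
        return self.calls[:, i1], self.calls[:, i2]

    def progeny_calls(self) -> np.ndarray:
        return self.calls[:, self.progeny_indices]

    # ------------------------------------------------------------------
    def subset_sites(self, mask: np.ndarray) -> "SnpMatrix":
        """Return a new matrix restricted to sites where *mask* is True."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SnpMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[idx],
            samples=list(self.samples),
            parents=self.parents,
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def sort_sites(self) -> "SnpMatrix":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["scaffold"].to_numpy()))
        return self.subset_sites(order)

    def scaffold_groups(self) -> dict[str, np.ndarray]:
        """Site row indices per scaffold, in (scaffold, pos) order."""
        out: dict[str, np.ndarray] = {}
        scaff = self.sites["scaffold"].to_numpy()
        for s in pd.unique(scaff):
            out[s] = np.flatnonzero(scaff == s)
        return out

    # ------------------------------------------------------------------
    def to_tsv(self, sites_path, calls_path) -> None:
        """Write the site table and a 0/1/2/NA coded genotype matrix."""
        self.sites.to_csv(sites_path, sep="\t", index=False)
        labels = np.array(["NA", "AA", "AB", "BB"])  # index by call+1
        df = pd.DataFrame(labels[self.calls + 1], columns=self.samples)
        df.insert(0, "pos", self.sites["pos"].to_numpy())
        df.insert(0, "scaffold", self.sites["scaffold"].to_numpy())
        df.to_csv(calls_path, sep="\t", index=False)

    @staticmethod
    def from_tsv(sites_path, calls_path, parents: tuple[str, str]) -> "SnpMatrix":
        sites = pd.read_csv(sites_path, sep="\t")
        df = pd.read_csv(calls_path, sep="\t", dtype=str, keep_default_na=False)
        samples = [c for c in df.columns if c not in ("scaffold", "pos")]
        calls = np.vectorize(CALL_CODES.get)(df[samples].to_numpy()).astype(np.int8)
        return SnpMatrix(sites=sites, calls=calls, samples=samples, parents=parents)


@dataclass
class FilterReport:
    """Counts of sites removed per rule, in application order."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, rule: str, n: int) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + int(n)

    def total_removed(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "removed": list(self.counts.values())}
        )
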