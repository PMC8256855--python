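"""Packaged reference tables from the published diploid blueberry map.

Two small fixtures ship with the package: the per-linkage-group
summary of the published high-density bin map (12 LGs) and the
published multi-year QTL summary (13 printed rows; rows reporting two
co-detected QTLs are expanded to one record per QTL, 15 records).
They feed the arithmetic cross-checks: map totals/means and per-trait
QTL means recomputed by :func:`bluebin.linkage.map_summary` and
:func:`bluebin.qtl.qtl_report` must reproduce the published values.

Both files are checksummed at load time; a mismatch is fatal.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "reference_map_summary.tsv":
        "6ccb96fec290231cece69b1fe121c178902775cdab76958ded693580bf949e1a",
    "reference_qtl_summary.tsv":
        "ece07331fc70321a7281567909cd5f728a3b5be9e9ff55c658131f60e8855be0",
}


class FixtureError(RuntimeError):
    """Packaged reference table missing or corrupted."""


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("bluebin").joinpath("data", name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"checksum mismatch for packaged table {name}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", comment="#")


def load_reference_map_summary() -> pd.DataFrame:
    """Per-LG rows: lg, n_bins, n_snps, length_cm, n_gaps_gt10."""
    return _load("reference_map_summary.tsv")


def load_reference_qtl_summary() -> pd.DataFrame:
    """Per-QTL records: trait, year, cutoff_lod, peak_lod, lg,
    bin_first, bin_last, h2, r2, r2_over_h2."""
    return _load("reference_qtl_summary.tsv")
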