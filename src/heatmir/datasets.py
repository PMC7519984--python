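"""Loaders for the curated tables shipped with the package.

``rice_hc_pairs.tsv`` is the curated high-confidence miRNA-family -> target
table for the heat-stressed rice post-meiosis panicle (29 families, 178
distinct target genes, with per-side direction labels).
``rice_ogro_records.tsv`` holds the functionally characterized-gene records
matching those targets.  ``goslim_synthetic.tsv`` is a small synthetic
GO-Slim annotation covering a subset of the target genes, standing in for a
live classification-service export.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from heatmir import io


def _data_path(name: str):
    return resources.files("heatmir.data") / name


def data_sha256(name: str) -> str:
    """Checksum of a packaged data file (pins the curated transcriptions)."""
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def load_hc_pair_table() -> pd.DataFrame:
    """Curated family -> gene direction table (183 rows, 29 families)."""
    with resources.as_file(_data_path("rice_hc_pairs.tsv")) as path:
        return io.read_family_target_table(path)


def load_ogro_table() -> pd.DataFrame:
    """Characterized-gene records for the curated target genes."""
    with resources.as_file(_data_path("rice_ogro_records.tsv")) as path:
        return io.read_ogro_table(path)


def load_goslim_table() -> pd.DataFrame:
    """Synthetic GO-Slim annotation over a subset of the curated targets."""
    with resources.as_file(_data_path("goslim_synthetic.tsv")) as path:
        return io.read_goslim_table(path)
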