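"""Loaders for the published summary tables shipped as package data.

These transcriptions of the study's printed tables serve as fixtures for
the downstream stages: the MTA table (per-trait associations with map
positions), the MTA-QTL region table, the meta-QTL summary table and the
projected quality-gene list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_mta_table",
    "load_mtaqtl_table",
    "load_mqtl_table",
    "load_gene_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("qtlome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_mta_table() -> pd.DataFrame:
    """92 published marker-trait associations (trait, marker, environment,
    chromosome with linkage group, position in cM, -log10 p, marker R^2)."""
    df = _read("table1_mtas.tsv")
    df["environment"] = df["environment"].astype(str)
    return df


def load_mtaqtl_table() -> pd.DataFrame:
    """37 published MTA-QTL regions with traits, member and environment counts."""
    return _read("table2_mtaqtls.tsv")


def load_mqtl_table() -> pd.DataFrame:
    """45 published meta-QTLs with consensus position, CI and member counts."""
    return _read("table4_mqtls.tsv")


def load_gene_table() -> pd.DataFrame:
    """Known grain-quality genes projected onto the consensus map."""
    return _read("table5_genes.tsv")
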