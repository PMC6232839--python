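"""Readers and writers for the pipeline's plain-text interchange formats."""

from __future__ import annotations

import pandas as pd

from .types import QtlRecord

__all__ = ["read_qtl_table", "write_qtl_table", "read_phenotypes", "write_phenotypes"]

QTL_COLUMNS = [
    "qtl_id", "study_id", "trait", "cross_type", "n_progeny", "r2", "lod",
    "chromosome", "position_cM", "ci_cM", "left_marker", "right_marker",
]


def read_qtl_table(path) -> list[QtlRecord]:
    """Literature QTL table CSV -> records; blank ci/flanking fields allowed."""
    df = pd.read_csv(path)
    records = []
    for _, r in df.iterrows():
        records.append(
            QtlRecord(
                qtl_id=str(r["qtl_id"]),
                study_id=str(r["study_id"]),
                trait=str(r["trait"]),
                cross_type=str(r["cross_type"]),
                n_progeny=int(r["n_progeny"]),
                r2=float(r["r2"]),
                lod=float(r["lod"]),
                chromosome=str(r["chromosome"]),
                position_cM=float(r["position_cM"]),
                reported_ci=None if pd.isna(r.get("ci_cM")) else float(r["ci_cM"]),
                left_marker=None if pd.isna(r.get("left_marker")) else str(r["left_marker"]),
                right_marker=None if pd.isna(r.get("right_marker")) else str(r["right_marker"]),
            )
        )
    return records


def write_qtl_table(records: list[QtlRecord], path) -> None:
    rows = [
        dict(
            qtl_id=q.qtl_id, study_id=q.study_id, trait=q.trait,
            cross_type=q.cross_type, n_progeny=q.n_progeny, r2=q.r2,
            lod=q.lod, chromosome=q.chromosome, position_cM=q.position_cM,
            ci_cM=q.reported_ci, left_marker=q.left_marker,
            right_marker=q.right_marker,
        )
        for q in records
    ]
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["year"] = df["year"].astype(str)
    df["is_check"] = df["is_check"].astype(bool)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
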