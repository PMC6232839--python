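"""Core containers shared across the pipeline.

Genotypes are dominant (presence/absence) DArT-style calls held as a float
matrix with 1 = present, 0 = absent, NaN = missing.  Genetic maps are plain
DataFrames in centimorgans; chromosome labels may carry a linkage-group
suffix ("1A.1", "3A.1") and the two linkage groups of one chromosome are
distinct coordinate systems throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "SubpopAssignment",
    "QtlRecord",
    "ProjectedQtl",
    "MetaQtl",
    "base_chromosome",
    "genome_of",
]


def base_chromosome(chrom: str) -> str:
    """Strip a linkage-group suffix: '1A.2' -> '1A'."""
    return str(chrom).split(".")[0].split(" ")[0]


def genome_of(chrom: str) -> str:
    """Genome letter (A/B) of a durum chromosome label like '2B' or '1A.2'."""
    base = base_chromosome(chrom)
    for ch in base:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot determine genome of chromosome {chrom!r}")


@dataclass
class MarkerMap:
    """Genetic map: one row per marker with chromosome and position in cM."""

    entries: pd.DataFrame  # columns: marker, chromosome, position_cM

    COLUMNS = ("marker", "chromosome", "position_cM")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries, columns=list(self.COLUMNS))
        if df["marker"].duplicated().any():
            dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker ids in map: {dups[:5]}")
        df["position_cM"] = df["position_cM"].astype(float)
        df["chromosome"] = df["chromosome"].astype(str)
        self.entries = df.sort_values(
            ["chromosome", "position_cM", "marker"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, marker: str) -> bool:
        return marker in set(self.entries["marker"])

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.entries["chromosome"].unique())

    def chromosome_of(self, marker: str) -> str:
        return self._lookup(marker, "chromosome")

    def position_of(self, marker: str) -> float:
        return self._lookup(marker, "position_cM")

    def _lookup(self, marker: str, col: str):
        rows = self.entries.loc[self.entries["marker"] == marker, col]
        if rows.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return rows.iloc[0]

    def on_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.entries[self.entries["chromosome"] == str(chrom)]

    def subset(self, markers: Iterable[str]) -> "MarkerMap":
        keep = set(markers)
        return MarkerMap(self.entries[self.entries["marker"].isin(keep)].copy())

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t")
        df.columns = list(cls.COLUMNS)[: len(df.columns)]
        return cls(df)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Accessions x markers presence/absence matrix (1/0, NaN = missing)."""

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids not unique")
        valid = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not valid.all():
            raise ValueError("calls must be 0, 1 or NaN")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker: str) -> int:
        try:
            return self.marker_ids.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in genotype matrix") from None

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker)]

    def missingness(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.calls).mean(axis=0)

    def presence_frequency(self) -> np.ndarray:
        """Per-marker presence frequency over non-missing calls (NaN if none)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.calls, axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """min(f, 1-f) of presence frequency; NaN for all-missing markers."""
        f = self.presence_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, markers: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in markers]
        return GenotypeMatrix(
            self.accession_ids, [self.marker_ids[i] for i in idx], self.calls[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accession_ids, columns=self.marker_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class SubpopAssignment:
    """Hard subpopulation labels plus soft membership proportions Q.

    Q rows sum to 1; accessions with no clear membership carry the label
    'admixed' and are excluded from subpopulation-contrast analyses.
    """

    labels: pd.Series  # accession -> subpop label
    Q: pd.DataFrame  # accession x subpop proportions

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        self.Q = pd.DataFrame(self.Q)
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if ((self.Q < -1e-12) | (self.Q > 1 + 1e-12)).any().any():
            raise ValueError("Q entries must lie in [0, 1]")
        missing = set(self.Q.index) - set(self.labels.index)
        if missing:
            raise ValueError(f"accessions without a label: {sorted(missing)[:5]}")

    @property
    def subpops(self) -> list[str]:
        return list(self.Q.columns)

    def structured(self) -> list[str]:
        """Accessions with a real subpopulation label (admixed excluded)."""
        return [a for a, l in self.labels.items() if l != "admixed"]


@dataclass
class QtlRecord:
    """One literature QTL with its study metadata, on the study's own map."""

    qtl_id: str
    study_id: str
    trait: str
    cross_type: str  # RIL | DH | BC | F2
    n_progeny: int
    r2: float
    lod: float
    chromosome: str
    position_cM: float
    reported_ci: float | None = None
    left_marker: str | None = None
    right_marker: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r2 <= 1:
            raise ValueError(f"{self.qtl_id}: r2 must be in (0, 1], got {self.r2}")
        if self.n_progeny < 10:
            raise ValueError(f"{self.qtl_id}: n_progeny must be >= 10")


@dataclass
class ProjectedQtl:
    """A literature QTL carried onto the consensus map."""

    record: QtlRecord
    consensus_position: float | None
    ci_lo: float | None
    ci_hi: float | None
    status: str  # "projected" | "no_common_markers"
    extrapolated: bool = False

    @property
    def ci95(self) -> float | None:
        if self.ci_lo is None or self.ci_hi is None:
            return None
        return self.ci_hi - self.ci_lo

    @property
    def sd(self) -> float | None:
        """Gaussian sd implied by the 95% CI width (width / 3.92)."""
        w = self.ci95
        return None if w is None else w / 3.92


@dataclass
class MetaQtl:
    """A cluster of projected QTLs on the consensus map."""

    mqtl_id: str
    chromosome: str
    position_cM: float
    ci95_cM: float
    members: list[ProjectedQtl] = field(default_factory=list)
    left_marker: str | None = None
    right_marker: str | None = None

    @property
    def n_qtl(self) -> int:
        return len(self.members)

    @property
    def traits(self) -> list[str]:
        return sorted({m.record.trait for m in self.members})


def mtas_to_frame(mtas: pd.DataFrame | Iterable[Mapping]) -> pd.DataFrame:
    """Normalise MTA rows into the canonical column order."""
    df = pd.DataFrame(mtas)
    cols = ["trait", "marker", "environment", "chromosome", "position_cM",
            "neg_log10_p", "r2"]
    return df[[c for c in cols if c in df.columns]].copy()
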