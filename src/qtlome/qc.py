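"""Marker quality-control cascade for dominant presence/absence genotypes.

Filters are applied sequentially in the order: duplicated call patterns,
missingness (strictly more than the threshold), minor allele frequency
(strictly below the threshold, computed on non-missing calls as
min(f, 1-f) of the presence frequency), and finally removal of markers
without a position on the genetic map.  When the failure categories are
disjoint the final retained set does not depend on filter order; the
report records the sequential counts either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MarkerMap

__all__ = [
    "QCReport",
    "find_duplicate_patterns",
    "filter_missingness",
    "filter_maf",
    "anchor_to_map",
    "run_qc",
]


@dataclass
class QCReport:
    n_input: int
    removed_duplicates: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_all_missing: list[str] = field(default_factory=list)
    removed_unmapped: list[str] = field(default_factory=list)
    per_marker: pd.DataFrame | None = None

    @property
    def removed_union(self) -> set[str]:
        return (
            set(self.removed_duplicates)
            | set(self.removed_missing)
            | set(self.removed_maf)
            | set(self.removed_all_missing)
            | set(self.removed_unmapped)
        )

    @property
    def n_retained(self) -> int:
        return self.n_input - len(self.removed_union)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_duplicates": sorted(self.removed_duplicates),
            "removed_missing": sorted(self.removed_missing),
            "removed_maf": sorted(self.removed_maf),
            "removed_all_missing": sorted(self.removed_all_missing),
            "removed_unmapped": sorted(self.removed_unmapped),
        }


def find_duplicate_patterns(
    G: GenotypeMatrix, ignore_missing: bool = False
) -> list[list[str]]:
    """Group markers with identical call vectors.

    Missing is compared as a distinct symbol by default; with
    `ignore_missing`, two markers match when they agree on every accession
    where both are non-missing.  Within each group the first marker in
    input order is the keeper; the rest are flagged by the QC cascade.
    """
    groups: dict[bytes, list[str]] = {}
    if ignore_missing:
        # pairwise agreement on shared non-missing calls
        out: list[list[str]] = []
        used = np.zeros(G.n_markers, dtype=bool)
        C = G.calls
        for i in range(G.n_markers):
            if used[i]:
                continue
            grp = [G.marker_ids[i]]
            for j in range(i + 1, G.n_markers):
                if used[j]:
                    continue
                both = ~np.isnan(C[:, i]) & ~np.isnan(C[:, j])
                if both.any() and np.array_equal(C[both, i], C[both, j]):
                    grp.append(G.marker_ids[j])
                    used[j] = True
            if len(grp) > 1:
                out.append(grp)
        return out
    coded = np.nan_to_num(G.calls, nan=2.0).astype(np.int8)
    for j, marker in enumerate(G.marker_ids):
        groups.setdefault(coded[:, j].tobytes(), []).append(marker)
    return [g for g in groups.values() if len(g) > 1]


def filter_missingness(G: GenotypeMatrix, max_missing: float = 0.20) -> list[str]:
    """Markers whose missing fraction is strictly greater than `max_missing`."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    miss = G.missingness()
    return [m for m, f in zip(G.marker_ids, miss) if f > max_missing]


def filter_maf(
    G: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[list[str], list[str]]:
    """Markers with min(f, 1-f) strictly below `min_maf`.

    Returns (low_maf, all_missing); markers with no non-missing calls are
    reported separately rather than lumped with low-frequency markers.
    """
    maf = G.minor_allele_frequency()
    low, empty = [], []
    for m, v in zip(G.marker_ids, maf):
        if np.isnan(v):
            empty.append(m)
        elif v < min_maf:
            low.append(m)
    return low, empty


def anchor_to_map(
    G: GenotypeMatrix, marker_map: MarkerMap
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop markers without a map position; error if none remain."""
    mapped = set(marker_map.entries["marker"])
    keep = [m for m in G.marker_ids if m in mapped]
    removed = [m for m in G.marker_ids if m not in mapped]
    if not keep:
        raise ValueError("no genotyped marker has a map position")
    return G.subset_markers(keep), removed


def run_qc(
    G: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    ignore_missing_duplicates: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential QC cascade: duplicates, missingness, MAF, map anchoring."""
    report = QCReport(n_input=G.n_markers)

    dup_groups = find_duplicate_patterns(G, ignore_missing=ignore_missing_duplicates)
    report.removed_duplicates = [m for g in dup_groups for m in g[1:]]
    keep = [m for m in G.marker_ids if m not in set(report.removed_duplicates)]
    G1 = G.subset_markers(keep)

    report.removed_missing = filter_missingness(G1, max_missing)
    G2 = G1.subset_markers(
        [m for m in G1.marker_ids if m not in set(report.removed_missing)]
    )

    report.removed_maf, report.removed_all_missing = filter_maf(G2, min_maf)
    drop = set(report.removed_maf) | set(report.removed_all_missing)
    G3 = G2.subset_markers([m for m in G2.marker_ids if m not in drop])

    if marker_map is not None:
        G3, report.removed_unmapped = anchor_to_map(G3, marker_map)

    report.per_marker = pd.DataFrame(
        {
            "marker": G.marker_ids,
            "missingness": G.missingness(),
            "presence_frequency": G.presence_frequency(),
        }
    )
    return G3, report
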