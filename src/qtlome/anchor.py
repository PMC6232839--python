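"""Genetic-to-physical conversion and gene lookup around significant markers.

A marker's genetic neighbourhood (default +/- 1 cM, widened to its
linkage-disequilibrium block when one exists) is converted to a physical
interval using the local Mb/cM ratio derived from the nearest pair of
markers placed on both the consensus map and the genome assembly; gene
models intersecting the interval are read from a GFF3 annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MarkerMap

__all__ = [
    "PhysicalInterval",
    "genetic_to_physical_ratio",
    "marker_interval",
    "genes_in_interval",
    "ld_block",
]


@dataclass
class PhysicalInterval:
    chromosome: str
    start_bp: int  # half-open [start, end)
    end_bp: int
    source_marker: str
    genetic_window_cM: float
    ratio_mb_per_cm: float
    degenerate: bool = False

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


def genetic_to_physical_ratio(
    marker: str,
    consensus: MarkerMap,
    physical: dict[str, float],
) -> tuple[float, bool]:
    """Local Mb-per-cM ratio at a marker from the nearest common pair.

    `physical` maps marker ids to base-pair positions.  The ratio is
    (bp_b - bp_a)/(cM_b - cM_a) over the closest pair of commonly placed
    markers spanning the target; when no pair flanks it the nearest pair
    is used and the extrapolation flag set.  Returns (ratio in Mb/cM,
    extrapolated).  A pair at equal physical positions yields ratio 0
    flagged degenerate via ValueError-free zero return.
    """
    chrom = consensus.chromosome_of(marker)
    target_cm = consensus.position_of(marker)
    cm = consensus.on_chromosome(chrom)
    common = cm[cm["marker"].isin(physical.keys())]
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 markers on chromosome {chrom} with physical positions"
        )
    pos = common["position_cM"].to_numpy()
    ids = common["marker"].to_numpy()
    left = np.flatnonzero(pos <= target_cm)
    right = np.flatnonzero(pos >= target_cm)
    extrapolated = False
    if len(left) and len(right):
        a, b = ids[left[-1]], ids[right[0]]
        if a == b:  # marker itself is anchored; widen to a proper pair
            if len(left) > 1:
                a = ids[left[-2]]
            elif len(right) > 1:
                b = ids[right[1]]
    else:
        # no flanking pair: nearest two markers, extrapolating
        order = np.argsort(np.abs(pos - target_cm))
        a, b = ids[order[0]], ids[order[1]]
        extrapolated = True
    cm_a, cm_b = consensus.position_of(a), consensus.position_of(b)
    if cm_a == cm_b:
        raise ValueError(f"anchor markers {a!r}, {b!r} at coincident cM")
    ratio_bp = (physical[b] - physical[a]) / (cm_b - cm_a)
    return abs(ratio_bp) / 1e6, extrapolated


def marker_interval(
    marker: str,
    consensus: MarkerMap,
    physical: dict[str, float],
    window_cM: float = 1.0,
    ld_block_cM: float | None = None,
    proxy_marker: str | None = None,
) -> PhysicalInterval:
    """Physical interval for marker +/- window (or its LD block if wider).

    The marker needs a physical anchor; if it lacks one, a `proxy_marker`
    mapped at the same genetic position must be supplied explicitly
    (never substituted silently).
    """
    anchor = marker
    if marker not in physical:
        if proxy_marker is None:
            raise KeyError(
                f"marker {marker!r} has no physical position; pass an explicit "
                "proxy_marker mapped at the same genetic position"
            )
        if proxy_marker not in physical:
            raise KeyError(f"proxy marker {proxy_marker!r} has no physical position")
        anchor = proxy_marker
    half = window_cM
    if ld_block_cM is not None:
        half = max(half, ld_block_cM / 2.0)
    ratio_mb, _ = genetic_to_physical_ratio(anchor, consensus, physical)
    center_bp = physical[anchor]
    half_bp = half * ratio_mb * 1e6
    start = int(round(center_bp - half_bp))
    end = int(round(center_bp + half_bp))
    return PhysicalInterval(
        chromosome=consensus.chromosome_of(anchor),
        start_bp=max(start, 0),
        end_bp=max(end, 0),
        source_marker=marker,
        genetic_window_cM=half,
        ratio_mb_per_cm=ratio_mb,
        degenerate=(end <= start),
    )


def genes_in_interval(interval: PhysicalInterval, annotation) -> pd.DataFrame:
    """Gene models whose span intersects [start, end) of the interval.

    `annotation` is a GFF3 path or an open gffutils FeatureDB.  GFF3
    1-based inclusive coordinates are treated as spanning
    [start, end + 1) internally; results are sorted by start.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    empty = pd.DataFrame(columns=["gene_id", "seqid", "start", "end", "strand"])
    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        try:
            db = gffutils.create_db(
                str(annotation), ":memory:", merge_strategy="create_unique",
                keep_order=True,
            )
        except EmptyInputError:
            return empty
    seqids = {f.seqid for f in db.all_features()}
    if not seqids:
        return empty
    if interval.chromosome not in seqids:
        raise KeyError(
            f"chromosome {interval.chromosome!r} not in annotation; "
            f"available: {sorted(seqids)}"
        )
    rows = []
    for g in db.features_of_type("gene"):
        if g.seqid != interval.chromosome:
            continue
        # GFF3 inclusive -> half-open [start, end+1); intersect [lo, hi)
        if g.start < interval.end_bp and (g.end + 1) > interval.start_bp:
            rows.append(
                dict(gene_id=g.id, seqid=g.seqid, start=g.start, end=g.end,
                     strand=g.strand)
            )
    out = pd.DataFrame(rows, columns=["gene_id", "seqid", "start", "end", "strand"])
    return out.sort_values(["start", "gene_id"], kind="stable").reset_index(drop=True)


def ld_block(
    G: GenotypeMatrix,
    marker: str,
    marker_map: MarkerMap,
    r2_threshold: float = 0.5,
) -> tuple[float, list[str]]:
    """Genetic extent (cM) of the LD block around a focal marker.

    Grows the block outwards along the map; a neighbouring marker joins
    while its presence/absence r^2 with every marker already in the block
    is at or above the threshold (monomorphic or undefined pairs count as
    below).  Returns (span in cM, block marker ids).
    """
    chrom = marker_map.chromosome_of(marker)
    cm = marker_map.on_chromosome(chrom)
    ordered = [m for m in cm["marker"] if m in set(G.marker_ids)]
    if marker not in ordered:
        raise KeyError(f"marker {marker!r} not genotyped on its chromosome")
    i = ordered.index(marker)

    def r2(a: str, b: str) -> float:
        xa, xb = G.column(a), G.column(b)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() < 3:
            return 0.0
        va, vb = xa[ok], xb[ok]
        if va.std() == 0 or vb.std() == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1] ** 2)

    block = [marker]
    lo = hi = i
    while lo > 0 and all(r2(ordered[lo - 1], b) >= r2_threshold for b in block):
        lo -= 1
        block.insert(0, ordered[lo])
    while hi < len(ordered) - 1 and all(
        r2(ordered[hi + 1], b) >= r2_threshold for b in block
    ):
        hi += 1
        block.append(ordered[hi])
    span = marker_map.position_of(block[-1]) - marker_map.position_of(block[0])
    return float(span), block
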