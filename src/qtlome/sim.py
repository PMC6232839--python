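"""Synthetic-data generators for every stage of the pipeline.

The generators emulate the study conditions: ~165 durum accessions in five
structured subpopulations, ~1100 dominant presence/absence markers over 14
chromosomes, three year-environments observed in a non-replicated augmented
field design with replicated checks, and a multi-study QTL literature
(RIL/DH/BC/F2 crosses, N 60-300, PVE 0.01-0.55) scattered around true
meta-QTL positions.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MarkerMap, QtlRecord, SubpopAssignment

__all__ = [
    "SimulationConfig",
    "gen_marker_map",
    "gen_structured_genotypes",
    "gen_phenotypes",
    "gen_qc_fixture",
    "fixture_map_for",
    "gen_qtl_literature",
]

DEFAULT_SUBPOPS = ("EM", "EB+T", "WB+E", "WM", "Modern")

#: Default variance components on the scale of a protein-content-like trait:
#: year effects dominate (the trait's between-year swings are large relative
#: to genetic differences), marker effects are a few percent of the mean.
DEFAULT_VARIANCE_COMPONENTS = {
    "year": 4.0,
    "genotype": 1.0,
    "row": 0.25,
    "column": 0.25,
    "residual": 0.5,
}


@dataclass
class SimulationConfig:
    """Knobs for the genotype/phenotype simulators."""

    n_accessions: int = 165
    n_markers: int = 1100
    n_subpops: int = 5
    divergence: float = 0.15  # Balding-Nichols F: between-subpop drift
    missing_rate: float = 0.03
    admixed_fraction: float = 0.10
    n_years: int = 3
    grand_mean: float = 16.0  # protein-content-like scale (%)
    planted_qtls: list = field(default_factory=list)  # (marker, trait, effect)
    variance_components: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    check_every: int = 10  # one replicated check every k-th plot
    n_checks: int = 3
    plots_per_row: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 1:
            raise ValueError(f"divergence must be in [0, 1], got {self.divergence}")
        for p in ("missing_rate", "admixed_fraction"):
            v = getattr(self, p)
            if not 0 <= v <= 1:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        for k, v in self.variance_components.items():
            if v < 0:
                raise ValueError(f"variance component {k!r} must be >= 0, got {v}")


def gen_marker_map(
    n_chrom: int, markers_per_chrom: int, chrom_length: float, seed: int
) -> MarkerMap:
    """Uniform-random marker map over `n_chrom` chromosomes.

    Chromosome labels follow the durum A/B-genome convention (1A, 1B, ...,
    7B) when n_chrom <= 14, else plain 'chr<k>'.
    """
    if n_chrom < 1 or markers_per_chrom < 1:
        raise ValueError("n_chrom and markers_per_chrom must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    rng = np.random.default_rng(seed)
    if n_chrom <= 14:
        labels = [f"{i}{g}" for i in range(1, 8) for g in "AB"][:n_chrom]
    else:
        labels = [f"chr{i}" for i in range(1, n_chrom + 1)]
    rows = []
    k = 0
    for chrom in labels:
        pos = np.sort(rng.uniform(0.0, chrom_length, markers_per_chrom))
        for p in pos:
            rows.append((f"sPt-{k:05d}", chrom, float(p)))
            k += 1
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def gen_structured_genotypes(
    marker_map: MarkerMap, config: SimulationConfig
) -> tuple[GenotypeMatrix, SubpopAssignment]:
    """Balding-Nichols-style structured presence/absence genotypes.

    Per marker, an ancestral presence frequency p ~ U(0.1, 0.9) is perturbed
    per subpopulation by Beta(p(1-F)/F, (1-p)(1-F)/F) with F = divergence;
    F = 0 reproduces the ancestral frequency exactly (no structure).
    A configurable fraction of accessions is admixed (Dirichlet Q rows);
    the rest have one-hot Q and a hard label.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    markers = list(marker_map.entries["marker"])[: cfg.n_markers]
    if len(markers) < cfg.n_markers:
        raise ValueError(
            f"map has {len(markers)} markers, config wants {cfg.n_markers}"
        )
    subpops = list(DEFAULT_SUBPOPS[: cfg.n_subpops])
    if cfg.n_subpops > len(DEFAULT_SUBPOPS):
        subpops += [f"SP{i}" for i in range(len(DEFAULT_SUBPOPS), cfg.n_subpops)]

    n, m, s = cfg.n_accessions, len(markers), cfg.n_subpops
    accessions = [f"acc{i:04d}" for i in range(n)]

    p_anc = rng.uniform(0.1, 0.9, m)
    F = cfg.divergence
    if F == 0:
        p_sub = np.tile(p_anc, (s, 1))
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(np.tile(a, (s, 1)), np.tile(b, (s, 1)))

    n_admixed = int(round(cfg.admixed_fraction * n))
    hard = rng.integers(0, s, n)
    Q = np.zeros((n, s))
    Q[np.arange(n), hard] = 1.0
    labels = np.array([subpops[h] for h in hard], dtype=object)
    if n_admixed:
        idx = rng.choice(n, n_admixed, replace=False)
        Q[idx] = rng.dirichlet(np.ones(s), n_admixed)
        labels[idx] = "admixed"

    # individual presence probability = Q-weighted subpop frequency
    prob = Q @ p_sub
    calls = (rng.random((n, m)) < prob).astype(float)
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = np.nan

    G = GenotypeMatrix(accessions, markers, calls)
    sp = SubpopAssignment(
        labels=pd.Series(labels, index=accessions),
        Q=pd.DataFrame(Q, index=accessions, columns=subpops),
    )
    return G, sp


def _marker_share_kinship(calls: np.ndarray) -> np.ndarray:
    """Fraction of non-missing markers with identical calls, per pair."""
    X = np.where(np.isnan(calls), 0.5, calls)  # missing matches nothing exactly
    obs = (~np.isnan(calls)).astype(float)
    # identical calls contribute 1: use 1 - |xi - xj| summed over shared markers
    n = calls.shape[0]
    K = np.empty((n, n))
    P = np.nan_to_num(calls, nan=0.0)
    Pc = obs - P  # 1 where call == 0
    shared = obs @ obs.T
    same = P @ P.T + Pc @ Pc.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = same / shared
    return K


def gen_phenotypes(
    G: GenotypeMatrix,
    config: SimulationConfig,
    trait: str = "GPC",
) -> pd.DataFrame:
    """Plot-level phenotypes from an augmented design with replicated checks.

    plot value = grand mean + year + row + column + planted marker effects
    + polygenic term (MVN with covariance proportional to marker-sharing
    kinship) + residual.  Checks are interleaved every `check_every`-th plot
    and replicated identically in every year; test entries appear once per
    year.  Returns a long-format table (accession, year, row, column,
    is_check, trait, value).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    vc = {**DEFAULT_VARIANCE_COMPONENTS, **cfg.variance_components}
    for marker, tr, _ in cfg.planted_qtls:
        if marker not in G.marker_ids:
            raise KeyError(f"planted marker {marker!r} not in genotype matrix")

    n = G.n_accessions
    accessions = list(G.accession_ids)

    # genetic values: polygenic + planted, constant across years
    genetic = np.zeros(n)
    if vc["genotype"] > 0:
        K = _marker_share_kinship(G.calls)
        K = K / np.mean(np.diag(K))
        # remove the constant allele-sharing baseline so `genotype` is the
        # variance of independent deviations (kinship only shapes correlation)
        off = K[~np.eye(n, dtype=bool)].mean()
        if off < 1.0:
            K = (K - off) / (1.0 - off)
        np.fill_diagonal(K, 1.0)
        w, V = np.linalg.eigh((K + K.T) / 2)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        genetic += np.sqrt(vc["genotype"]) * (L @ rng.standard_normal(n))
    for marker, tr, effect in cfg.planted_qtls:
        if tr != trait:
            continue
        x = np.nan_to_num(G.column(marker), nan=0.0)
        genetic += effect * x

    check_names = [f"check_{i + 1}" for i in range(cfg.n_checks)]
    check_effects = {
        c: (np.sqrt(vc["genotype"]) * rng.standard_normal() if vc["genotype"] > 0 else 0.0)
        for c in check_names
    }

    # field layout: entries in seeded order, a check after every k-th test plot
    order = rng.permutation(n)
    plots: list[tuple[str, bool]] = []
    ci = 0
    for j, a in enumerate(order):
        plots.append((accessions[a], False))
        if (j + 1) % cfg.check_every == 0:
            plots.append((check_names[ci % cfg.n_checks], True))
            ci += 1
    n_rows = int(np.ceil(len(plots) / cfg.plots_per_row))

    years = [str(2007 + i) for i in range(cfg.n_years)]
    year_eff = (
        np.sqrt(vc["year"]) * rng.standard_normal(cfg.n_years)
        if vc["year"] > 0
        else np.zeros(cfg.n_years)
    )
    rows_out = []
    gen_lookup = dict(zip(accessions, genetic))
    for yi, year in enumerate(years):
        row_eff = np.sqrt(vc["row"]) * rng.standard_normal(n_rows)
        col_eff = np.sqrt(vc["column"]) * rng.standard_normal(cfg.plots_per_row)
        for pi, (entry, is_check) in enumerate(plots):
            r, c = divmod(pi, cfg.plots_per_row)
            g = check_effects[entry] if is_check else gen_lookup[entry]
            eps = (
                np.sqrt(vc["residual"]) * rng.standard_normal()
                if vc["residual"] > 0
                else 0.0
            )
            value = cfg.grand_mean + year_eff[yi] + row_eff[r] + col_eff[c] + g + eps
            rows_out.append((entry, year, r, c, is_check, trait, value))
    return pd.DataFrame(
        rows_out,
        columns=["accession", "year", "row", "column", "is_check", "trait", "value"],
    )


def gen_qc_fixture(
    n_total: int,
    n_duplicate: int,
    n_high_missing: int,
    n_low_maf: int,
    seed: int,
    n_accessions: int = 165,
) -> GenotypeMatrix:
    """Genotype matrix engineered so the QC cascade flags exact counts.

    The failure categories are disjoint by construction: duplicates are
    copies of clean markers (placed after their source so the source is
    kept), high-missing markers have 25% missing calls with balanced
    non-missing frequencies, and low-MAF markers have ~2% presence with no
    missing calls.  Clean markers have no missing calls, frequencies in
    [0.2, 0.8] and pairwise-distinct patterns.
    """
    n_clean = n_total - n_duplicate - n_high_missing - n_low_maf
    if n_clean < 0:
        raise ValueError("category counts exceed n_total")
    if n_duplicate > n_clean:
        raise ValueError("need at least one clean source marker per duplicate")
    rng = np.random.default_rng(seed)
    n = n_accessions
    seen: set[bytes] = set()
    cols: list[np.ndarray] = []

    def unique_column(freq: float) -> np.ndarray:
        for _ in range(1000):
            col = (rng.random(n) < freq).astype(float)
            f = col.mean()
            if not 0.15 <= f <= 0.85:
                continue
            key = col.tobytes()
            if key not in seen:
                seen.add(key)
                return col
        raise RuntimeError("could not draw a unique clean column")

    for _ in range(n_clean):
        cols.append(unique_column(rng.uniform(0.25, 0.75)))
    clean_cols = list(cols)

    dup_sources = rng.choice(n_clean, n_duplicate, replace=False)
    for s in dup_sources:
        cols.append(clean_cols[s].copy())

    n_miss = int(np.ceil(0.25 * n))  # strictly above the 20% threshold
    for _ in range(n_high_missing):
        col = unique_column(0.5)
        miss_idx = rng.choice(n, n_miss, replace=False)
        col = col.copy()
        col[miss_idx] = np.nan
        cols.append(col)

    n_present = max(1, int(np.floor(0.02 * n)))  # MAF ~0.02 < 0.05
    for _ in range(n_low_maf):
        col = np.zeros(n)
        col[rng.choice(n, n_present, replace=False)] = 1.0
        key = col.tobytes()
        while key in seen:
            col = np.zeros(n)
            col[rng.choice(n, n_present, replace=False)] = 1.0
            key = col.tobytes()
        seen.add(key)
        cols.append(col)

    markers = [f"fPt-{i:04d}" for i in range(n_total)]
    accessions = [f"acc{i:04d}" for i in range(n)]
    return GenotypeMatrix(accessions, markers, np.column_stack(cols))


def fixture_map_for(
    marker_ids: list[str],
    n_unmapped: int,
    n_chrom: int = 14,
    chrom_length: float = 200.0,
    seed: int = 0,
) -> MarkerMap:
    """Map covering all but the last-drawn `n_unmapped` of the given markers."""
    if n_unmapped > len(marker_ids):
        raise ValueError("n_unmapped exceeds number of markers")
    rng = np.random.default_rng(seed)
    mapped = list(rng.permutation(marker_ids)[: len(marker_ids) - n_unmapped])
    labels = [f"{i}{g}" for i in range(1, 8) for g in "AB"][:n_chrom]
    rows = []
    for i, mk in enumerate(sorted(mapped)):
        chrom = labels[i % n_chrom]
        rows.append((mk, chrom, float(rng.uniform(0, chrom_length))))
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


_CROSS_TYPES = ("RIL", "DH", "BC", "F2")
_CROSS_PROBS = (0.5, 0.2, 0.1, 0.2)
_TRAITS = ("GPC", "GS", "YI", "YPC", "TW")


def gen_qtl_literature(
    consensus: MarkerMap,
    true_mqtls: list[tuple[str, float, float]],
    n_studies: int,
    seed: int,
    n_qtls: int | None = None,
    common_markers_per_chrom: int = 4,
    fraction_without_common_markers: float = 0.0,
) -> tuple[list[QtlRecord], dict[str, MarkerMap]]:
    """Simulate a multi-study QTL literature around true meta-QTL positions.

    Each study has its own per-chromosome affine (rescaled and shifted)
    coordinate system sharing `common_markers_per_chrom` markers with the
    consensus map; a `fraction_without_common_markers` of studies shares
    none (to exercise projection failure).  Per QTL, a cross type, progeny
    count N ~ U{60..300} and PVE R2 (right-skewed in [0.01, 0.55]) are
    drawn; the QTL's positional error around its meta-QTL position is
    proportional to the precision implied by its empirical CI
    (sd_i = CI_i/3.92), rescaled so the root-mean-square scatter equals the
    meta-QTL's `spread` (spread = 0 -> no noise).
    """
    if common_markers_per_chrom < 2:
        raise ValueError("need at least 2 common markers per chromosome")
    rng = np.random.default_rng(seed)
    n_qtls = n_qtls if n_qtls is not None else 10 * len(true_mqtls)

    studies = [f"study{i:02d}" for i in range(n_studies)]
    n_nocommon = int(round(fraction_without_common_markers * n_studies))
    nocommon = set(rng.choice(n_studies, n_nocommon, replace=False))

    # per study+chromosome affine transform consensus -> study coordinates
    chroms = sorted({c for c, _, _ in true_mqtls})
    transform: dict[tuple[str, str], tuple[float, float]] = {}
    study_maps: dict[str, MarkerMap] = {}
    for si, study in enumerate(studies):
        rows = []
        for chrom in chroms:
            scale = rng.uniform(0.8, 1.25)
            shift = rng.uniform(0.0, 10.0)
            transform[(study, chrom)] = (scale, shift)
            cons = consensus.on_chromosome(chrom)
            if si in nocommon or len(cons) < 2:
                # private markers only: nothing shared with the consensus
                for j in range(common_markers_per_chrom):
                    rows.append(
                        (f"{study}-{chrom}-m{j}", chrom,
                         float(rng.uniform(0, cons["position_cM"].max() if len(cons) else 100.0)))
                    )
                continue
            k = min(common_markers_per_chrom, len(cons))
            # spread anchors over the chromosome: first, last, random interior
            idx = np.unique(
                np.r_[0, len(cons) - 1, rng.choice(len(cons), max(k - 2, 0), replace=False)]
            )
            for i in idx:
                mk = cons.iloc[i]
                rows.append((mk["marker"], chrom, scale * mk["position_cM"] + shift))
        study_maps[study] = MarkerMap(
            pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS))
        )

    # raw study precisions, then rescale scatter to the requested spread
    records: list[QtlRecord] = []
    assign = rng.integers(0, len(true_mqtls), n_qtls)
    cross = rng.choice(len(_CROSS_TYPES), n_qtls, p=_CROSS_PROBS)
    N = rng.integers(60, 301, n_qtls)
    R2 = 0.01 + 0.54 * rng.beta(1.6, 5.0, n_qtls)
    sd_raw = np.empty(n_qtls)
    for i in range(n_qtls):
        num = 163.0 if _CROSS_TYPES[cross[i]] == "RIL" else 530.0
        sd_raw[i] = (num / (N[i] * R2[i])) / 3.92
    z = rng.standard_normal(n_qtls)

    for j, (chrom, _, spread) in enumerate(true_mqtls):
        members = np.flatnonzero(assign == j)
        if len(members) == 0:
            continue
        rms = float(np.sqrt(np.mean(sd_raw[members] ** 2)))
        for i in members:
            scale_i = spread * sd_raw[i] / rms if rms > 0 else 0.0
            dev = scale_i * z[i]
            mqtl_pos = true_mqtls[j][1]
            study = studies[int(rng.integers(0, n_studies))]
            a, b = transform[(study, chrom)]
            true_pos = mqtl_pos + dev
            lod = max(2.0, -(N[i] / (2 * np.log(10))) * np.log(max(1 - R2[i], 1e-9)))
            records.append(
                QtlRecord(
                    qtl_id=f"q{i:03d}",
                    study_id=study,
                    trait=str(rng.choice(_TRAITS)),
                    cross_type=_CROSS_TYPES[cross[i]],
                    n_progeny=int(N[i]),
                    r2=float(R2[i]),
                    lod=float(lod),
                    chromosome=chrom,
                    position_cM=float(a * true_pos + b),
                )
            )
    return records, study_maps
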