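"""Mixed-linear-model association scan with kinship and structure (K+Q).

The model per marker is y = mu + Q v + x beta + u + e with cov(u)
proportional to the allele-sharing kinship K.  Variance components are
estimated once on the null model (no marker) by REML on the spectral
decomposition of K and reused for every marker — the
population-parameters-previously-determined shortcut — after which each
marker test is an F-test in the whitened (decorrelated) model.

The significance threshold follows the Q-Q-plot rule: the observed
-log10(p) at the smallest rank from which the observed quantiles deviate
from the uniform expectation by more than `delta` for all larger ranks,
floored at 2.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist

from .types import GenotypeMatrix, MarkerMap, genome_of, mtas_to_frame

__all__ = [
    "compute_kinship",
    "mlm_scan",
    "qq_threshold",
    "call_mtas",
    "summarize_mtas",
    "genomic_lambda",
]


def compute_kinship(G: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing kinship: fraction of markers with identical calls.

    Computed over pairwise non-missing markers; bent to positive
    semi-definiteness by shifting negative eigenvalues if needed.  The
    diagonal is 1 by construction (mean diagonal 1).
    """
    C = G.calls
    obs = (~np.isnan(C)).astype(float)
    P = np.nan_to_num(C, nan=0.0)
    Pc = obs - P
    shared = obs @ obs.T
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"accessions {G.accession_ids[i]!r} and {G.accession_ids[j]!r} "
            "share no non-missing calls"
        )
    K = (P @ P.T + Pc @ Pc.T) / shared
    K = (K + K.T) / 2.0
    w = np.linalg.eigvalsh(K)
    if w[0] < 0:
        K = K + (1e-8 - w[0]) * np.eye(K.shape[0])
    return pd.DataFrame(K, index=G.accession_ids, columns=G.accession_ids)


def _null_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """REML variance ratio for y = X b + u + e, cov(u) = s2g K.

    Returns (lambda = s2g/s2e, eigenvalues, eigenvectors of K).
    """
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    n, p = X.shape

    def neg_reml(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        w = lam * s + 1.0
        Xw = Xt / w[:, None]
        XtX = Xt.T @ Xw
        try:
            beta = np.linalg.solve(XtX, Xw.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / w))
        sign, logdet_XtX = np.linalg.slogdet(XtX)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(w))
            + logdet_XtX
            + (n - p)
        )
        return -ll

    res = minimize_scalar(neg_reml, bounds=(-5.0, 5.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = 10.0 ** res.x
    return lam, s, U


def mlm_scan(
    G: GenotypeMatrix,
    y: pd.Series,
    Q: pd.DataFrame | None = None,
    K: pd.DataFrame | None = None,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Per-marker K+Q mixed-model F-tests.

    `y` is a phenotype (typically BLUPs) indexed by accession; Q columns
    are membership proportions (one column is dropped against the
    intercept); K defaults to the allele-sharing kinship of G.  Markers
    with within-sample MAF below `min_maf`, or collinear with the fixed
    part, are skipped with a reason.  Returns a frame with p, -log10(p)
    and marker R^2 (marker SS / total SS of the whitened model).
    """
    acc = [a for a in G.accession_ids if a in set(y.index)]
    if len(acc) < 10:
        raise ValueError("need >= 10 accessions with phenotype and genotypes")
    idx = [G.accession_ids.index(a) for a in acc]
    C = G.calls[idx, :]
    yv = y.reindex(acc).to_numpy(float)
    if np.isnan(yv).any():
        raise ValueError("phenotype contains missing values")

    X0 = [np.ones((len(acc), 1))]
    if Q is not None:
        Qm = Q.reindex(acc).to_numpy(float)
        X0.append(Qm[:, :-1])  # drop one column against the intercept
    X0 = np.hstack(X0)

    if K is None:
        Km = compute_kinship(G.subset_markers(G.marker_ids)).loc[acc, acc].to_numpy()
    else:
        Km = K.loc[acc, acc].to_numpy(float)

    lam, s, U = _null_reml(yv, X0, Km)
    w = np.sqrt(lam * s + 1.0)
    # whiten: rows of the rotated model divided by per-eigenvalue sd
    yt = (U.T @ yv) / w
    X0t = (U.T @ X0) / w[:, None]

    # project the fixed part out of y and every marker
    B0, *_ = np.linalg.lstsq(X0t, yt, rcond=None)
    ry = yt - X0t @ B0
    ss_res0 = float(ry @ ry)
    ybar_w = float(np.mean(yt))
    ss_total = float(np.sum((yt - ybar_w) ** 2))

    Xmk = np.where(np.isnan(C), np.nanmean(C, axis=0), C)  # mean-impute
    maf = np.minimum(np.nanmean(C, axis=0), 1 - np.nanmean(C, axis=0))
    Xt = (U.T @ Xmk) / w[:, None]
    P0 = np.linalg.lstsq(X0t, Xt, rcond=None)[0]
    RX = Xt - X0t @ P0  # marker residuals after the fixed part

    n, p0 = X0t.shape
    df2 = n - p0 - 1
    rxx = np.sum(RX * RX, axis=0)
    rxy = RX.T @ ry
    out = []
    for j, marker in enumerate(G.marker_ids):
        if not np.isfinite(maf[j]) or maf[j] < min_maf:
            out.append((marker, np.nan, np.nan, np.nan, "low_maf"))
            continue
        if rxx[j] < 1e-10 * n:
            out.append((marker, np.nan, np.nan, np.nan, "collinear"))
            continue
        ss_marker = rxy[j] ** 2 / rxx[j]
        rss = ss_res0 - ss_marker
        if rss <= 0:
            rss = 1e-12
        F = ss_marker / (rss / df2)
        p = float(f_dist.sf(F, 1, df2))
        r2 = float(ss_marker / ss_total) if ss_total > 0 else np.nan
        out.append((marker, p, -np.log10(max(p, 1e-300)), r2, "tested"))
    return pd.DataFrame(
        out, columns=["marker", "p", "neg_log10_p", "r2", "status"]
    )


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor from median chi-square (1 df)."""
    from scipy.stats import chi2

    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi = chi2.isf(p, 1)
    return float(np.median(chi) / chi2.ppf(0.5, 1))


def qq_threshold(
    p_values: np.ndarray, delta: float = 0.1, floor: float = 2.0
) -> tuple[float, bool]:
    """Q-Q-plot significance threshold on the -log10(p) scale.

    Observed -log10(p), sorted ascending, is compared with uniform
    expected quantiles; the threshold is the observed value at the
    smallest rank from which observed - expected > delta holds for all
    larger ranks.  Never below `floor`.  Returns (threshold, deviated):
    deviated is False when no deviation point exists and the floor is
    returned.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 50:
        raise ValueError("need >= 50 p-values for a Q-Q threshold")
    obs = np.sort(-np.log10(np.clip(p, 1e-300, 1.0)))
    n = len(obs)
    exp = -np.log10((n - np.arange(n) - 0.5) / n)  # ascending (k-0.5)/n quantiles
    above = obs - exp > delta
    # smallest rank from which deviation holds for all larger ranks
    run = above[::-1]
    k = 0
    while k < n and run[k]:
        k += 1
    if k > 0:
        idx = n - k
        return max(float(obs[idx]), floor), True
    return floor, False


def call_mtas(
    scans: dict[tuple[str, str], pd.DataFrame],
    thresholds: dict[tuple[str, str], float] | float,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Collect marker-trait associations above per-(trait, environment)
    thresholds into a single MTA table with map positions."""
    rows = []
    for (trait, env), scan in scans.items():
        thr = thresholds if np.isscalar(thresholds) else thresholds[(trait, env)]
        hits = scan[scan["neg_log10_p"] >= thr]
        for _, h in hits.iterrows():
            chrom, pos = None, np.nan
            if marker_map is not None and h["marker"] in marker_map:
                chrom = marker_map.chromosome_of(h["marker"])
                pos = marker_map.position_of(h["marker"])
            rows.append(
                dict(trait=trait, marker=h["marker"], environment=env,
                     chromosome=chrom, position_cM=pos,
                     neg_log10_p=h["neg_log10_p"], r2=h["r2"])
            )
    return mtas_to_frame(rows) if rows else pd.DataFrame(
        columns=["trait", "marker", "environment", "chromosome", "position_cM",
                 "neg_log10_p", "r2"]
    )


def summarize_mtas(mtas: pd.DataFrame) -> dict:
    """Headline counts: MTAs, unique markers, per-trait counts, genome share."""
    if mtas.empty:
        return dict(n_mtas=0, n_markers=0, per_trait={}, genome_share={})
    genomes = mtas["chromosome"].map(genome_of)
    share = (genomes.value_counts(normalize=True) * 100).round(0).to_dict()
    recurrent = (
        mtas.groupby(["trait", "marker"])["environment"].nunique()
    )
    return dict(
        n_mtas=len(mtas),
        n_markers=mtas["marker"].nunique(),
        per_trait=mtas["trait"].value_counts().to_dict(),
        genome_share={g: int(v) for g, v in share.items()},
        n_chromosomes=mtas["chromosome"].map(
            lambda c: c.split(".")[0]
        ).nunique(),
        markers_in_multiple_environments=int((recurrent >= 2).sum()),
    )
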