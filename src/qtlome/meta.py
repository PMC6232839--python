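"""Literature-QTL confidence intervals, homothetic projection, and
meta-QTL clustering by a Gaussian mixture with information-criterion
model selection.

Confidence intervals missing from a source study are estimated by the
empirical population-size formulas CI = 163/(N*R2) for RIL crosses and
CI = 530/(N*R2) for DH, BC and F2 progenies, read as 95% interval widths
centered on the QTL position.  Projection onto the consensus map is a
per-interval linear rescaling anchored on markers common to both maps.
Clustering treats each projected QTL position as Gaussian around its
meta-QTL with known per-QTL standard deviation CI/3.92; the number of
components is chosen by AIC (BIC/AICc selectable), ties toward fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MarkerMap, MetaQtl, ProjectedQtl, QtlRecord

__all__ = [
    "estimate_ci",
    "project_qtl",
    "project_all",
    "MixtureFit",
    "fit_mixture",
    "select_model",
    "assign_and_filter",
    "MetaConfig",
    "run_meta",
]

_CI_NUMERATOR = {"RIL": 163.0, "DH": 530.0, "BC": 530.0, "F2": 530.0}


def estimate_ci(cross_type: str, n_progeny: int, r2: float) -> float:
    """95% CI width (cM): 163/(N*R2) for RIL, 530/(N*R2) for DH/BC/F2."""
    if cross_type not in _CI_NUMERATOR:
        raise ValueError(f"unknown cross type {cross_type!r}")
    if n_progeny <= 0:
        raise ValueError("n_progeny must be > 0")
    if not 0 < r2 <= 1:
        raise ValueError("r2 must be in (0, 1]")
    return _CI_NUMERATOR[cross_type] / (n_progeny * r2)


def _interpolator(study_pos: np.ndarray, cons_pos: np.ndarray, max_extrapolation: float = 20.0):
    """Piecewise-linear transform through common-marker anchor pairs."""

    def transform(p: float) -> tuple[float, bool]:
        if study_pos[0] <= p <= study_pos[-1]:
            j = int(np.searchsorted(study_pos, p, side="right")) - 1
            j = min(max(j, 0), len(study_pos) - 2)
            extrap = False
        elif p < study_pos[0]:
            j, extrap = 0, True
        else:
            j, extrap = len(study_pos) - 2, True
        sa, sb = study_pos[j], study_pos[j + 1]
        ca, cb = cons_pos[j], cons_pos[j + 1]
        scale = (cb - ca) / (sb - sa)
        anchor_s, anchor_c = (sa, ca) if p <= sb else (sb, cb)
        if extrap:
            dist = min(abs(p - study_pos[0]), abs(p - study_pos[-1]))
            if dist > max_extrapolation:
                return np.nan, True
        return anchor_c + (p - anchor_s) * scale, extrap

    return transform


def project_qtl(
    qtl: QtlRecord,
    study_map: MarkerMap,
    consensus: MarkerMap,
    ci_precedence: str = "reported",
    max_extrapolation: float = 20.0,
) -> ProjectedQtl:
    """Homothetic projection of one QTL onto the consensus map.

    Finds the markers common to both maps on the QTL's chromosome and
    linearly rescales within the flanking common interval; a QTL outside
    the common-marker span uses the nearest interval's scale anchored at
    the nearest common marker, flagged as extrapolated and downgraded to
    unprojectable beyond `max_extrapolation` cM.  The CI (reported if
    present and `ci_precedence='reported'`, else the empirical formula) is
    projected by the same transform.
    """
    chrom = qtl.chromosome
    sm = study_map.on_chromosome(chrom)
    cm = consensus.on_chromosome(chrom)
    common = sorted(set(sm["marker"]) & set(cm["marker"]))
    if len(common) < 2:
        return ProjectedQtl(qtl, None, None, None, "no_common_markers")

    spos = np.array([study_map.position_of(m) for m in common])
    cpos = np.array([consensus.position_of(m) for m in common])
    order = np.argsort(spos)
    spos, cpos = spos[order], cpos[order]
    if np.any(np.diff(spos) == 0):
        raise ValueError(
            f"{qtl.qtl_id}: coincident common markers on the study map"
        )
    inverted = bool(np.any(np.diff(cpos) < 0))
    if inverted:
        import warnings

        warnings.warn(
            f"{qtl.qtl_id}: marker order inverted between maps; using |scale|",
            stacklevel=2,
        )
        cpos = np.abs(cpos - cpos[0]) + cpos.min()
        cpos = np.sort(cpos)

    transform = _interpolator(spos, cpos, max_extrapolation)
    pos, extrap = transform(qtl.position_cM)
    if not np.isfinite(pos):
        return ProjectedQtl(qtl, None, None, None, "no_common_markers", True)

    if ci_precedence == "reported" and qtl.reported_ci is not None:
        ci_study = float(qtl.reported_ci)
    else:
        ci_study = estimate_ci(qtl.cross_type, qtl.n_progeny, qtl.r2)
    lo_s, hi_s = qtl.position_cM - ci_study / 2, qtl.position_cM + ci_study / 2
    lo, _ = transform(np.clip(lo_s, spos[0] - max_extrapolation, None))
    hi, _ = transform(np.clip(hi_s, None, spos[-1] + max_extrapolation))
    if not (np.isfinite(lo) and np.isfinite(hi)):
        # CI ends beyond the extrapolation cap: keep the study width
        lo, hi = pos - ci_study / 2, pos + ci_study / 2
    lo, hi = min(lo, hi), max(lo, hi)
    lo, hi = min(lo, pos), max(hi, pos)
    if hi - lo <= 0:
        hi = lo + 1e-6
    return ProjectedQtl(qtl, float(pos), float(lo), float(hi), "projected", extrap)


def project_all(
    qtls: list[QtlRecord],
    study_maps: dict[str, MarkerMap],
    consensus: MarkerMap,
    **kw,
) -> list[ProjectedQtl]:
    out = []
    for q in qtls:
        sm = study_maps.get(q.study_id)
        if sm is None:
            out.append(ProjectedQtl(q, None, None, None, "no_common_markers"))
        else:
            out.append(project_qtl(q, sm, consensus, **kw))
    return out


@dataclass
class MixtureFit:
    k: int
    means: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # n x k
    log_likelihood: float
    n_free_parameters: int

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_free_parameters

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + np.log(n) * self.n_free_parameters

    @property
    def aicc(self) -> float:
        n = self.posteriors.shape[0]
        p = self.n_free_parameters
        if n - p - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * p * (p + 1) / (n - p - 1)


def _em(
    x: np.ndarray,
    sd: np.ndarray,
    mu0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MixtureFit:
    n, k = len(x), len(mu0)
    mu = mu0.astype(float).copy()
    wts = np.full(k, 1.0 / k)
    var = sd ** 2
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step: responsibilities under per-observation known variance
        logphi = (
            -0.5 * ((x[:, None] - mu[None, :]) ** 2) / var[:, None]
            - 0.5 * np.log(2 * np.pi * var)[:, None]
            + np.log(np.clip(wts, 1e-300, None))[None, :]
        )
        m = logphi.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logphi - m).sum(axis=1))
        ll = float(lse.sum())
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite mixture likelihood")
        gamma = np.exp(logphi - lse[:, None])
        # M-step
        wts = gamma.mean(axis=0)
        precision = gamma / var[:, None]
        denom = precision.sum(axis=0)
        empty = denom <= 1e-12
        if empty.any():
            raise _EmptyComponent()
        mu = (precision * x[:, None]).sum(axis=0) / denom
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return MixtureFit(
        k=k, means=mu, weights=wts, posteriors=gamma,
        log_likelihood=prev_ll, n_free_parameters=2 * k - 1,
    )


class _EmptyComponent(Exception):
    pass


def fit_mixture(
    positions: np.ndarray,
    sds: np.ndarray,
    k: int,
    n_starts: int = 1,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a k-component Gaussian mixture with known per-QTL sd.

    Initialised at the k-quantiles of the positions (deterministic);
    additional random restarts perturb the quantile means.  If a
    component empties during EM the fit is retried with k-1 and the
    result flagged through its reduced k.
    """
    x = np.asarray(positions, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if len(x) != len(sd):
        raise ValueError("positions and sds must have equal length")
    if k > len(np.unique(x)):
        raise ValueError(f"k={k} exceeds {len(np.unique(x))} distinct positions")
    if np.any(sd <= 0):
        raise ValueError("all sds must be > 0")

    qs = np.quantile(x, (np.arange(k) + 0.5) / k)
    starts = [qs]
    rng = np.random.default_rng(seed)
    span = max(x.max() - x.min(), 1.0)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(qs + rng.normal(0, 0.05 * span, k))

    best: MixtureFit | None = None
    for mu0 in starts:
        try:
            fit = _em(x, sd, np.sort(mu0))
        except _EmptyComponent:
            if k == 1:
                raise FloatingPointError("mixture collapsed at k=1")
            fit = fit_mixture(x, sd, k - 1, n_starts=1, seed=seed)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def select_model(fits: list[MixtureFit], criterion: str = "aic") -> MixtureFit:
    """Fit with the minimal information criterion; ties toward smaller k."""
    if not fits:
        raise ValueError("no fits to select from")
    n = fits[0].posteriors.shape[0]

    def score(f: MixtureFit) -> float:
        if criterion == "aic":
            return f.aic
        if criterion == "bic":
            return f.bic(n)
        if criterion == "aicc":
            return f.aicc
        raise ValueError(f"unknown criterion {criterion!r}")

    ordered = sorted(fits, key=lambda f: (round(score(f), 12), f.k))
    return ordered[0]


@dataclass
class MetaConfig:
    """Pre-filter and assignment rules for the meta-analysis.

    lod_min and ci_max exclude weak/imprecise QTLs before clustering;
    ambiguity_cutoff is the minimum posterior membership for a QTL to be
    assigned to its best component (the membership-coefficient rule).
    The mixture/AIC estimator is shared by both chromosome-size branches:
    single-start EM below `method_switch_n` QTLs, multi-start above.
    """

    lod_min: float = 2.0
    ci_max: float = 100.0
    ambiguity_cutoff: float = 0.6
    criterion: str = "aic"
    method_switch_n: int = 10
    k_max: int = 10
    multi_starts: int = 5
    seed: int = 0


def assign_and_filter(
    fit: MixtureFit,
    qtls: list[ProjectedQtl],
    consensus: MarkerMap | None = None,
    config: MetaConfig | None = None,
    chromosome: str | None = None,
    id_offset: int = 0,
) -> tuple[list[MetaQtl], list[ProjectedQtl], list[tuple[ProjectedQtl, str]]]:
    """Assign clustered QTLs to meta-QTLs and apply the exclusion rules.

    QTLs whose maximum posterior membership falls below the ambiguity
    cutoff (CI overlapping several components) are excluded; one-member
    components become singletons.  MQTL position is the precision-weighted
    mean of member positions and its 95% CI is 3.92/sqrt(sum 1/sd_i^2);
    flanking markers are the nearest consensus markers outside the CI.
    """
    cfg = config or MetaConfig()
    chrom = chromosome or (qtls[0].record.chromosome if qtls else "NA")
    excluded: list[tuple[ProjectedQtl, str]] = []
    singles: list[ProjectedQtl] = []

    members: dict[int, list[ProjectedQtl]] = {j: [] for j in range(fit.k)}
    for i, q in enumerate(qtls):
        post = fit.posteriors[i]
        j = int(np.argmax(post))
        if post[j] < cfg.ambiguity_cutoff:
            excluded.append((q, "ambiguous_membership"))
        else:
            members[j].append(q)

    mqtls: list[MetaQtl] = []
    idx = id_offset
    for j in sorted(members, key=lambda j: fit.means[j]):
        ms = members[j]
        if len(ms) == 0:
            continue
        if len(ms) == 1:
            singles.append(ms[0])
            continue
        prec = np.array([1.0 / q.sd ** 2 for q in ms])
        pos = np.array([q.consensus_position for q in ms])
        center = float((prec * pos).sum() / prec.sum())
        ci95 = float(3.92 / np.sqrt(prec.sum()))
        idx += 1
        left, right = _flanking_markers(consensus, chrom, center, ci95)
        mqtls.append(
            MetaQtl(
                mqtl_id=f"mqtl{chrom}.{idx - id_offset}",
                chromosome=chrom,
                position_cM=center,
                ci95_cM=ci95,
                members=ms,
                left_marker=left,
                right_marker=right,
            )
        )
    return mqtls, singles, excluded


def _flanking_markers(
    consensus: MarkerMap | None, chrom: str, center: float, ci95: float
) -> tuple[str | None, str | None]:
    if consensus is None:
        return None, None
    cm = consensus.on_chromosome(chrom)
    if cm.empty:
        return None, None
    lo, hi = center - ci95 / 2, center + ci95 / 2
    left = cm[cm["position_cM"] <= lo]
    right = cm[cm["position_cM"] >= hi]
    return (
        left.iloc[-1]["marker"] if len(left) else None,
        right.iloc[0]["marker"] if len(right) else None,
    )


@dataclass
class MetaReport:
    mqtls: list[MetaQtl]
    singletons: list[ProjectedQtl]
    excluded: list[tuple[ProjectedQtl, str]]
    unprojected: list[ProjectedQtl]
    fits: dict[str, MixtureFit] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [
            dict(
                chromosome=m.chromosome, mqtl=m.mqtl_id,
                position_cM=round(m.position_cM, 1),
                ci95_cM=round(m.ci95_cM, 2), left_marker=m.left_marker,
                right_marker=m.right_marker, n_qtl=m.n_qtl,
                traits=",".join(m.traits),
            )
            for m in self.mqtls
        ]
        return pd.DataFrame(
            rows, columns=["chromosome", "mqtl", "position_cM", "ci95_cM",
                           "left_marker", "right_marker", "n_qtl", "traits"]
        )

    def ci_reduction(self) -> float:
        """1 - (mean MQTL CI / mean member CI); > 0 means pooling helped."""
        member_cis = [q.ci95 for m in self.mqtls for q in m.members]
        if not member_cis or not self.mqtls:
            return np.nan
        return 1.0 - np.mean([m.ci95_cM for m in self.mqtls]) / np.mean(member_cis)

    def conserved(self, n_projected: int) -> bool:
        n = (
            sum(m.n_qtl for m in self.mqtls)
            + len(self.singletons)
            + len(self.excluded)
        )
        return n == n_projected


def run_meta(
    projected: list[ProjectedQtl],
    consensus: MarkerMap | None = None,
    config: MetaConfig | None = None,
) -> MetaReport:
    """Full per-chromosome meta-analysis of projected QTLs.

    Chromosomes with fewer QTLs than the method switch use a single-start
    exhaustive k-scan; larger ones use the same estimator with multi-start
    EM.  Unprojectable QTLs are reported separately; the conservation
    invariant (members + singletons + excluded = projected input) holds.
    """
    cfg = config or MetaConfig()
    unprojected = [q for q in projected if q.status != "projected"]
    usable = [q for q in projected if q.status == "projected"]

    excluded: list[tuple[ProjectedQtl, str]] = []
    pre: dict[str, list[ProjectedQtl]] = {}
    for q in usable:
        if q.record.lod < cfg.lod_min:
            excluded.append((q, "low_lod"))
        elif q.ci95 > cfg.ci_max:
            excluded.append((q, "large_ci"))
        else:
            pre.setdefault(q.record.chromosome, []).append(q)

    mqtls: list[MetaQtl] = []
    singles: list[ProjectedQtl] = []
    fits: dict[str, MixtureFit] = {}
    for chrom in sorted(pre):
        qtls = pre[chrom]
        if len(qtls) == 1:
            singles.extend(qtls)
            continue
        x = np.array([q.consensus_position for q in qtls])
        sd = np.array([q.sd for q in qtls])
        n_distinct = len(np.unique(x))
        k_max = min(cfg.k_max, n_distinct)
        n_starts = 1 if len(qtls) < cfg.method_switch_n else cfg.multi_starts
        fit_list = [
            fit_mixture(x, sd, k, n_starts=n_starts, seed=cfg.seed + k)
            for k in range(1, k_max + 1)
        ]
        best = select_model(fit_list, cfg.criterion)
        fits[chrom] = best
        m, s, e = assign_and_filter(
            best, qtls, consensus, cfg, chromosome=chrom
        )
        mqtls.extend(m)
        singles.extend(s)
        excluded.extend(e)
    return MetaReport(mqtls, singles, excluded, unprojected, fits)
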