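"""Phenotype modelling for the augmented field design.

The plot-level mixed model treats the replicated check cultivars as fixed
effects and row, column and cultivar as random effects; REML variance
components and cultivar BLUPs come from statsmodels' MixedLM.  The combined
ANOVA operates on per-year BLUPs (one value per cultivar-year, since test
entries are unreplicated within a year) with the year x cultivar
interaction as the error term, and partitions the cultivar sum of squares
into between- and within-subpopulation components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .types import SubpopAssignment

__all__ = [
    "VarianceComponents",
    "fit_blup",
    "combined_anova",
    "tukey_hsd",
    "compact_letter_display",
    "sedimentation_index",
    "quality_index",
    "QI_WEIGHTS",
]

QI_WEIGHTS = {"GPC": 0.40, "GS": 0.30, "YI": 0.20, "TW": 0.10}


@dataclass
class VarianceComponents:
    components: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0
    converged: bool = True

    def __getitem__(self, key: str) -> float:
        if key == "residual":
            return self.residual
        return self.components[key]


def _vc_dummies(values: pd.Series) -> tuple[list[str], np.ndarray]:
    """0/1 dummy matrix over the non-null levels of a factor.

    Null entries (e.g. check plots for the cultivar factor) get all-zero
    rows, i.e. no random effect.
    """
    levels = sorted({v for v in values if v is not None})
    mat = np.zeros((len(values), len(levels)))
    index = {l: j for j, l in enumerate(levels)}
    for i, v in enumerate(values):
        if v is not None:
            mat[i, index[v]] = 1.0
    return levels, mat


def fit_blup(
    pheno: pd.DataFrame,
    trait: str,
    year: str | None = None,
    random_effects: tuple[str, ...] = ("cultivar", "row", "column"),
) -> tuple[pd.DataFrame, VarianceComponents]:
    """REML fit of the augmented-design mixed model; returns cultivar BLUPs.

    With `year` given, fits that year's plots; with ``year=None`` fits all
    years jointly ("across"), with year as a fixed effect and row/column
    effects nested within year.  Check cultivars enter the fixed part; test
    cultivars are a random effect whose conditional means are the BLUPs.
    """
    df = pheno[pheno["trait"] == trait]
    if year is not None:
        df = df[df["year"].astype(str) == str(year)]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}, year {year!r}")
    df = df.reset_index(drop=True)

    across = year is None and df["year"].nunique() > 1
    # fixed part: intercept (+ year) + one dummy per check cultivar
    X_parts = [np.ones((len(df), 1))]
    names = ["Intercept"]
    if across:
        years = sorted(df["year"].astype(str).unique())
        for y in years[1:]:
            X_parts.append((df["year"].astype(str) == y).to_numpy(float)[:, None])
            names.append(f"year[{y}]")
    checks = sorted(df.loc[df["is_check"], "accession"].unique())
    for c in checks:
        X_parts.append(
            ((df["accession"] == c) & df["is_check"]).to_numpy(float)[:, None]
        )
        names.append(f"check[{c}]")
    X = np.hstack(X_parts)

    def nest(col: pd.Series) -> pd.Series:
        if across:
            return df["year"].astype(str) + ":" + col.astype(str)
        return col.astype(str)

    vc_values = {
        "cultivar": df.apply(
            lambda r: None if r["is_check"] else str(r["accession"]), axis=1
        ),
        "row": nest(df["row"]),
        "column": nest(df["column"]),
    }
    vc_names, vc_colnames, vc_mats = [], [], []
    for name in random_effects:
        levels, mat = _vc_dummies(vc_values[name])
        if len(levels) < 2:
            continue
        vc_names.append(name)
        vc_colnames.append([[str(l) for l in levels]])  # statsmodels wraps as name[level]
        vc_mats.append([mat])
    if not vc_names:
        raise ValueError("no random effect has at least two levels")

    spec = VCSpec(vc_names, vc_colnames, vc_mats)
    y = df["value"].to_numpy(float)
    groups = np.zeros(len(df))
    model = MixedLM(y, pd.DataFrame(X, columns=names), groups=groups, exog_vc=spec)
    import warnings

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs is fast but can stall on boundary optima; keep the better of
        # the two fits by restricted likelihood
        for meth in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=[meth], maxiter=2000)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result is None or (
                np.isfinite(cand.llf) and cand.llf > result.llf + 1e-9
            ):
                result = cand
    if result is None or not np.isfinite(result.llf):
        raise RuntimeError(
            f"REML did not converge for trait {trait!r}, year {year!r}"
        )

    comps = {n: max(float(v), 0.0) for n, v in zip(vc_names, result.vcomp)}
    vcs = VarianceComponents(
        components=comps, residual=float(result.scale), converged=result.converged
    )

    re = next(iter(result.random_effects.values()))
    blups = []
    for key, val in re.items():
        if key.startswith("cultivar["):
            blups.append((key[len("cultivar["):-1], float(val)))
    blup_df = pd.DataFrame(blups, columns=["accession", "blup"])
    blup_df.insert(1, "trait", trait)
    blup_df.insert(2, "year", str(year) if year is not None else "across")
    return blup_df, vcs


def combined_anova(
    blups: pd.DataFrame,
    sp: SubpopAssignment,
    value_col: str = "blup",
) -> pd.DataFrame:
    """Combined two-way ANOVA on cultivar-year values with SS partition.

    Expects one value per (accession, year); admixed accessions are
    excluded.  Tests year and cultivar (partitioned into between- and
    within-subpopulation) against the year x cultivar interaction mean
    square.  Returns a table with SS, df, MS, F, p and the percentage of
    the total and of the model SS per row.
    """
    df = blups.copy()
    df["year"] = df["year"].astype(str)
    structured = set(sp.structured())
    df = df[df["accession"].isin(structured)]
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("combined ANOVA needs >= 2 years (interaction is the error term)")
    # keep cultivars observed in every year so the layout is balanced
    counts = df.groupby("accession")["year"].nunique()
    keep = counts[counts == len(years)].index
    df = df[df["accession"].isin(keep)]
    wide = df.pivot_table(index="accession", columns="year", values=value_col)
    n_c, n_y = wide.shape
    y = wide.to_numpy()
    grand = y.mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_year = float(n_c * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_cult = float(n_y * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_int = ss_total - ss_year - ss_cult

    labels = sp.labels.reindex(wide.index)
    cult_means = pd.Series(y.mean(axis=1), index=wide.index)
    sp_means = cult_means.groupby(labels).mean()
    sp_sizes = cult_means.groupby(labels).size()
    ss_between = float(n_y * (sp_sizes * (sp_means - grand) ** 2).sum())
    ss_within = ss_cult - ss_between

    df_year = n_y - 1
    df_cult = n_c - 1
    df_between = max(len(sp_sizes) - 1, 0)
    df_within = df_cult - df_between
    df_int = df_year * df_cult
    ms_int = ss_int / df_int if df_int > 0 else np.nan

    def row(src, ss, dfree):
        ms = ss / dfree if dfree > 0 else np.nan
        F = ms / ms_int if ms_int > 0 else np.inf if ss > 0 else np.nan
        p = float(f_dist.sf(F, dfree, df_int)) if np.isfinite(F) else np.nan
        return dict(source=src, ss=ss, df=dfree, ms=ms, F=F, p=p)

    rows = [
        row("year", ss_year, df_year),
        row("cultivar", ss_cult, df_cult),
        row("between_sp", ss_between, df_between),
        row("within_sp", ss_within, df_within),
        dict(source="year_x_cultivar", ss=ss_int, df=df_int, ms=ms_int,
             F=np.nan, p=np.nan),
        dict(source="total", ss=ss_total, df=n_c * n_y - 1, ms=np.nan,
             F=np.nan, p=np.nan),
    ]
    out = pd.DataFrame(rows)
    ss_model = ss_year + ss_cult
    out["pct_total_ss"] = 100 * out["ss"] / ss_total if ss_total > 0 else 0.0
    out["pct_model_ss"] = 100 * out["ss"] / ss_model if ss_model > 0 else 0.0
    return out


def tukey_hsd(
    means: pd.Series,
    mse: float,
    df_error: int,
    n_per_group: pd.Series | int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey mean comparison with a compact letter display.

    Unbalanced group sizes use the harmonic-mean size in the critical
    range.  Groups sharing a letter are not significantly different at
    `alpha`.
    """
    means = pd.Series(means).astype(float)
    if len(means) < 2:
        raise ValueError("need >= 2 groups")
    if isinstance(n_per_group, int):
        n_h = float(n_per_group)
    else:
        n = pd.Series(n_per_group).astype(float).reindex(means.index)
        n_h = len(n) / (1.0 / n).sum()
    k = len(means)
    q_crit = studentized_range.ppf(1 - alpha, k, df_error)
    if mse == 0:
        crit = 0.0
    else:
        crit = q_crit * np.sqrt(mse / n_h)

    order = means.sort_values(ascending=False)
    differs = {
        (a, b): abs(order[a] - order[b]) > crit
        for a in order.index
        for b in order.index
        if a != b
    }
    letters = compact_letter_display(list(order.index), differs)
    return pd.DataFrame(
        {"mean": order, "letters": [letters[g] for g in order.index]}
    )


def compact_letter_display(
    groups: list, differs: dict[tuple, bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment: split any class containing a
    significantly different pair, then drop classes contained in others."""
    classes: list[frozenset] = [frozenset(groups)]
    for a, b in {tuple(sorted(pair)) for pair, d in differs.items() if d}:
        nxt: list[frozenset] = []
        for cls in classes:
            if a in cls and b in cls:
                nxt.extend((cls - {a}, cls - {b}))
            else:
                nxt.append(cls)
        classes = [
            cls for cls in nxt
            if cls and not any(cls < other for other in nxt)
        ]
        classes = list(dict.fromkeys(classes))
    # letter order follows the best mean within each class
    order = {g: i for i, g in enumerate(groups)}
    classes.sort(key=lambda cls: min(order[g] for g in cls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        g: "".join(alphabet[i] for i, cls in enumerate(classes) if g in cls)
        for g in groups
    }


def sedimentation_index(gs, gpc):
    """SI = GS / GPC, in mL per protein unit."""
    gs = np.asarray(gs, dtype=float)
    gpc = np.asarray(gpc, dtype=float)
    if np.any(gpc <= 0):
        raise ValueError("GPC must be > 0")
    out = gs / gpc
    return float(out) if out.ndim == 0 else out


def quality_index(
    values: dict[str, float],
    check_means: dict[str, float],
    weights: dict[str, float] | None = None,
) -> float:
    """EU quality index: trait-wise percentage of the check mean, weighted.

    Default weights are GPC 40%, GS 30%, YI 20%, TW 10%; all traits equal
    to their check means gives QI = 100.
    """
    weights = dict(QI_WEIGHTS if weights is None else weights)
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    qi = 0.0
    for t, w in weights.items():
        if t not in values or t not in check_means:
            raise KeyError(f"trait {t!r} missing from values or check means")
        if check_means[t] <= 0:
            raise ValueError(f"check mean for {t!r} must be > 0")
        qi += w * 100.0 * values[t] / check_means[t]
    return qi
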