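"""Chain MTAs into MTA-QTL regions and subpopulation allele analytics.

Associations within a configurable gap (default 10 cM, the upper end of
the field's 5-10 cM convention given linkage-disequilibrium decay of up to
~8 cM) on the same linkage group belong to one region.  The allele
analytics report per-subpopulation carrier frequencies, carrier vs
non-carrier trait means, and carrier frequencies in the trait's upper and
lower deciles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .types import GenotypeMatrix, SubpopAssignment, base_chromosome

__all__ = [
    "MTAQtl",
    "chain_mtas",
    "summarize_mtaqtls",
    "carrier_frequency",
    "presence_effect",
    "percentile_carriers",
]


@dataclass
class MTAQtl:
    mtaqtl_id: str
    chromosome: str  # full linkage-group label, e.g. "1A.2"
    region: tuple[float, float]
    members: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_mtas(self) -> int:
        return len(self.members)

    @property
    def traits(self) -> list[str]:
        return sorted(self.members["trait"].unique())

    @property
    def n_environments(self) -> int:
        return int(self.members["environment"].nunique())


def chain_mtas(mtas: pd.DataFrame, gap: float = 10.0) -> list[MTAQtl]:
    """Single-linkage chaining of MTAs along each linkage group.

    Positions are sorted per linkage group (1A.1 and 1A.2 are distinct);
    a new region starts when the gap to the previous position exceeds
    `gap`.  Identical positions always co-group.  Ids are assigned per
    base chromosome in map order: mtaq2B.1, mtaq2B.2, ...
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    df = mtas.copy()
    if df["position_cM"].isna().any() or df["chromosome"].isna().any():
        bad = df.loc[df["position_cM"].isna() | df["chromosome"].isna(), "marker"]
        raise ValueError(f"MTAs without a map position: {list(bad)[:5]}")
    df["chromosome"] = df["chromosome"].astype(str)
    df["_base"] = df["chromosome"].map(base_chromosome)

    out: list[MTAQtl] = []
    counters: dict[str, int] = {}
    for base in sorted(df["_base"].unique()):
        sub_base = df[df["_base"] == base]
        # linkage groups of one chromosome numbered consecutively, in order
        for lg in sorted(sub_base["chromosome"].unique()):
            sub = sub_base[sub_base["chromosome"] == lg].sort_values(
                "position_cM", kind="stable"
            )
            pos = sub["position_cM"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > gap)
            starts = np.r_[0, breaks + 1]
            ends = np.r_[breaks, len(pos) - 1]
            for s, e in zip(starts, ends):
                counters[base] = counters.get(base, 0) + 1
                grp = sub.iloc[s : e + 1].drop(columns="_base")
                out.append(
                    MTAQtl(
                        mtaqtl_id=f"mtaq{base}.{counters[base]}",
                        chromosome=lg,
                        region=(float(pos[s]), float(pos[e])),
                        members=grp.reset_index(drop=True),
                    )
                )
    return out


def summarize_mtaqtls(groups) -> dict:
    """Global summary: MTAs per region, single-trait share, environments.

    Accepts a list of MTAQtl or a pre-built table with columns n_mtas and
    traits (comma-separated or list), e.g. a transcribed published table.
    """
    if isinstance(groups, pd.DataFrame):
        n_mtas = groups["n_mtas"].astype(int)
        traits = groups["traits"].map(
            lambda t: t if isinstance(t, (list, tuple)) else str(t).split(",")
        )
        n_env = groups.get("n_environments")
    else:
        n_mtas = pd.Series([g.n_mtas for g in groups], dtype=int)
        traits = pd.Series([g.traits for g in groups])
        n_env = pd.Series([g.n_environments for g in groups])
    if len(n_mtas) == 0:
        return dict(n_groups=0, n_mtas_total=0, mtas_per_group={},
                    n_single_mta=0, pct_single_trait=np.nan)
    n_traits = traits.map(len)
    summary = dict(
        n_groups=int(len(n_mtas)),
        n_mtas_total=int(n_mtas.sum()),
        mtas_per_group=n_mtas.value_counts().sort_index().to_dict(),
        n_single_mta=int((n_mtas == 1).sum()),
        n_single_trait=int((n_traits == 1).sum()),
        pct_single_trait=round(100.0 * (n_traits == 1).mean()),
        traits_per_group=n_traits.value_counts().sort_index().to_dict(),
    )
    if n_env is not None:
        summary["environments_per_group"] = (
            pd.Series(n_env).astype(int).value_counts().sort_index().to_dict()
        )
    return summary


def carrier_frequency(
    G: GenotypeMatrix, marker: str, sp: SubpopAssignment
) -> pd.Series:
    """Per-subpopulation fraction of carriers among non-missing calls."""
    calls = pd.Series(G.column(marker), index=G.accession_ids)
    labels = sp.labels.reindex(calls.index)
    out = {}
    for pop in sp.subpops:
        vals = calls[labels == pop].dropna()
        out[pop] = float(vals.mean()) if len(vals) else np.nan
    return pd.Series(out, name=marker)


def presence_effect(
    G: GenotypeMatrix,
    marker: str,
    blups: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Carrier vs non-carrier trait means with a two-group comparison.

    Uses Welch's t-test at `alpha` and reports the relative effect
    100 * (mean_present - mean_absent) / mean_absent; groups share a
    letter when not significantly different.
    """
    calls = pd.Series(G.column(marker), index=G.accession_ids)
    common = blups.index.intersection(calls.dropna().index)
    y = blups.reindex(common).astype(float)
    x = calls.reindex(common)
    pres, absn = y[x == 1], y[x == 0]
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError(f"marker {marker!r}: one carrier class is empty")
    v1, v0 = pres.var(ddof=1), absn.var(ddof=1)
    n1, n0 = len(pres), len(absn)
    se = np.sqrt(v1 / n1 + v0 / n0)
    if se == 0:
        significant = pres.mean() != absn.mean()
        p = 0.0 if significant else 1.0
    else:
        tt = (pres.mean() - absn.mean()) / se
        dfree = (v1 / n1 + v0 / n0) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
        p = float(2 * t_dist.sf(abs(tt), dfree))
        significant = p < alpha
    letters = ("a", "b") if significant else ("a", "a")
    mean_p, mean_a = float(pres.mean()), float(absn.mean())
    rel = 100.0 * (mean_p - mean_a) / mean_a if mean_a != 0 else np.nan
    return dict(
        mean_absent=mean_a, mean_present=mean_p,
        letter_absent=letters[1] if mean_a < mean_p else letters[0],
        letter_present=letters[0] if mean_a < mean_p else letters[1],
        p=p, relative_effect_pct=rel, n_present=n1, n_absent=n0,
    )


def percentile_carriers(
    G: GenotypeMatrix,
    marker: str,
    blups: pd.Series,
    q: float = 0.10,
) -> dict:
    """Carrier frequency in the top and bottom q-quantile of the trait.

    Accessions are ranked by BLUP; each tail holds ceil(q*n) accessions,
    widened to include any accessions tied with the cut value.
    """
    calls = pd.Series(G.column(marker), index=G.accession_ids)
    common = blups.index.intersection(calls.dropna().index)
    y = blups.reindex(common).astype(float).sort_values()
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 accessions")
    k = int(np.ceil(q * n))
    lo_cut, hi_cut = y.iloc[k - 1], y.iloc[n - k]
    lower = y[y <= lo_cut].index
    upper = y[y >= hi_cut].index
    return dict(
        upper_freq=float(calls.reindex(upper).mean()),
        lower_freq=float(calls.reindex(lower).mean()),
        n_upper=len(upper),
        n_lower=len(lower),
    )
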