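"""Band-level statistics along elevational gradients.

Occurrence records (gradient, genus, elevational band, dataset class) are
aggregated into per-band means of genus net diversification rate (DivElev)
and genus stem age (AgeElev), genus richness, and the relative quantities
relElev (band elevation as % of the highest occupied band on the gradient)
and relRich (band richness as % of the gradient's maximum band richness).

Group comparisons between dataset classes use a one-way ANOVA followed by a
Tukey–Kramer HSD test, which honors unequal group sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "RECORD_COLUMNS",
    "dedupe",
    "band_stats",
    "one_way_anova",
    "tukey_hsd",
    "group_comparison",
    "AnovaResult",
    "GroupComparison",
    "read_records",
]

RECORD_COLUMNS = ["gradient_id", "genus", "elevation_m", "dataset_class"]
DATASET_CLASSES = ("all", "epiphyte", "non_epiphyte")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns {sorted(missing)}")
    if (df["elevation_m"] < 0).any():
        raise ValueError("negative band elevations in records")
    return df[RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS]]


def dedupe(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce to one record per (gradient, genus, band, class), stable order."""
    return records.drop_duplicates(subset=RECORD_COLUMNS, keep="first").reset_index(drop=True)


def band_stats(
    records: pd.DataFrame,
    profiles: pd.DataFrame,
    dataset_class: str | None = None,
    distinct_genera: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(gradient, band) statistics.

    Parameters
    ----------
    records
        Occurrence records with columns ``gradient_id, genus, elevation_m,
        dataset_class``.
    profiles
        Genus profile frame with columns ``genus, stem_age_ma, div_rate``
        (as produced by :func:`divelev.rates.profiles_to_frame`).
    dataset_class
        If given, restrict to records of that class.
    distinct_genera
        Average rates/ages over the *distinct* genera present in a band
        (default, matching the one-record-per-genus reduction).  With
        ``False`` every raw record contributes, so a genus recorded twice in
        a band is weighted twice.

    Returns
    -------
    (stats, dropped)
        ``stats`` has one row per band; ``dropped`` logs records whose genus
        has no profile (reason code ``no_profile``).
    """
    df = records.copy()
    if dataset_class is not None:
        df = df[df["dataset_class"] == dataset_class]
    if distinct_genera:
        df = dedupe(df)
    known = set(profiles["genus"])
    bad = ~df["genus"].isin(known)
    dropped = df[bad].copy()
    dropped["reason"] = "no_profile"
    df = df[~bad]
    if df.empty:
        empty = pd.DataFrame(
            columns=["gradient_id", "elevation_m", "div_elev", "age_elev",
                     "richness", "rel_elev", "rel_rich"]
        )
        return empty, dropped.reset_index(drop=True)

    prof = profiles.set_index("genus")
    df = df.assign(
        div_rate=df["genus"].map(prof["div_rate"]),
        stem_age=df["genus"].map(prof["stem_age_ma"]),
    )
    grouped = df.groupby(["gradient_id", "elevation_m"], sort=True)
    stats = grouped.agg(
        div_elev=("div_rate", "mean"),
        age_elev=("stem_age", "mean"),
        richness=("genus", "nunique"),
    ).reset_index()
    max_elev = stats.groupby("gradient_id")["elevation_m"].transform("max")
    max_rich = stats.groupby("gradient_id")["richness"].transform("max")
    stats["rel_elev"] = 100.0 * stats["elevation_m"] / max_elev
    stats["rel_rich"] = 100.0 * stats["richness"] / max_rich
    return stats, dropped.reset_index(drop=True)


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def _as_groups(groups) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=float) for k, v in dict(groups).items()}


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over a label → values mapping.

    Degenerate inputs follow fixed conventions: identical values everywhere
    give F = 0, p = 1; zero within-group variance with differing group means
    gives F = +inf, p = 0.
    """
    g = _as_groups(groups)
    if len(g) < 2 or any(len(v) < 2 for v in g.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    values = list(g.values())
    N = sum(len(v) for v in values)
    df1, df2 = len(g) - 1, N - len(g)
    within = sum(((v - v.mean()) ** 2).sum() for v in values)
    grand = np.concatenate(values).mean()
    between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    if within == 0.0:
        if between == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(math.inf, df1, df2, 0.0)
    F = (between / df1) / (within / df2)
    p = float(st.f.sf(F, df1, df2))
    return AnovaResult(float(F), df1, df2, p)


def tukey_hsd(groups) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons (studentized-range adjusted p).

    Returns a tidy frame with one row per unordered pair: the mean
    difference, the adjusted p value and the 95% family-wise confidence
    interval.  Unequal group sizes are handled by the Kramer correction.
    """
    g = _as_groups(groups)
    if len(g) < 2 or any(len(v) < 2 for v in g.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    labels = list(g)
    res = st.tukey_hsd(*[g[l] for l in labels])
    ci = res.confidence_interval(confidence_level=0.95)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "diff": float(res.statistic[i, j]),
                "p_adj": float(min(1.0, res.pvalue[i, j])),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    summary: pd.DataFrame      # n / mean / median / IQR per group
    anova: AnovaResult
    tukey: pd.DataFrame


def group_comparison(groups) -> GroupComparison:
    """ANOVA + Tukey–Kramer bundle over a label → values mapping."""
    g = _as_groups(groups)
    rows = []
    for label, v in g.items():
        q1, q3 = np.percentile(v, [25, 75])
        rows.append(
            {"group": label, "n": len(v), "mean": float(v.mean()),
             "median": float(np.median(v)), "iqr": float(q3 - q1)}
        )
    return GroupComparison(
        summary=pd.DataFrame(rows),
        anova=one_way_anova(g),
        tukey=tukey_hsd(g),
    )
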