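"""Reliability and group-comparison statistics.

Two families of statistics accompany the outline method:

* **Landmark reliability.**  Repeated landmark placements by several raters
  are summarised with the intraclass correlation ICC(2,1): two-way random
  effects, absolute agreement, single measures.  It is computed here
  directly from the two-way ANOVA mean squares,

      ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

  with MSR the between-target, MSC the between-rater and MSE the residual
  mean square, n targets and k raters.  ICC > 0.75 is taken as acceptable
  reliability.

* **Group comparison.**  Per-degree group mean curves and the per-degree
  range (max - min across group members), and a one-way ANOVA of subject
  summary values.  Because group variances are typically unequal, Levene's
  test (mean-centred) guards the homogeneity assumption and the
  Games-Howell procedure -- Welch's t with Welch-Satterthwaite degrees of
  freedom referred to the studentized-range distribution -- provides the
  post hoc pairwise comparisons.  Bonferroni-adjusted p-values are reported
  alongside, and significance is flagged on the adjusted value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVariance, SingletonGroup, UndefinedICC

__all__ = [
    "icc_2_1",
    "reliability_report",
    "group_mean_curves",
    "games_howell",
    "compare_groups",
]

ACCEPTABLE_ICC = 0.75


def icc_2_1(table: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Parameters
    ----------
    table
        (n_targets, k_raters) matrix of one measured component, no missing
        cells, n >= 2 and k >= 2.

    Raises
    ------
    UndefinedICC
        When the table carries no variance at all.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"ratings table must be (n>=2, k>=2), got {x.shape}")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings table contains non-finite cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand, atol=1e-15):
        raise UndefinedICC("ratings table has zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-30:
        raise UndefinedICC("ICC denominator vanishes")
    return float((msr - mse) / denom)


def reliability_report(ratings: pd.DataFrame) -> pd.DataFrame:
    """Intra- and inter-rater ICC per landmark and axis.

    Parameters
    ----------
    ratings
        Long format with columns ``subject, landmark, rater, session, x, y, z``
        (mm).  Intra-rater ICC treats one rater's sessions as columns;
        inter-rater ICC uses per-rater session means as columns.  Besides
        the x/y/z axes an ``r3d`` component is reported: the 3-D Euclidean
        deviation of each placement from that landmark's per-subject mean
        position.

    Returns
    -------
    DataFrame with columns ``landmark, axis, kind, rater, icc, acceptable``.
    """
    required = {"subject", "landmark", "rater", "session", "x", "y", "z"}
    if not required <= set(ratings.columns):
        raise ValueError(f"ratings must have columns {sorted(required)}")
    df = ratings.copy()
    center = df.groupby(["subject", "landmark"])[["x", "y", "z"]].transform("mean")
    df["r3d"] = np.sqrt(((df[["x", "y", "z"]] - center) ** 2).sum(axis=1))

    def _icc_row(table: np.ndarray, **meta) -> dict:
        try:
            icc = icc_2_1(table)
        except UndefinedICC:
            # e.g. perfectly repeated placements: no variance to apportion
            icc = np.nan
        return dict(**meta, icc=icc, acceptable=bool(icc > ACCEPTABLE_ICC))

    rows = []
    for lm, sub in df.groupby("landmark"):
        for axis in ("x", "y", "z", "r3d"):
            # intra-rater: targets x sessions for each rater
            for rater, rsub in sub.groupby("rater"):
                piv = rsub.pivot_table(index="subject", columns="session", values=axis)
                if piv.shape[1] >= 2 and not piv.isna().any().any():
                    rows.append(
                        _icc_row(piv.to_numpy(), landmark=lm, axis=axis,
                                 kind="intra", rater=rater)
                    )
            # inter-rater: targets x raters, session-averaged
            piv = sub.pivot_table(index="subject", columns="rater", values=axis)
            if piv.shape[1] >= 2 and not piv.isna().any().any():
                rows.append(
                    _icc_row(piv.to_numpy(), landmark=lm, axis=axis,
                             kind="inter", rater="all")
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupCurveSummary:
    """Per-degree summaries of a cohort of polar curves, by group."""

    mean_curves: pd.DataFrame  # index theta 0..359, one column per group
    range_curves: pd.DataFrame  # per-degree max-min across group members
    range_mean: pd.Series  # mean over degrees of the per-degree range
    range_sd: pd.Series  # SD over degrees of the per-degree range
    group_sizes: pd.Series


def group_mean_curves(curves_by_group: dict[str, list]) -> GroupCurveSummary:
    """Per-degree group mean curves and per-degree range statistics.

    For every degree the range is the spread (max - min) of the relative
    radius across group members; its mean and SD over the 360 degrees
    summarise within-group shape variability (wide in unrestricted normal
    growth, narrow in the stereotyped synostotic shapes).
    """
    means, ranges, sizes = {}, {}, {}
    for label, curves in curves_by_group.items():
        arr = np.vstack([np.asarray(getattr(c, "radii_rel", c), dtype=float) for c in curves])
        if arr.shape[0] < 2:
            raise SingletonGroup(f"group {label!r} has fewer than 2 members")
        means[label] = arr.mean(axis=0)
        ranges[label] = arr.max(axis=0) - arr.min(axis=0)
        sizes[label] = arr.shape[0]
    mean_df = pd.DataFrame(means)
    range_df = pd.DataFrame(ranges)
    return GroupCurveSummary(
        mean_curves=mean_df,
        range_curves=range_df,
        range_mean=range_df.mean(axis=0),
        range_sd=range_df.std(axis=0, ddof=1),
        group_sizes=pd.Series(sizes),
    )


def games_howell(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal-variance groups.

    For each pair the Welch statistic t = |m_i - m_j| / sqrt(v_i/n_i +
    v_j/n_j) with Welch-Satterthwaite df is referred to the studentized
    range distribution with k groups via q = t * sqrt(2).
    """
    labels = list(samples)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    stats = {
        lab: (np.mean(v), np.var(v, ddof=1), len(v)) for lab, v in samples.items()
    }
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ma, va, na = stats[a]
        mb, vb, nb = stats[b]
        if na < 2 or nb < 2:
            raise SingletonGroup(f"group {a!r} or {b!r} has fewer than 2 subjects")
        se2 = va / na + vb / nb
        if se2 <= 0:
            raise DegenerateVariance(f"pair ({a}, {b}) has zero pooled variance")
        diff = ma - mb
        t = abs(diff) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        rows.append(
            dict(group_a=a, group_b=b, mean_diff=diff, se=np.sqrt(se2), t=t, df=df, p=p)
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + post hoc report for subject summary values by group."""

    anova_f: float
    anova_p: float
    levene_w: float
    levene_p: float
    posthoc: pd.DataFrame  # Games-Howell p plus Bonferroni-adjusted p
    n_comparisons: int

    def to_text(self) -> str:
        lines = [
            f"One-way ANOVA: F = {self.anova_f:.4f}, p = {self.anova_p:.4g}",
            f"Levene's test (mean-centred): W = {self.levene_w:.4f}, p = {self.levene_p:.4g}",
            f"Games-Howell post hoc ({self.n_comparisons} comparisons, "
            "Bonferroni-adjusted p alongside):",
            self.posthoc.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_groups(values_by_group: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA with Levene's check and Games-Howell post hoc.

    ``values_by_group`` maps group label to a 1-D array of per-subject
    summary values (e.g. each subject's mean per-degree range).  Pairwise
    significance is flagged on the Bonferroni-adjusted Games-Howell p.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise SingletonGroup("need at least two groups to compare")
    for lab, v in groups.items():
        if len(v) < 2:
            raise SingletonGroup(f"group {lab!r} has fewer than 2 subjects")
    if all(np.var(v) < 1e-30 for v in groups.values()):
        raise DegenerateVariance("all groups have zero within-group variance")

    arrays = list(groups.values())
    f, p = sps.f_oneway(*arrays)
    w, lp = sps.levene(*arrays, center="mean")
    post = games_howell(groups)
    m = len(post)
    post = post.assign(
        p_bonferroni=np.minimum(1.0, post["p"] * m),
    )
    post = post.assign(significant=post["p_bonferroni"] < 0.05)
    return GroupComparison(
        anova_f=float(f),
        anova_p=float(p),
        levene_w=float(w),
        levene_p=float(lp),
        posthoc=post,
        n_comparisons=m,
    )
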