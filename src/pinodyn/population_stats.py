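"""Fate classification, hierarchical summaries, and hypothesis tests.

Vesicle fates (successful endosomal-identity gain vs collapse) are scored
from the endosomal-marker channel; summaries aggregate track -> cell ->
experiment before testing, mirroring how per-cell and per-experiment means
are presented.  Categorical comparisons use a two-sided Fisher exact test
computed with exact rational arithmetic; two-group comparisons use the
pooled-variance Student t-test, multi-group comparisons one-way ANOVA with
Tukey HSD.  The liposome coincidence-enhancement ratio is included as a
numeric computation on band intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import channel_column


# ---------------------------------------------------------------------------
# fate classification


@dataclass
class OutcomeRule:
    """Success criterion: sustained endosomal-marker gain on a large vesicle.

    A track is a success when its marker exceeds baseline + ``z_threshold``
    robust SDs for at least ``min_consecutive_frames`` consecutive frames
    before the track ends, and its first-frame equivalent diameter exceeds
    ``min_diameter_um``.  Tracks that survive to the end of the movie
    without a marker gain are censored rather than called collapses.
    """

    z_threshold: float = 3.0
    min_consecutive_frames: int = 3
    min_diameter_um: float = 1.0
    baseline_frames: int = 5


def _marker_gain_frames(
    marker: np.ndarray, rule: OutcomeRule
) -> bool:
    base = marker[: rule.baseline_frames]
    baseline = float(np.median(base))
    robust_sd = 1.4826 * float(np.median(np.abs(base - baseline)))
    thr = baseline + rule.z_threshold * robust_sd
    above = marker > thr
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= rule.min_consecutive_frames:
            return True
    return False


def classify_outcomes(
    tracks: pd.DataFrame,
    marker_channel: str,
    rule: OutcomeRule | None = None,
    *,
    movie_end_frame: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score success / collapse / censored per track and per-cell rates.

    Returns ``(outcomes, per_cell)`` where ``outcomes`` has one row per
    track (``track_id, cell_id, fate, first_area_um2``) and ``per_cell``
    carries ``successes, collapses, success_rate`` with the rate defined
    as successes / (successes + collapses); censored tracks do not enter
    the denominator.
    """
    rule = rule or OutcomeRule()
    col = channel_column(marker_channel)
    if col not in tracks.columns:
        raise KeyError(f"marker channel {marker_channel!r} missing from tracks")
    if movie_end_frame is None:
        movie_end_frame = int(tracks["frame"].max()) if len(tracks) else 0

    rows = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        first_area = float(g["area_um2"].iloc[0])
        diameter = 2.0 * math.sqrt(first_area / math.pi)
        gained = _marker_gain_frames(g[col].to_numpy(dtype=float), rule)
        if gained and diameter > rule.min_diameter_um:
            fate = "success"
        elif int(g["frame"].iloc[-1]) >= movie_end_frame:
            fate = "censored"
        else:
            fate = "collapse"
        rows.append(
            {
                "track_id": tid,
                "cell_id": g["cell_id"].iloc[0] if "cell_id" in g else "cell0",
                "fate": fate,
                "first_area_um2": first_area,
            }
        )
    outcomes = pd.DataFrame(rows)
    if len(outcomes):
        counts = (
            outcomes.pivot_table(
                index="cell_id", columns="fate", aggfunc="size", fill_value=0
            )
            .reindex(columns=["success", "collapse", "censored"], fill_value=0)
            .rename(columns={"success": "successes", "collapse": "collapses", "censored": "censored"})
            .reset_index()
        )
        denom = counts["successes"] + counts["collapses"]
        counts["success_rate"] = np.where(
            denom > 0, counts["successes"] / denom.replace(0, np.nan), np.nan
        )
    else:
        counts = pd.DataFrame(
            columns=["cell_id", "successes", "collapses", "censored", "success_rate"]
        )
    return outcomes, counts


# ---------------------------------------------------------------------------
# Fisher's exact test (exact rational arithmetic)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value by the probability-mass criterion.

    Sums the hypergeometric probabilities of every 2x2 table with the same
    margins whose probability does not exceed that of the observed table.
    All arithmetic is exact (Fractions); the result is emitted as float.
    A degenerate table (a zero row or column margin) returns p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        not float(x).is_integer() for x in (a, b, c, d)
    ):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0

    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p = prob(k)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def contingency_from_outcomes(
    per_group_counts: Mapping[str, tuple[int, int]]
) -> tuple[list[list[int]], list[str]]:
    """Build a 2x2 (group x success/collapse) table from pooled counts."""
    labels = list(per_group_counts)
    if len(labels) != 2:
        raise ValueError("need exactly two groups for a 2x2 table")
    table = [list(map(int, per_group_counts[g])) for g in labels]
    return table, labels


# ---------------------------------------------------------------------------
# group comparison (t-test / ANOVA + Tukey)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: float
    p_value: float
    unit_of_analysis: str
    group_means: dict[str, float]
    pairwise: pd.DataFrame | None = None


def aggregate_hierarchy(
    df: pd.DataFrame,
    value: str,
    group: str = "group",
    cell: str = "cell_id",
    experiment: str = "experiment_id",
) -> tuple[dict[str, np.ndarray], str]:
    """Aggregate track -> cell -> experiment means per group.

    Tests run on per-experiment means when every group has at least three
    experiments, otherwise on per-cell means; the unit actually used is
    returned alongside the values.
    """
    per_cell = (
        df.groupby([group, experiment, cell])[value].mean().reset_index()
    )
    n_exp = per_cell.groupby(group)[experiment].nunique()
    if (n_exp >= 3).all():
        per_exp = per_cell.groupby([group, experiment])[value].mean()
        values = {
            g: per_exp.loc[g].to_numpy() for g in per_exp.index.get_level_values(0).unique()
        }
        return values, "experiment"
    values = {
        g: per_cell.loc[per_cell[group] == g, value].to_numpy()
        for g in per_cell[group].unique()
    }
    return values, "cell"


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    unit_of_analysis: str = "cell",
) -> GroupComparison:
    """Two-sided pooled-variance t-test (2 groups) or one-way ANOVA (>2).

    For more than two groups, Tukey HSD pairwise comparisons via the
    studentized-range distribution are attached.  Raises on any group with
    fewer than two units, or on an undefined statistic (all groups with
    zero within-group variance in the two-group case).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 units")
    labels = list(groups)
    means = {k: float(v.mean()) for k, v in groups.items()}

    if len(groups) == 2:
        x, y = groups[labels[0]], groups[labels[1]]
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            if means[labels[0]] == means[labels[1]]:
                # identical constant groups: no evidence of a difference
                return GroupComparison(
                    "student_t", 0.0, len(x) + len(y) - 2, 1.0,
                    unit_of_analysis, means,
                )
            raise ValueError("zero within-group variance: t undefined")
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return GroupComparison(
            "student_t",
            float(t),
            float(len(x) + len(y) - 2),
            float(p),
            unit_of_analysis,
            means,
        )

    arrays = [groups[k] for k in labels]
    if all(a.var(ddof=1) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        df_between = len(arrays) - 1
        return GroupComparison(
            "anova", 0.0, float(df_between), 1.0, unit_of_analysis, means
        )
    f, p = stats.f_oneway(*arrays)
    tuk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": means[labels[i]] - means[labels[j]],
                    "p_adj": float(tuk.pvalue[i, j]),
                }
            )
    return GroupComparison(
        "anova",
        float(f),
        float(len(labels) - 1),
        float(p),
        unit_of_analysis,
        means,
        pairwise=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# liposome coincidence enhancement


def coincidence_enhancement_ratio(
    bound_fractions: Mapping[str, float],
    both_key: str = "both",
) -> float:
    """Fold enhancement of dual-lipid binding over the best single lipid.

    ``bound_fractions`` maps condition names (e.g. PI3P-only, PI4P-only,
    and ``both``) to bound fractions in [0, 1]; the ratio is
    bound(both) / max(single-lipid fractions).  Requires at least one
    positive single-lipid fraction.
    """
    if both_key not in bound_fractions:
        raise KeyError(f"missing {both_key!r} condition")
    for k, v in bound_fractions.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"fraction {k!r}={v} outside [0, 1]")
    singles = [v for k, v in bound_fractions.items() if k != both_key]
    if not singles or max(singles) == 0.0:
        raise ValueError("ratio undefined: all single-lipid fractions are 0")
    return bound_fractions[both_key] / max(singles)
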