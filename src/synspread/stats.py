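"""Group comparisons: two-tailed t-test, one-way ANOVA, Tukey HSD.

The test statistics are computed from their textbook formulas (pooled-
variance Student t; between/within mean squares for F; studentized range
for Tukey), with scipy.stats providing only the reference distributions
for p-values. Degenerate inputs are defined explicitly: identical group
means with zero pooled variance give a zero statistic and p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DESIGN_TWO_GROUP = "TWO_GROUP"
DESIGN_MULTI_GROUP = "MULTI_GROUP"


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    design: str
    test: str
    statistic: float
    p_value: float
    df: tuple
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    clean = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise StatsError(f"group {name!r} has fewer than 2 values")
        if not np.all(np.isfinite(arr)):
            raise StatsError(f"group {name!r} contains non-finite values")
        clean[name] = arr
    return clean


def two_sample_t(a, b) -> tuple[float, float, int]:
    """Two-tailed pooled-variance Student t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(diff) * np.inf), 0.0, df
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), min(p, 1.0), df


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """One-way fixed-effects ANOVA F statistic from mean squares."""
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0, df_b, df_w
        return float("inf"), 0.0, df_b, df_w
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, df_b, df_w


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j)); p from
    the studentized range distribution with k groups and the within df.
    """
    names = list(groups)
    arrays = [groups[n] for n in names]
    k = len(names)
    n = sum(a.size for a in arrays)
    df_w = n - k
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ms_within = ss_within / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = a.mean() - b.mean()
            if ms_within == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            rows.append(
                {"group_a": names[i], "group_b": names[j],
                 "mean_diff": float(diff), "q": float(q), "p_value": min(p, 1.0)}
            )
    return pd.DataFrame(rows)


def group_compare(groups: dict[str, object], design: str | None = None) -> GroupComparison:
    """Compare condition means.

    TWO_GROUP: two-tailed pooled t-test. MULTI_GROUP: one-way ANOVA with
    Tukey HSD post-hoc pairs. Design defaults to the number of groups.
    """
    clean = _check_groups(dict(groups))
    if design is None:
        design = DESIGN_TWO_GROUP if len(clean) == 2 else DESIGN_MULTI_GROUP
    if design == DESIGN_TWO_GROUP:
        if len(clean) != 2:
            raise StatsError(f"TWO_GROUP design needs 2 groups, got {len(clean)}")
        a, b = clean.values()
        t, p, df = two_sample_t(a, b)
        return GroupComparison(
            design=design, test="two-tailed t-test", statistic=t, p_value=p, df=(df,)
        )
    if design == DESIGN_MULTI_GROUP:
        if len(clean) < 2:
            raise StatsError("MULTI_GROUP design needs at least 2 groups")
        f, p, df_b, df_w = one_way_anova(list(clean.values()))
        posthoc = tukey_hsd(clean)
        return GroupComparison(
            design=design, test="one-way ANOVA", statistic=f, p_value=p,
            df=(df_b, df_w), posthoc=posthoc,
        )
    raise StatsError(f"unknown design {design!r}")
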