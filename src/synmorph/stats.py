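"""Study-level aggregation and nonparametric statistics.

Aggregation follows the two-level protocol: a mean per subject first, then
an unweighted mean ± SD across subjects.  Group comparisons use the
Kruskal–Wallis H test (rank sums with tie correction) with post-hoc
two-sided Mann–Whitney U tests per pair; post-hoc p values are
Bonferroni-adjusted by default (the adjustment is configurable and logged
in the result).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class SubjectAggregate:
    parameter: str
    per_subject_mean: dict[str, float]
    per_subject_sd: dict[str, float]
    per_subject_n: dict[str, int]
    grand_mean: float
    grand_sd: float | None          # None when only one subject
    n_subjects: int
    excluded_subjects: list[str] = field(default_factory=list)


def aggregate_subjects(
    table: pd.DataFrame, parameter: str, subject_col: str = "subject_id"
) -> SubjectAggregate:
    """Two-level mean ± SD: within-subject mean first, then an unweighted
    mean ± SD across the subject means.  Subjects with no valid rows are
    excluded with a warning."""
    if subject_col not in table.columns or parameter not in table.columns:
        raise StatsError(f"missing column {subject_col!r} or {parameter!r}")
    if len(table) == 0:
        raise StatsError("empty table")
    means, sds, ns = {}, {}, {}
    excluded = []
    for sid, grp in table.groupby(subject_col, sort=True):
        vals = grp[parameter].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            excluded.append(str(sid))
            import warnings

            warnings.warn(f"subject {sid!r} has no valid rows for {parameter!r}; excluded")
            continue
        means[str(sid)] = float(vals.mean())
        sds[str(sid)] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        ns[str(sid)] = int(len(vals))
    if not means:
        raise StatsError("no subject has valid rows")
    mvals = np.array(list(means.values()))
    return SubjectAggregate(
        parameter=parameter,
        per_subject_mean=means,
        per_subject_sd=sds,
        per_subject_n=ns,
        grand_mean=float(mvals.mean()),
        grand_sd=float(mvals.std(ddof=1)) if len(mvals) > 1 else None,
        n_subjects=len(mvals),
        excluded_subjects=excluded,
    )


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    p_adjusted: float


@dataclass
class StatResult:
    parameter: str
    groups: list[str]
    h_statistic: float
    p_value: float
    pairwise: list[PairwiseResult]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    adjustment: str = "bonferroni"


def kruskal_posthoc(
    groups: dict[str, np.ndarray],
    parameter: str = "",
    adjustment: str = "bonferroni",
) -> StatResult:
    """Kruskal–Wallis H across the groups, then a two-sided Mann–Whitney U
    for every pair.  Each group needs at least 2 values."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 2:
            raise StatsError(f"group {name!r} has fewer than 2 values")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0   # all values identical: no rank information
    else:
        h, p = sps.kruskal(*arrays)
    pairs = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for a, b in combinations(range(len(names)), 2):
        u, pu = sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
        padj = min(pu * n_pairs, 1.0) if adjustment == "bonferroni" else pu
        pairs.append(
            PairwiseResult(
                group_a=names[a],
                group_b=names[b],
                u_statistic=float(u),
                p_value=float(pu),
                p_adjusted=float(padj),
            )
        )
    return StatResult(
        parameter=parameter,
        groups=names,
        h_statistic=float(h),
        p_value=float(p),
        pairwise=pairs,
        group_means={n: float(v.mean()) for n, v in zip(names, arrays)},
        group_sds={n: float(v.std(ddof=1)) for n, v in zip(names, arrays)},
        adjustment=adjustment,
    )


def stat_result_to_dict(r: StatResult) -> dict:
    return {
        "parameter": r.parameter,
        "groups": r.groups,
        "H": r.h_statistic,
        "p": r.p_value,
        "adjustment": r.adjustment,
        "group_means": r.group_means,
        "group_sds": r.group_sds,
        "pairwise": [
            {
                "a": p.group_a,
                "b": p.group_b,
                "U": p.u_statistic,
                "p": p.p_value,
                "p_adj": p.p_adjusted,
            }
            for p in r.pairwise
        ],
    }
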