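"""Group-comparison statistics for spicule cohorts.

The comparisons used throughout the study: a one-sample z-test of a mean
ratio against 1, a paired t-test (tip vs back signal), the Kruskal-Wallis
rank test across treatment groups (with tie correction), mean fold changes,
and between-timepoint growth rates. Sample standard deviations use the n−1
denominator throughout. No multiple-testing correction is applied by
default, matching the original reporting; a Bonferroni option exists.

Statistics are computed from their closed forms here, with p-values from
scipy's normal / Student-t / chi-square distributions; scipy's own test
functions are deliberately not called, so they can serve as independent
cross-checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "one_sample_z_test",
    "paired_t_test",
    "kruskal_wallis",
    "fold_change",
    "growth_rate",
    "compare_cohorts",
]

#: Below this per-group size the chi-square approximation to the
#: Kruskal-Wallis H null distribution is unreliable.
KRUSKAL_MIN_GROUP_N = 5


@dataclass
class GroupComparison:
    """One named statistical comparison: statistic, p-value, effect size."""

    test_name: str
    statistic_value: float
    p_value: float
    tails: int = 2
    group_sizes: tuple[int, ...] = ()
    effect: float | None = None
    effect_units: str = ""
    df: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _check_tails(tails: int) -> None:
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")


def one_sample_z_test(values: Sequence[float], mu0: float = 1.0, tails: int = 2) -> GroupComparison:
    """z-test of a sample mean against mu0 (e.g. a ratio against 1).

    z = (mean − mu0) / (s/√n) with the sample standard deviation; p from the
    standard normal, one-tailed in the direction of the observed deviation
    or two-tailed.
    """
    _check_tails(tails)
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    z = (x.mean() - mu0) / (sd / math.sqrt(n))
    p_one = sps.norm.sf(abs(z))
    p = p_one if tails == 1 else 2 * p_one
    return GroupComparison(
        test_name="one_sample_z",
        statistic_value=float(z),
        p_value=float(min(p, 1.0)),
        tails=tails,
        group_sizes=(n,),
        effect=float(x.mean() - mu0),
        effect_units="mean difference from mu0",
    )


def paired_t_test(a: Sequence[float], b: Sequence[float], tails: int = 2) -> GroupComparison:
    """Paired t-test on differences d = a − b, df = n − 1."""
    _check_tails(tails)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal lengths")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    p_one = sps.t.sf(abs(t), df=n - 1)
    p = p_one if tails == 1 else 2 * p_one
    return GroupComparison(
        test_name="paired_t",
        statistic_value=float(t),
        p_value=float(min(p, 1.0)),
        tails=tails,
        group_sizes=(n, n),
        effect=float(d.mean()),
        effect_units="mean paired difference",
        df=n - 1,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H over k groups, with mid-ranks and tie correction.

    H = 12/(N(N+1)) Σ R_j²/n_j − 3(N+1), divided by 1 − Σ(t³−t)/(N³−N)
    over tied value multiplicities t; p from chi-square with k−1 df.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 1 for g in arrays):
        raise ValueError("need >= 2 groups, each non-empty")
    pooled = np.concatenate(arrays)
    N = len(pooled)
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        raise ValueError("no variation: all values identical")
    if min(len(g) for g in arrays) < KRUSKAL_MIN_GROUP_N:
        warnings.warn(
            f"group size below {KRUSKAL_MIN_GROUP_N}: chi-square approximation is rough"
        )
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    H = 0.0
    start = 0
    sizes = []
    for g in arrays:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        sizes.append(len(g))
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (N**3 - N))
    if tie > 0:
        H /= tie
    dof = len(arrays) - 1
    p = float(sps.chi2.sf(H, df=dof))
    return GroupComparison(
        test_name="kruskal_wallis",
        statistic_value=float(H),
        p_value=p,
        tails=2,
        group_sizes=tuple(sizes),
        df=dof,
    )


def fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Ratio of group means, mean(a) / mean(b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    mb = b.mean()
    if mb == 0:
        raise ZeroDivisionError("fold change undefined: zero denominator mean")
    return float(a.mean() / mb)


def growth_rate(
    records: pd.DataFrame,
    condition: str,
    t1_hpf: float,
    t2_hpf: float,
    field_name: str = "volume_um3",
) -> float:
    """Mean growth rate of a field between two timepoints (units per hour).

    (mean at t2 − mean at t1) / (t2 − t1) over the condition's records —
    e.g. the mineral deposition rate in µm³/hr between 48 and 72 hpf.
    """
    if not t2_hpf > t1_hpf:
        raise ValueError("t2 must be later than t1")
    sub = records[records["condition"] == condition]
    g1 = sub[sub["timepoint_hpf"] == t1_hpf][field_name]
    g2 = sub[sub["timepoint_hpf"] == t2_hpf][field_name]
    for tp, g in ((t1_hpf, g1), (t2_hpf, g2)):
        if len(g) == 0:
            raise ValueError(f"missing group: condition {condition!r} at {tp} hpf")
    return float((g2.mean() - g1.mean()) / (t2_hpf - t1_hpf))


def compare_cohorts(
    records: pd.DataFrame, plan: Mapping, bonferroni: bool = False
) -> list[GroupComparison]:
    """Run a plan of per-field, per-timepoint comparisons on a record table.

    The plan maps:

    - ``fields``: record columns to compare (e.g. volume_um3);
    - ``conditions``: [reference, treatment] labels;
    - ``timepoints_hpf``: timepoints to compare at;
    - ``tests``: any of "kruskal_wallis", "fold_change";
    - optionally ``growth_rate_between``: [t1, t2] to add per-condition rates.

    No multiple-testing correction is applied unless ``bonferroni=True``;
    the choice is recorded in each output's metadata.
    """
    required = {"fields", "conditions", "timepoints_hpf", "tests"}
    missing = required - set(plan)
    if missing:
        raise ValueError(f"plan missing entries: {sorted(missing)}")
    cond_ref, cond_alt = plan["conditions"]
    for c in (cond_ref, cond_alt):
        if c not in set(records["condition"]):
            raise ValueError(f"plan names a missing condition: {c!r}")
    out: list[GroupComparison] = []
    for fieldname in plan["fields"]:
        if fieldname not in records.columns:
            raise ValueError(f"plan names a missing field: {fieldname!r}")
        for tp in plan["timepoints_hpf"]:
            sel = records["timepoint_hpf"] == tp
            a = records[sel & (records["condition"] == cond_ref)][fieldname].to_numpy()
            b = records[sel & (records["condition"] == cond_alt)][fieldname].to_numpy()
            if len(a) == 0 or len(b) == 0:
                raise ValueError(f"no records for timepoint {tp} in plan field {fieldname!r}")
            if "kruskal_wallis" in plan["tests"]:
                cmp = kruskal_wallis([a, b])
                cmp.effect = fold_change(a, b)
                cmp.effect_units = f"{cond_ref}/{cond_alt} mean ratio"
                cmp.meta.update(field=fieldname, timepoint_hpf=tp)
                out.append(cmp)
            if "fold_change" in plan["tests"]:
                out.append(
                    GroupComparison(
                        test_name="fold_change",
                        statistic_value=fold_change(a, b),
                        p_value=1.0,
                        group_sizes=(len(a), len(b)),
                        effect=fold_change(a, b),
                        effect_units=f"{cond_ref}/{cond_alt} mean ratio",
                        meta={"field": fieldname, "timepoint_hpf": tp},
                    )
                )
        if "growth_rate_between" in plan:
            t1, t2 = plan["growth_rate_between"]
            for cond in (cond_ref, cond_alt):
                rate = growth_rate(records, cond, t1, t2, fieldname)
                n1 = int(((records["condition"] == cond) & (records["timepoint_hpf"] == t1)).sum())
                n2 = int(((records["condition"] == cond) & (records["timepoint_hpf"] == t2)).sum())
                out.append(
                    GroupComparison(
                        test_name="growth_rate",
                        statistic_value=rate,
                        p_value=1.0,
                        group_sizes=(n1, n2),
                        effect=rate,
                        effect_units=f"{fieldname} per hour",
                        meta={"field": fieldname, "condition": cond, "t1": t1, "t2": t2},
                    )
                )
    n_tests = sum(1 for c in out if c.test_name in ("kruskal_wallis",))
    for c in out:
        c.meta["multiple_testing"] = "bonferroni" if bonferroni else "none"
        if bonferroni and c.test_name == "kruskal_wallis" and n_tests:
            c.p_value = min(1.0, c.p_value * n_tests)
    return out
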