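"""Group comparison of barrier samples and error propagation.

One barrier sample comes from one (replica, monomer) pair; groups (WT vs a
mutant) and forms (apo / holo variants) are compared by a two-sample t-test
— Welch's unequal-variance test by default, the pooled-variance variant by
flag.  Reported uncertainties are standard deviations; combining independent
errors uses root-sum-of-squares by default (a literal sum-of-errors square
root is available for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["BarrierSample", "ComparisonResult", "welch_ttest",
           "propagate_sd", "summarize_barriers"]


@dataclass
class BarrierSample:
    value: float  # kcal/mol, absolute (vacuum-referenced)
    group: str  # e.g. WT / Y350F
    form: str = "apo"  # apo / holo-LLP+substrate / holo-external-aldimine
    replica: int = 0
    monomer: str = "A"


@dataclass
class ComparisonResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    dof: float
    p: float
    significant: bool
    alpha: float = 0.05


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float],
                alpha: float = 0.05,
                equal_var: bool = False) -> ComparisonResult:
    """Two-sample t-test (Welch by default), two-sided."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(a.mean(), b.mean(), 0.0, 0.0, 0.0,
                                    float(len(a) + len(b) - 2), 1.0, False,
                                    alpha)
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        dof = len(a) + len(b) - 2.0
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                + vb ** 2 / (len(b) - 1))
    return ComparisonResult(float(a.mean()), float(b.mean()),
                            float(a.std(ddof=1)), float(b.std(ddof=1)),
                            float(t), float(dof), float(p), bool(p < alpha),
                            alpha)


def propagate_sd(sds: Sequence[float], literal_sum: bool = False) -> float:
    """Combine independent standard deviations.

    Default: root-sum-of-squares (standard propagation for a sum or
    difference).  ``literal_sum=True`` returns sqrt(sum of the errors
    themselves) instead.
    """
    s = np.asarray(sds, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("standard deviations must be non-negative")
    if literal_sum:
        return float(np.sqrt(np.sum(s)))
    return float(np.sqrt(np.sum(s * s)))


def summarize_barriers(samples: Sequence[BarrierSample], bulk_reference,
                       alpha: float = 0.05,
                       compare_groups: Optional[tuple] = None) -> pd.DataFrame:
    """Per-(group, form) barrier summary relative to the bulk reference.

    Columns: absolute mean ± sd, relative barrier (mean − bulk mean_G) with
    root-sum-square propagated sd, a one-sample t-test of the relative
    barrier against zero, and (when two groups share a form) the two-sample
    Welch p-value with an ns/significant flag.
    """
    if bulk_reference is None:
        raise ValueError("bulk reference required")
    bulk_g = bulk_reference.mean_G
    bulk_sd = bulk_reference.sd if np.isfinite(bulk_reference.sd) else 0.0
    df = pd.DataFrame([{"value": s.value, "group": s.group, "form": s.form,
                        "replica": s.replica, "monomer": s.monomer}
                       for s in samples])
    rows = []
    for (group, form), sub in df.groupby(["group", "form"], sort=True):
        vals = sub["value"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rel = mean - bulk_g
        rel_sd = propagate_sd([sd, bulk_sd])
        if len(vals) > 1 and vals.std(ddof=1) > 0:
            t1, p1 = sps.ttest_1samp(vals - bulk_g, 0.0)
            p_vs_zero = float(p1)
        else:
            p_vs_zero = float("nan")
        rows.append({"group": group, "form": form, "n": len(vals),
                     "barrier_abs_mean": mean, "barrier_abs_sd": sd,
                     "barrier_rel_mean": rel, "barrier_rel_sd": rel_sd,
                     "p_vs_zero": p_vs_zero})
    out = pd.DataFrame(rows)
    # pairwise group comparison within each form
    out["p_vs_other"] = np.nan
    out["flag"] = ""
    for form, sub in out.groupby("form"):
        groups = list(sub["group"])
        if compare_groups is not None:
            pairs = [compare_groups] if set(compare_groups) <= set(groups) \
                else []
        else:
            pairs = [(groups[i], groups[j]) for i in range(len(groups))
                     for j in range(i + 1, len(groups))]
        for ga, gb in pairs:
            va = df[(df["group"] == ga) & (df["form"] == form)]["value"]
            vb = df[(df["group"] == gb) & (df["form"] == form)]["value"]
            if len(va) < 2 or len(vb) < 2:
                continue
            res = welch_ttest(va, vb, alpha=alpha)
            flag = "*" if res.significant else "ns"
            for g in (ga, gb):
                m = (out["group"] == g) & (out["form"] == form)
                out.loc[m, "p_vs_other"] = res.p
                out.loc[m, "flag"] = flag
    return out
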