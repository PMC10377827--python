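"""Clinical-covariate handling for the three-group cohort design.

Covers the enrollment screen (exclusion criteria for inflammation,
obesity, poor glycemic control, hypertriglyceridemia, substance use and
renal impairment), nonparametric group summaries as median (Q1-Q3), and
the Kruskal-Wallis test for intergroup differences, with an exact
permutation p value available at small sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("control", "IFG", "T2D")

#: Exclusion thresholds applied at enrollment. A subject exceeding any of
#: these (or flagged for substance use / microalbuminuria) is ineligible.
EXCLUSION_RULES = {
    "crp": ("inflammation (CRP > 6 mg/L)", lambda v: v > 6.0),
    "esr": ("inflammation (ESR > 30 mm/h)", lambda v: v > 30.0),
    "bmi": ("obesity (BMI > 30 kg/m^2)", lambda v: v > 30.0),
    "hba1c": ("poor glycemic control (HbA1c > 8%)", lambda v: v > 8.0),
    "triglycerides": (
        "moderate-to-severe hypertriglyceridemia (triglycerides > 175 mg/dL)",
        lambda v: v > 175.0,
    ),
    "egfr": ("renal impairment (eGFR < 60 mL/min/1.73 m^2)", lambda v: v < 60.0),
    "smoking": ("smoking", bool),
    "alcohol": ("alcohol use", bool),
    "drug_use": ("drug use (incl. miRNA-active medication)", bool),
    "microalbuminuria": ("renal impairment (microalbuminuria)", bool),
}


@dataclass
class ClinicalRecord:
    """One subject's enrollment covariates; ``None`` marks a missing value."""

    subject: str
    group: str
    sex: str | None = None
    age: float | None = None
    bmi: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    fasting_glucose: float | None = None
    hba1c: float | None = None
    total_cholesterol: float | None = None
    ldl_cholesterol: float | None = None
    hdl_cholesterol: float | None = None
    triglycerides: float | None = None
    crp: float | None = None
    esr: float | None = None
    egfr: float | None = None
    microalbuminuria: bool | None = None
    smoking: bool | None = None
    alcohol: bool | None = None
    drug_use: bool | None = None
    t2d_duration: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        numeric = (
            "age bmi sbp dbp fasting_glucose hba1c total_cholesterol "
            "ldl_cholesterol hdl_cholesterol triglycerides crp esr egfr "
            "t2d_duration"
        ).split()
        for name in numeric:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be non-negative and finite, got {v}")


def screen_eligibility(record: ClinicalRecord) -> tuple[bool, list[str], list[str]]:
    """Apply the enrollment exclusion criteria to one subject.

    Returns ``(eligible, violations, unknown)``: the criteria violated,
    and the criteria that could not be evaluated because the field is
    missing. A subject is eligible iff no criterion is violated.
    """
    violations, unknown = [], []
    for attr, (label, is_violated) in EXCLUSION_RULES.items():
        value = getattr(record, attr)
        if value is None:
            unknown.append(label)
        elif is_violated(value):
            violations.append(label)
    return not violations, violations, unknown


def summarize_median_iqr(
    values_by_group: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Median and interquartile range per group.

    Quartiles use linear interpolation between order statistics (the
    common type-7 convention). One row per group with columns
    ``n, median, q1, q3``.
    """
    rows = {}
    for group, values in values_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} has no values")
        rows[group] = {
            "n": arr.size,
            "median": float(np.median(arr)),
            "q1": float(np.quantile(arr, 0.25)),
            "q3": float(np.quantile(arr, 0.75)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _kw_h(pooled_ranks: np.ndarray, sizes: Sequence[int], tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled ranks laid out group by
    group."""
    n = pooled_ranks.size
    h = 0.0
    start = 0
    for size in sizes:
        r = pooled_ranks[start:start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis(
    groups: Sequence[Sequence[float]], exact: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis H and p value across two or more groups.

    The default p comes from the chi-square approximation with k-1
    degrees of freedom (tie-corrected H). With ``exact=True`` the p value
    is instead computed by exhaustive enumeration of all group
    assignments of the pooled data — feasible for small cohorts only
    (total n up to ~12). If every pooled value is identical, H = 0 and
    p = 1.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if not exact:
        h, p = stats.kruskal(*arrays)
        return float(h), float(p)

    sizes = [a.size for a in arrays]
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    h_obs = _kw_h(ranks, sizes, tie_factor)

    # exhaustive enumeration over distinct partitions of the pooled
    # observations into groups of the observed sizes (multinomial count,
    # far smaller than n!)
    seen = 0
    at_least = 0
    for assignment in _partitions(tuple(range(n)), sizes):
        perm_ranks = ranks[list(assignment)]
        h = _kw_h(perm_ranks, sizes, tie_factor)
        seen += 1
        if h >= h_obs - 1e-12:
            at_least += 1
    return h_obs, at_least / seen


def _partitions(indices: tuple[int, ...], sizes: Sequence[int]):
    """Yield every split of ``indices`` into consecutive groups of the
    given sizes, as one concatenated index tuple per split."""
    if len(sizes) == 1:
        yield indices
        return
    rest_sizes = sizes[1:]
    for chosen in combinations(indices, sizes[0]):
        chosen_set = set(chosen)
        remaining = tuple(i for i in indices if i not in chosen_set)
        for rest in _partitions(remaining, rest_sizes):
            yield chosen + rest


def summarize_clinical_table(
    frame: pd.DataFrame, parameters: Sequence[str], exact: bool = False
) -> pd.DataFrame:
    """Group summaries plus Kruskal-Wallis p per clinical parameter.

    ``frame`` holds one row per subject with a ``group`` column; the
    output mirrors a clinical characteristics table: one row per
    parameter, ``median (q1-q3)`` per group, and the intergroup p value.
    """
    if "group" not in frame.columns:
        raise ValueError("clinical table needs a 'group' column")
    rows = []
    groups = [g for g in GROUPS if g in set(frame["group"])] or sorted(
        set(frame["group"])
    )
    for param in parameters:
        by_group = {
            g: frame.loc[frame["group"] == g, param].dropna().to_numpy()
            for g in groups
        }
        by_group = {g: v for g, v in by_group.items() if v.size}
        summary = summarize_median_iqr(by_group)
        h, p = kruskal_wallis(list(by_group.values()), exact=exact)
        row = {"parameter": param, "H": h, "p": p}
        for g in by_group:
            s = summary.loc[g]
            row[g] = f"{s['median']:g} ({s['q1']:g}-{s['q3']:g})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
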