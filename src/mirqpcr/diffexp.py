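"""Differential expression by the comparative-Ct method.

For each miRNA detected in both groups of a contrast,
ddCt = dCt(test) - dCt(reference), fold change FC = 2^(-ddCt), and the
signed fold regulation FR equals FC when FC >= 1 and -1/FC otherwise, so a
halving is reported as -2 rather than 0.5. Classification uses the
conventional +/-2 threshold; signature rules operate on classified
contrasts: a high-stringency cut at |FR| >= 10, a monotone-progression
predicate across the prediabetes -> diabetes contrasts, and a
condition-specific rule selecting miRNAs deregulated in exactly one case
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import NormalizedProfile
from .panel_io import ComparisonFixture, ComparisonRecord, PanelDefinition

#: Conventional fold-regulation significance threshold.
FR_THRESHOLD = 2.0
#: High-stringency fold-regulation threshold.
FR_THRESHOLD_STRINGENT = 10.0
#: Printed precision of fold-regulation values (decimal places).
FR_PRECISION = 2


@dataclass(frozen=True)
class Contrast:
    test: str
    reference: str

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise ValueError("contrast test and reference groups must differ")

    @property
    def name(self) -> str:
        return f"{self.test}_vs_{self.reference}"


@dataclass
class SignatureSet:
    """miRNAs selected by one signature rule, with the fold-regulation
    evidence that satisfied the rule's predicate."""

    rule: str
    selected: list[str]
    evidence: dict[str, dict] = field(default_factory=dict)

    def __contains__(self, mirna: str) -> bool:
        return mirna in set(self.selected)

    def __len__(self) -> int:
        return len(self.selected)


@dataclass
class ConcordanceReport:
    """Agreement between two normalization methods on one contrast."""

    method_a: str
    method_b: str
    n_common: int
    label_agreement: float
    sign_agreement: float
    n_a_leq_b: int  # miRNAs where |FR_a| <= |FR_b|

    def __post_init__(self) -> None:
        for frac in (self.label_agreement, self.sign_agreement):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("agreement fractions must lie in [0, 1]")


def fold_regulation(ddct: float) -> tuple[float, float]:
    """Fold change and signed fold regulation for one ddCt.

    FC = 2^(-ddct); FR = FC if FC >= 1 else -1/FC. ddct = 0 gives
    (FC, FR) = (1, 1): no change is +1 by convention, never -1.
    """
    if not math.isfinite(ddct):
        raise ValueError(f"ddCt must be finite, got {ddct}")
    fc = 2.0 ** (-ddct)
    fr = fc if fc >= 1.0 else -1.0 / fc
    return fc, fr


def classify_fr(fr: float, threshold: float = FR_THRESHOLD) -> str:
    """Classify a fold regulation at printed (2-decimal) precision."""
    r = round(fr, FR_PRECISION)
    if r >= threshold:
        return "up"
    if r <= -threshold:
        return "down"
    return "unchanged"


def delta_delta_ct(
    test: NormalizedProfile, ref: NormalizedProfile
) -> pd.Series:
    """Per-miRNA ddCt between two profiles normalized by the same method.

    Defined for assays detected in both profiles; assays present in only
    one side are absent from the result (not_evaluable downstream).
    """
    if test.method != ref.method:
        raise ValueError(
            f"normalization method mismatch: {test.method} vs {ref.method}"
        )
    common = test.dct.index.intersection(ref.dct.index)
    return (test.dct[common] - ref.dct[common]).rename("ddct")


def compare_profiles(
    test: NormalizedProfile,
    ref: NormalizedProfile,
    panel: PanelDefinition | None = None,
    threshold: float = FR_THRESHOLD,
) -> list[ComparisonRecord]:
    """Full contrast between two normalized profiles.

    Restricted to panel targets when ``panel`` is given (controls and the
    spike-in are never reported as differentially expressed). miRNAs
    undetected in either profile come back labelled ``not_evaluable``.
    """
    ddct = delta_delta_ct(test, ref)
    universe: Iterable[str]
    if panel is not None:
        universe = [
            a for a in panel.targets
            if a in test.dct.index or a in ref.dct.index
        ]
    else:
        universe = sorted(set(test.dct.index) | set(ref.dct.index))
    records = []
    for mirna in universe:
        if mirna in ddct.index:
            fc, fr = fold_regulation(float(ddct[mirna]))
            records.append(
                ComparisonRecord(
                    mirna=mirna,
                    ddct=float(ddct[mirna]),
                    fold_change=fc,
                    fold_regulation=fr,
                    label=classify_fr(fr, threshold),
                )
            )
        else:
            records.append(
                ComparisonRecord(
                    mirna=mirna, ddct=math.nan, fold_change=math.nan,
                    fold_regulation=math.nan, label="not_evaluable",
                )
            )
    return records


def classify_contrast(
    records: Sequence[ComparisonRecord] | ComparisonFixture,
    threshold: float = FR_THRESHOLD,
) -> list[ComparisonRecord]:
    """(Re-)label records, or build labelled records from a printed-table
    fixture, at the given fold-regulation threshold."""
    if isinstance(records, ComparisonFixture):
        records = records_from_fixture(records)
    out = []
    for r in records:
        if r.label == "not_evaluable":
            out.append(r)
            continue
        out.append(
            ComparisonRecord(
                mirna=r.mirna, ddct=r.ddct, fold_change=r.fold_change,
                fold_regulation=r.fold_regulation,
                label=classify_fr(r.fold_regulation, threshold),
            )
        )
    return out


def records_from_fixture(
    fixture: ComparisonFixture, threshold: float = FR_THRESHOLD
) -> list[ComparisonRecord]:
    """Reconstruct comparison records from printed fold regulations.

    ddCt and fold change are back-computed from FR via the sign
    convention; they inherit the table's printed precision.
    """
    records = []
    for mirna, fr in fixture.fold_regulation.items():
        fc = fr if fr >= 1 else -1.0 / fr
        records.append(
            ComparisonRecord(
                mirna=mirna,
                ddct=-math.log2(fc),
                fold_change=fc,
                fold_regulation=fr,
                label=classify_fr(fr, threshold),
            )
        )
    return records


def count_labels(records: Sequence[ComparisonRecord]) -> dict[str, int]:
    counts = {"up": 0, "down": 0, "unchanged": 0, "not_evaluable": 0}
    for r in records:
        counts[r.label] += 1
    return counts


def _fr_map(records: Sequence[ComparisonRecord]) -> dict[str, float]:
    return {
        r.mirna: r.fold_regulation
        for r in records
        if r.label != "not_evaluable"
    }


def high_stringency_set(
    contrasts: Mapping[str, Sequence[ComparisonRecord]],
    threshold: float = FR_THRESHOLD_STRINGENT,
) -> SignatureSet:
    """miRNAs reaching |FR| >= threshold in at least one case-vs-control
    contrast; evidence records every contrast's FR for each hit."""
    if not contrasts:
        raise ValueError("at least one contrast is required")
    fr_maps = {name: _fr_map(recs) for name, recs in contrasts.items()}
    selected: list[str] = []
    evidence: dict[str, dict] = {}
    universe = sorted({m for fm in fr_maps.values() for m in fm})
    for mirna in universe:
        frs = {name: fm.get(mirna) for name, fm in fr_maps.items()}
        hits = {
            name: fr for name, fr in frs.items()
            if fr is not None and abs(round(fr, FR_PRECISION)) >= threshold
        }
        if hits:
            selected.append(mirna)
            evidence[mirna] = {
                "fold_regulation": frs,
                "passing_contrasts": sorted(hits),
            }
    return SignatureSet(rule="high_stringency", selected=selected, evidence=evidence)


def progression_signature(
    ifg_vs_ctrl: Sequence[ComparisonRecord],
    t2d_vs_ctrl: Sequence[ComparisonRecord],
    min_fr: float = FR_THRESHOLD,
) -> SignatureSet:
    """miRNAs whose fold regulation versus the euglycemic reference rises
    strictly from the prediabetic to the diabetic group.

    Selects miRNAs evaluable in both contrasts with
    FR(T2D vs ctrl) > FR(IFG vs ctrl) and FR(T2D vs ctrl) >= min_fr.
    """
    fr_ifg, fr_t2d = _fr_map(ifg_vs_ctrl), _fr_map(t2d_vs_ctrl)
    selected, evidence = [], {}
    for mirna in sorted(set(fr_ifg) & set(fr_t2d)):
        a, b = fr_ifg[mirna], fr_t2d[mirna]
        if b > a and b >= min_fr:
            selected.append(mirna)
            evidence[mirna] = {"fr_ifg_vs_ctrl": a, "fr_t2d_vs_ctrl": b}
    return SignatureSet(rule="progression", selected=selected, evidence=evidence)


def condition_specific_set(
    focal_vs_ctrl: Sequence[ComparisonRecord],
    other_vs_ctrl: Sequence[ComparisonRecord],
    threshold: float = FR_THRESHOLD,
) -> SignatureSet:
    """miRNAs deregulated in the focal case group but not in the other.

    Selected when |FR_focal| >= threshold while the other contrast is
    below threshold (or the miRNA is absent from it, i.e. unchanged), and
    any sub-threshold trend in the other group points the same way.
    """
    fr_focal, fr_other = _fr_map(focal_vs_ctrl), _fr_map(other_vs_ctrl)
    selected, evidence = [], {}
    for mirna in sorted(fr_focal):
        fr = fr_focal[mirna]
        if abs(round(fr, FR_PRECISION)) < threshold:
            continue
        other = fr_other.get(mirna)
        if other is not None:
            if abs(round(other, FR_PRECISION)) >= threshold:
                continue
            if math.copysign(1, other) != math.copysign(1, fr):
                continue
        selected.append(mirna)
        evidence[mirna] = {
            "fr_focal": fr,
            "fr_other": other,
            "direction": "up" if fr > 0 else "down",
        }
    return SignatureSet(
        rule="condition_specific", selected=selected, evidence=evidence
    )


def normalization_concordance(
    results_by_method: Mapping[str, Sequence[ComparisonRecord]],
    global_method: str = "global_mean",
) -> list[ConcordanceReport]:
    """Pairwise agreement between normalization methods on one contrast.

    For each method pair: fraction of shared evaluable miRNAs with the
    same classification label, fraction with the same FR sign, and the
    count where the first method's |FR| does not exceed the second's
    (mean-centric normalization is expected to be the more conservative).
    """
    methods = list(results_by_method)
    if len(methods) < 2:
        raise ValueError("concordance needs at least two methods")
    # put the global/mean-centric method first in each pair
    methods.sort(key=lambda m: (m != global_method, m))
    maps = {
        m: {r.mirna: r for r in results_by_method[m] if r.label != "not_evaluable"}
        for m in methods
    }
    reports = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            common = sorted(set(maps[ma]) & set(maps[mb]))
            if not common:
                raise ValueError(f"no shared evaluable miRNAs for {ma} vs {mb}")
            same_label = sum(
                maps[ma][m].label == maps[mb][m].label for m in common
            )
            same_sign = sum(
                math.copysign(1, maps[ma][m].fold_regulation)
                == math.copysign(1, maps[mb][m].fold_regulation)
                for m in common
            )
            a_leq_b = sum(
                abs(maps[ma][m].fold_regulation)
                <= abs(maps[mb][m].fold_regulation)
                for m in common
            )
            reports.append(
                ConcordanceReport(
                    method_a=ma,
                    method_b=mb,
                    n_common=len(common),
                    label_agreement=same_label / len(common),
                    sign_agreement=same_sign / len(common),
                    n_a_leq_b=a_leq_b,
                )
            )
    return reports
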