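"""Sample-level quality control for serum miRNA qPCR profiles.

Three checks gate a serum sample before expression analysis: the hemolysis
index (Ct difference miR-23a-3p minus miR-451a, which blows up when
erythrocyte-derived miR-451a contaminates the serum), spectrophotometric
RNA purity ratios, and the detection filter that discards amplifications
with raw Ct above 35 cycles. Expression tiers (high / moderate / low /
undetected) summarise how much of the panel a profile actually covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .panel_io import CtMatrix, PanelDefinition

#: Hemolysis pass rule: delta Ct strictly below this many cycles.
HEMOLYSIS_THRESHOLD = 5.0
#: Detection cut-off: raw Ct above this is treated as undetected.
DETECTION_CT_MAX = 35.0
#: Acceptable A260/A280 and A260/A230 absorbance-ratio windows (inclusive).
PURITY_260_280 = (1.9, 2.1)
PURITY_260_230 = (2.0, 2.2)

TIERS = ("high", "moderate", "low", "undetected")


@dataclass
class QcReport:
    """Per-sample QC summary; ``None`` marks a quantity that could not be
    computed (e.g. an undetermined hemolysis-pair Ct)."""

    sample: str
    hemolysis_delta_ct: float | None
    hemolysis_pass: bool
    purity_260_280: float | None = None
    purity_260_230: float | None = None
    purity_pass: bool | None = None
    n_detected: int = 0
    tier_counts: dict[str, int] | None = None

    def to_row(self) -> dict:
        row = asdict(self)
        tiers = row.pop("tier_counts") or {}
        for t in TIERS:
            row[f"n_{t}"] = tiers.get(t)
        return row


def hemolysis_index(
    profile: pd.Series,
    panel: PanelDefinition,
    threshold: float = HEMOLYSIS_THRESHOLD,
) -> tuple[float | None, bool]:
    """Hemolysis delta Ct = Ct(miR-23a-3p) - Ct(miR-451a) for one sample.

    Returns ``(delta_ct, passed)``; passed iff delta_ct < threshold.
    If either pair Ct is undetermined the index is ``None`` and the sample
    fails (the indicator cannot vouch for it). Raises ``KeyError`` if a
    pair assay is missing from the profile.
    """
    num, den = panel.hemolysis_pair
    for assay in (num, den):
        if assay not in profile.index:
            raise KeyError(f"hemolysis-pair assay {assay!r} absent from profile")
    ct_num, ct_den = float(profile[num]), float(profile[den])
    if math.isnan(ct_num) or math.isnan(ct_den):
        return None, False
    delta = ct_num - ct_den
    return delta, delta < threshold


def purity_check(
    a260_280: float | None, a260_230: float | None
) -> tuple[bool | None, bool | None]:
    """Check spectrophotometric purity ratios against the accepted windows
    (1.9-2.1 and 2.0-2.2, inclusive).

    Returns a pass flag per ratio; ``None`` in means unknown out (a missing
    measurement is flagged, not failed). Non-positive ratios are errors.
    """
    flags = []
    for ratio, (lo, hi) in ((a260_280, PURITY_260_280), (a260_230, PURITY_260_230)):
        if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
            flags.append(None)
            continue
        if ratio <= 0:
            raise ValueError(f"absorbance ratio must be positive, got {ratio}")
        flags.append(lo <= ratio <= hi)
    return tuple(flags)


def filter_detected(
    matrix: CtMatrix, ct_max: float = DETECTION_CT_MAX
) -> tuple[CtMatrix, pd.DataFrame]:
    """Mask out undetected reactions (Ct > ct_max or undetermined).

    Returns a new CtMatrix in which undetected cells are NaN, plus the
    boolean detection mask (True = detected). The input is not modified.
    """
    values = matrix.values
    mask = values.le(ct_max) & values.notna()
    filtered = values.where(mask)
    return CtMatrix(values=filtered, groups=matrix.groups.copy()), mask


def expression_tiers(
    profile: pd.Series, panel: PanelDefinition, ct_max: float = DETECTION_CT_MAX
) -> dict[str, int]:
    """Count target assays per expression tier for one profile.

    high: Ct <= 25; moderate: 25 < Ct <= 30; low: 30 < Ct <= ct_max;
    undetected: Ct > ct_max or undetermined. Controls and spike-in are
    excluded; the four counts partition the target assays present.
    """
    targets = [a for a in panel.targets if a in profile.index]
    cts = profile[targets].to_numpy(dtype=float)
    detected = np.isfinite(cts) & (cts <= ct_max)
    high = int(np.sum(detected & (cts <= 25.0)))
    moderate = int(np.sum(detected & (cts > 25.0) & (cts <= 30.0)))
    low = int(np.sum(detected & (cts > 30.0)))
    return {
        "high": high,
        "moderate": moderate,
        "low": low,
        "undetected": len(targets) - high - moderate - low,
    }


def qc_sample(
    profile: pd.Series,
    panel: PanelDefinition,
    sample: str = "",
    hemolysis_threshold: float = HEMOLYSIS_THRESHOLD,
    ct_max: float = DETECTION_CT_MAX,
    a260_280: float | None = None,
    a260_230: float | None = None,
) -> QcReport:
    """Full QC for one sample profile."""
    delta, hpass = hemolysis_index(profile, panel, threshold=hemolysis_threshold)
    p280, p230 = purity_check(a260_280, a260_230)
    purity_pass = None if (p280 is None and p230 is None) else (
        (p280 is not False) and (p230 is not False)
    )
    tiers = expression_tiers(profile, panel, ct_max=ct_max)
    cts = profile.to_numpy(dtype=float)
    n_detected = int(np.sum(np.isfinite(cts) & (cts <= ct_max)))
    return QcReport(
        sample=sample or str(profile.name),
        hemolysis_delta_ct=delta,
        hemolysis_pass=hpass,
        purity_260_280=a260_280,
        purity_260_230=a260_230,
        purity_pass=purity_pass,
        n_detected=n_detected,
        tier_counts=tiers,
    )


def qc_matrix(
    matrix: CtMatrix,
    panel: PanelDefinition,
    hemolysis_threshold: float = HEMOLYSIS_THRESHOLD,
    ct_max: float = DETECTION_CT_MAX,
    strict: bool = False,
) -> pd.DataFrame:
    """QC every sample of a matrix; one row per sample.

    With ``strict=True`` a hemolysis failure raises instead of flagging,
    aborting the pipeline before normalization.
    """
    rows = []
    for sample in matrix.samples:
        report = qc_sample(
            matrix.sample_profile(sample),
            panel,
            sample=sample,
            hemolysis_threshold=hemolysis_threshold,
            ct_max=ct_max,
        )
        if strict and not report.hemolysis_pass:
            raise RuntimeError(
                f"sample {sample} fails hemolysis QC "
                f"(delta Ct = {report.hemolysis_delta_ct})"
            )
        rows.append(report.to_row())
    return pd.DataFrame(rows).set_index("sample")
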