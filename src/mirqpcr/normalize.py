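"""Ct normalization: raw Ct profiles to per-assay delta Ct.

Three interchangeable reference statistics are supported:

* ``global_mean`` — the arithmetic mean Ct of every detected assay in the
  profile, endogenous controls and spike-in included. This mean-centric
  strategy assumes the average expression of a large panel is constant
  across samples at equal RNA input, and is the primary method here.
* ``reference_genes`` — the mean Ct of the detected endogenous small
  nucleolar RNA controls.
* ``spike_in`` — the Ct of the exogenous cel-miR-39 spike-in, which tracks
  extraction efficiency rather than biology.

In every case dCt(m) = Ct(m) - reference, defined only for assays detected
at or below the Ct cut-off; undetected assays stay undefined rather than
being imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import PanelDefinition
from .qc import DETECTION_CT_MAX

logger = logging.getLogger(__name__)

METHODS = ("global_mean", "reference_genes", "spike_in")


class NormalizationError(ValueError):
    """Profile cannot be normalized by the requested method."""


@dataclass
class NormalizedProfile:
    """Per-assay delta Ct for one sample or pooled group.

    ``dct`` is indexed by assay and covers detected assays only;
    ``reference_value`` is the subtracted Ct statistic.
    """

    name: str
    method: str
    reference_value: float
    dct: pd.Series

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise NormalizationError(f"unknown normalization method {self.method!r}")
        if not math.isfinite(self.reference_value):
            raise NormalizationError("reference value is not finite")

    def linear(self) -> pd.Series:
        """Linearised relative expression 2^(-dCt) per detected assay."""
        return np.exp2(-self.dct)


def _detected(profile: pd.Series, ct_max: float) -> pd.Series:
    cts = profile.astype(float)
    return cts[np.isfinite(cts) & (cts <= ct_max)]


def global_ct_mean_normalize(
    profile: pd.Series,
    panel: PanelDefinition,
    ct_max: float = DETECTION_CT_MAX,
    name: str | None = None,
) -> NormalizedProfile:
    """Normalize one profile against its global mean Ct.

    The reference is the arithmetic mean over ALL detected assays —
    targets, endogenous controls and spike-in alike — so the resulting
    delta Cts average to zero over the detected set. Requires at least two
    detected assays.
    """
    known = [a for a in profile.index if a in panel]
    detected = _detected(profile[known], ct_max)
    if len(detected) < 2:
        raise NormalizationError(
            f"global mean needs >= 2 detected assays, found {len(detected)}"
        )
    reference = float(detected.mean())
    return NormalizedProfile(
        name=name or str(profile.name),
        method="global_mean",
        reference_value=reference,
        dct=detected - reference,
    )


def reference_gene_normalize(
    profile: pd.Series,
    panel: PanelDefinition,
    ct_max: float = DETECTION_CT_MAX,
    name: str | None = None,
) -> NormalizedProfile:
    """Normalize against the mean Ct of detected endogenous controls.

    Undetected controls are dropped from the mean with a warning; if all
    controls are undetected the profile cannot be normalized.
    """
    controls = [a for a in panel.endogenous_controls if a in profile.index]
    detected_controls = _detected(profile[controls], ct_max)
    if detected_controls.empty:
        raise NormalizationError("no endogenous control detected")
    if len(detected_controls) < len(controls):
        dropped = sorted(set(controls) - set(detected_controls.index))
        logger.warning("undetected endogenous controls dropped: %s", dropped)
    reference = float(detected_controls.mean())
    targets = [a for a in panel.targets if a in profile.index]
    dct = _detected(profile[targets], ct_max) - reference
    return NormalizedProfile(
        name=name or str(profile.name),
        method="reference_genes",
        reference_value=reference,
        dct=dct,
    )


def spikein_normalize(
    profile: pd.Series,
    panel: PanelDefinition,
    ct_max: float = DETECTION_CT_MAX,
    name: str | None = None,
) -> NormalizedProfile:
    """Normalize against the exogenous spike-in Ct.

    An undetermined spike-in signals extraction failure and raises.
    """
    if panel.spike_in not in profile.index:
        raise NormalizationError(f"spike-in {panel.spike_in!r} absent from profile")
    ct_spike = float(profile[panel.spike_in])
    if math.isnan(ct_spike) or ct_spike > ct_max:
        raise NormalizationError(
            f"spike-in {panel.spike_in} undetected: extraction failure"
        )
    targets = [a for a in panel.targets if a in profile.index]
    dct = _detected(profile[targets], ct_max) - ct_spike
    return NormalizedProfile(
        name=name or str(profile.name),
        method="spike_in",
        reference_value=ct_spike,
        dct=dct,
    )


_NORMALIZERS = {
    "global_mean": global_ct_mean_normalize,
    "reference_genes": reference_gene_normalize,
    "spike_in": spikein_normalize,
}


def normalize_profile(
    profile: pd.Series,
    panel: PanelDefinition,
    method: str = "global_mean",
    ct_max: float = DETECTION_CT_MAX,
    name: str | None = None,
) -> NormalizedProfile:
    """Dispatch to one of the three normalization strategies."""
    try:
        fn = _NORMALIZERS[method]
    except KeyError:
        raise NormalizationError(f"unknown normalization method {method!r}") from None
    return fn(profile, panel, ct_max=ct_max, name=name)
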