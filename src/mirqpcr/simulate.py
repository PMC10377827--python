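"""Synthetic serum-miRNA qPCR cohorts with known ground truth.

The generator emulates the measurement process of a pooled-design array
study: per-assay baseline Cts laid out in expression tiers (a few highly
expressed assays, a moderate band, a long low/undetected tail), per-sample
global Ct offsets standing in for RNA input and extraction efficiency,
planted group-specific log2 expression effects (positive effect = higher
expression = lower Ct), Gaussian technical noise, censoring of weak
amplifications, optional hemolysis contamination of chosen samples, and
equimolar pooling of each group's samples into a single profile.

The accompanying :class:`SimulationTruth` carries everything needed for
parameter-recovery tests: the planted effects and offsets, plus analytic
expected fold regulations per contrast — both the naive closed form from
the effects alone and method-aware expectations that account for how the
planted effects themselves move a mean-centric reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import CtMatrix, PanelDefinition, load_panel

#: Printed fold regulations used to seed realistic default effects
#: (per miRNA: case-group FR versus the euglycemic reference).
_DEFAULT_EFFECT_FRS: dict[str, tuple[float, float]] = {
    # (FR in IFG vs control, FR in T2D vs control)
    "hsa-miR-4301": (124.8, 142.74),
    "hsa-let-7b-5p": (100.66, 90.34),
    "hsa-miR-195-5p": (23.16, 25.76),
    "hsa-miR-523-5p": (32.75, 34.47),
    "hsa-let-7a-5p": (37.1, 48.41),
    "hsa-miR-3135b": (15.49, 18.99),
    "hsa-miR-1281": (7.85, 14.9),
    "hsa-miR-3610": (6.16, 7.93),
    "hsa-miR-3200-5p": (8.3, 13.06),
    "hsa-miR-4651": (7.91, 10.76),
    "hsa-miR-1225-3p": (1.9, 3.62),
    "hsa-miR-146a-5p": (-1.3, -2.64),
    "hsa-miR-328-3p": (-52.22, -30.54),
    "hsa-miR-324-5p": (-15.1, -2.95),
    "hsa-miR-382-5p": (-14.59, -11.49),
}


def fr_to_log2(fr: float) -> float:
    """Signed fold regulation to a log2 expression effect."""
    if abs(fr) < 1:
        raise ValueError(f"|fold regulation| must be >= 1, got {fr}")
    return math.log2(fr) if fr > 0 else -math.log2(-fr)


def log2_to_fr(effect: float) -> float:
    """Log2 expression effect to signed fold regulation."""
    fc = 2.0 ** effect
    return fc if fc >= 1.0 else -1.0 / fc


def default_effect_table() -> dict[str, dict[str, float]]:
    """Planted log2 effects per miRNA per case group.

    Derived from a realistic spread of serum fold regulations
    (|effect| roughly 0.4-7.2 log2 units, both directions, several
    miRNAs rising from the prediabetic to the diabetic group).
    """
    return {
        mirna: {"IFG": fr_to_log2(fr_ifg), "T2D": fr_to_log2(fr_t2d)}
        for mirna, (fr_ifg, fr_t2d) in _DEFAULT_EFFECT_FRS.items()
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Defaults reproduce the study conditions this generator emulates:
    three groups of 10 serum samples each profiled on a 372-target panel,
    with roughly 3 highly and 35 moderately expressed targets in the
    reference group, 0.5-cycle per-sample global offsets, 0.25-cycle
    technical noise, detection at Ct 35 and hard censoring at Ct 40.
    """

    panel: PanelDefinition | None = None
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "IFG": 10, "T2D": 10}
    )
    reference_group: str = "control"
    n_high_targets: int = 3
    n_moderate_targets: int = 35
    baseline_high: tuple[float, float] = (22.0, 24.8)
    baseline_moderate: tuple[float, float] = (25.3, 29.5)
    baseline_low: tuple[float, float] = (30.2, 39.0)
    baseline_controls: tuple[float, float] = (24.0, 28.0)
    baseline_spike: tuple[float, float] = (20.0, 22.0)
    #: Ct(miR-23a-3p) is pinned this far above Ct(miR-451a) in clean serum.
    hemolysis_baseline_delta: float = 2.0
    effects: dict[str, dict[str, float]] = field(default_factory=default_effect_table)
    offset_sd: float = 0.5
    noise_sd: float = 0.25
    detection_ct: float = 35.0
    censor_ct: float = 40.0
    hemolysis_samples: tuple[str, ...] = ()
    hemolysis_shift: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = load_panel()
        if not self.group_sizes:
            raise ValueError("at least one group is required")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.reference_group not in self.group_sizes:
            raise ValueError(f"reference group {self.reference_group!r} not simulated")
        for sd, what in ((self.offset_sd, "offset_sd"), (self.noise_sd, "noise_sd")):
            if sd < 0:
                raise ValueError(f"{what} must be >= 0")
        if self.hemolysis_shift < 0:
            raise ValueError("hemolysis_shift must be >= 0")
        if self.censor_ct < self.detection_ct:
            raise ValueError("hard censor must not be below the detection cut-off")
        n_targets = len(self.panel.targets)
        if self.n_high_targets + self.n_moderate_targets > n_targets:
            raise ValueError("tier design exceeds the number of panel targets")
        unknown = [m for m in self.effects if m not in set(self.panel.targets)]
        if unknown:
            raise ValueError(f"effects planted on assays outside the panel: {unknown}")
        for mirna, per_group in self.effects.items():
            bad = [g for g in per_group if g not in self.group_sizes]
            if bad:
                raise ValueError(f"effect for {mirna} names unknown groups: {bad}")
            if any(not math.isfinite(e) for e in per_group.values()):
                raise ValueError(f"non-finite effect for {mirna}")

    def sample_names(self) -> dict[str, list[str]]:
        return {
            g: [f"{g}_{i + 1:02d}" for i in range(n)]
            for g, n in self.group_sizes.items()
        }


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    config: SimulationConfig
    baselines: pd.Series  # noiseless reference-group Ct per assay
    effects: pd.DataFrame  # assays x groups, log2; reference column is 0
    offsets: pd.Series  # per-sample global Ct offset

    def planted_fr(self, test: str, ref: str) -> pd.Series:
        """Naive expected fold regulation from the effects alone.

        This is what a normalization whose reference carries no group
        effect (spike-in, or effect-free reference genes) recovers.
        """
        delta = self.effects[test] - self.effects[ref]
        return delta.map(log2_to_fr).rename(f"{test}_vs_{ref}")

    def noiseless_ct(self, group: str) -> pd.Series:
        """Pooled-profile Ct for one group absent offsets and noise."""
        return self.baselines - self.effects[group]

    def detected(self, group: str) -> pd.Series:
        ct = self.noiseless_ct(group)
        return ct.notna() & (ct <= self.config.detection_ct)

    def expected_fr(self, test: str, ref: str, method: str = "global_mean") -> pd.Series:
        """Analytic expected fold regulation per target for one contrast.

        For ``global_mean`` the expectation includes the shift the planted
        effects impose on the detected-set mean of each pooled profile;
        for ``reference_genes`` and ``spike_in`` (whose reference assays
        carry no planted effect) it reduces to the naive closed form.
        Only targets detected in both pooled profiles appear.
        """
        ct_t, ct_r = self.noiseless_ct(test), self.noiseless_ct(ref)
        det_t, det_r = self.detected(test), self.detected(ref)
        if method == "global_mean":
            ref_t = float(ct_t[det_t].mean())
            ref_r = float(ct_r[det_r].mean())
        elif method in ("reference_genes", "spike_in"):
            assays = (
                list(self.config.panel.endogenous_controls)
                if method == "reference_genes"
                else [self.config.panel.spike_in]
            )
            ref_t = float(ct_t[assays].mean())
            ref_r = float(ct_r[assays].mean())
        else:
            raise ValueError(f"unknown method {method!r}")
        targets = [
            a for a in self.config.panel.targets if det_t[a] and det_r[a]
        ]
        ddct = (ct_t[targets] - ref_t) - (ct_r[targets] - ref_r)
        return ddct.map(lambda d: log2_to_fr(-d)).rename(f"{test}_vs_{ref}")


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CtMatrix, SimulationTruth]:
    """Draw one synthetic cohort.

    Ct(m, s) = baseline(m) - effect_group(s)(m) + offset(s) + noise(m, s),
    hard-censored to undetermined above ``config.censor_ct``. The RNG is a
    single stream seeded from ``seed`` (or ``config.seed``) with fixed
    draw order: baselines, then offsets, then noise — so outputs are
    reproducible across runs and releases.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = config.panel
    targets = list(panel.targets)

    # tier assignment: planted assays go to the moderate band first so
    # effects of several log2 units cannot push them out of detection
    planted = [m for m in targets if m in config.effects]
    pair = list(panel.hemolysis_pair)
    moderate = list(
        dict.fromkeys(planted + pair)
    )[: config.n_moderate_targets]
    rest = [m for m in targets if m not in set(moderate)]
    high = rest[: config.n_high_targets]
    n_more_moderate = config.n_moderate_targets - len(moderate)
    moderate += rest[config.n_high_targets: config.n_high_targets + n_more_moderate]
    low = [m for m in targets if m not in set(moderate) | set(high)]

    # draw 1: baselines
    baselines = pd.Series(index=panel.all_assays, dtype=float)
    for names, (lo, hi) in (
        (high, config.baseline_high),
        (moderate, config.baseline_moderate),
        (low, config.baseline_low),
        (list(panel.endogenous_controls), config.baseline_controls),
        ([panel.spike_in], config.baseline_spike),
    ):
        baselines[names] = rng.uniform(lo, hi, size=len(names))
    # pin the hemolysis indicator pair to a clean-serum separation
    num, den = panel.hemolysis_pair
    baselines[num] = baselines[den] + config.hemolysis_baseline_delta

    groups = config.sample_names()
    samples = [s for g in groups.values() for s in g]
    group_of = pd.Series(
        {s: g for g, names in groups.items() for s in names}, name="group"
    )

    # draw 2: per-sample global offsets
    offsets = pd.Series(
        rng.normal(0.0, config.offset_sd, size=len(samples)), index=samples
    )

    effects = pd.DataFrame(
        0.0, index=baselines.index, columns=list(config.group_sizes)
    )
    for mirna, per_group in config.effects.items():
        for g, e in per_group.items():
            effects.at[mirna, g] = e

    # draw 3: technical noise, one draw per (assay, sample) cell
    noise = rng.normal(
        0.0, config.noise_sd, size=(len(baselines), len(samples))
    )
    ct = (
        baselines.to_numpy()[:, None]
        - effects[group_of[samples].to_numpy()].to_numpy()
        + offsets.to_numpy()[None, :]
        + noise
    )
    values = pd.DataFrame(ct, index=baselines.index, columns=samples)

    for s in config.hemolysis_samples:
        if s not in values.columns:
            raise ValueError(f"hemolysis sample {s!r} not in the cohort")
        values[s] = inject_hemolysis(
            values[s], config.hemolysis_shift, mirna=den
        )

    values = values.where(values <= config.censor_ct)
    values = values.clip(lower=0.0)

    matrix = CtMatrix(values=values, groups=group_of)
    truth = SimulationTruth(
        config=config, baselines=baselines, effects=effects, offsets=offsets
    )
    return matrix, truth


def inject_hemolysis(
    profile: pd.Series, shift: float, mirna: str = "hsa-miR-451a"
) -> pd.Series:
    """Contaminate one profile with erythrocyte lysate: the red-cell
    miRNA's Ct drops by ``shift`` cycles; everything else is unchanged."""
    if shift < 0:
        raise ValueError("hemolysis shift must be >= 0")
    if mirna not in profile.index:
        raise KeyError(f"{mirna!r} absent from profile")
    out = profile.copy()
    out[mirna] = out[mirna] - shift
    return out


def pool_samples(matrix: CtMatrix, group: str) -> pd.Series:
    """Equimolar pooling of one group's samples into a single profile.

    Pooling equal RNA masses averages concentrations, so the pooled Ct is
    computed on the linear scale: pooled Ct(m) = -log2(mean_s 2^(-Ct(m, s)))
    over the samples where m amplified; a miRNA undetermined in every
    sample stays undetermined.
    """
    samples = matrix.group_samples(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    linear = np.exp2(-matrix.values[samples])
    pooled_linear = linear.mean(axis=1, skipna=True)
    with np.errstate(divide="ignore"):
        pooled = -np.log2(pooled_linear)
    return pooled.rename(group)


def pool_groups(matrix: CtMatrix) -> CtMatrix:
    """Pool every group of a cohort; columns become the group names."""
    groups = list(dict.fromkeys(matrix.groups))
    pooled = pd.DataFrame({g: pool_samples(matrix, g) for g in groups})
    return CtMatrix(
        values=pooled, groups=pd.Series(groups, index=groups, name="group")
    )
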