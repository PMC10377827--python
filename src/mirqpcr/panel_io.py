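"""Panel definition and tabular I/O for Ct matrices and comparison tables.

The panel is the assay universe of one qPCR array run: target miRNAs,
endogenous small-RNA controls (SNORDs / RNU6B), one exogenous spike-in
(cel-miR-39) and the hemolysis indicator pair miR-23a-3p / miR-451a.
Raw Ct data arrive as CSV in either long layout (sample, group, assay, ct)
or wide layout (assays as rows, samples as columns); undetermined
amplifications are carried as NaN throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sentinel for a reaction that never crossed the detection threshold.
UNDETERMINED = math.nan

#: Input tokens recognised as an undetermined Ct.
UNDETERMINED_TOKENS = {"undetermined", "na", "nan", ""}

#: Instrument Ct range; values outside are parse errors, not data.
CT_MIN, CT_MAX_VALID = 0.0, 45.0

CLASS_LABELS = ("up", "down", "unchanged", "not_evaluable")


class PanelError(ValueError):
    """Invalid panel composition."""


class CtTableError(ValueError):
    """Malformed Ct or comparison table."""


def _parse_signed_float(token: str) -> float:
    """Parse a number accepting both ASCII hyphen and Unicode minus."""
    return float(str(token).replace("−", "-").strip())


@dataclass(frozen=True)
class PanelDefinition:
    """The assay universe of one array layout.

    targets, endogenous_controls and the spike-in are pairwise disjoint;
    the hemolysis pair must be two distinct target assays.
    """

    targets: tuple[str, ...]
    endogenous_controls: tuple[str, ...]
    spike_in: str
    hemolysis_pair: tuple[str, str]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        controls = tuple(self.endogenous_controls)
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "endogenous_controls", controls)
        object.__setattr__(self, "hemolysis_pair", tuple(self.hemolysis_pair))
        if not targets:
            raise PanelError("panel must define at least one target assay")
        for ids, what in ((targets, "targets"), (controls, "endogenous_controls")):
            if any(not i or not str(i).strip() for i in ids):
                raise PanelError(f"empty assay ID in {what}")
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise PanelError(f"duplicate assay IDs in {what}: {dup}")
        if not self.spike_in or not self.spike_in.strip():
            raise PanelError("spike-in assay ID is empty")
        t, c, s = set(targets), set(controls), {self.spike_in}
        for a, b, la, lb in (
            (t, c, "targets", "controls"),
            (t, s, "targets", "spike-in"),
            (c, s, "controls", "spike-in"),
        ):
            overlap = a & b
            if overlap:
                raise PanelError(f"{la} and {lb} overlap: {sorted(overlap)}")
        if len(self.hemolysis_pair) != 2 or self.hemolysis_pair[0] == self.hemolysis_pair[1]:
            raise PanelError("hemolysis pair must name two distinct assays")
        missing = [a for a in self.hemolysis_pair if a not in t]
        if missing:
            raise PanelError(f"hemolysis pair assays not among targets: {missing}")

    @property
    def all_assays(self) -> tuple[str, ...]:
        """Targets, then controls, then spike-in, in panel order."""
        return self.targets + self.endogenous_controls + (self.spike_in,)

    def __contains__(self, assay: str) -> bool:
        return assay in set(self.all_assays)


@dataclass
class CtMatrix:
    """Raw Ct values, assays (rows) by samples (columns).

    ``values`` holds finite Cts in [0, 45] or NaN (undetermined);
    ``groups`` maps each sample to its study group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise CtTableError(f"samples without a group label: {missing}")
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and (finite.min() < CT_MIN or finite.max() > CT_MAX_VALID):
            raise CtTableError(
                f"Ct values outside [{CT_MIN:g}, {CT_MAX_VALID:g}] present"
            )

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_profile(self, sample: str) -> pd.Series:
        """One sample's Ct values indexed by assay."""
        return self.values[sample]

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.groups.copy())


@dataclass(frozen=True)
class ComparisonRecord:
    """Per-miRNA result of one two-group contrast.

    fold_change = 2^(-ddct); fold_regulation equals fold_change when
    fold_change >= 1 and -1/fold_change otherwise, so down-regulation is
    reported as a negative magnitude with |FR| >= 1.
    """

    mirna: str
    ddct: float
    fold_change: float
    fold_regulation: float
    label: str = "unchanged"

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "not_evaluable":
            if not (self.fold_change > 0):
                raise ValueError("fold change must be positive")
            if abs(self.fold_regulation) < 1 - 1e-12:
                raise ValueError("|fold regulation| must be >= 1")


@dataclass
class ComparisonFixture:
    """Fold-regulation values transcribed from a printed comparison table."""

    contrast: str
    fold_regulation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mirna, fr in self.fold_regulation.items():
            if not math.isfinite(fr):
                raise CtTableError(f"non-finite fold regulation for {mirna}")
            if abs(fr) < 1:
                raise CtTableError(
                    f"fold regulation {fr} for {mirna} violates |FR| >= 1"
                )

    def __len__(self) -> int:
        return len(self.fold_regulation)


# ---------------------------------------------------------------------------
# panel loading

def _packaged(relpath: str):
    return resources.files("mirqpcr").joinpath("data", *relpath.split("/"))


def load_panel(path: str | Path | None = None) -> PanelDefinition:
    """Load a panel definition from YAML/JSON; ``None`` loads the packaged
    372-target serum/plasma default."""
    if path is None:
        text = _packaged("panels/serum_plasma_384.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
    panel = PanelDefinition(
        targets=tuple(raw["targets"]),
        endogenous_controls=tuple(raw.get("endogenous_controls", ())),
        spike_in=raw["spike_in"],
        hemolysis_pair=tuple(raw["hemolysis_pair"]),
        name=raw.get("name", "unnamed"),
    )
    logger.info(
        "panel %s: %d targets, %d controls, spike-in %s",
        panel.name, len(panel.targets), len(panel.endogenous_controls), panel.spike_in,
    )
    return panel


# ---------------------------------------------------------------------------
# Ct tables

def _coerce_ct(token, where: str) -> float:
    if isinstance(token, float) and math.isnan(token):
        return UNDETERMINED
    s = str(token).strip()
    if s.lower() in UNDETERMINED_TOKENS:
        return UNDETERMINED
    try:
        ct = _parse_signed_float(s)
    except ValueError:
        raise CtTableError(f"non-numeric Ct {token!r} at {where}") from None
    if not (CT_MIN <= ct <= CT_MAX_VALID):
        raise CtTableError(f"Ct {ct} outside [{CT_MIN:g}, {CT_MAX_VALID:g}] at {where}")
    return ct


def read_ct_table(
    path: str | Path,
    layout: str = "long",
    panel: PanelDefinition | None = None,
    strict: bool = True,
    default_group: str = "other",
) -> CtMatrix:
    """Read a raw Ct CSV in long or wide layout into a :class:`CtMatrix`.

    Long layout needs columns ``sample, group, assay, ct``; wide layout has
    assays as the first column and samples as remaining columns, with group
    labels either in a second header row ``group`` or supplied as
    ``default_group``. Assays absent from ``panel`` raise (strict) or are
    dropped with a warning.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if layout == "long":
        required = {"sample", "group", "assay", "ct"}
        if not required.issubset(raw.columns):
            raise CtTableError(f"long layout requires columns {sorted(required)}")
        dup = raw.duplicated(subset=["assay", "sample"], keep=False)
        if dup.any():
            first = raw.loc[dup, ["assay", "sample"]].iloc[0]
            raise CtTableError(
                f"duplicate (assay, sample) key ({first['assay']}, {first['sample']})"
            )
        cts = [
            _coerce_ct(r.ct, f"({r.assay}, {r.sample})") for r in raw.itertuples()
        ]
        frame = raw.assign(ct=cts).pivot(index="assay", columns="sample", values="ct")
        # preserve file order of assays and samples
        frame = frame.reindex(
            index=raw["assay"].drop_duplicates(), columns=raw["sample"].drop_duplicates()
        )
        groups = (
            raw.drop_duplicates("sample").set_index("sample")["group"].reindex(frame.columns)
        )
        conflicting = raw.groupby("sample")["group"].nunique()
        if (conflicting > 1).any():
            bad = list(conflicting.index[conflicting > 1])
            raise CtTableError(f"conflicting group labels for samples: {bad}")
    else:
        assay_col = raw.columns[0]
        if raw[assay_col].duplicated().any():
            dup_ids = sorted(raw.loc[raw[assay_col].duplicated(), assay_col])
            raise CtTableError(f"duplicate assay rows: {dup_ids}")
        frame = raw.set_index(assay_col)
        if "group" in frame.index:
            groups = frame.loc["group"].astype(str)
            frame = frame.drop(index="group")
        else:
            groups = pd.Series(default_group, index=frame.columns)
        frame = frame.apply(
            lambda col: [
                _coerce_ct(v, f"({a}, {col.name})") for a, v in col.items()
            ],
        )
        groups = groups.reindex(frame.columns)
    frame.index.name = "assay"
    frame.columns.name = "sample"
    if panel is not None:
        known = set(panel.all_assays)
        unknown = [a for a in frame.index if a not in known]
        if unknown:
            if strict:
                raise CtTableError(f"assays not in panel: {unknown}")
            logger.warning("dropping %d assays not in panel: %s", len(unknown), unknown)
            frame = frame.drop(index=unknown)
    return CtMatrix(values=frame, groups=groups.rename("group"))


def write_ct_table(matrix: CtMatrix, path: str | Path, layout: str = "long") -> None:
    """Write a CtMatrix back to CSV (long or wide layout)."""
    path = Path(path)
    if layout == "long":
        rows = []
        for sample in matrix.samples:
            group = matrix.groups[sample]
            for assay in matrix.assays:
                ct = matrix.values.at[assay, sample]
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "assay": assay,
                        "ct": "Undetermined" if math.isnan(ct) else f"{ct:.4f}",
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)
    elif layout == "wide":
        out = matrix.values.copy()
        header = pd.DataFrame(
            [matrix.groups.values], index=pd.Index(["group"], name="assay"),
            columns=out.columns,
        )
        pd.concat([header, out]).to_csv(path)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


# ---------------------------------------------------------------------------
# comparison tables

def read_comparison_fixture(path: str | Path, contrast: str | None = None) -> ComparisonFixture:
    """Read a two-column TSV (mature_id, fold_regulation).

    Values may use the Unicode minus sign. Rows violating the sign
    convention (|FR| < 1) or duplicating an ID raise :class:`CtTableError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"mature_id", "fold_regulation"}
    if not required.issubset(frame.columns):
        raise CtTableError(f"comparison fixture requires columns {sorted(required)}")
    if frame["mature_id"].duplicated().any():
        dup = sorted(frame.loc[frame["mature_id"].duplicated(), "mature_id"])
        raise CtTableError(f"duplicate mature IDs: {dup}")
    values = {
        str(r.mature_id): _parse_signed_float(r.fold_regulation)
        for r in frame.itertuples()
    }
    return ComparisonFixture(contrast=contrast or path.stem, fold_regulation=values)


def packaged_fixture(contrast: str) -> ComparisonFixture:
    """Load one of the packaged printed-table fixtures.

    ``contrast`` is one of ``ifg_vs_control``, ``t2d_vs_control``,
    ``t2d_vs_ifg``.
    """
    res = _packaged(f"fixtures/{contrast}.tsv")
    with resources.as_file(res) as p:
        return read_comparison_fixture(p, contrast=contrast)


def write_comparison_table(
    records: Sequence[ComparisonRecord], path: str | Path
) -> None:
    """Write one contrast's records as TSV, sorted by descending fold
    regulation (ties broken by mature ID); round-trips through
    :func:`read_comparison_fixture` at 2-decimal precision."""
    evaluable = [r for r in records if r.label != "not_evaluable"]
    ordered = sorted(evaluable, key=lambda r: (-r.fold_regulation, r.mirna))
    frame = pd.DataFrame(
        {
            "mature_id": [r.mirna for r in ordered],
            "fold_regulation": [f"{r.fold_regulation:.2f}" for r in ordered],
            "fold_change": [f"{r.fold_change:.4f}" for r in ordered],
            "ddct": [f"{r.ddct:.4f}" for r in ordered],
            "label": [r.label for r in ordered],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
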