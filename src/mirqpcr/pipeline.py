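"""End-to-end orchestration: QC -> normalize -> compare -> signatures -> report.

A single configuration mapping drives the whole run. Input is either a raw
Ct CSV, a simulated cohort (the default demo), or — in fixture mode —
printed per-contrast fold-regulation tables, which bypass normalization
entirely and feed the signature rules directly. All outputs are plain TSV
and JSON under a run directory; figure data (the log-log scatter of
linearized expression) is exported as a table rather than rendered.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import (
    ComparisonRecord,
    ConcordanceReport,
    Contrast,
    SignatureSet,
    classify_fr,
    compare_profiles,
    condition_specific_set,
    count_labels,
    high_stringency_set,
    normalization_concordance,
    progression_signature,
    records_from_fixture,
)
from .normalize import NormalizedProfile, normalize_profile
from .panel_io import (
    CtMatrix,
    PanelDefinition,
    load_panel,
    packaged_fixture,
    read_comparison_fixture,
    read_ct_table,
    write_comparison_table,
)
from .qc import DETECTION_CT_MAX, HEMOLYSIS_THRESHOLD, qc_matrix
from .simulate import SimulationConfig, pool_groups, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (
    {"test": "IFG", "reference": "control"},
    {"test": "T2D", "reference": "control"},
    {"test": "T2D", "reference": "IFG"},
)


@dataclass(frozen=True)
class ScatterPoint:
    """One miRNA on the log-log expression scatter of a contrast:
    x = 2^(-dCt) in the reference group, y = the same in the test group."""

    mirna: str
    x: float
    y: float
    label: str

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0):
            raise ValueError("linearized expression must be positive")


def scatter_data(
    test: NormalizedProfile,
    ref: NormalizedProfile,
    threshold: float = 2.0,
    panel: PanelDefinition | None = None,
) -> list[ScatterPoint]:
    """Scatter points for one contrast; labels agree with the contrast
    classification at the same threshold."""
    records = compare_profiles(test, ref, panel=panel, threshold=threshold)
    x, y = ref.linear(), test.linear()
    points = []
    for r in records:
        if r.label == "not_evaluable":
            continue
        points.append(
            ScatterPoint(
                mirna=r.mirna,
                x=float(x[r.mirna]),
                y=float(y[r.mirna]),
                label=r.label,
            )
        )
    return points


@dataclass
class RunBundle:
    """Everything one pipeline run produced, ready to serialise."""

    manifest: dict
    qc: pd.DataFrame | None
    profiles: dict[str, dict[str, NormalizedProfile]]  # method -> group -> profile
    contrasts: dict[str, list[ComparisonRecord]]  # primary-method results
    contrasts_by_method: dict[str, dict[str, list[ComparisonRecord]]]
    signatures: dict[str, SignatureSet]
    concordance: dict[str, list[ConcordanceReport]]
    scatter: dict[str, list[ScatterPoint]]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        if self.qc is not None:
            self.qc.to_csv(outdir / "qc_report.tsv", sep="\t")
        for method, by_group in self.profiles.items():
            frame = pd.DataFrame(
                {g: p.dct for g, p in by_group.items()}
            ).sort_index()
            frame.index.name = "assay"
            frame.to_csv(outdir / f"dct_{method}.tsv", sep="\t")
        for name, records in self.contrasts.items():
            write_comparison_table(records, outdir / f"contrast_{name}.tsv")
        sig_json = {
            name: {"rule": s.rule, "selected": s.selected, "evidence": s.evidence}
            for name, s in self.signatures.items()
        }
        (outdir / "signatures.json").write_text(
            json.dumps(sig_json, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )
        conc_json = {
            name: [dataclasses.asdict(r) for r in reports]
            for name, reports in self.concordance.items()
        }
        (outdir / "concordance.json").write_text(
            json.dumps(conc_json, indent=2, sort_keys=True) + "\n"
        )
        for name, points in self.scatter.items():
            pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
                outdir / f"scatter_{name}.tsv", sep="\t", index=False
            )
        return outdir


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_contrast_list(config: Mapping) -> list[Contrast]:
    raw = config.get("contrasts", list(DEFAULT_CONTRASTS))
    return [Contrast(test=c["test"], reference=c["reference"]) for c in raw]


def run_pipeline(
    config: Mapping[str, Any] | None = None, outdir: str | Path | None = None
) -> RunBundle:
    """Run the full analysis described by ``config``.

    With no config a demo run is performed: a simulated three-group
    cohort (seeded), pooled per group and analysed at the conventional
    thresholds. Supplying ``input.ct_csv`` analyses measured data;
    ``input.fixtures`` switches to fixture mode where printed
    fold-regulation tables feed the signature rules directly. Identical
    config (and seed) reproduces the bundle bit-for-bit.
    """
    config = dict(config or {})
    thresholds = {
        "significant": 2.0, "stringent": 10.0,
        **config.get("thresholds", {}),
    }
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": _jsonable_config(config),
        "stages": {},
    }
    input_cfg = dict(config.get("input", {"simulate": {}}))
    if "fixtures" in input_cfg:
        bundle = _run_fixture_mode(config, input_cfg, thresholds, manifest)
    else:
        bundle = _run_ct_mode(config, input_cfg, thresholds, manifest)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _jsonable_config(config: Mapping) -> dict:
    def conv(obj):
        if isinstance(obj, Mapping):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return repr(obj)

    return conv(config)


def _run_ct_mode(config, input_cfg, thresholds, manifest) -> RunBundle:
    panel = load_panel(config.get("panel"))
    seed = int(config.get("seed", 0))
    if "ct_csv" in input_cfg:
        path = Path(input_cfg["ct_csv"])
        matrix = read_ct_table(
            path,
            layout=input_cfg.get("layout", "long"),
            panel=panel,
            strict=bool(input_cfg.get("strict", True)),
        )
        manifest["input"] = {"ct_csv": str(path), "sha256": _hash_file(path)}
    else:
        sim_overrides = dict(input_cfg.get("simulate", {}))
        sim_overrides.setdefault("seed", seed)
        sim_config = SimulationConfig(panel=panel, **sim_overrides)
        matrix, _truth = simulate_cohort(sim_config)
        manifest["input"] = {"simulate": _jsonable_config(sim_overrides)}
    manifest["seed"] = seed

    qc_cfg = dict(config.get("qc", {}))
    ct_max = float(qc_cfg.get("ct_max", DETECTION_CT_MAX))
    qc_report = qc_matrix(
        matrix,
        panel,
        hemolysis_threshold=float(
            qc_cfg.get("hemolysis_threshold", HEMOLYSIS_THRESHOLD)
        ),
        ct_max=ct_max,
        strict=bool(qc_cfg.get("strict", False)),
    )
    manifest["stages"]["qc"] = {
        "n_samples": int(len(qc_report)),
        "n_hemolysis_fail": int((~qc_report["hemolysis_pass"]).sum()),
    }

    # pool individual samples into one profile per group (no-op when the
    # input already holds one column per group)
    pooled = (
        pool_groups(matrix)
        if any(len(matrix.group_samples(g)) > 1 for g in set(matrix.groups))
        else matrix
    )
    norm_cfg = dict(config.get("normalization", {}))
    methods = list(norm_cfg.get("methods", ["global_mean", "reference_genes"]))
    primary = norm_cfg.get("primary", methods[0])
    profiles: dict[str, dict[str, NormalizedProfile]] = {}
    for method in methods:
        profiles[method] = {
            g: normalize_profile(
                pooled.sample_profile(g), panel, method=method, ct_max=ct_max, name=g
            )
            for g in pooled.samples
        }
    manifest["stages"]["normalize"] = {
        "methods": methods,
        "primary": primary,
        "groups": list(pooled.samples),
    }

    contrast_list = _build_contrast_list(config)
    by_method: dict[str, dict[str, list[ComparisonRecord]]] = {}
    for method in methods:
        by_method[method] = {}
        for c in contrast_list:
            records = compare_profiles(
                profiles[method][c.test],
                profiles[method][c.reference],
                panel=panel,
                threshold=thresholds["significant"],
            )
            by_method[method][c.name] = records
    contrasts = by_method[primary]
    manifest["stages"]["compare"] = {
        name: count_labels(records) for name, records in contrasts.items()
    }

    signatures = _signatures_from_contrasts(
        config, contrasts, contrast_list, thresholds
    )
    manifest["stages"]["signatures"] = {
        name: len(s) for name, s in signatures.items()
    }

    concordance = {}
    if len(methods) > 1:
        for c in contrast_list:
            concordance[c.name] = normalization_concordance(
                {m: by_method[m][c.name] for m in methods}
            )

    scatter = {
        c.name: scatter_data(
            profiles[primary][c.test],
            profiles[primary][c.reference],
            threshold=thresholds["significant"],
            panel=panel,
        )
        for c in contrast_list
    }

    return RunBundle(
        manifest=manifest,
        qc=qc_report,
        profiles=profiles,
        contrasts=contrasts,
        contrasts_by_method=by_method,
        signatures=signatures,
        concordance=concordance,
        scatter=scatter,
    )


def _run_fixture_mode(config, input_cfg, thresholds, manifest) -> RunBundle:
    """Signature analysis straight from printed comparison tables."""
    fixtures_cfg: Mapping[str, str] = input_cfg["fixtures"]
    contrasts: dict[str, list[ComparisonRecord]] = {}
    manifest["input"] = {"fixtures": {}}
    for name, source in fixtures_cfg.items():
        if source == "packaged":
            fixture = packaged_fixture(name)
            manifest["input"]["fixtures"][name] = "packaged"
        else:
            fixture = read_comparison_fixture(source, contrast=name)
            manifest["input"]["fixtures"][name] = {
                "path": str(source), "sha256": _hash_file(Path(source))
            }
        contrasts[name] = records_from_fixture(
            fixture, threshold=thresholds["significant"]
        )
    supplements = {}
    for name, source in input_cfg.get("supplements", {}).items():
        fixture = (
            read_comparison_fixture(source, contrast=name)
            if source != "packaged"
            else packaged_fixture(f"{name}_subthreshold")
        )
        supplements[name] = records_from_fixture(
            fixture, threshold=thresholds["significant"]
        )
    manifest["stages"]["compare"] = {
        name: count_labels(records) for name, records in contrasts.items()
    }
    contrast_list = [
        Contrast(*name.split("_vs_")) for name in contrasts if "_vs_" in name
    ]
    signatures = _signatures_from_contrasts(
        config, contrasts, contrast_list, thresholds, supplements=supplements
    )
    manifest["stages"]["signatures"] = {
        name: len(s) for name, s in signatures.items()
    }
    return RunBundle(
        manifest=manifest,
        qc=None,
        profiles={},
        contrasts=contrasts,
        contrasts_by_method={"fixture": contrasts},
        signatures=signatures,
        concordance={},
        scatter={},
    )


def _signatures_from_contrasts(
    config, contrasts, contrast_list, thresholds, supplements=None
) -> dict[str, SignatureSet]:
    """Apply the three signature rules to whatever contrasts are present."""
    sig_cfg = dict(config.get("signatures", {}))
    reference = sig_cfg.get("reference_group", "control")
    # contrast names may come from fixture file stems; match case-insensitively
    lookup = {name.lower(): name for name in contrasts}

    def find(test: str, ref: str) -> str | None:
        return lookup.get(f"{test}_vs_{ref}".lower())

    signatures: dict[str, SignatureSet] = {}
    vs_ctrl = {
        name: contrasts[name]
        for name in contrasts
        if name.lower().endswith(f"_vs_{reference.lower()}")
    }
    if vs_ctrl:
        signatures["high_stringency"] = high_stringency_set(
            vs_ctrl, threshold=thresholds["stringent"]
        )
    order = sig_cfg.get("progression_order", ["IFG", "T2D"])
    prog_names = [find(g, reference) for g in order]
    if all(n is not None for n in prog_names):
        signatures["progression"] = progression_signature(
            contrasts[prog_names[0]],
            contrasts[prog_names[1]],
            min_fr=thresholds["significant"],
        )
        focal = sig_cfg.get("condition_specific_focal", order[-1])
        other = sig_cfg.get("condition_specific_other", order[0])
        focal_name, other_name = find(focal, reference), find(other, reference)
        other_records = list(contrasts[other_name])
        if supplements and other_name in supplements:
            known = {r.mirna for r in other_records}
            other_records += [
                r for r in supplements[other_name] if r.mirna not in known
            ]
        signatures["condition_specific"] = condition_specific_set(
            contrasts[focal_name],
            other_records,
            threshold=thresholds["significant"],
        )
    return signatures
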