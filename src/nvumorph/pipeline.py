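"""End-to-end orchestration: config validation, batch analysis, report.

A run consumes either a list of segmented stacks (TIFF/HDF5 + role map,
each tagged with a group label) or a phantom-cohort specification, then
measures BM thickness and NVU feature frequencies per capillary,
compares every metric between the two groups, and writes a JSON report
plus per-capillary and per-event CSV tables.  All randomness derives
from a single seed recorded in every artifact; rerunning a config with
the same seed reproduces the metrics tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import DetectorParams, summarize_capillary
from .io import LabelVolume, RoleMap, read_label_stack
from .phantom import (
    DetachmentSpec,
    EffectMultipliers,
    PegSpec,
    PhantomSpec,
    PhantomSpecError,
    TubuleSpec,
    make_cohort,
)
from .stats import ComparisonResult, compare_metric_table
from .thickness import stack_thickness

logger = logging.getLogger("nvumorph")


class ConfigError(ValueError):
    """Raised with the complete list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations))


_TOP_KEYS = {"seed", "output_dir", "log_level", "cohort", "inputs", "detector", "stats"}
_COHORT_KEYS = {"n_per_group", "groups", "template", "bm_base_sd_nm"}
_STATS_KEYS = {"test"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    seed: int = 0
    output_dir: Path = Path("nvumorph_out")
    log_level: str = "INFO"
    detector: DetectorParams = DetectorParams()
    test_rule: str = "auto"
    # phantom-cohort mode
    cohort_template: PhantomSpec | None = None
    cohort_groups: dict[str, EffectMultipliers] = field(default_factory=dict)
    n_per_group: int = 9
    bm_base_sd_nm: float = 6.0
    # real-stack mode: (stack path, role map path, group label)
    inputs: tuple[tuple[Path, Path, str], ...] = ()
    raw: dict = field(default_factory=dict)


def _spec_from_dict(doc: Mapping[str, Any]) -> PhantomSpec:
    doc = dict(doc)
    feature_parsers = {
        "pegs": PegSpec,
        "detachments": DetachmentSpec,
        "tubules": TubuleSpec,
    }
    kwargs: dict[str, Any] = {}
    for key, value in doc.items():
        if key in feature_parsers:
            kwargs[key] = tuple(feature_parsers[key](**f) for f in value)
        elif key in ("shape_yx", "voxel_size_nm"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PhantomSpec(**kwargs)


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a YAML/JSON config document (or mapping).

    Collects *all* violations before failing, so one round of fixes
    suffices.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.is_file():
            raise ConfigError([f"config file not found: {path}"])
        doc = yaml.safe_load(path.read_text())
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ConfigError(["config document must be a mapping"])

    violations: list[str] = []
    for key in doc:
        if key not in _TOP_KEYS:
            violations.append(f"unknown key {key!r}")

    seed = doc.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        violations.append("seed must be a non-negative integer")

    det_doc = doc.get("detector", {}) or {}
    detector = DetectorParams()
    known_det = {f.name for f in dataclasses.fields(DetectorParams)}
    bad = [k for k in det_doc if k not in known_det]
    if bad:
        violations.extend(f"unknown detector key {k!r}" for k in bad)
    else:
        try:
            detector = DetectorParams(**det_doc)
        except ValueError as exc:
            violations.append(str(exc))
    for k in ("min_gap_width_nm", "lucent_gap_threshold_nm", "max_gap_search_nm"):
        if k in det_doc and not (isinstance(det_doc[k], (int, float)) and det_doc[k] > 0):
            violations.append(f"{k} must be > 0")

    stats_doc = doc.get("stats", {}) or {}
    for key in stats_doc:
        if key not in _STATS_KEYS:
            violations.append(f"unknown stats key {key!r}")
    test_rule = stats_doc.get("test", "auto")
    if test_rule not in ("auto", "student_t", "mann_whitney"):
        violations.append(f"stats.test must be auto|student_t|mann_whitney, got {test_rule!r}")

    cohort_template = None
    cohort_groups: dict[str, EffectMultipliers] = {}
    n_per_group = 9
    bm_sd = 6.0
    inputs: list[tuple[Path, Path, str]] = []

    if "cohort" in doc and "inputs" in doc:
        violations.append("specify either 'cohort' or 'inputs', not both")
    if "cohort" not in doc and "inputs" not in doc:
        violations.append("one of 'cohort' or 'inputs' is required")

    if "cohort" in doc:
        cdoc = doc["cohort"] or {}
        for key in cdoc:
            if key not in _COHORT_KEYS:
                violations.append(f"unknown cohort key {key!r}")
        n_per_group = cdoc.get("n_per_group", 9)
        if not isinstance(n_per_group, int) or n_per_group < 1:
            violations.append("cohort.n_per_group must be a positive integer")
        bm_sd = cdoc.get("bm_base_sd_nm", 6.0)
        if not isinstance(bm_sd, (int, float)) or bm_sd < 0:
            violations.append("cohort.bm_base_sd_nm must be >= 0")
        try:
            cohort_template = _spec_from_dict(cdoc.get("template", {}) or {})
        except (PhantomSpecError, TypeError, ValueError) as exc:
            violations.append(f"cohort.template: {exc}")
        gdoc = cdoc.get("groups", {"control": {}, "treated": {}})
        if not isinstance(gdoc, Mapping) or len(gdoc) != 2:
            violations.append("cohort.groups must map exactly two group labels to effect multipliers")
        else:
            for label, eff in gdoc.items():
                try:
                    cohort_groups[str(label)] = EffectMultipliers(**(eff or {}))
                except (TypeError, ValueError) as exc:
                    violations.append(f"cohort.groups[{label!r}]: {exc}")

    if "inputs" in doc:
        for i, item in enumerate(doc["inputs"] or []):
            missing = [k for k in ("stack", "role_map", "group") if k not in item]
            if missing:
                violations.append(f"inputs[{i}] lacks keys {missing}")
                continue
            stack, rmap = Path(item["stack"]), Path(item["role_map"])
            for p in (stack, rmap):
                if not p.is_file():
                    violations.append(f"inputs[{i}]: file not found: {p}")
            inputs.append((stack, rmap, str(item["group"])))

    if violations:
        raise ConfigError(violations)
    return RunConfig(
        seed=seed,
        output_dir=Path(doc.get("output_dir", "nvumorph_out")),
        log_level=str(doc.get("log_level", "INFO")),
        detector=detector,
        test_rule=test_rule,
        cohort_template=cohort_template,
        cohort_groups=cohort_groups,
        n_per_group=n_per_group,
        bm_base_sd_nm=float(bm_sd),
        inputs=tuple(inputs),
        raw=dict(doc),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

#: Metrics compared between groups (frequencies are per 10 µm).
COMPARED_METRICS = (
    "freq_peg_socket",
    "freq_peg_socket_partially_detached",
    "freq_detachment",
    "freq_detachment_endothelium",
    "freq_detachment_pericyte",
    "freq_tubule",
    "freq_tubule_transendothelial",
    "bm_mean_nm",
    "bm_max_nm",
)


@dataclass(frozen=True)
class AnalysisReport:
    """All artifacts of one pipeline run."""

    seed: int
    version: str
    config_echo: dict
    capillaries: pd.DataFrame
    events: pd.DataFrame
    comparisons: tuple[ComparisonResult, ...]
    warnings: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "config": self.config_echo,
            "n_capillaries": int(len(self.capillaries)),
            "comparisons": [
                {
                    "metric": c.metric,
                    "test": c.test_name,
                    "method": c.method,
                    "statistic": c.statistic,
                    "p_two_tailed": c.p_two_tailed,
                    "stars": c.stars,
                    "groups": {
                        c.group_a: {"mean": c.mean_a, "sem": c.sem_a, "n": c.n_a},
                        c.group_b: {"mean": c.mean_b, "sem": c.sem_b, "n": c.n_b},
                    },
                    "significant_at": {str(k): v for k, v in c.significant_at.items()},
                }
                for c in self.comparisons
            ],
            "warnings": list(self.warnings),
        }


def cohort_metric_table(
    template,
    effects: Mapping[str, "EffectMultipliers"],
    n_per_group: int,
    rng_seed: int,
    bm_base_sd_nm: float = 6.0,
) -> pd.DataFrame:
    """Per-capillary metric table for a simulated two-group cohort,
    computed from the phantoms' analytic ground truth (manifest mode).

    Columns mirror the rasterised pipeline (``freq_*`` per 10 µm,
    ``bm_mean_nm``/``bm_max_nm``) but come from the planted-feature
    manifests and the analytic thickness field, not from rasterised
    stacks — the detector-equals-manifest identity is established
    separately on rasterised phantoms.  This is the fast path for
    large statistical simulations (power and type-I error).
    """
    rows: list[dict] = []
    for gi, (label, effect) in enumerate(sorted(effects.items())):
        members = make_cohort(
            template, n_per_group, effect,
            rng_seed=rng_seed * len(effects) + gi,
            bm_base_sd_nm=bm_base_sd_nm, rasterise=False,
        )
        for i, m in enumerate(members):
            row = {
                "group": label,
                "capillary": f"{label}_{i:02d}",
                "bm_mean_nm": m.ground_truth.analytic_mean_thickness_nm,
                "bm_max_nm": m.ground_truth.analytic_max_thickness_nm,
            }
            for k, v in m.ground_truth.counts.items():
                row[f"count_{k}"] = v
            for k, v in m.ground_truth.expected_frequency_per_10um.items():
                row[f"freq_{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def analyse_capillary(
    volume: LabelVolume,
    role_map: RoleMap,
    detector: DetectorParams,
    group: str,
    capillary_id: str,
) -> tuple[dict, list[dict], list[str]]:
    """Measure one capillary: thickness + features -> (row, event rows, warnings)."""
    warnings: list[str] = []
    profile = stack_thickness(volume, role_map)
    if profile.skipped_z:
        warnings.append(f"{capillary_id}: skipped {len(profile.skipped_z)} empty BM slice(s)")
    metrics = summarize_capillary(volume, role_map, detector)
    n_boundary = sum(e.at_boundary for e in metrics.events)
    if n_boundary:
        warnings.append(f"{capillary_id}: {n_boundary} event(s) touch the stack boundary")
    row = {
        "group": group,
        "capillary": capillary_id,
        "n_slices": volume.n_slices,
        "depth_um": metrics.depth_um,
        "bm_mean_nm": profile.aggregate_mean_nm,
        "bm_max_nm": profile.aggregate_max_nm,
        "n_thickness_samples": profile.n_samples_total,
        "n_skipped_slices": len(profile.skipped_z),
        "n_boundary_events": n_boundary,
    }
    for key, v in metrics.counts.items():
        row[f"count_{key}"] = v
    for key, v in metrics.frequency_per_10um.items():
        row[f"freq_{key}"] = v
    event_rows = [
        {
            "group": group,
            "capillary": capillary_id,
            "feature_type": e.feature_type,
            "z_start": e.z_start,
            "z_end": e.z_end,
            "voxel_count": e.voxel_count,
            "centroid_z": e.centroid[0],
            "centroid_y": e.centroid[1],
            "centroid_x": e.centroid[2],
            "target_role": e.target_role or "",
            "attachment_state": e.attachment_state or "",
            "opening_class": e.opening_class or "",
            "max_gap_nm": e.max_gap_nm,
            "at_boundary": e.at_boundary,
        }
        for e in metrics.events
    ]
    return row, event_rows, warnings


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> AnalysisReport:
    """Execute the full analysis described by a validated config."""
    t0 = time.perf_counter()
    rows: list[dict] = []
    event_rows: list[dict] = []
    warnings: list[str] = []

    stage = "input"
    try:
        capillaries: list[tuple[str, str, LabelVolume, RoleMap]] = []
        if config.cohort_template is not None:
            stage = "phantom-cohort"
            for gi, (label, effect) in enumerate(sorted(config.cohort_groups.items())):
                members = make_cohort(
                    config.cohort_template,
                    config.n_per_group,
                    effect,
                    rng_seed=config.seed * 1000 + gi,
                    bm_base_sd_nm=config.bm_base_sd_nm,
                    rasterise=True,
                )
                for i, m in enumerate(members):
                    capillaries.append((label, f"{label}_{i:02d}", m.volume, m.role_map))
        else:
            for stack, rmap, group in config.inputs:
                stage = f"read {stack}"
                volume, role_map = read_label_stack(stack, rmap)
                capillaries.append((group, stack.stem, volume, role_map))

        for group, cap_id, volume, role_map in capillaries:
            stage = f"analyse {cap_id}"
            logger.info("analysing %s (%d slices)", cap_id, volume.n_slices)
            row, erows, warns = analyse_capillary(
                volume, role_map, config.detector, group, cap_id
            )
            rows.append(row)
            event_rows.extend(erows)
            warnings.extend(warns)

        stage = "statistics"
        table = pd.DataFrame(rows)
        comparisons: list[ComparisonResult] = []
        if table["group"].nunique() == 2:
            for metric in COMPARED_METRICS:
                if metric in table.columns:
                    comparisons.append(
                        compare_metric_table(table, metric, test=config.test_rule)
                    )
        else:
            warnings.append("single group present: no comparisons computed")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    report = AnalysisReport(
        seed=config.seed,
        version=__version__,
        config_echo=config.raw,
        capillaries=pd.DataFrame(rows),
        events=pd.DataFrame(event_rows),
        comparisons=tuple(comparisons),
        warnings=tuple(warnings),
    )
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    if write_outputs:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        report.capillaries.to_csv(out / "capillaries.csv", index=False)
        report.events.to_csv(out / "events.csv", index=False)
        (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2, default=_json_default) + "\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
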