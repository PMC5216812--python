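"""End-to-end orchestration: configuration, cohort and image pipelines, and
the self-contained acceptance suite over the transcribed fixture tables."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import io as vio
from . import survival as surv
from . import vm_imaging as vmi
from .synthetic_data import load_paper_fixtures

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_cohort_pipeline",
    "run_image_pipeline",
    "run_acceptance_suite",
]


@dataclass
class PipelineConfig:
    """Flat configuration shared by the image and cohort stages.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    # image stage
    scales_px: tuple = tuple(vmi.DEFAULT_SCALES_PX)
    threshold_policy: str = "quantile"
    threshold_q: float = 0.05
    min_component_px: int = 30
    dilation_px: int = 2
    # expression stage
    marker_gene_ids: tuple = expr.DEFAULT_MARKERS
    t_all: float = 5.0
    t_two: float = 20.0
    strat_gene: str = "DSG2"
    strat_fraction: float = 0.10
    strat_mode: str = "range"
    de_fdr: float = 0.005
    de_min_fold: float = 2.0
    values_are_cpm: bool = False
    # survival stage
    hr_method: str = "oe"
    # bookkeeping
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.threshold_q < 1:
            raise ValueError("threshold_q must lie in (0, 1)")
        if self.threshold_policy not in {"fixed", "quantile", "otsu"}:
            raise ValueError(f"unknown threshold_policy {self.threshold_policy!r}")
        if self.strat_mode not in {"range", "quantile"}:
            raise ValueError(f"unknown strat_mode {self.strat_mode!r}")
        if self.hr_method not in {"oe", "cox"}:
            raise ValueError(f"unknown hr_method {self.hr_method!r}")
        if self.dilation_px < 0 or self.min_component_px < 0:
            raise ValueError("dilation_px and min_component_px must be >= 0")
        if not 0 < self.strat_fraction < 0.5:
            raise ValueError("strat_fraction must lie in (0, 0.5)")
        if not 0 < self.de_fdr < 1 or self.de_min_fold < 1:
            raise ValueError("de_fdr must lie in (0,1) and de_min_fold be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("scales_px", "marker_gene_ids"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales_px"] = list(d["scales_px"])
        d["marker_gene_ids"] = list(d["marker_gene_ids"])
        return d


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    def summary(self) -> dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
            "wall_clock_s": self.wall_clock_s,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.summary(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_cohort_pipeline(
    counts: expr.CountMatrix,
    clinical: pd.DataFrame,
    config: PipelineConfig,
) -> RunReport:
    """Filter -> stratify -> survival -> differential expression.

    Deterministic given inputs and config; each stage's key numbers land in
    the report, and a stage failure aborts with a stage-named diagnostic.
    """
    t0 = time.perf_counter()
    report = RunReport(config=config.to_dict())

    try:
        cpm = (
            expr.CPMMatrix(list(counts.gene_ids), list(counts.sample_ids), counts.counts)
            if config.values_are_cpm
            else expr.compute_cpm(counts)
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("cpm", e) from e

    try:
        filt = expr.keratinocyte_contamination_filter(
            cpm, config.marker_gene_ids, config.t_all, config.t_two
        )
    except Exception as e:
        raise StageError("contamination_filter", e) from e
    report.stages["contamination_filter"] = {
        "n_input": len(counts.sample_ids),
        "n_kept": len(filt.kept_sample_ids),
        "n_removed": len(filt.removed_sample_ids),
        "removed_sample_ids": filt.removed_sample_ids,
        "rule": filt.rule,
    }

    kept_cpm = cpm.subset_samples(filt.kept_sample_ids)
    kept_counts = counts.subset_samples(filt.kept_sample_ids)

    try:
        strat = expr.stratify_by_expression_range(
            kept_cpm, config.strat_gene, config.strat_fraction, config.strat_mode
        )
    except KeyError as e:
        raise StageError("stratification", e) from e
    except Exception as e:
        raise StageError("stratification", e) from e
    sizes = {
        g: len(strat.samples_in(g)) for g in ("low", "mid", "high")
    }
    report.stages["stratification"] = {
        "gene": config.strat_gene,
        "mode": str(strat.mode.value),
        "fraction": strat.fraction,
        "low_cut": strat.low_cut,
        "high_cut": strat.high_cut,
        "group_sizes": sizes,
    }

    try:
        records = vio.survival_records_from_clinical(clinical, strat.group_of_sample)
        lr = surv.logrank_test(records)
        km = {
            g: surv.km_estimate([r for r in records if r.group == g])
            for g in ("high", "low")
        }
    except Exception as e:
        raise StageError("survival", e) from e
    # logrank groups are sorted labels: a="high", b="low"
    report.stages["survival"] = {
        "n_records": len(records),
        "median_days_high": km["high"].median_days,
        "median_days_low": km["low"].median_days,
        "chi_square": lr.chi_square,
        "p_value": lr.p_value,
        "hazard_ratio_high_vs_low": lr.hazard_ratio_oe,
        "hr_method": config.hr_method,
    }

    try:
        de = expr.nb_exact_de_test(
            kept_counts,
            {s: g for s, g in strat.group_of_sample.items() if g in ("high", "low")},
            fdr=config.de_fdr,
            min_fold=config.de_min_fold,
        )
    except Exception as e:
        raise StageError("differential_expression", e) from e
    report.stages["differential_expression"] = {
        "n_genes": len(de.gene_ids),
        "n_overexpressed": de.n_overexpressed,
        "n_underexpressed": de.n_underexpressed,
        "dispersion": de.dispersion,
        "thresholds": de.thresholds,
    }

    report.wall_clock_s = time.perf_counter() - t0
    return report


def run_image_pipeline(
    images: list,
    config: PipelineConfig,
    labels: list | None = None,
) -> RunReport:
    """Score a batch of two-channel images; compare groups when labelled.

    ``images`` holds :class:`~vmquant.vm_imaging.TwoChannelImage` objects;
    ``labels`` optionally assigns each a group name for the two-sample
    comparison.
    """
    t0 = time.perf_counter()
    if not images:
        raise StageError("vm_score", ValueError("empty image batch"))
    if labels is not None and len(labels) != len(images):
        raise StageError("vm_score", ValueError("labels length != image count"))
    report = RunReport(config=config.to_dict())
    per_image = []
    for i, img in enumerate(images):
        try:
            q = vmi.quantify_vm(
                img,
                scales_px=config.scales_px,
                threshold_policy=config.threshold_policy,
                threshold_value=config.threshold_q,
                min_component_px=config.min_component_px,
                dilation_px=config.dilation_px,
            )
        except Exception as e:
            raise StageError(f"vm_score[{i}]", e) from e
        entry = {
            "index": i,
            "vm_score": q.vm_score,
            "pas_area_fraction": q.pas_area_fraction,
            "category": str(q.category.value),
            "params": q.params,
        }
        if labels is not None:
            entry["group"] = labels[i]
        per_image.append(entry)
    report.stages["vm_score"] = {"n_images": len(per_image), "images": per_image}

    if labels is not None and len(set(labels)) == 2:
        scores = [(e["vm_score"], e["group"]) for e in per_image]
        try:
            mean_a, mean_b, p = vmi.compare_vm_by_group(scores)
        except Exception as e:
            raise StageError("group_comparison", e) from e
        la, lb = sorted(set(labels))
        report.stages["group_comparison"] = {
            "groups": [la, lb],
            "mean": {la: mean_a, lb: mean_b},
            "p_value": p,
            "test": "unpaired two-sided t-test",
        }
    report.wall_clock_s = time.perf_counter() - t0
    return report


def run_acceptance_suite() -> dict:
    """Run the in-study worked examples and report expected vs computed.

    Failures are reported, never raised.
    """
    results = {}
    fixtures = load_paper_fixtures()

    summary = surv.concordance_summary(fixtures.matched_cohort_table)
    results["t1_concordance"] = {
        "expected": 6,
        "computed": summary.n_concordant,
        "n_total": summary.n_total,
        "discordant_patient_ids": summary.discordant_patient_ids,
        "pass": summary.n_concordant == 6
        and sorted(summary.discordant_patient_ids) == [3, 5],
    }

    t = fixtures.stage_contingency
    table = surv.ContingencyTable2x2(
        int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    )
    _, p = surv.fisher_exact_2x2(table)
    results["t2_fisher_stage"] = {
        "expected": 0.294,
        "computed": round(p, 3),
        "p_value": p,
        "pass": round(p, 3) == 0.294,
    }
    results["all_pass"] = all(
        v["pass"] for k, v in results.items() if isinstance(v, dict)
    )
    return results
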