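"""End-to-end cohort analysis: metrics, quality indices, NTCP, statistics.

``run_analysis`` consumes a paired cohort (in memory or via a manifest
path) and produces a report with four sections mirroring a clinical
plan-comparison publication: target-volume summary (median/range),
plan-quality indices (HI, CN), per-organ dose-metric comparisons, and NTCP
comparisons with per-patient differences, difference bins and relative
risk.  The renderer only rounds — every number is produced by the metric,
radiobiology and statistics modules.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort
from .dvh import MetricSpec
from .errors import ValidationError
from .plan_quality import ConformityInputs, conformation_number, homogeneity_index
from .radiobiology import (FractionationScheme, builtin_parameter_registry,
                           ntcp_from_dvh)
from .stats import ComparisonRow, PairedSample, compare_paired_metric, summarize_volumes

__all__ = ["AnalysisConfig", "Report", "run_analysis", "default_metric_panel"]


def default_metric_panel() -> dict[str, list[MetricSpec]]:
    """Per-organ dose-metric panel of a standard upper-GI comparison."""
    pct = lambda d: MetricSpec("volume_at_dose", d, "percent")
    cc = lambda d: MetricSpec("volume_at_dose", d, "cc")
    dcc = lambda v: MetricSpec("dose_at_volume", v, "GyE")
    mean = MetricSpec("mean_dose", 0.0, "GyE")
    return {
        "stomach": [pct(55), cc(50), pct(50), pct(45), pct(40), pct(30),
                    pct(20), pct(10), dcc(0.1)],
        "duodenum": [pct(55), pct(50), pct(40), pct(30), pct(25), pct(20),
                     pct(10), dcc(0.1), dcc(1.0)],
        "small_bowel": [pct(54), pct(50), pct(45), pct(40), pct(30), pct(20),
                        pct(10), dcc(0.1)],
        "stoduo": [pct(55), cc(50), pct(50), pct(40), pct(30), pct(20),
                   pct(10)],
        "kidneys": [mean, pct(23)],
        "liver": [mean, pct(35), pct(30)],
        "spinal_cord": [dcc(0.1)],
    }


def default_ntcp_panel() -> dict[str, list[str]]:
    """Structure -> LKB parameter keys (organ/source) to evaluate."""
    panel: dict[str, list[str]] = {}
    for p in builtin_parameter_registry():
        panel.setdefault(p.organ, []).append(p.key)
    return panel


@dataclass
class AnalysisConfig:
    reference: str = "photon"          # denominator of RR, minuend of deltas
    metric_panel: dict = field(default_factory=default_metric_panel)
    ntcp_panel: dict = field(default_factory=default_ntcp_panel)
    alpha: float = 0.05
    apply_eqd2: bool = True
    alpha_beta: float = 4.0

    def hash(self) -> str:
        blob = json.dumps({
            "reference": self.reference,
            "metric_panel": {k: [(m.kind, m.threshold, m.output_unit)
                                 for m in v]
                             for k, v in self.metric_panel.items()},
            "ntcp_panel": self.ntcp_panel,
            "alpha": self.alpha,
            "apply_eqd2": self.apply_eqd2,
            "alpha_beta": self.alpha_beta,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class Report:
    meta: dict
    volume_summary: dict
    quality_rows: list[ComparisonRow]
    metric_rows: list[tuple[str, ComparisonRow]]   # (organ, row)
    ntcp_rows: list[tuple[str, str, ComparisonRow]]  # (organ, params key, row)
    warnings: list[str]

    # -- rendering ---------------------------------------------------------

    def _row_record(self, row: ComparisonRow, digits: int = 2) -> dict:
        rec = {
            "metric": row.metric,
            f"{row.label_a}_mean": round(row.mean_a, digits),
            f"{row.label_a}_sd": (None if math.isnan(row.sd_a)
                                  else round(row.sd_a, digits)),
            f"{row.label_b}_mean": round(row.mean_b, digits),
            f"{row.label_b}_sd": (None if math.isnan(row.sd_b)
                                  else round(row.sd_b, digits)),
            "p": None if math.isnan(row.p_two_sided) else round(row.p_two_sided, 3),
            "significant": row.significant,
        }
        if row.rr_mean is not None:
            rec["rr_mean"] = round(row.rr_mean, 2)
            rec["rr_sd"] = (None if row.rr_sd is None or math.isnan(row.rr_sd)
                            else round(row.rr_sd, 2))
        if row.delta_bin_counts is not None:
            le5, mid, gt10 = row.delta_bin_counts
            rec["delta_le5"] = le5
            rec["delta_5to10"] = mid
            rec["delta_gt10"] = gt10
        if row.note:
            rec["note"] = row.note
        return rec

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "volume_summary": self.volume_summary,
            "plan_quality": [self._row_record(r, 2) for r in self.quality_rows],
            "dose_metrics": [dict(organ=o, **self._row_record(r))
                             for o, r in self.metric_rows],
            "ntcp": [dict(organ=o, parameters=k, **self._row_record(r))
                     for o, k, r in self.ntcp_rows],
            "full_precision": {
                "ntcp": [
                    {"organ": o, "parameters": k,
                     "mean_a": r.mean_a, "mean_b": r.mean_b,
                     "p": r.p_two_sided,
                     "deltas": [float(x) for x in r.deltas],
                     "rr": None if r.rr is None else [float(x) for x in r.rr]}
                    for o, k, r in self.ntcp_rows
                ],
            },
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dict(organ=o, **self._row_record(r))
                             for o, r in self.metric_rows])

    def ntcp_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dict(organ=o, parameters=k, **self._row_record(r))
                             for o, k, r in self.ntcp_rows])


def _paired_values(cohort: Cohort, reference: str, rival: str, fn) -> PairedSample:
    a = np.array([fn(p.plans[reference]) for p in cohort.patients])
    b = np.array([fn(p.plans[rival]) for p in cohort.patients])
    return PairedSample(reference, rival, a, b)


def run_analysis(cohort: Cohort | str | Path,
                 config: AnalysisConfig | None = None) -> Report:
    """Run the full paired-cohort comparison and return the report.

    A missing structure or plan for any patient is a hard error naming the
    patient; degenerate statistics become per-row notes and the run
    continues.
    """
    if not isinstance(cohort, Cohort):
        from .io import load_cohort
        cohort = load_cohort(cohort)
    config = config or AnalysisConfig()
    cohort.require_paired()
    techs = cohort.techniques
    if config.reference not in techs:
        raise ValidationError(
            f"reference technique {config.reference!r} not in cohort {techs}")
    rival = next(t for t in techs if t != config.reference)
    ref = config.reference
    warnings: list[str] = []

    # target volume summary (volumes are anatomy, identical across arms)
    volume_summary = {}
    first_tech = techs[0]
    for tv in ("GTV", "CTV", "PTV"):
        values = [p.plans[first_tech].target_volumes_cc.get(tv)
                  for p in cohort.patients]
        if any(v is None for v in values):
            continue
        median, (lo, hi) = summarize_volumes(values)
        volume_summary[tv] = {"median_cc": round(median, 1),
                              "range_cc": [round(lo, 1), round(hi, 1)],
                              "n": len(values)}

    # plan quality: HI and CN on the CTV
    quality_rows: list[ComparisonRow] = []

    def _hi(plan):
        return homogeneity_index(plan.dvhs["CTV"])

    def _cn(plan):
        if plan.ctv95_cc is None or plan.v95_body_cc is None:
            raise ValidationError("conformity volumes missing")
        return conformation_number(ConformityInputs(
            plan.target_volumes_cc["CTV"], plan.ctv95_cc, plan.v95_body_cc))

    for label, fn in (("CTV HI", _hi), ("CTV CN", _cn)):
        try:
            sample = _paired_values(cohort, ref, rival, fn)
        except (KeyError, ValidationError) as exc:
            warnings.append(f"{label}: skipped ({exc})")
            continue
        quality_rows.append(compare_paired_metric(sample, metric=label,
                                                  alpha=config.alpha))

    # per-organ dose metrics
    metric_rows: list[tuple[str, ComparisonRow]] = []
    for organ, specs in config.metric_panel.items():
        for patient in cohort.patients:
            for t in (ref, rival):
                if organ not in patient.plans[t].dvhs:
                    raise ValidationError(
                        f"patient {patient.patient_id} has no {organ!r} DVH "
                        f"for technique {t!r}")
        for mspec in specs:
            sample = _paired_values(
                cohort, ref, rival, lambda plan, m=mspec: m.evaluate(plan.dvhs[organ]))
            row = compare_paired_metric(sample, metric=mspec.label(),
                                        alpha=config.alpha)
            if row.note:
                warnings.append(f"{organ} {mspec.label()}: {row.note}")
            metric_rows.append((organ, row))

    # NTCP comparisons
    registry = {p.key: p for p in builtin_parameter_registry()}
    ntcp_rows: list[tuple[str, str, ComparisonRow]] = []
    for organ, keys in config.ntcp_panel.items():
        for key in keys:
            params = registry[key]

            def _ntcp(plan, params=params, organ=organ):
                scheme = FractionationScheme(plan.prescription_gy,
                                             plan.fractions,
                                             config.alpha_beta)
                return 100.0 * ntcp_from_dvh(plan.dvhs[organ], params, scheme,
                                             apply_eqd2=config.apply_eqd2)

            sample = _paired_values(cohort, ref, rival, _ntcp)
            sample = PairedSample(ref, rival, sample.values_a, sample.values_b,
                                  unit="%")
            try:
                row = compare_paired_metric(sample, metric=params.endpoint,
                                            alpha=config.alpha,
                                            include_rr=True, include_bins=True)
            except Exception as exc:  # e.g. zero reference NTCP
                warnings.append(f"{organ} {key}: {exc}")
                row = compare_paired_metric(sample, metric=params.endpoint,
                                            alpha=config.alpha,
                                            include_rr=False,
                                            include_bins=True)
            if row.note:
                warnings.append(f"{organ} {key}: {row.note}")
            ntcp_rows.append((organ, key, row))

    meta = {
        "software": "ntcpkit",
        "version": __version__,
        "config_hash": config.hash(),
        "reference_technique": ref,
        "rival_technique": rival,
        "n_patients": len(cohort.patients),
    }
    meta.update({k: v for k, v in cohort.meta.items()
                 if k in ("seed", "generator")})
    return Report(meta, volume_summary, quality_rows, metric_rows, ntcp_rows,
                  warnings)
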