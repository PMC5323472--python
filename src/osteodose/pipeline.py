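"""End-to-end orchestration: calibration, per-patient dosimetry, cohort study.

Three entry points mirror how the analysis is run in practice:

* :func:`run_calibration` — build the phantom recovery curve and the voxel
  dose kernel, writing both with provenance metadata;
* :func:`run_patient` — quantify a scan series, integrate voxel TACs,
  convolve with the kernel, segment lesions and summarise patient doses;
* :func:`run_cohort_study` — generate (or load) a cohort and run the full
  statistical analysis: activity-cut and median-split survival comparisons,
  multivariable Cox regression, log-volume correlations and biomarker
  response tests.

Every stochastic stage takes its seed from :class:`RunConfig`; outputs
embed the config so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from .dosimetry import (
    PatientDoseSummary,
    cohort_dose_table,
    compute_dose_map,
    summarize_lesions,
    summarize_patient,
)
from .grids import GridSpec
from .kernel import DoseKernel, generate_voxel_kernel
from .kinetics import fit_retention, integrate_tac_map, whole_body_dose
from .nuclide import NuclideData
from .quantify import (
    RecoveryCurve,
    build_recovery_curve,
    calibrate_to_activity,
    chang_attenuation_correct,
    dew_scatter_correct,
    segment_lesions,
)
from .synthetic import (
    CohortModel,
    ImagingModel,
    PharmacokineticModel,
    RetentionSeries,
    ScanSeries,
    generate_cohort,
    generate_phantom_set,
    scan_phantoms,
)

__all__ = ["RunConfig", "PatientInputs", "run_calibration", "run_patient", "run_cohort_study"]

logger = logging.getLogger("osteodose")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Serialisable configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    nuclide: NuclideData = field(default_factory=NuclideData)
    imaging: ImagingModel = field(default_factory=ImagingModel)
    pk: PharmacokineticModel = field(default_factory=PharmacokineticModel)
    cohort: CohortModel = field(default_factory=CohortModel)
    voxel_size_mm: float = 4.67
    kernel_source: str = "generate"  # "generate" or a path prefix to load
    kernel_n_histories: int = 200_000
    kernel_halfwidth_voxels: int | None = None
    recovery_curve_source: str = "build"  # "build" or a CSV path
    min_lesion_volume_ml: float = 0.5
    scan_times_h: tuple[float, ...] = (1.0, 4.0, 24.0, 48.0, 72.0)

    # ---- JSON round trip --------------------------------------------------

    _NESTED = {
        "nuclide": NuclideData,
        "imaging": ImagingModel,
        "pk": PharmacokineticModel,
        "cohort": CohortModel,
    }

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name in self._NESTED:
                sub = dataclasses.asdict(val)
                sub.pop("spectrum", None)  # spectrum tables travel as CSV, not config
                sub.pop("energy_windows", None)
                sub.pop("attenuation_outline", None)
                d[f.name] = sub
            elif isinstance(val, tuple):
                d[f.name] = list(val)
            else:
                d[f.name] = val
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "out_dir" not in d:
            raise ConfigError("missing required config fields: ['out_dir']")
        kwargs = dict(d)
        for name, typ in cls._NESTED.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                sub = dict(kwargs[name])
                if name == "pk":
                    # fast fraction is re-derived from the retention target
                    # unless explicitly pinned
                    sub.setdefault("wholebody_fast_fraction", None)
                try:
                    kwargs[name] = typ(**sub)
                except TypeError as exc:
                    raise ConfigError(f"bad {name} config: {exc}") from exc
        if "scan_times_h" in kwargs:
            kwargs["scan_times_h"] = tuple(kwargs["scan_times_h"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CalibrationArtifacts:
    curve: RecoveryCurve
    kernel: DoseKernel
    threshold_log: pd.DataFrame  # per-phantom volume/threshold entries


def run_calibration(config: RunConfig) -> CalibrationArtifacts:
    """Build (or load) the recovery curve and dose kernel.

    Outputs are written only after every stage has succeeded, so a sizing
    error in the kernel configuration leaves no partial artifacts.
    """
    out = Path(config.out_dir)
    logger.info("calibration: recovery curve source=%s", config.recovery_curve_source)
    if config.recovery_curve_source == "build":
        phantoms = generate_phantom_set(GridSpec(voxel_size_mm=config.voxel_size_mm))
        images = scan_phantoms(phantoms, config.imaging, config.nuclide)
        curve = build_recovery_curve(images, [o.true_volume_ml for o, _ in phantoms])
    else:
        curve = RecoveryCurve.from_csv(config.recovery_curve_source)
    if config.kernel_source == "generate":
        kernel = generate_voxel_kernel(
            config.nuclide,
            voxel_size_mm=config.voxel_size_mm,
            grid_halfwidth_voxels=config.kernel_halfwidth_voxels,
            n_histories=config.kernel_n_histories,
            seed=config.seed,
        )
    else:
        kernel = DoseKernel.load(
            config.kernel_source + ".nii", config.kernel_source + ".json"
        )
    log = pd.DataFrame({"volume_ml": curve.volumes_ml, "threshold": curve.thresholds})
    out.mkdir(parents=True, exist_ok=True)
    curve.to_csv(out / "recovery_curve.csv")
    kernel.save(out / "kernel.nii", out / "kernel.json")
    log.to_csv(out / "calibration_log.csv", index=False)
    config.to_json(out / "run_config.json")
    logger.info("calibration artifacts written to %s", out)
    return CalibrationArtifacts(curve, kernel, log)


@dataclass
class PatientInputs:
    """Everything the per-patient chain needs."""

    patient_id: str
    scans: ScanSeries
    retention: RetentionSeries
    administered_mbq: float
    mass_kg: float


def run_patient(
    config: RunConfig,
    inputs: PatientInputs,
    calibration: CalibrationArtifacts,
) -> PatientDoseSummary:
    """Quantification → kinetics → dosimetry for one patient.

    Missing scan time points (None images) are skipped with a warning; the
    TAC integration proceeds on the remaining points.
    """
    imaging = config.imaging
    activities = []
    times = []
    for i, t in enumerate(inputs.scans.times_h):
        if inputs.scans.peak[i] is None or inputs.scans.sub[i] is None:
            logger.warning("patient %s: scan at %.1f h missing; skipped", inputs.patient_id, t)
            continue
        img = dew_scatter_correct(inputs.scans.peak[i], inputs.scans.sub[i], imaging.energy_windows)
        if imaging.attenuation_outline is not None:
            img = chang_attenuation_correct(
                img, imaging.attenuation_outline, imaging.attenuation_n_angles
            )
        activities.append(
            calibrate_to_activity(img, imaging.sensitivity_cps_per_mbq, imaging.acquisition_time_s)
        )
        times.append(float(t))
    if not activities:
        raise ValueError(f"patient {inputs.patient_id}: no usable scan time points")
    cumulated = integrate_tac_map(activities, times, config.nuclide)
    dose_map = compute_dose_map(cumulated, calibration.kernel)
    masks = segment_lesions(
        dose_map, calibration.curve, min_volume_ml=config.min_lesion_volume_ml
    )
    lesions = summarize_lesions(dose_map, masks)
    fit = fit_retention(inputs.retention)
    wbd = whole_body_dose(fit, inputs.administered_mbq, inputs.mass_kg, config.nuclide)
    summary = summarize_patient(lesions, wbd, inputs.administered_mbq, inputs.patient_id)
    out = Path(config.out_dir) / f"patient_{inputs.patient_id}"
    out.mkdir(parents=True, exist_ok=True)
    dose_map.save(out / "dose_map.nii")
    summary.to_json(out / "summary.json")
    fit.to_json(out / "retention_fit.json")
    logger.info(
        "patient %s: %d lesions, PMAD %.3g Gy, WBD %.3g Gy",
        inputs.patient_id,
        len(lesions),
        summary.patient_mean_absorbed_dose_gy,
        wbd,
    )
    return summary


# ---------------------------------------------------------------------------
# Cohort study
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": {
        "n_patients": int,
        "activity_split": dict,
        "median_splits": dict,
        "cox_multivariable": dict,
        "correlations": dict,
        "response": dict,
        "config": dict,
    }
}


def validate_report(report: dict) -> list[str]:
    """Structural validation against the bundled report schema; returns a
    list of problems (empty when valid)."""
    problems = []
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in report:
            problems.append(f"missing key: {key}")
        elif not isinstance(report[key], typ):
            problems.append(f"key {key}: expected {typ.__name__}, got {type(report[key]).__name__}")
    return problems


def _km_entry(result: cohort_stats.KMGroupResult) -> dict:
    return {
        "groups": list(result.groups),
        "median_os_months": result.median_os,
        "logrank_p": result.logrank_p,
        "hazard_ratio": result.hazard_ratio if result.hr_defined else None,
        "hr_ci95": list(result.hr_ci) if result.hr_defined else None,
    }


def run_cohort_study(
    config: RunConfig, cohort_table: pd.DataFrame | None = None
) -> dict:
    """Full statistical analysis of a (simulated or supplied) cohort.

    The report covers: survival split at the 3.5 GBq administered-activity
    cut-point (skipped with a flag when the cohort was treated at a single
    activity), median splits on PMAD, WBD, disease volume, ALP and PSA,
    multivariable Cox regression of those dose/volume covariates,
    log-volume correlations, and Fisher tests of ≥50 % biomarker decline by
    dose group.
    """
    table = cohort_table if cohort_table is not None else generate_cohort(config.cohort)
    if len(table) < 4:
        raise ValueError(f"cohort of {len(table)} patients is too small to analyse")
    report: dict = {"n_patients": int(len(table)), "config": config.to_dict()}

    # administered-activity split (outcome-oriented cut-point, 3.5 GBq)
    activity_gbq = table["administered_mbq"] / 1000.0
    if activity_gbq.nunique() > 1 and (activity_gbq > 3.5).any() and (activity_gbq <= 3.5).any():
        groups = cohort_stats.dichotomize(
            table.assign(activity_gbq=activity_gbq), "activity_gbq", "fixed_cutpoint", cutpoint=3.5
        )
        report["activity_split"] = _km_entry(
            cohort_stats.km_logrank(table.assign(_g=groups), "_g")
        )
    else:
        report["activity_split"] = {"skipped": "single administered-activity level"}

    report["median_splits"] = {}
    for var in ("pmad_gy", "wbd_gy", "disease_volume_ml", "alp_u_l", "psa_ng_ml"):
        groups = cohort_stats.dichotomize(table, var, "median")
        report["median_splits"][var] = _km_entry(
            cohort_stats.km_logrank(table.assign(_g=groups), "_g")
        )

    table = table.assign(ln_disease_volume=np.log(table["disease_volume_ml"]))
    cox = cohort_stats.cox_multivariable(table, ["ln_disease_volume", "wbd_gy", "pmad_gy"])
    report["cox_multivariable"] = {
        "covariates": cox.covariates,
        "hazard_ratios": cox.hazard_ratios.to_dict(),
        "ci_low": cox.ci_low.to_dict(),
        "ci_high": cox.ci_high.to_dict(),
        "p_values": cox.p_values.to_dict(),
        "n_events": cox.n_events,
        "warnings": cox.warnings_,
    }

    report["correlations"] = {}
    for name, y in (
        ("pmad_vs_ln_volume", table["pmad_gy"]),
        ("wbd_vs_ln_volume", table["wbd_gy"]),
        ("ln_alp_vs_ln_volume", np.log(table["alp_u_l"])),
    ):
        c = cohort_stats.pearson_log(table["disease_volume_ml"], y)
        report["correlations"][name] = {
            "r": c.r,
            "p": c.p_value,
            "ci95": [c.ci_low, c.ci_high],
        }

    report["response"] = {}
    if {"psa_max_decline", "alp_max_decline"} <= set(table.columns):
        dose_groups = cohort_stats.dichotomize(table, "pmad_gy", "median")
        for marker in ("psa", "alp"):
            decline = table[f"{marker}_max_decline"] >= 0.5
            contingency = np.array(
                [
                    [int((decline & (dose_groups == g)).sum()), int((~decline & (dose_groups == g)).sum())]
                    for g in ("below", "above")
                ]
            )
            report["response"][marker] = {
                "table": contingency.tolist(),
                "fisher_p": cohort_stats.fisher_response_test(contingency),
            }
    else:
        report["response"] = {"skipped": "no biomarker response columns"}

    problems = validate_report(report)
    if problems:  # defensive: schema and builder live side by side
        raise RuntimeError(f"report failed schema validation: {problems}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cohort_report.json").write_text(json.dumps(report, indent=2, default=float))
    table.to_csv(out / "cohort_table.csv", index=False)
    logger.info("cohort report written to %s", out / "cohort_report.json")
    return report
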