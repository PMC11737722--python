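"""End-to-end orchestration: simulate -> score -> model -> report.

A single YAML config drives each run; every analysis choice that the
source material leaves open (grid steps, change normalisation, support
requirement, collinearity handling, variance-test variant, multiple-
testing mode) surfaces as a config key so sensitivity analyses are
scriptable.  Identical config + seed yields an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, synth, threshold
from .features import average_sweeps, score_erg

log = logging.getLogger("vethresh")

MODES = ("simulate", "analyze", "full")

#: admissible data ranges for QC (generous around the experimental design)
QC_THETA_RANGE = (0.0, 60.0)
QC_PHI_RANGE = (0.0, 5000.0)


@dataclass
class RunConfig:
    mode: str = "full"
    seed: int = 0
    input: Optional[str] = None
    workbook_map: Optional[dict] = None
    grid: dict = field(default_factory=dict)
    alphas: Sequence[float] = threshold.DEFAULT_ALPHAS
    delta_mode: str = "difference"
    support_min: int = threshold.DEFAULT_SUPPORT_MIN
    bonferroni: bool = False
    collinearity_r: float = threshold.COLLINEARITY_R
    variance_test: str = "f"
    dose_truth: Optional[dict] = None
    waveform_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if any(not (0.0 < a < 1.0) for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        if self.delta_mode not in ("difference", "relative"):
            raise ValueError("delta_mode must be 'difference' or 'relative'")
        if self.mode in ("simulate", "full") and self.dose_truth is None:
            raise ValueError(f"{self.mode} mode requires dose_truth")
        if self.mode == "analyze" and self.input is None:
            raise ValueError("analyze mode requires an input path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def grid_spec(self) -> threshold.GridSpec:
        return threshold.GridSpec(**self.grid)

    def sha256(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        payload["alphas"] = list(self.alphas)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class QCReport:
    records: list
    exclusions: list
    n_input: int

    def summary(self) -> dict:
        return {"n_input": self.n_input, "n_kept": len(self.records),
                "exclusions": self.exclusions}


def validate_inputs(data) -> QCReport:
    """Flag and exclude invalid rows; exclusions are listed, never silent.

    Accepts a dose-response DataFrame (column contract of the dose CSV) or
    a list of records.  Checks: finite dy in at least one outcome, dose
    values within admissible ranges, no duplicate subject/eye/timepoint.
    """
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        df = io.records_to_frame(data)
    records, exclusions = [], []
    seen = set()
    for i, row in enumerate(df.itertuples()):
        reason = None
        theta, phi = float(row.theta_deg), float(row.phi_deg_s)
        dy_a, dy_l = float(row.dy_amplitude), float(row.dy_latency)
        if not (np.isfinite(dy_a) or np.isfinite(dy_l)):
            reason = "no finite dy value"
        elif not np.isfinite(theta) or not np.isfinite(phi):
            reason = "non-finite dose"
        elif not (QC_THETA_RANGE[0] <= theta <= QC_THETA_RANGE[1]):
            reason = f"theta {theta} outside range {QC_THETA_RANGE}"
        elif not (QC_PHI_RANGE[0] <= phi <= QC_PHI_RANGE[1]):
            reason = f"phi {phi} outside range {QC_PHI_RANGE}"
        else:
            key = (row.subject_id, row.eye, row.timepoint)
            if key in seen:
                reason = f"duplicate subject/eye/timepoint {key}"
            seen.add(key)
        if reason is not None:
            exclusions.append({"row": i, "subject_id": str(row.subject_id),
                               "reason": reason})
        else:
            records.append(threshold.DoseResponseRecord(
                subject_id=str(row.subject_id), eye=str(row.eye),
                timepoint=str(row.timepoint), theta=theta, phi=phi,
                dy_amplitude=dy_a, dy_latency=dy_l))
    return QCReport(records=records, exclusions=exclusions, n_input=len(df))


def _dose_truth_from_config(cfg: RunConfig, outcome: str,
                            seed: int) -> Optional[synth.DoseResponseTruth]:
    spec = (cfg.dose_truth or {}).get(outcome)
    if spec is None:
        return None
    design = cfg.dose_truth.get("design", "pilot")
    if design == "pilot":
        design = synth.pilot_design()
    else:
        design = [tuple(map(float, d)) for d in design]
    return synth.DoseResponseTruth(
        theta0=float(spec["theta0"]), phi0=float(spec["phi0"]),
        c1=float(spec["c1"]), c2=float(spec.get("c2", 0.0)),
        sigma=float(spec.get("sigma", 0.0)), design=design, seed=seed)


def _simulate(cfg: RunConfig, outdir: Path, seed: int) -> list:
    amp_truth = _dose_truth_from_config(cfg, "amplitude", seed)
    lat_truth = _dose_truth_from_config(cfg, "latency", seed + 1000003)
    if amp_truth is None:
        raise ValueError("dose_truth must define an 'amplitude' truth")
    timepoint = (cfg.dose_truth or {}).get("timepoint", "D7")
    records = synth.generate_dose_response(amp_truth, lat_truth,
                                           timepoint=timepoint)
    io.write_dose_csv(records, outdir / "dose_response.csv")
    log.info("simulated %d dose-response records -> dose_response.csv",
             len(records))
    if cfg.waveform_truth:
        _simulate_waveforms(cfg, outdir, seed)
    return records


def _simulate_waveforms(cfg: RunConfig, outdir: Path, seed: int) -> None:
    spec = dict(cfg.waveform_truth)
    kinds = spec.pop("kinds", ["erg"])
    truth = synth.WaveformTruth(**spec, seed=seed + 2000003)
    rows = []
    for kind in kinds:
        sweeps = synth.generate_waveform(truth, kind)
        io.write_sweeps_csv(sweeps, outdir / f"sweeps_{kind}.csv")
        io.write_truth_yaml(truth, outdir / f"sweeps_{kind}.truth.yaml")
        if kind == "erg":
            feats = score_erg(average_sweeps(sweeps))
            values = {"a_amp": feats.a_amp, "a_time": feats.a_time,
                      "b_amp": feats.b_amp, "b_time": feats.b_time,
                      "sop": feats.sop, "phnr_amp": feats.phnr_amp,
                      "phnr_time": feats.phnr_time}
            rows += io.feature_rows("sim", "OD", "D0", values, "uV",
                                    feats.flags)
    if rows:
        io.write_features_csv(rows, outdir / "features.csv")
        log.info("scored simulated waveforms -> features.csv")


def _load_records(cfg: RunConfig) -> pd.DataFrame:
    path = Path(cfg.input)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        if not cfg.workbook_map:
            raise ValueError(
                "reading a workbook requires a workbook_map config")
        records = io.read_study_workbook(path, cfg.workbook_map)
        return io.records_to_frame(records)
    return pd.read_csv(path)


def _analyze(cfg: RunConfig, records: list, outdir: Path) -> dict:
    grid = cfg.grid_spec()
    results: dict = {}
    by_tp: dict[str, list] = {}
    for r in records:
        by_tp.setdefault(r.timepoint, []).append(r)
    for tp, recs in sorted(by_tp.items()):
        for outcome in ("amplitude", "latency"):
            y = [getattr(r, f"dy_{outcome}") for r in recs]
            if not any(np.isfinite(v) for v in y):
                continue
            scan = threshold.grid_scan(recs, grid, outcome=outcome,
                                       timepoint=tp,
                                       collinearity_r=cfg.collinearity_r)
            threshold.apply_selections(scan, cfg.alphas, cfg.support_min,
                                       cfg.bonferroni)
            contours = threshold.contour_surface(scan)
            subdir = outdir / f"gridscan_{outcome}_{tp}"
            io.write_gridscan(scan, subdir, contours)
            amin = scan.argmin_p()
            results.setdefault(outcome, {})[tp] = {
                "selections": {str(a): (None if s is None else list(s))
                               for a, s in scan.selections.items()},
                "argmin_p": list(amin),
                "min_p": float(scan.p_surface.min()),
                "n": scan.n,
                "multiple_testing": ("bonferroni" if cfg.bonferroni
                                     else "uncorrected"),
            }
            log.info("grid scan %s/%s: min p = %.3g at %s",
                     outcome, tp, scan.p_surface.min(), amin)
    return results


def run(config: RunConfig, outdir, seed: Optional[int] = None) -> dict:
    """Execute one configured run and write its report under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed

    if config.mode in ("simulate", "full"):
        records = _simulate(config, outdir, seed)
    else:
        records = None

    report: dict = {
        "mode": config.mode,
        "seed": seed,
        "config_sha256": config.sha256(),
        "delta_mode": config.delta_mode,
        "versions": _versions(),
    }

    if config.mode in ("analyze", "full"):
        if config.mode == "analyze":
            frame = _load_records(config)
        else:
            frame = io.records_to_frame(records)
        qc = validate_inputs(frame)
        report["qc"] = qc.summary()
        if not qc.records:
            raise ValueError("no valid records after input validation")
        report["outcomes"] = _analyze(config, qc.records, outdir)

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
    return report


def _versions() -> dict:
    import scipy
    return {"vethresh": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
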