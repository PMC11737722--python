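"""Readers and writers for the package's plain-text interchange formats.

Sweeps travel as long-format CSV (sweep_id, time_ms, voltage) with a YAML
sidecar describing the planted truth; dose-response tables as CSV with the
column contract (subject_id, eye, timepoint, theta_deg, phi_deg_s,
dy_amplitude, dy_latency); scored features as tidy CSV rows.  A reader for
supplementary-style XLSX workbooks (rows = variables, columns = animals)
is provided behind an explicit column-mapping config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .features import SweepSet
from .threshold import DoseResponseRecord, GridScan

DOSE_COLUMNS = ["subject_id", "eye", "timepoint", "theta_deg", "phi_deg_s",
                "dy_amplitude", "dy_latency"]

FEATURE_COLUMNS = ["subject_id", "eye", "timepoint", "feature", "value",
                   "units", "quality_flag"]


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def write_sweeps_csv(s: SweepSet, path) -> None:
    n_sweeps, n_samples = s.sweeps.shape
    df = pd.DataFrame({
        "sweep_id": np.repeat(np.arange(n_sweeps), n_samples),
        "time_ms": np.tile(s.time_ms, n_sweeps),
        "voltage": s.sweeps.ravel(),
    })
    df.to_csv(path, index=False)


def read_sweeps_csv(path, modality: str,
                    sampling_rate: Optional[float] = None) -> SweepSet:
    df = pd.read_csv(path)
    ids = df["sweep_id"].unique()
    first = df[df["sweep_id"] == ids[0]]
    time_ms = first["time_ms"].to_numpy()
    sweeps = np.vstack([
        df.loc[df["sweep_id"] == i, "voltage"].to_numpy() for i in ids])
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(time_ms[1] - time_ms[0])
    return SweepSet(sweeps=sweeps, time_ms=time_ms,
                    sampling_rate=sampling_rate, modality=modality)


def write_truth_yaml(truth, path) -> None:
    d = dataclasses.asdict(truth)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[DoseResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "eye": [r.eye for r in records],
        "timepoint": [r.timepoint for r in records],
        "theta_deg": [r.theta for r in records],
        "phi_deg_s": [r.phi for r in records],
        "dy_amplitude": [r.dy_amplitude for r in records],
        "dy_latency": [r.dy_latency for r in records],
    })


def write_dose_csv(records: Sequence[DoseResponseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.12g")


def read_dose_csv(path) -> list[DoseResponseRecord]:
    df = pd.read_csv(path)
    missing = set(DOSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dose CSV missing columns: {sorted(missing)}")
    return [
        DoseResponseRecord(
            subject_id=str(row.subject_id), eye=str(row.eye),
            timepoint=str(row.timepoint), theta=float(row.theta_deg),
            phi=float(row.phi_deg_s),
            dy_amplitude=float(row.dy_amplitude),
            dy_latency=float(row.dy_latency))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def feature_rows(subject_id: str, eye: str, timepoint: str, features: dict,
                 units: str, flags: Sequence[str] = ()) -> list[dict]:
    flag = ";".join(flags)
    return [{"subject_id": subject_id, "eye": eye, "timepoint": timepoint,
             "feature": name, "value": value, "units": units,
             "quality_flag": flag}
            for name, value in features.items() if value is not None]


def write_features_csv(rows: Sequence[dict], path) -> None:
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# supplementary-style workbook
# ---------------------------------------------------------------------------

def read_study_workbook(path, column_map: dict) -> list[DoseResponseRecord]:
    """Read a variables-by-animals XLSX sheet into dose-response records.

    ``column_map`` must provide::

        sheet: str                     # sheet name
        theta: str                     # row label of rotation amplitude
        phi: str                       # row label of angular velocity
        timepoints:                    # per timepoint, row labels
          D0: {dy_amplitude: str, dy_latency: str}
          D7: {dy_amplitude: str, dy_latency: str}
        eye: str                       # optional, default OD

    Rows denote variables; each column is one animal.  The workbook layout
    is not standardised, hence the explicit mapping.
    """
    for key in ("sheet", "theta", "phi", "timepoints"):
        if key not in column_map:
            raise ValueError(f"column_map missing required key {key!r}")
    df = pd.read_excel(path, sheet_name=column_map["sheet"], index_col=0)
    eye = column_map.get("eye", "OD")

    def row(label: str) -> np.ndarray:
        if label not in df.index:
            raise ValueError(f"row label {label!r} not found in workbook")
        return pd.to_numeric(df.loc[label], errors="coerce").to_numpy(float)

    theta = row(column_map["theta"])
    phi = row(column_map["phi"])
    records: list[DoseResponseRecord] = []
    for tp, rows_ in column_map["timepoints"].items():
        dy_amp = row(rows_["dy_amplitude"]) if "dy_amplitude" in rows_ \
            else np.full(theta.size, np.nan)
        dy_lat = row(rows_["dy_latency"]) if "dy_latency" in rows_ \
            else np.full(theta.size, np.nan)
        for i, col in enumerate(df.columns):
            if not (np.isfinite(dy_amp[i]) or np.isfinite(dy_lat[i])):
                continue
            records.append(DoseResponseRecord(
                subject_id=str(col), eye=eye, timepoint=tp,
                theta=float(theta[i]), phi=float(phi[i]),
                dy_amplitude=float(dy_amp[i]), dy_latency=float(dy_lat[i])))
    return records


# ---------------------------------------------------------------------------
# grid-scan output directory
# ---------------------------------------------------------------------------

def write_gridscan(scan: GridScan, outdir,
                   contours: Optional[dict] = None,
                   plot: bool = True) -> None:
    """Write p_surface.csv, coefficients.csv, selections.json, contours."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tg, pg = scan.theta_grid, scan.phi_grid
    ii, jj = np.meshgrid(np.arange(tg.size), np.arange(pg.size),
                         indexing="ij")
    base = pd.DataFrame({
        "theta0_deg": tg[ii.ravel()],
        "phi0_deg_s": pg[jj.ravel()],
    })
    psurf = base.copy()
    psurf["p_value"] = scan.p_surface.ravel()
    psurf.to_csv(outdir / "p_surface.csv", index=False, float_format="%.12g")
    coef = base.copy()
    coef["c1"] = scan.c1_surface.ravel()
    coef["c2"] = scan.c2_surface.ravel()
    coef["rss"] = scan.rss_surface.ravel()
    coef["identifiable"] = scan.identifiable.ravel()
    coef.to_csv(outdir / "coefficients.csv", index=False, float_format="%.12g")
    sel = {str(a): (None if v is None else {"theta0": v[0], "phi0": v[1]})
           for a, v in scan.selections.items()}
    (outdir / "selections.json").write_text(json.dumps(
        {"outcome": scan.outcome, "timepoint": scan.timepoint,
         "n": scan.n, "selections": sel}, indent=2))
    if contours is not None:
        rows = []
        for level, polys in contours.items():
            for k, poly in enumerate(polys):
                for th, ph in poly:
                    rows.append({"level": level, "path_id": k,
                                 "theta0_deg": th, "phi0_deg_s": ph})
        pd.DataFrame(rows, columns=["level", "path_id", "theta0_deg",
                                    "phi0_deg_s"]).to_csv(
            outdir / "contours.csv", index=False, float_format="%.12g")
        if plot:
            _plot_contours(scan, outdir / "contours.png")


def _plot_contours(scan: GridScan, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    lo, hi = scan.p_surface.min(), scan.p_surface.max()
    levels = [lv for lv in (0.001, 0.01, 0.05) if lo < lv < hi]
    if levels:
        cs = ax.contour(scan.theta_grid, scan.phi_grid, scan.p_surface.T,
                        levels=levels)
        ax.clabel(cs, inline=True, fontsize=8)
    ax.set_xlabel("theta0 (deg)")
    ax.set_ylabel("phi0 (deg/s)")
    ax.set_title(f"constant-probability contours ({scan.outcome}"
                 f"{', ' + scan.timepoint if scan.timepoint else ''})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
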