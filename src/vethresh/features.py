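"""Scoring of averaged visual-electrophysiology traces.

ERG traces are scored for the a-wave (baseline to first negative trough),
b-wave (a-wave trough to highest subsequent peak), oscillatory potentials
(trough-to-peak on a band-pass filtered copy, only wavelets before the
b-wave peak), their sum (SOP), the photopic negative response (baseline to
the trough following the b-wave) and flicker amplitude (mean trough-to-peak
excursion per cycle).  fVEP traces are scored for the N1-P1 complex:
amplitude difference and latency difference between the first prominent
negative trough and the following positive peak, both timed from flash
onset.

All amplitudes are reported as non-negative magnitudes referenced to the
pre-stimulus baseline; all times are milliseconds from flash onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import signal

MODALITIES = ("erg", "fvep", "flicker")

#: pre-stimulus window used to define the baseline (ms before flash onset)
BASELINE_WINDOW_MS = 20.0

#: pass band used to isolate oscillatory potentials (Hz)
OP_BAND_HZ = (75.0, 300.0)

#: multiple of the pre-stimulus residual SD a deflection must exceed
DETECTION_FLOOR_SD = 3.0

#: OP peaks additionally must reach this fraction of the largest filtered
#: peak in the search window, which rejects band-edge leakage of the slow
#: a/b lobes without an absolute voltage cutoff
OP_RELATIVE_FLOOR = 0.2

_TINY = 1e-12

OP_LABELS = ("OP1-2", "OP3", "OP4", "OP5")

FLICKER_FREQ_HZ = 20.0


class FeatureAbsent(Exception):
    """A requested waveform component could not be located."""


class AWave(NamedTuple):
    amp: float
    time: float


class BWave(NamedTuple):
    amp: float
    time: float
    boundary: bool          # peak sits on the window edge (monotone rise)
    from_baseline: bool     # no a-wave; referenced to baseline instead


class PhNR(NamedTuple):
    amp: float
    time: float
    above_baseline: bool    # trough never dipped below baseline


@dataclass
class SweepSet:
    """Repeated-stimulus voltage sweeps on a common uniform time grid.

    ``time_ms`` is relative to flash onset (onset at 0); samples with
    negative times form the pre-stimulus baseline window.
    """

    sweeps: np.ndarray
    time_ms: np.ndarray
    sampling_rate: float
    modality: str

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.sweeps.ndim != 2 or self.sweeps.shape[0] < 1:
            raise ValueError("need at least one sweep")
        if self.sweeps.shape[1] != self.time_ms.size:
            raise ValueError("ragged sweeps: sweep length does not match time axis")
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time axis must be uniformly spaced")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]


@dataclass
class Waveform:
    """A single averaged trace, time-locked to flash onset."""

    time_ms: np.ndarray
    voltage: np.ndarray
    modality: str
    baseline_value: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time_ms.size != self.voltage.size:
            raise ValueError("time and voltage must have equal length")
        dt = np.diff(self.time_ms)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time must be uniformly spaced")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if np.isnan(self.baseline_value):
            self.baseline_value = _baseline(self.time_ms, self.voltage)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / self.dt_ms

    def detection_floor(self) -> float:
        """3x the residual SD in the pre-stimulus baseline window."""
        mask = _baseline_mask(self.time_ms)
        if mask.sum() < 2:
            return _TINY
        sd = float(np.std(self.voltage[mask] - self.baseline_value))
        return max(DETECTION_FLOOR_SD * sd, _TINY)


@dataclass
class ERGFeatureSet:
    a_amp: Optional[float]
    a_time: Optional[float]
    b_amp: Optional[float]
    b_time: Optional[float]
    op_amps: dict
    sop: float
    phnr_amp: Optional[float]
    phnr_time: Optional[float]
    flags: list


@dataclass
class FVEPFeatureSet:
    n1_time: float
    p1_time: float
    amplitude_n1p1: float
    latency_n1p1: float


def _baseline_mask(time_ms: np.ndarray) -> np.ndarray:
    return (time_ms < 0) & (time_ms >= -BASELINE_WINDOW_MS)


def _baseline(time_ms: np.ndarray, voltage: np.ndarray) -> float:
    mask = _baseline_mask(time_ms)
    if not mask.any():
        return float(voltage[0])
    return float(np.mean(voltage[mask]))


def _refine_extremum(time_ms: np.ndarray, voltage: np.ndarray, idx: int,
                     refine: bool = True) -> tuple[float, float]:
    """Parabolic interpolation through the discrete extremum and neighbours."""
    t, v = float(time_ms[idx]), float(voltage[idx])
    if not refine or idx == 0 or idx == voltage.size - 1:
        return t, v
    vm, v0, vp = voltage[idx - 1], voltage[idx], voltage[idx + 1]
    denom = vm - 2.0 * v0 + vp
    if abs(denom) < _TINY:
        return t, v
    delta = 0.5 * (vm - vp) / denom
    if abs(delta) > 1.0:    # not a clean quadratic vertex
        return t, v
    dt = float(time_ms[1] - time_ms[0])
    return t + delta * dt, v0 - 0.25 * (vm - vp) * delta


#: Gaussian smoothing width (ms) used only to localise peak/trough times;
#: the scored components are broad lobes, so mild smoothing suppresses
#: sample-level jitter without moving them.  Amplitudes are always read
#: from the raw trace at the located extremum.
LOCALIZE_SMOOTH_SIGMA_MS = 2.5


def _smooth(v: np.ndarray, dt_ms: float,
            sigma_ms: float = LOCALIZE_SMOOTH_SIGMA_MS) -> np.ndarray:
    half = int(np.ceil(4 * sigma_ms / dt_ms))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * dt_ms) / sigma_ms) ** 2)
    k /= k.sum()
    return np.convolve(np.pad(v, half, mode="edge"), k, mode="valid")


def design_op_filter(sampling_rate: float):
    """Zero-phase band-pass used to isolate oscillatory potentials."""
    nyq = sampling_rate / 2.0
    lo, hi = OP_BAND_HZ
    hi = min(hi, 0.95 * nyq)
    return signal.butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def op_filter_gain(sampling_rate: float, freq_hz: float) -> float:
    """Round-trip (forward+backward) filter gain at ``freq_hz``."""
    sos = design_op_filter(sampling_rate)
    w, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq_hz / sampling_rate])
    return float(np.abs(h[0]) ** 2)


# ---------------------------------------------------------------------------
# sweep-level operations
# ---------------------------------------------------------------------------

def average_sweeps(s: SweepSet) -> Waveform:
    """Pointwise mean of all sweeps; baseline from the pre-stimulus window."""
    v = s.sweeps.mean(axis=0)
    return Waveform(time_ms=s.time_ms.copy(), voltage=v, modality=s.modality)


def subtract_control(sig: Waveform, control: Waveform) -> Waveform:
    """Signal-minus-control difference trace; baseline is recomputed."""
    if sig.modality != control.modality:
        raise ValueError("modalities differ")
    if sig.time_ms.size != control.time_ms.size or not np.allclose(
            sig.time_ms, control.time_ms):
        raise ValueError("mismatched time grids")
    return Waveform(time_ms=sig.time_ms.copy(),
                    voltage=sig.voltage - control.voltage,
                    modality=sig.modality)


# ---------------------------------------------------------------------------
# ERG scoring
# ---------------------------------------------------------------------------

def measure_a_wave(w: Waveform, refine: bool = True) -> Optional[AWave]:
    """First post-onset local minimum below baseline by the detection floor.

    Returns ``None`` when no qualifying trough exists (feature absent).
    """
    if w.modality != "erg":
        raise ValueError("a-wave is defined for ERG traces")
    floor = w.detection_floor()
    post = np.where(w.time_ms >= 0)[0]
    if post.size < 3:
        raise ValueError("no post-onset samples")
    sv = _smooth(w.voltage, w.dt_ms)
    seg = sv[post]
    minima, _ = signal.find_peaks(-seg, prominence=floor)
    qualifying = [m for m in minima if seg[m] < w.baseline_value - floor]
    if not qualifying:
        return None
    idx = post[qualifying[0]]
    t, _ = _refine_extremum(w.time_ms, sv, idx, refine)
    return AWave(amp=w.baseline_value - float(w.voltage[idx]), time=t)


def measure_b_wave(w: Waveform, a: Optional[AWave],
                   refine: bool = True) -> Optional[BWave]:
    """Global maximum after the a-wave trough, referenced to the trough.

    Without an a-wave the search starts at onset and the amplitude is
    referenced to baseline (flagged via ``from_baseline``).
    """
    if w.modality != "erg":
        raise ValueError("b-wave is defined for ERG traces")
    if a is not None:
        start_t, ref = a.time, w.baseline_value - a.amp
        from_baseline = False
    else:
        start_t, ref = 0.0, w.baseline_value
        from_baseline = True
    win = np.where(w.time_ms > start_t)[0]
    if win.size == 0:
        return None
    sv = _smooth(w.voltage, w.dt_ms)
    idx = win[int(np.argmax(sv[win]))]
    boundary = idx == w.voltage.size - 1 or idx == win[0]
    t, _ = _refine_extremum(w.time_ms, sv, idx, refine)
    return BWave(amp=float(w.voltage[idx]) - ref, time=t,
                 boundary=bool(boundary), from_baseline=from_baseline)


def extract_ops(w: Waveform, b_time: float,
                a_time: Optional[float] = None,
                rel_floor: float = OP_RELATIVE_FLOOR) -> list[float]:
    """Trough-to-peak amplitudes of band-passed wavelets before the b-peak.

    The trace is band-pass filtered (zero phase), peaks are picked with a
    prominence floor, and each amplitude is the peak minus the immediately
    preceding trough on the filtered trace.  Peaks at or after ``b_time``
    are discarded; at most four are returned in temporal order.
    """
    if w.modality != "erg":
        raise ValueError("OPs are defined for ERG traces")
    sos = design_op_filter(w.sampling_rate)
    filt = signal.sosfiltfilt(sos, w.voltage - w.baseline_value)

    bmask = _baseline_mask(w.time_ms)
    noise_sd = float(np.std(filt[bmask])) if bmask.sum() >= 2 else 0.0
    floor = max(DETECTION_FLOOR_SD * noise_sd, _TINY)

    lo = 0.0 if a_time is None else a_time + 2.0  # skip a-trough leakage
    window = (w.time_ms > lo) & (w.time_ms < b_time)
    if not window.any():
        return []
    peaks, _ = signal.find_peaks(filt, prominence=floor)
    troughs, _ = signal.find_peaks(-filt, prominence=floor)
    peaks = [p for p in peaks if window[p]]
    if not peaks:
        return []
    candidates: list[float] = []
    for p in peaks:
        prior = [t for t in troughs if t < p]
        ref = filt[prior[-1]] if prior else 0.0
        candidates.append(float(filt[p] - ref))
    max_amp = max(candidates)
    amps = [a for a in candidates if a >= rel_floor * max_amp][:4]
    return amps


def compute_sop(op_amps: Sequence[float]) -> tuple[float, list[str]]:
    """Sum of available labeled OP amplitudes plus any missing labels."""
    amps = list(op_amps)[:4]
    missing = list(OP_LABELS[len(amps):])
    return float(sum(amps)), missing


def measure_phnr(w: Waveform, b_time: float,
                 refine: bool = True) -> Optional[PhNR]:
    """Deepest trough after the b-wave, measured from baseline."""
    if w.modality != "erg":
        raise ValueError("PhNR is defined for ERG traces")
    win = np.where(w.time_ms > b_time)[0]
    if win.size == 0:
        return None
    sv = _smooth(w.voltage, w.dt_ms)
    idx = win[int(np.argmin(sv[win]))]
    t, _ = _refine_extremum(w.time_ms, sv, idx, refine)
    drop = w.baseline_value - float(w.voltage[idx])
    return PhNR(amp=max(drop, 0.0), time=t, above_baseline=bool(drop < 0))


def measure_flicker(w: Waveform, freq_hz: float = FLICKER_FREQ_HZ) -> float:
    """Mean trough-to-following-peak excursion across complete cycles."""
    if w.modality != "flicker":
        raise ValueError("flicker amplitude is defined for flicker traces")
    post = w.time_ms >= 0
    duration_s = (w.time_ms[post][-1] - w.time_ms[post][0]) / 1000.0
    if duration_s < 1.0 / freq_hz:
        raise ValueError("need at least one full stimulus cycle")
    v = w.voltage
    floor = w.detection_floor()
    peaks, _ = signal.find_peaks(v, prominence=floor)
    troughs, _ = signal.find_peaks(-v, prominence=floor)
    peaks = [p for p in peaks if post[p]]
    troughs = [t for t in troughs if post[t]]
    excursions = []
    for t in troughs:
        nxt = [p for p in peaks if p > t]
        if nxt:
            excursions.append(v[nxt[0]] - v[t])
    if not excursions:
        return 0.0
    # keep only excursions of the dominant oscillation; residual noise
    # wiggles that survive the prominence floor would dilute the mean
    emax = max(excursions)
    kept = [e for e in excursions if e >= 0.5 * emax]
    return float(np.mean(kept))


def score_erg(w: Waveform) -> ERGFeatureSet:
    """Full ERG feature extraction with quality flags."""
    flags: list[str] = []
    a = measure_a_wave(w)
    if a is None:
        flags.append("a_wave_absent")
    b = measure_b_wave(w, a)
    if b is None:
        flags.append("b_wave_absent")
    else:
        if b.boundary:
            flags.append("b_wave_boundary_peak")
        if b.from_baseline:
            flags.append("b_wave_from_baseline")
    op_amps: dict = {}
    sop = 0.0
    phnr = None
    if b is not None:
        amps = extract_ops(w, b.time, a_time=None if a is None else a.time)
        sop, missing = compute_sop(amps)
        op_amps = dict(zip(OP_LABELS, amps))
        if not amps:
            flags.append("sop_low_confidence")
        elif missing:
            flags.append("op_missing:" + ",".join(missing))
        phnr = measure_phnr(w, b.time)
        if phnr is not None and phnr.above_baseline:
            flags.append("phnr_above_baseline")
    return ERGFeatureSet(
        a_amp=None if a is None else a.amp,
        a_time=None if a is None else a.time,
        b_amp=None if b is None else b.amp,
        b_time=None if b is None else b.time,
        op_amps=op_amps, sop=sop,
        phnr_amp=None if phnr is None else phnr.amp,
        phnr_time=None if phnr is None else phnr.time,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# fVEP scoring
# ---------------------------------------------------------------------------

def measure_fvep(w: Waveform, refine: bool = True) -> FVEPFeatureSet:
    """N1 (first prominent negative trough) to P1 (next positive peak).

    Extrema are localised on a lightly smoothed copy of the trace (the
    raw voltage at the located extrema defines the amplitudes).  Raises
    :class:`FeatureAbsent` when either component is missing.
    """
    if w.modality != "fvep":
        raise ValueError("N1-P1 metrics are defined for fVEP traces")
    floor = w.detection_floor()
    post = set(np.where(w.time_ms >= 0)[0])
    v = w.voltage
    sv = _smooth(v, w.dt_ms)
    troughs, _ = signal.find_peaks(-sv, prominence=floor)
    troughs = [t for t in troughs if t in post
               and sv[t] < w.baseline_value - floor]
    if not troughs:
        raise FeatureAbsent("no qualifying N1 trough")
    n1_idx = troughs[0]
    peaks, _ = signal.find_peaks(sv, prominence=floor)
    peaks = [p for p in peaks
             if p > n1_idx and sv[p] > w.baseline_value + floor]
    if not peaks:
        raise FeatureAbsent("no qualifying P1 peak after N1")
    p1_idx = peaks[0]
    n1_t, _ = _refine_extremum(w.time_ms, sv, n1_idx, refine)
    p1_t, _ = _refine_extremum(w.time_ms, sv, p1_idx, refine)
    return FVEPFeatureSet(
        n1_time=n1_t, p1_time=p1_t,
        amplitude_n1p1=float(v[p1_idx] - v[n1_idx]),
        latency_n1p1=p1_t - n1_t,
    )


def normalize_change(pre_value: float, post_value: float,
                     mode: str = "difference") -> float:
    """Change relative to the baseline (pre-injury) reading.

    ``difference`` returns post - pre in native units; ``relative`` returns
    (post - pre)/|pre| and requires a non-zero baseline.
    """
    if not np.isfinite(pre_value):
        raise ValueError("pre_value must be finite")
    if mode == "difference":
        return float(post_value - pre_value)
    if mode == "relative":
        if pre_value == 0:
            raise ValueError("relative mode requires non-zero baseline")
        return float((post_value - pre_value) / abs(pre_value))
    raise ValueError(f"unknown mode {mode!r}")
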