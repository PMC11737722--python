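"""Synthetic sweep sets and dose-response tables with known ground truth.

Waveforms are built from phenomenological templates (Gaussian lobes for the
a-wave, b-wave, PhNR, N1 and P1; a Gabor wavelet train for the oscillatory
potentials) so that every scoring rule downstream has a known answer.  The
dose-response generator draws observations around the piecewise-linear
two-threshold mean with Gaussian residual noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import SweepSet, design_op_filter, op_filter_gain
from .threshold import DoseResponseRecord, eq1_mean

#: default sampling rate (Hz); resolves 100-150 Hz OPs comfortably
DEFAULT_SAMPLING_RATE = 2000.0

#: pre-stimulus window included in every sweep (ms)
PRE_STIM_MS = 50.0

#: post-onset sweep durations (ms)
SWEEP_POST_MS = {"erg": 250.0, "fvep": 450.0, "flicker": 450.0}

FLICKER_FREQ_HZ = 20.0

#: template lobe widths (ms); narrow enough that lobes do not interact at
#: the default component times
A_SIGMA_MS = 6.0
B_SIGMA_MS = 9.0
PHNR_SIGMA_MS = 8.0
N1_SIGMA_MS = 8.0
P1_SIGMA_MS = 12.0
OP_SIGMA_MS = 2.5


@dataclass
class WaveformTruth:
    """Planted component structure of one synthetic recording.

    ERG amplitudes are in microvolts, fVEP amplitudes in millivolts; all
    times are milliseconds from flash onset.  ``a_amp`` and ``phnr_amp``
    are magnitudes of negative deflections.
    """

    a_amp: float = 120.0
    a_time: float = 18.0
    b_amp: float = 240.0
    b_time: float = 55.0
    op_amps: Sequence[float] = (12.0, 8.0, 6.0, 4.0)
    op_freq: float = 120.0
    phnr_amp: float = 35.0
    phnr_time: float = 110.0
    n1_amp: float = 0.04
    p1_amp: float = 0.06
    n1_time: float = 35.0
    p1_time: float = 75.0
    noise_sd: float = 0.0
    n_sweeps: int = 1
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a_time < self.b_time < self.phnr_time):
            raise ValueError(
                "violated invariant: a_time < b_time < phnr_time")
        if not self.n1_time < self.p1_time:
            raise ValueError("violated invariant: n1_time < p1_time")
        if self.n_sweeps < 1:
            raise ValueError("violated invariant: n_sweeps >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("violated invariant: sampling_rate > 0")
        if self.noise_sd < 0:
            raise ValueError("violated invariant: noise_sd >= 0")
        for name in ("a_amp", "b_amp", "phnr_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"violated invariant: {name} >= 0")
        if len(self.op_amps) > 5 or any(a < 0 for a in self.op_amps):
            raise ValueError(
                "violated invariant: op_amps are >= 0 with at most 5 entries")
        if self.op_freq <= 0:
            raise ValueError("violated invariant: op_freq > 0")


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _time_axis(kind: str, sampling_rate: float) -> np.ndarray:
    dt = 1000.0 / sampling_rate
    n_pre = int(round(PRE_STIM_MS / dt))
    n_post = int(round(SWEEP_POST_MS[kind] / dt))
    return (np.arange(-n_pre, n_post + 1)) * dt


def _op_train_times(truth: WaveformTruth) -> list[float]:
    """OP wavelet centres: one period apart starting after the a-trough."""
    period = 1000.0 / truth.op_freq
    return [truth.a_time + (i + 1) * period for i in range(len(truth.op_amps))]


def _op_train(truth: WaveformTruth, t: np.ndarray,
              background: Optional[np.ndarray] = None) -> np.ndarray:
    """Gabor wavelet train whose band-passed trough-to-peak amplitudes
    equal the planted values.

    Wavelet amplitudes are calibrated empirically: each unit wavelet is
    passed through the scoring filter, the peak and immediately-preceding
    trough sample of the superposed response (including the band-pass
    residue of the slow lobes, ``background``) are located, and the
    linear system mapping planted peak heights to measured trough-to-peak
    excursions is solved.  This absorbs filter gain, envelope reshaping,
    lobe leakage and the shared troughs of adjacent wavelets.
    """
    from scipy import signal as _sig

    times = _op_train_times(truth)
    m = len(times)
    half = 1000.0 / (2.0 * truth.op_freq)
    k = math.exp(-0.5 * (half / OP_SIGMA_MS) ** 2)
    gain = op_filter_gain(truth.sampling_rate, truth.op_freq)
    sos = design_op_filter(truth.sampling_rate)

    units = []
    for t0 in times:
        g = _gauss(t, t0, OP_SIGMA_MS) * np.cos(
            2 * np.pi * truth.op_freq * (t - t0) / 1000.0)
        units.append((g, _sig.sosfiltfilt(sos, g)))
    base = np.zeros_like(t) if background is None \
        else _sig.sosfiltfilt(sos, background)

    target = np.asarray(truth.op_amps, dtype=float)
    amps = np.maximum(target / ((1.0 + k) * gain), 0.0)  # analytic guess
    for _ in range(2):
        combined = base + sum(a * u for a, (_, u) in zip(amps, units))
        pk_idx, tr_idx = [], []
        for t0 in times:
            win = (t >= t0 - half / 2) & (t <= t0 + half / 2)
            iw = np.flatnonzero(win)
            pk = iw[np.argmax(combined[iw])]
            twin = (t >= t0 - 1.5 * half) & (t < t[pk])
            it = np.flatnonzero(twin)
            tr = pk if it.size == 0 else it[np.argmin(combined[it])]
            pk_idx.append(pk)
            tr_idx.append(tr)
        M = np.array([[u[pk_idx[i]] - u[tr_idx[i]] for _, u in units]
                      for i in range(m)])
        offset = np.array([base[pk_idx[i]] - base[tr_idx[i]]
                           for i in range(m)])
        try:
            sol = np.linalg.solve(M, target - offset)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(sol)):
            break
        amps = np.clip(sol, 0.0, None)
    return sum(a * g for a, (g, _) in zip(amps, units))


def waveform_template(truth: WaveformTruth, kind: str,
                      time_ms: Optional[np.ndarray] = None) -> np.ndarray:
    """Deterministic noise-free component sum for one sweep."""
    if kind not in SWEEP_POST_MS:
        raise ValueError(f"kind must be one of {tuple(SWEEP_POST_MS)}")
    t = _time_axis(kind, truth.sampling_rate) if time_ms is None else time_ms
    v = np.zeros_like(t)
    if kind == "erg":
        v -= truth.a_amp * _gauss(t, truth.a_time, A_SIGMA_MS)
        v += truth.b_amp * _gauss(t, truth.b_time, B_SIGMA_MS)
        v -= truth.phnr_amp * _gauss(t, truth.phnr_time, PHNR_SIGMA_MS)
        if truth.op_amps:
            v += _op_train(truth, t, background=v.copy())
    elif kind == "fvep":
        v -= truth.n1_amp * _gauss(t, truth.n1_time, N1_SIGMA_MS)
        v += truth.p1_amp * _gauss(t, truth.p1_time, P1_SIGMA_MS)
    else:  # flicker: steady-state response, trough-to-peak == b_amp
        v += np.where(t >= 0,
                      0.5 * truth.b_amp *
                      np.sin(2 * np.pi * FLICKER_FREQ_HZ * t / 1000.0),
                      0.0)
    return v


def generate_waveform(truth: WaveformTruth, kind: str = "erg") -> SweepSet:
    """Seeded sweeps: noise-free template plus i.i.d. Gaussian noise."""
    t = _time_axis(kind, truth.sampling_rate)
    template = waveform_template(truth, kind, t)
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.noise_sd, size=(truth.n_sweeps, t.size)) \
        if truth.noise_sd > 0 else np.zeros((truth.n_sweeps, t.size))
    return SweepSet(sweeps=template[None, :] + noise, time_ms=t,
                    sampling_rate=truth.sampling_rate, modality=kind)


def generate_control_sweeps(truth: WaveformTruth,
                            kind: str = "erg") -> SweepSet:
    """Noise-only sweeps matching the signal sweeps' grid and modality.

    Mirrors the flashless control recording: all component amplitudes are
    forced to zero, leaving the same number of equally long noisy sweeps.
    """
    t = _time_axis(kind, truth.sampling_rate)
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.noise_sd, size=(truth.n_sweeps, t.size)) \
        if truth.noise_sd > 0 else np.zeros((truth.n_sweeps, t.size))
    return SweepSet(sweeps=noise, time_ms=t,
                    sampling_rate=truth.sampling_rate, modality=kind)


# ---------------------------------------------------------------------------
# dose-response generation
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseTruth:
    """Planted two-threshold piecewise-linear truth for one outcome."""

    theta0: float
    phi0: float
    c1: float
    c2: float = 0.0
    sigma: float = 0.0
    design: Sequence[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta0 < 0 or self.phi0 < 0:
            raise ValueError("violated invariant: thresholds >= 0")
        if self.sigma < 0:
            raise ValueError("violated invariant: sigma >= 0")
        if len(self.design) == 0:
            raise ValueError("violated invariant: design non-empty")
        for th, ph in self.design:
            if th < 0 or ph < 0:
                raise ValueError("violated invariant: design doses >= 0")


def generate_dose_response(truth: DoseResponseTruth,
                           latency_truth: Optional[DoseResponseTruth] = None,
                           timepoint: str = "D7",
                           eye: str = "OD") -> list[DoseResponseRecord]:
    """One record per design point: piecewise-linear mean + Gaussian noise.

    ``truth`` fills ``dy_amplitude``; an optional second truth sharing the
    same design fills ``dy_latency`` (NaN otherwise).
    """
    rng = np.random.default_rng(truth.seed)
    theta = np.array([d[0] for d in truth.design], dtype=float)
    phi = np.array([d[1] for d in truth.design], dtype=float)
    dy_amp = eq1_mean(theta, phi, theta0=truth.theta0, phi0=truth.phi0,
                      c1=truth.c1, c2=truth.c2)
    dy_amp = dy_amp + rng.normal(0.0, truth.sigma, size=theta.size) \
        if truth.sigma > 0 else dy_amp
    if latency_truth is not None:
        if list(latency_truth.design) != list(truth.design):
            raise ValueError("latency truth must share the design")
        rng_l = np.random.default_rng(latency_truth.seed)
        dy_lat = eq1_mean(theta, phi, theta0=latency_truth.theta0,
                          phi0=latency_truth.phi0, c1=latency_truth.c1,
                          c2=latency_truth.c2)
        if latency_truth.sigma > 0:
            dy_lat = dy_lat + rng_l.normal(0.0, latency_truth.sigma,
                                           size=theta.size)
    else:
        dy_lat = np.full(theta.size, np.nan)
    return [
        DoseResponseRecord(subject_id=f"s{i + 1:02d}", theta=float(theta[i]),
                           phi=float(phi[i]),
                           dy_amplitude=float(np.asarray(dy_amp)[i]),
                           dy_latency=float(dy_lat[i]),
                           timepoint=timepoint, eye=eye)
        for i in range(theta.size)
    ]


#: velocity/amplitude coupling of the rotation apparatus (deg/s per deg),
#: chosen so the top of the design reaches 47 deg at ~3320 deg/s
PHI_PER_THETA = 3320.0 / 47.0


def pilot_design() -> list[tuple[float, float]]:
    """Documented reconstruction of the 27-animal pilot dose design.

    Cohorts: 3 negative controls (no rotation), 3 positive controls at
    saccade level (10 deg, 500 deg/s), then low (n=4), medium (n=8) and
    high (n=9) groups spanning up to 47 deg with velocity proportional to
    amplitude.  Exact per-animal doses were not published and the stated
    cohort sizes sum to one more than the stated 27 animals; the high
    group is reduced by one here so the total is 27.  Group placements
    are evenly spaced within plausible sub-ranges.
    """
    design: list[tuple[float, float]] = [(0.0, 0.0)] * 3
    design += [(10.0, 500.0)] * 3
    low = np.linspace(12.0, 18.0, 4)
    med = np.linspace(20.0, 32.0, 8)
    high = np.linspace(34.0, 47.0, 9)
    for th in np.concatenate([low, med, high]):
        design.append((float(th), float(PHI_PER_THETA * th)))
    return design


def sigma_for_target_p(design: Sequence[tuple[float, float]],
                       theta0: float, c1: float,
                       p_target: float) -> float:
    """Residual SD giving an expected single-hinge F-test p near ``p_target``.

    Uses E[F] ~ 1 + c1^2 * Sxx / sigma^2 for the regression-through-origin
    hinge fit with the q=1, n-1 reference distribution.
    """
    from scipy.stats import f as f_dist
    theta = np.array([d[0] for d in design], dtype=float)
    x = np.clip(theta - theta0, 0.0, None)
    sxx = float(np.sum(x ** 2))
    n = theta.size
    f_star = float(f_dist.isf(p_target, 1, n - 1))
    if f_star <= 1:
        raise ValueError("p_target too large for calibration")
    return math.sqrt(c1 ** 2 * sxx / (f_star - 1.0))
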