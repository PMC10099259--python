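"""Synthetic paired load-cell / force-plate walking trials.

This module generates biomechanically plausible single-stance walking
trials: three uniaxial plantar load-cell channels (heel, 1st metatarsal,
5th metatarsal) sampled at the load-cell acquisition rate, and the paired
three-axis ground reaction force (vertical, anterior-posterior,
medial-lateral) sampled at the force-plate rate. Every trial carries a
ground-truth sidecar (heel-strike, toe-off, mid-stance AP zero crossing,
per-axis peaks) so downstream event detection and estimation can be
scored against known values.

The waveform templates are parametric stand-ins for real gait:

* vertical GRF -- the classic M-shape (loading-response and push-off
  maxima around 1.1-1.2 body weight with a mid-stance valley),
* AP GRF -- braking (negative) then propulsion (positive) with a single
  zero crossing at a subject-specific fraction of stance,
* ML GRF -- a small positive hump whose amplitude is coupled to the
  subject's 1st/5th-metatarsal gain ratio,
* load cells -- Gaussian pressure bumps progressing heel -> 5th
  metatarsal -> 1st metatarsal, with a configurable timing offset
  between the two metatarsal channels.

All randomness flows through an explicit :class:`numpy.random.Generator`;
a fixed :class:`SyntheticConfig` reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectProfile",
    "SyntheticConfig",
    "LoadCellRecording",
    "ForcePlateRecording",
    "TrialTruth",
    "SENSOR_CAPACITY_N",
    "vertical_grf_waveform",
    "ap_grf_waveform",
    "ml_grf_waveform",
    "loadcell_waveforms",
    "generate_trial",
    "generate_dataset",
    "make_subject",
]

#: Rated capacity of one uniaxial optical load cell, newtons.
SENSOR_CAPACITY_N = 980.70

# Vertical GRF template constants: bump weights, bump centers and width
# (phase units), and the exponent of the sine taper that pins both
# endpoints to zero. Centers sit slightly outside 25%/75% of stance
# because the taper pulls the realized maxima inward; with these values
# the maxima land at ~0.30/0.70 of stance at 1.0-1.1 body weight.
VERT_A1 = 1.2
VERT_A2 = 1.15
VERT_C1 = 0.24
VERT_C2 = 0.76
VERT_SIGMA = 0.18
VERT_GAMMA = 0.5

#: AP amplitude as a fraction of body weight.
AP_AMPLITUDE_BW = 0.18

# ML amplitude coupling: C = (ML_C0 + ML_C1 * gain_met1/gain_met5) * BW.
ML_C0 = 0.03
ML_C1 = 0.02

# Load-cell bump layout: nominal gains (fraction of BW) and phase widths.
HEEL_GAIN = 0.55
MET1_GAIN = 0.45
MET5_GAIN = 0.25
HEEL_CENTER = 0.22
# Bump width calibrated so the pooled correlation between the load-cell
# sum and the vertical GRF over default cohorts sits near 0.84.
LC_SIGMA = 0.15
MET5_CENTER_DEFAULT = 0.60
MET1_CENTER_DEFAULT = 0.72


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait parameters driving every waveform template.

    ``ap_crossing_phase`` is the stance fraction at which the AP force
    changes sign from braking to propulsion; ``met5_center`` /
    ``met1_center`` locate the metatarsal pressure bumps as stance
    fractions; ``channel_gains`` scales (heel, met1, met5) relative to
    body weight; ``timing_group`` marks whether the two metatarsal bumps
    are near-simultaneous ("similar") or lateral-first ("different").
    """

    subject_id: str
    body_weight: float
    stance_duration: float
    ap_crossing_phase: float
    met5_center: float
    met1_center: float
    channel_gains: tuple[float, float, float]
    timing_group: str
    #: Latent ML amplitude factor (similar-timing subjects only): the
    #: part of the medial-lateral force not expressed in the plantar
    #: channels when both metatarsals load simultaneously.
    ml_latent: float = 0.0

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError("body_weight must be positive")
        if not 0 < self.stance_duration < 2:
            raise ValueError("stance_duration must lie in (0, 2) s")
        if not 0.3 < self.ap_crossing_phase < 0.7:
            raise ValueError("ap_crossing_phase must lie in (0.3, 0.7)")
        if self.timing_group not in ("similar", "different"):
            raise ValueError(f"unknown timing_group {self.timing_group!r}")
        if self.timing_group == "different" and self.met5_center > self.met1_center:
            raise ValueError("met5_center must not exceed met1_center for 'different' timing")
        if self.timing_group == "similar" and abs(self.met5_center - self.met1_center) >= 0.02:
            raise ValueError("'similar' timing requires |met5_center - met1_center| < 0.02")
        if any(g <= 0 for g in self.channel_gains):
            raise ValueError("channel_gains must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Population- and acquisition-level knobs for dataset generation.

    Defaults emulate the study population this generator stands in for:
    healthy young adults with a mean stance time of 0.59 s, body weight
    around 650 N, load cells sampled at 100 Hz and the force plate at
    120 Hz.
    """

    n_subjects: int = 60
    trials_per_subject: int = 2
    seed: int = 0
    stance_duration_mean: float = 0.59
    stance_duration_sd: float = 0.04
    body_weight_mean: float = 650.0
    body_weight_sd: float = 90.0
    swing_noise_sd: float = 1.5
    sensor_noise_sd: float = 2.0
    fraction_similar_timing: float = 0.25
    lc_rate: float = 100.0
    fp_rate: float = 120.0

    def __post_init__(self) -> None:
        for name in ("stance_duration_sd", "body_weight_sd", "swing_noise_sd", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.fraction_similar_timing <= 1:
            raise ValueError("fraction_similar_timing must lie in [0, 1]")
        # Both instruments must resolve the 15 Hz content band.
        if min(self.lc_rate, self.fp_rate) <= 2 * 15.0:
            raise ValueError("sampling rates must exceed twice the 15 Hz content band")
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("n_subjects and trials_per_subject must be >= 1")


@dataclass(frozen=True)
class LoadCellRecording:
    """Three plantar load-cell force channels at the native rate (N)."""

    subject_id: str
    trial_id: str
    sample_rate: float
    heel: np.ndarray
    met1: np.ndarray
    met5: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.heel) == len(self.met1) == len(self.met5)):
            raise ValueError("load-cell channels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.heel)) / self.sample_rate

    def channel_matrix(self) -> np.ndarray:
        """(3, T) array ordered (heel, met1, met5)."""
        return np.stack([self.heel, self.met1, self.met5])


@dataclass(frozen=True)
class ForcePlateRecording:
    """Three-axis GRF channels at the native rate (N), zero in swing."""

    subject_id: str
    trial_id: str
    sample_rate: float
    vertical: np.ndarray
    ap: np.ndarray
    ml: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.vertical) == len(self.ap) == len(self.ml)):
            raise ValueError("force-plate channels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.vertical)) / self.sample_rate

    def channel_matrix(self) -> np.ndarray:
        """(3, T) array ordered (vertical, ap, ml)."""
        return np.stack([self.vertical, self.ap, self.ml])


@dataclass(frozen=True)
class TrialTruth:
    """Ground-truth event times (s from recording start) and peaks (N)."""

    heel_strike_time: float
    toe_off_time: float
    ap_crossing_time: float
    peak_vertical: float
    peak_ap: float
    peak_ml: float

    def __post_init__(self) -> None:
        if not self.heel_strike_time < self.ap_crossing_time < self.toe_off_time:
            raise ValueError("events must be ordered heel strike < AP crossing < toe off")


def _check_phase(phase: np.ndarray | float) -> np.ndarray:
    p = np.asarray(phase, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("phase must lie in [0, 1]")
    return p


def _bump(p: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((p - center) / sigma) ** 2)


def vertical_grf_waveform(phase, subject: SubjectProfile):
    """Noiseless vertical GRF (N) at stance fraction ``phase``.

    Two Gaussian bumps at 25% and 75% of stance, tapered by
    ``sin(pi p)^gamma`` so the force is exactly zero at heel strike and
    toe off; peaks land near 1.1-1.2 body weight with a mid-stance
    valley (the M-shape of level walking).
    """
    p = _check_phase(phase)
    bumps = VERT_A1 * _bump(p, VERT_C1, VERT_SIGMA) + VERT_A2 * _bump(p, VERT_C2, VERT_SIGMA)
    y = subject.body_weight * bumps * np.sin(np.pi * p) ** VERT_GAMMA
    return np.where((p == 0.0) | (p == 1.0), 0.0, y)  # taper exact at endpoints


def ap_grf_waveform(phase, subject: SubjectProfile):
    """Noiseless AP GRF (N): braking (<0) then propulsion (>0).

    The sign change sits exactly at ``subject.ap_crossing_phase``; the
    same sine taper as the vertical channel pins the endpoints to zero.
    """
    p = _check_phase(phase)
    p0 = subject.ap_crossing_phase
    amp = AP_AMPLITUDE_BW * subject.body_weight
    taper = np.sin(np.pi * p) ** VERT_GAMMA
    braking = -np.sin(np.pi * np.minimum(p, p0) / p0)
    propulsion = np.sin(np.pi * (np.maximum(p, p0) - p0) / (1.0 - p0))
    y = amp * taper * np.where(p <= p0, braking, propulsion)
    return np.where((p == 0.0) | (p == 1.0), 0.0, y)


def ml_grf_waveform(phase, subject: SubjectProfile):
    """Noiseless ML GRF (N), a small positive hump.

    Amplitude is a deterministic function of the metatarsal gain ratio
    (gain_met1 / gain_met5), so the ML axis is recoverable from the
    load-cell channels in principle. Similar-timing subjects carry an
    extra latent amplitude factor (``subject.ml_latent``) that the
    load cells do not see: with coincident metatarsal loading the
    plantar channels no longer resolve the lateral-to-medial transfer,
    so part of the ML amplitude becomes irreducibly unpredictable.
    """
    p = _check_phase(phase)
    _, g1, g5 = subject.channel_gains
    if g5 == 0:
        raise ValueError("gain_met5 must be non-zero")
    amp = (ML_C0 + ML_C1 * g1 / g5) * (1.0 + subject.ml_latent) * subject.body_weight
    return amp * np.sin(np.pi * p) * (1.0 + 0.3 * np.sin(2 * np.pi * p))


def loadcell_waveforms(phase, subject: SubjectProfile):
    """Noiseless (heel, met1, met5) load-cell forces (N) at ``phase``.

    Gaussian pressure bumps: heel early in stance, then the 5th and 1st
    metatarsals at the subject's bump centers. For the "different"
    timing group the lateral (5th) bump precedes the medial (1st) one,
    matching the usual heel -> lateral -> medial pressure progression.
    """
    p = _check_phase(phase)
    gh, g1, g5 = subject.channel_gains
    bw = subject.body_weight
    heel = gh * bw * _bump(p, HEEL_CENTER, LC_SIGMA)
    met1 = g1 * bw * _bump(p, subject.met1_center, LC_SIGMA)
    met5 = g5 * bw * _bump(p, subject.met5_center, LC_SIGMA)
    return heel, met1, met5


def _grid_peak(f, n: int = 2001) -> float:
    p = np.linspace(0.0, 1.0, n)
    return float(np.max(f(p)))


def make_subject(
    subject_id: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    timing_group: str | None = None,
) -> SubjectProfile:
    """Draw one subject from the population model.

    Stance duration and body weight are truncated normals; channel
    gains are jittered +-20% around the nominal layout; the metatarsal
    bump centers depend on the timing group, and the AP crossing phase
    is coupled to the metatarsal timing offset
    (``0.45 + 0.25 * (met1_center - met5_center)`` plus a small jitter).
    """
    if timing_group is None:
        timing_group = (
            "similar" if rng.random() < config.fraction_similar_timing else "different"
        )

    def trunc_normal(mean: float, sd: float, lo: float, hi: float) -> float:
        if sd == 0:
            return float(np.clip(mean, lo, hi))
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)
        return float(np.clip(mean, lo, hi))

    stance = trunc_normal(config.stance_duration_mean, config.stance_duration_sd, 0.4, 0.9)
    weight = trunc_normal(config.body_weight_mean, config.body_weight_sd, 400.0, 1000.0)
    gains = tuple(
        float(g * rng.uniform(0.8, 1.2)) for g in (HEEL_GAIN, MET1_GAIN, MET5_GAIN)
    )
    ml_latent = 0.0
    if timing_group == "different":
        met5 = float(np.clip(MET5_CENTER_DEFAULT + rng.normal(0, 0.02), 0.50, 0.68))
        met1 = float(np.clip(MET1_CENTER_DEFAULT + rng.normal(0, 0.02), met5, 0.85))
    else:
        center = float(np.clip(0.66 + rng.normal(0, 0.02), 0.55, 0.80))
        met5 = center
        met1 = float(center + np.clip(rng.normal(0, 0.005), -0.019, 0.019))
        ml_latent = float(np.clip(rng.normal(0, 0.25), -0.5, 0.5))
    p0 = 0.45 + 0.25 * (met1 - met5) + rng.normal(0, 0.01)
    p0 = float(np.clip(p0, 0.32, 0.68))
    return SubjectProfile(
        subject_id=subject_id,
        body_weight=weight,
        stance_duration=stance,
        ap_crossing_phase=p0,
        met5_center=met5,
        met1_center=met1,
        channel_gains=gains,  # type: ignore[arg-type]
        timing_group=timing_group,
        ml_latent=ml_latent,
    )


def generate_trial(
    subject: SubjectProfile,
    config: SyntheticConfig,
    rng: np.random.Generator,
    trial_id: str = "t0",
) -> tuple[LoadCellRecording, ForcePlateRecording, TrialTruth]:
    """Simulate one walking trial for ``subject``.

    Both instruments record the same physical event on their own native
    time grids (sample k at k/rate, starting at t = 0). The load cells
    see the whole pass -- at least 0.3 s of swing padding before heel
    strike and after toe off, carrying zero-mean swing noise -- while
    the force plate reads exactly zero outside foot contact. Per-sample
    sensor noise is added to both instruments during stance.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")

    # Swing lead-in of 0.40-0.55 s: comfortably more than the 0.3 s
    # minimum, so zero-phase filter edge transients (< 1e-6 N by ~0.4 s)
    # have died out before heel strike.
    hs = float(rng.uniform(0.40, 0.55))
    stance = subject.stance_duration
    toe_off = hs + stance
    duration = toe_off + 0.35

    def sample(rate: float):
        n = int(np.floor(duration * rate)) + 1
        t = np.arange(n) / rate
        phase = (t - hs) / stance
        in_stance = (phase >= 0.0) & (phase <= 1.0)
        return t, np.clip(phase, 0.0, 1.0), in_stance

    # Load cells: waveform on stance, swing noise outside, sensor noise inside.
    t_lc, ph_lc, st_lc = sample(config.lc_rate)
    heel, met1, met5 = loadcell_waveforms(ph_lc, subject)
    lc = np.stack([heel, met1, met5])
    lc[:, ~st_lc] = 0.0
    if config.swing_noise_sd > 0:
        noise = rng.normal(0.0, config.swing_noise_sd, lc.shape)
        lc[:, ~st_lc] += noise[:, ~st_lc]
    if config.sensor_noise_sd > 0:
        noise = rng.normal(0.0, config.sensor_noise_sd, lc.shape)
        lc[:, st_lc] += noise[:, st_lc]
    lc = np.minimum(lc, SENSOR_CAPACITY_N)

    # Force plate: exactly zero outside contact, sensor noise in stance.
    t_fp, ph_fp, st_fp = sample(config.fp_rate)
    fp = np.stack(
        [
            vertical_grf_waveform(ph_fp, subject),
            ap_grf_waveform(ph_fp, subject),
            ml_grf_waveform(ph_fp, subject),
        ]
    )
    fp[:, ~st_fp] = 0.0
    if config.sensor_noise_sd > 0:
        noise = rng.normal(0.0, config.sensor_noise_sd, fp.shape)
        fp[:, st_fp] += noise[:, st_fp]

    truth = TrialTruth(
        heel_strike_time=hs,
        toe_off_time=toe_off,
        ap_crossing_time=hs + subject.ap_crossing_phase * stance,
        peak_vertical=_grid_peak(lambda p: vertical_grf_waveform(p, subject)),
        peak_ap=_grid_peak(lambda p: ap_grf_waveform(p, subject)),
        peak_ml=_grid_peak(lambda p: ml_grf_waveform(p, subject)),
    )
    lc_rec = LoadCellRecording(
        subject_id=subject.subject_id,
        trial_id=trial_id,
        sample_rate=config.lc_rate,
        heel=lc[0],
        met1=lc[1],
        met5=lc[2],
    )
    fp_rec = ForcePlateRecording(
        subject_id=subject.subject_id,
        trial_id=trial_id,
        sample_rate=config.fp_rate,
        vertical=fp[0],
        ap=fp[1],
        ml=fp[2],
    )
    return lc_rec, fp_rec, truth


@dataclass(frozen=True)
class SyntheticDataset:
    """All trials of one generated cohort plus the subject table."""

    subjects: tuple[SubjectProfile, ...]
    trials: tuple[tuple[LoadCellRecording, ForcePlateRecording, TrialTruth], ...]

    def __len__(self) -> int:
        return len(self.trials)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate ``n_subjects x trials_per_subject`` paired trials.

    Fully determined by ``config`` (including ``config.seed``); subject
    timing groups are Bernoulli draws with probability
    ``fraction_similar_timing``.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [
        make_subject(f"S{i:03d}", config, rng) for i in range(config.n_subjects)
    ]
    trials = []
    for subject in subjects:
        for k in range(config.trials_per_subject):
            trials.append(generate_trial(subject, config, rng, trial_id=f"t{k}"))
    return SyntheticDataset(subjects=tuple(subjects), trials=tuple(trials))
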