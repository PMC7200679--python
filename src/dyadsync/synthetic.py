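"""Synthetic dyadic fNIRS sessions with controllable inter-partner coupling.

Each channel's oxy-Hb series mixes a *shared* stimulus-locked latent
process (weight kappa) with an *independent* one (weight sqrt(1-kappa^2)),
keeping per-subject variance constant across kappa, so the expected
epoch-wise correlation between partners rises monotonically with kappa.
A deterministic event-locked hemodynamic response common to all subjects
sits on top, plus physiological noise (Mayer waves, respiration, cardiac),
white noise and a linear drift.  The father's stimulus-locked signal can
be delayed to emulate inter-partner lag.

Deoxy-Hb is produced as a scaled, sign-flipped copy of oxy-Hb with its own
noise — enough for the Beer-Lambert stage to have two chromophores.  When
raw dual-wavelength intensity output is requested, concentrations are
forward-projected through the Beer-Lambert model onto 760/850 nm optical
densities and exponentiated around a unit baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .io_core import (
    CONDITIONS,
    ISI_S,
    N_CHANNELS,
    N_EVENTS,
    N_TRIALS,
    STIMULI,
    STIMULUS_DURATION_S,
    CovariateRecord,
    DyadSession,
    EventSchedule,
    Recording,
    ValidationError,
    get_logger,
    write_covariates,
    write_events,
    write_timeseries,
)
from .preprocess import forward_mbll

__all__ = [
    "HrfParams",
    "SimulationConfig",
    "double_gamma_hrf",
    "generate_protocol",
    "simulate_dyad",
    "simulate_study",
    "inject_spikes",
    "write_study",
]

logger = get_logger()


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay_s >= self.undershoot_delay_s:
            raise ValidationError("HRF peak delay must precede the undershoot delay")
        if min(self.peak_dispersion_s, self.undershoot_dispersion_s, self.length_s) <= 0:
            raise ValidationError("HRF dispersions and length must be positive")


def double_gamma_hrf(fs: float, params: HrfParams | None = None) -> np.ndarray:
    """Sampled double-gamma HRF kernel, peak-normalised to 1."""
    p = params or HrfParams()
    t = np.arange(0, p.length_s, 1.0 / fs)
    peak = gamma_dist.pdf(t, p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s)
    under = gamma_dist.pdf(t, p.undershoot_delay_s / p.undershoot_dispersion_s,
                           scale=p.undershoot_dispersion_s)
    h = peak - p.undershoot_ratio * under
    return h / h.max()


@dataclass
class SimulationConfig:
    """Study-condition knobs for the dyad simulator.

    Amplitudes are on the micromolar scale of oxy-Hb concentration change.
    ``coupling_tog`` / ``coupling_sep`` are the shared-component weights
    kappa for the two conditions; ``inter_partner_lag_s`` delays the
    father's stimulus-locked signal.
    """

    n_dyads: int = 24
    sampling_rate: float = 7.81
    coupling_tog: float = 0.6
    coupling_sep: float = 0.1
    inter_partner_lag_s: float = 0.0
    stimulus_amplitudes: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in STIMULI}
    )
    latent_sd: float = 0.8           # uM, stimulus-locked fluctuation
    latent_background_weight: float = 0.5  # share of latent variance not event-locked
    mayer_amplitude: float = 0.2     # uM at ~0.1 Hz
    respiration_amplitude: float = 0.1  # uM at ~0.3 Hz
    cardiac_amplitude: float = 0.1   # uM at ~1.2 Hz (below Nyquist at 7.81 Hz)
    white_amplitude: float = 0.2     # uM
    drift_amplitude: float = 0.3     # uM peak-to-peak linear drift
    deoxy_scale: float = 1.0 / 3.0
    deoxy_noise: float = 0.05
    intensity_noise_od: float = 0.01
    spike_rate_per_min: float = 0.0
    spike_amplitude_robust_sd: float = 10.0
    bad_channel_spec: list[tuple[str, int, str]] = field(default_factory=list)
    signal_kind: str = "oxyhb"
    hrf: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for kappa in (self.coupling_tog, self.coupling_sep):
            if not (0.0 <= kappa <= 1.0):
                raise ValidationError(f"coupling must lie in [0, 1], got {kappa}")
        if abs(self.inter_partner_lag_s) > 2.0:
            raise ValidationError("inter-partner lag must lie within [-2, 2] s")
        for name in ("mayer_amplitude", "respiration_amplitude", "cardiac_amplitude",
                     "white_amplitude", "drift_amplitude", "latent_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for _, ch, mode in self.bad_channel_spec:
            if mode not in ("high_gain", "high_cv"):
                raise ValidationError(f"unknown bad-channel mode {mode!r}")
            if not (1 <= ch <= N_CHANNELS):
                raise ValidationError(f"bad-channel id {ch} outside 1..{N_CHANNELS}")

    def coupling_for(self, condition: str) -> float:
        if condition == "TOG":
            return self.coupling_tog
        if condition == "SEP":
            return self.coupling_sep
        raise ValidationError(f"no coupling configured for condition {condition!r}")


def generate_protocol(seed: int) -> EventSchedule:
    """Randomised presentation order: 6 stimuli x 3 trials, 15 s stimuli,
    10 s ISI, back-to-back from t = 0 (total span 440 s)."""
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(STIMULI)), N_TRIALS)
    rng.shuffle(order)
    seen: dict[int, int] = {}
    rows = []
    for k, s in enumerate(order):
        seen[s] = seen.get(s, 0) + 1
        rows.append(
            {
                "stimulus_id": STIMULI[s],
                "trial_index": seen[s],
                "onset": k * (STIMULUS_DURATION_S + ISI_S),
                "duration": STIMULUS_DURATION_S,
            }
        )
    return EventSchedule(events=pd.DataFrame(rows))


def _event_regressor(schedule: EventSchedule, fs: float, n: int,
                     amplitudes: dict[str, float] | None,
                     gains: np.ndarray | None,
                     hrf: np.ndarray) -> np.ndarray:
    """Boxcar event train (optionally per-event gains) convolved with the HRF.

    The kernel is area-normalised so a sustained stimulus plateaus at its
    configured amplitude.
    """
    train = np.zeros(n)
    for k, ev in enumerate(schedule.events.itertuples()):
        a = 1.0 if amplitudes is None else amplitudes.get(ev.stimulus_id, 0.0)
        g = 1.0 if gains is None else gains[k]
        i0 = int(round(ev.onset * fs))
        i1 = min(n, i0 + int(round(ev.duration * fs)))
        if i0 < n:
            train[i0:i1] += a * g
    return np.convolve(train, hrf / hrf.sum())[:n]


def _smooth_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance low-frequency Gaussian process (4th-order 0.15 Hz low-pass)."""
    sos = sps.butter(4, 0.15, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(20 * fs)))[int(20 * fs):]
    sd = x.std()
    return x / sd if sd > 0 else x


def _latent_component(rng: np.random.Generator, schedule: EventSchedule,
                      fs: float, n: int, hrf: np.ndarray, bg_weight: float) -> np.ndarray:
    """Zero-mean, unit-variance stimulus-locked latent process: HRF-convolved
    event train with standard-normal per-event gains, blended with a smooth
    background."""
    gains = rng.standard_normal(N_EVENTS)
    locked = _event_regressor(schedule, fs, n, None, gains, hrf)
    sd = locked.std()
    if sd > 0:
        locked = locked / sd
    bg = _smooth_noise(rng, n, fs)
    z = np.sqrt(1.0 - bg_weight) * locked + np.sqrt(bg_weight) * bg
    return z / z.std() if z.std() > 0 else z


def _physio_noise(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    t = np.arange(n) / cfg.sampling_rate
    out = np.zeros(n)
    for amp, freq in (
        (cfg.mayer_amplitude, 0.1),
        (cfg.respiration_amplitude, 0.3),
        (cfg.cardiac_amplitude, 1.2),
    ):
        if amp > 0:
            out += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if cfg.white_amplitude > 0:
        out += cfg.white_amplitude * rng.standard_normal(n)
    if cfg.drift_amplitude > 0:
        out += cfg.drift_amplitude * rng.uniform(-1, 1) * np.linspace(-0.5, 0.5, n)
    return out


def _delay(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift a series by an integer number of samples, edge-padded."""
    if shift == 0:
        return x.copy()
    out = np.empty_like(x)
    if shift > 0:
        out[shift:] = x[:-shift]
        out[:shift] = x[0]
    else:
        out[:shift] = x[-shift:]
        out[shift:] = x[-1]
    return out


def inject_spikes(
    series: np.ndarray,
    rate_per_min: float,
    amplitude_robust_sd: float,
    seed: int | np.random.Generator,
    fs: float = 7.81,
    max_width: int = 3,
) -> tuple[np.ndarray, list[int]]:
    """Add Poisson-placed short excursions; returns (series, spike positions).

    Amplitude is expressed in multiples of the series' robust SD
    (1.4826 * MAD); each spike spans 1-3 samples with a random sign.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    if rate_per_min <= 0 or n == 0:
        return x, []
    duration_min = n / fs / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    mad = np.median(np.abs(x - np.median(x)))
    robust_sd = 1.4826 * mad if mad > 0 else (x.std() if x.std() > 0 else 1.0)
    positions: list[int] = []
    starts = rng.integers(2, max(3, n - max_width - 2), size=count)
    for s in np.sort(starts):
        width = int(rng.integers(1, max_width + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for j in range(s, min(s + width, n - 1)):
            x[j] += sign * amplitude_robust_sd * robust_sd
            positions.append(int(j))
    return x, sorted(set(positions))


def _oxy_channels(cfg: SimulationConfig, schedule: EventSchedule, kappa: float,
                  rng: np.random.Generator, n: int, hrf: np.ndarray,
                  lag_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Build (mother, father) oxy-Hb arrays of shape (n_channels, n)."""
    fs = cfg.sampling_rate
    mu = np.sqrt(1.0 - kappa ** 2)
    mother = np.zeros((N_CHANNELS, n))
    father = np.zeros((N_CHANNELS, n))
    response = _event_regressor(schedule, fs, n, cfg.stimulus_amplitudes, None, hrf)
    for c in range(N_CHANNELS):
        shared = _latent_component(rng, schedule, fs, n, hrf, cfg.latent_background_weight)
        own_m = _latent_component(rng, schedule, fs, n, hrf, cfg.latent_background_weight)
        own_f = _latent_component(rng, schedule, fs, n, hrf, cfg.latent_background_weight)
        sig_m = response + cfg.latent_sd * (kappa * shared + mu * own_m)
        sig_f = response + cfg.latent_sd * (kappa * shared + mu * own_f)
        mother[c] = sig_m + _physio_noise(rng, cfg, n)
        father[c] = _delay(sig_f, lag_samples) + _physio_noise(rng, cfg, n)
    return mother, father


def _finish_recording(cfg: SimulationConfig, oxy: np.ndarray, subject_id: str, role: str,
                      condition: str, rng: np.random.Generator,
                      bad: dict[int, str], truth: dict) -> Recording:
    n = oxy.shape[1]
    deoxy = -cfg.deoxy_scale * oxy + cfg.deoxy_noise * rng.standard_normal(oxy.shape)

    if cfg.spike_rate_per_min > 0:
        for c in range(N_CHANNELS):
            oxy[c], pos = inject_spikes(oxy[c], cfg.spike_rate_per_min,
                                        cfg.spike_amplitude_robust_sd, rng, cfg.sampling_rate)
            truth.setdefault("spikes", {}).setdefault(subject_id, {})[c + 1] = pos

    gains = np.round(rng.uniform(1, 7, size=N_CHANNELS), 1)
    for ch, mode in bad.items():
        if mode == "high_gain":
            gains[ch - 1] = round(float(rng.uniform(8.5, 12.0)), 1)

    if cfg.signal_kind == "oxyhb":
        if any(mode == "high_cv" for mode in bad.values()):
            raise ValidationError(
                "high_cv bad channels need raw intensity output "
                "(signal_kind='raw_intensity_2wavelength')"
            )
        data = {"oxy": oxy, "deoxy": deoxy}
    elif cfg.signal_kind == "raw_intensity_2wavelength":
        od760, od850 = forward_mbll(oxy, deoxy)
        data = {}
        for label, od in (("wl760", od760), ("wl850", od850)):
            noise_sd = np.full(N_CHANNELS, cfg.intensity_noise_od)
            for ch, mode in bad.items():
                if mode == "high_cv":
                    noise_sd[ch - 1] = 0.12  # pushes CV well past 7.5%
            eps = noise_sd[:, None] * rng.standard_normal(od.shape)
            data[label] = np.exp(-(od + eps))  # unit baseline intensity
    else:
        raise ValidationError(f"simulator cannot emit signal kind {cfg.signal_kind!r}")

    return Recording(
        subject_id=subject_id,
        role=role,
        condition=condition,
        sampling_rate=cfg.sampling_rate,
        signal_kind=cfg.signal_kind,
        data=data,
        channel_ids=list(range(1, N_CHANNELS + 1)),
        channel_gains=gains,
    )


def simulate_dyad(
    config: SimulationConfig,
    condition: str,
    schedule: EventSchedule,
    dyad_id: str = "d01",
    rng: np.random.Generator | None = None,
    truth: dict | None = None,
) -> DyadSession:
    """Simulate one mother-father session for the given condition.

    The condition selects the coupling weight kappa.  ``truth`` (optional
    dict) collects ground truth: kappa, lag, spike positions, bad channels.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    kappa = config.coupling_for(condition)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = truth if truth is not None else {}
    truth.update({"kappa_" + condition: kappa, "lag_s": config.inter_partner_lag_s})

    fs = config.sampling_rate
    n = int(round((schedule.span_s + 20.0) * fs))  # 20 s tail past the last event
    hrf = double_gamma_hrf(fs, config.hrf)
    lag_samples = int(round(config.inter_partner_lag_s * fs))

    oxy_m, oxy_f = _oxy_channels(config, schedule, kappa, rng, n, hrf, lag_samples)

    mid, fid = f"{dyad_id}_m", f"{dyad_id}_f"
    bad_m = {ch: mode for subj, ch, mode in config.bad_channel_spec if subj == mid}
    bad_f = {ch: mode for subj, ch, mode in config.bad_channel_spec if subj == fid}
    truth.setdefault("bad_channels", {}).update({mid: bad_m, fid: bad_f})

    mother = _finish_recording(config, oxy_m, mid, "mother", condition, rng, bad_m, truth)
    father = _finish_recording(config, oxy_f, fid, "father", condition, rng, bad_f, truth)
    return DyadSession(dyad_id=dyad_id, mother=mother, father=father,
                       schedule=schedule, condition=condition)


def _simulate_covariates(n_dyads: int, rng: np.random.Generator) -> list[CovariateRecord]:
    from .io_core import RATIO_SCORES

    records = []
    for i in range(n_dyads):
        records.append(
            CovariateRecord(
                dyad_id=f"d{i + 1:02d}",
                mother_age=float(np.round(rng.normal(32.0, 4.0), 1)),
                father_age=float(np.round(rng.normal(34.0, 4.5), 1)),
                parity="primiparous" if rng.random() < 0.6 else "multiparous",
                mother_ratio_score=float(rng.choice(RATIO_SCORES)),
                father_ratio_score=float(rng.choice(RATIO_SCORES)),
            )
        )
    return records


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[DyadSession], list[CovariateRecord], dict]:
    """Simulate the full study: every dyad in both conditions, one
    randomised protocol per (dyad, condition), plus couple covariates and a
    ground-truth sidecar."""
    rng = np.random.default_rng(config.seed)
    sessions: list[DyadSession] = []
    truth: dict = {"seed": config.seed}
    for i in range(config.n_dyads):
        dyad_id = f"d{i + 1:02d}"
        for condition in CONDITIONS:
            schedule = generate_protocol(int(rng.integers(0, 2 ** 31 - 1)))
            sessions.append(
                simulate_dyad(config, condition, schedule, dyad_id=dyad_id,
                              rng=rng, truth=truth)
            )
    covariates = _simulate_covariates(config.n_dyads, rng)
    logger.info("simulated %d dyads x 2 conditions (seed %d)", config.n_dyads, config.seed)
    return sessions, covariates, truth


def write_study(
    sessions: list[DyadSession],
    covariates: list[CovariateRecord],
    truth: dict,
    out_dir: str | Path,
) -> None:
    """Write a simulated study in the package's on-disk layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        stem = f"{s.dyad_id}_{s.condition}"
        write_timeseries(s.mother, out / f"{stem}_mother.tsv")
        write_timeseries(s.father, out / f"{stem}_father.tsv")
        write_events(s.schedule, out / f"{stem}_events.tsv")
    write_covariates(covariates, out / "covariates.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
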