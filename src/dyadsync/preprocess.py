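"""Signal conditioning for raw fNIRS recordings.

The chain runs in a fixed order: channel rejection (gain / coefficient of
variation), spike replacement, discontinuity correction, band-pass
filtering, and finally conversion of optical density to hemoglobin
concentration changes via the modified Beer-Lambert law.

Spike and step detectors operate on first differences with MAD-scaled
thresholds: a spike is a short excursion bracketed by a pair of large,
opposite-signed jumps; a discontinuity is a lone large jump whose new level
persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_core import (
    AnalysisConfig,
    DataError,
    DyadSession,
    Recording,
    ValidationError,
    get_logger,
    load_extinction_table,
)

__all__ = [
    "QCReport",
    "channel_cv",
    "reject_channels",
    "detect_and_replace_spikes",
    "remove_discontinuities",
    "bandpass",
    "intensity_to_od",
    "mbll",
    "forward_mbll",
    "preprocess_recording",
    "preprocess_session",
]

logger = get_logger()

_MAD_SCALE = 1.4826  # MAD -> SD under normality


@dataclass
class QCReport:
    """Per-(subject, channel) quality-control ledger.

    ``rejected`` is True exactly when gain exceeds the gain threshold or
    the coefficient of variation exceeds the CV threshold (strict
    inequalities); the reason records which rule fired.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "subject_id",
                "channel_id",
                "gain",
                "cv_percent",
                "rejected",
                "rejection_reason",
                "spike_count",
                "discontinuity_count",
            ]
        )
    )

    def add(self, subject_id: str, channel_id: int, gain: float, cv: float,
            rejected: bool, reason: str) -> None:
        self.rows.loc[len(self.rows)] = [subject_id, channel_id, gain, cv, rejected, reason, 0, 0]

    def record_artifacts(self, subject_id: str, channel_id: int,
                         spikes: int = 0, steps: int = 0) -> None:
        sel = (self.rows.subject_id == subject_id) & (self.rows.channel_id == channel_id)
        self.rows.loc[sel, "spike_count"] += spikes
        self.rows.loc[sel, "discontinuity_count"] += steps

    def mask_for(self, subject_id: str) -> np.ndarray:
        """Boolean keep-mask in channel order for one subject."""
        sub = self.rows[self.rows.subject_id == subject_id].sort_values("channel_id")
        return ~sub["rejected"].to_numpy(dtype=bool)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def channel_cv(raw_series: np.ndarray) -> float:
    """Coefficient of variation of a raw intensity series, in percent.

    CV = 100 * SD / mean.  Requires a positive mean; a channel whose mean
    intensity is non-positive has no meaningful CV and is auto-rejected
    upstream.
    """
    x = np.asarray(raw_series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0 or x.mean() <= 0:
        raise DataError("CV undefined for a series with non-positive mean")
    return float(100.0 * x.std() / x.mean())


def reject_channels(
    gains: np.ndarray,
    cvs: np.ndarray,
    config: AnalysisConfig | None = None,
    subject_id: str = "unknown",
    report: QCReport | None = None,
) -> tuple[np.ndarray, QCReport]:
    """Exclude channels with gain > 8 or CV > 7.5% (strict inequalities).

    Returns (keep_mask, report).  A NaN CV (undefined, e.g. non-positive
    mean) counts as a CV rejection.
    """
    config = config or AnalysisConfig()
    gains = np.asarray(gains, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if gains.shape != cvs.shape:
        raise ValidationError("gains and cvs must have matching shapes")
    report = report or QCReport()
    keep = np.ones(gains.shape, dtype=bool)
    for i, (g, cv) in enumerate(zip(gains, cvs)):
        bad_gain = g > config.gain_threshold
        bad_cv = (not np.isfinite(cv)) or cv > config.cv_threshold
        if bad_gain and bad_cv:
            reason = "both"
        elif bad_gain:
            reason = "gain"
        elif bad_cv:
            reason = "cv"
        else:
            reason = "none"
        rejected = bad_gain or bad_cv
        keep[i] = not rejected
        report.add(subject_id, i + 1, g, cv, rejected, reason)
    return keep, report


def _robust_diff_sd(d: np.ndarray) -> float:
    mad = np.median(np.abs(d - np.median(d)))
    return float(_MAD_SCALE * mad)


def detect_and_replace_spikes(
    series: np.ndarray,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Replace short, large-amplitude excursions with interpolated values.

    A sample run is a spike when it is entered and left by first
    differences exceeding ``spike_mad_k`` MAD-scaled SDs with opposite
    signs, within ``max_spike_width`` samples.  Flagged runs are replaced
    by linear interpolation between the nearest clean neighbours, so a
    one-sample spike becomes the mean of its two neighbours.  Length is
    preserved.  Returns (cleaned, flagged_positions).
    """
    config = config or AnalysisConfig()
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    if n < 4:
        return x, []
    d = np.diff(x)
    sd = _robust_diff_sd(d)
    if sd == 0:
        # fall back to plain SD so an isolated spike on a constant
        # baseline is still catchable
        sd = float(d.std())
        if sd == 0:
            return x, []
    thr = config.spike_mad_k * sd
    big = np.flatnonzero(np.abs(d) > thr)

    flagged: list[int] = []
    used = np.zeros(d.size, dtype=bool)
    for i in big:
        if used[i]:
            continue
        # look for the opposite-signed return jump within the width budget
        for j in big:
            if j <= i or j - i > config.max_spike_width:
                continue
            if used[j] or np.sign(d[j]) == np.sign(d[i]):
                continue
            flagged.extend(range(i + 1, j + 1))
            used[i] = used[j] = True
            break
    flagged = sorted(set(flagged))
    if not flagged:
        return x, []

    if len(flagged) > 0.2 * n:
        logger.warning("spike replacement touched %.0f%% of samples (> 20%%): channel flagged",
                       100 * len(flagged) / n)

    good = np.ones(n, dtype=bool)
    good[flagged] = False
    idx = np.arange(n)
    x[~good] = np.interp(idx[~good], idx[good], x[good])
    return x, flagged


def remove_discontinuities(
    series: np.ndarray,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Correct persistent baseline steps by subtracting the jump.

    A step is a first difference exceeding ``step_mad_k`` MAD-scaled SDs
    that is *not* matched by an opposite return jump within the spike
    width budget — the level shift persists.  The estimated jump (relative
    to the median sample-to-sample difference) is subtracted from all
    subsequent samples.  Returns (corrected, step_positions).
    """
    config = config or AnalysisConfig()
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    if n < 4:
        return x, []
    d = np.diff(x)
    sd = _robust_diff_sd(d)
    if sd == 0:
        sd = float(d.std())
        if sd == 0:
            return x, []
    thr = config.step_mad_k * sd
    med = float(np.median(d))
    big = np.flatnonzero(np.abs(d) > thr)

    steps: list[int] = []
    for i in big:
        paired = any(
            0 < j - i <= config.max_spike_width and np.sign(d[j]) != np.sign(d[i])
            for j in big if j != i
        ) or any(
            0 < i - j <= config.max_spike_width and np.sign(d[j]) != np.sign(d[i])
            for j in big if j != i
        )
        if not paired:
            steps.append(int(i))
    for i in steps:
        x[i + 1:] -= d[i] - med
    return x, steps


def bandpass(
    series: np.ndarray,
    fs: float,
    low: float = 0.01,
    high: float = 0.2,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.01-0.2 Hz, order 3).

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the square of the single-pass Butterworth and phase is
    zero.  Raises for series shorter than three filter lengths.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 2 * high:
        raise ValidationError(f"sampling rate {fs} Hz too low for band high {high} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * order + 1)
    if x.shape[-1] < min_len:
        raise ValidationError(
            f"series of {x.shape[-1]} samples too short to filter; need >= {min_len} "
            f"({min_len / fs:.1f} s at {fs} Hz)"
        )
    return sps.sosfiltfilt(sos, x, axis=-1)


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density change: OD(t) = -ln(I(t) / mean(I)) per channel.

    Operates on the last axis; any non-positive sample is an error because
    log attenuation is undefined there.
    """
    I = np.asarray(intensity, dtype=float)
    finite = np.isfinite(I)
    if np.any(I[finite] <= 0):
        bad = np.argwhere((I <= 0) & finite)
        raise DataError(f"non-positive intensity sample at index {tuple(bad[0])}")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(I, axis=-1, keepdims=True)
        return -np.log(I / mean)


def _extinction_matrix(extinction_table: pd.DataFrame | None) -> np.ndarray:
    table = extinction_table if extinction_table is not None else load_extinction_table()
    try:
        rows = table.loc[[760, 850], ["ext_hbo", "ext_hbr"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValidationError(f"extinction table must cover 760 and 850 nm: {exc}") from exc
    return rows  # shape (2 wavelengths, 2 chromophores)


def mbll(
    od_760: np.ndarray,
    od_850: np.ndarray,
    dpf: float = 6.0,
    distance_cm: float = 3.0,
    extinction_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer-Lambert law: OD changes at two wavelengths to (oxy, deoxy).

    Solves, per sample, the 2x2 system
    ``dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF``
    with extinction coefficients in cm^-1 mM^-1 and path ``d`` in cm;
    concentration changes are returned in micromolar.
    """
    if dpf <= 0 or distance_cm <= 0:
        raise ValidationError("dpf and distance must be positive")
    E = _extinction_matrix(extinction_table)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValidationError("extinction matrix is singular; cannot separate chromophores")
    od = np.stack([np.asarray(od_760, dtype=float), np.asarray(od_850, dtype=float)])
    conc_mM = np.linalg.solve(E, od.reshape(2, -1)) / (distance_cm * dpf)
    conc_uM = conc_mM.reshape(od.shape) * 1e3
    return conc_uM[0], conc_uM[1]


def forward_mbll(
    oxy_uM: np.ndarray,
    deoxy_uM: np.ndarray,
    dpf: float = 6.0,
    distance_cm: float = 3.0,
    extinction_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: concentration changes (uM) to OD changes at 760/850 nm."""
    E = _extinction_matrix(extinction_table)
    conc_mM = np.stack([np.asarray(oxy_uM, dtype=float), np.asarray(deoxy_uM, dtype=float)]) * 1e-3
    od = (E @ conc_mM.reshape(2, -1)) * (distance_cm * dpf)
    od = od.reshape(conc_mM.shape)
    return od[0], od[1]


def preprocess_recording(
    rec: Recording,
    config: AnalysisConfig | None = None,
    report: QCReport | None = None,
) -> tuple[Recording, QCReport]:
    """Run the full conditioning chain on one recording.

    Order: reject channels -> replace spikes -> remove discontinuities ->
    band-pass -> Beer-Lambert conversion.  The result is an oxy/deoxy
    recording in which rejected channels are present but all-NaN.
    """
    config = config or AnalysisConfig()
    config.validate_for_rate(rec.sampling_rate)
    report = report or QCReport()

    gains = rec.channel_gains
    if gains is None:
        gains = np.ones(rec.n_channels)

    if rec.signal_kind == "raw_intensity_2wavelength":
        raw = rec.data["wl760"]
        cvs = np.array([
            channel_cv(raw[i]) if np.isfinite(raw[i]).any() and np.nanmean(raw[i]) > 0 else np.nan
            for i in range(rec.n_channels)
        ])
    else:
        # CV is an intensity metric; without raw intensity the CV rule
        # cannot fire and rejection falls back to gain only
        cvs = np.zeros(rec.n_channels)
    keep, report = reject_channels(gains, cvs, config, subject_id=rec.subject_id, report=report)

    labels = list(rec.data)
    cleaned: dict[str, np.ndarray] = {}
    for label in labels:
        arr = rec.data[label].astype(float).copy()
        for i in range(rec.n_channels):
            if not keep[i]:
                arr[i] = np.nan
                continue
            x, spikes = detect_and_replace_spikes(arr[i], config)
            x, steps = remove_discontinuities(x, config)
            report.record_artifacts(rec.subject_id, i + 1, len(spikes), len(steps))
            arr[i] = x
        cleaned[label] = arr

    if rec.signal_kind == "raw_intensity_2wavelength":
        od = {"od760": np.full_like(cleaned["wl760"], np.nan),
              "od850": np.full_like(cleaned["wl850"], np.nan)}
        for i in range(rec.n_channels):
            if keep[i]:
                od["od760"][i] = intensity_to_od(cleaned["wl760"][i])
                od["od850"][i] = intensity_to_od(cleaned["wl850"][i])
        cleaned, kind = od, "optical_density"
    else:
        kind = rec.signal_kind

    filtered = {}
    for label, arr in cleaned.items():
        out = np.full_like(arr, np.nan)
        for i in range(rec.n_channels):
            if keep[i] and np.isfinite(arr[i]).all():
                out[i] = bandpass(arr[i], rec.sampling_rate,
                                  config.band_low_hz, config.band_high_hz, config.filter_order)
        filtered[label] = out

    if kind == "optical_density":
        oxy = np.full_like(filtered["od760"], np.nan)
        deoxy = np.full_like(filtered["od850"], np.nan)
        for i in range(rec.n_channels):
            if keep[i]:
                oxy[i], deoxy[i] = mbll(filtered["od760"][i], filtered["od850"][i],
                                        config.dpf, config.distance_cm)
        data = {"oxy": oxy, "deoxy": deoxy}
    else:
        data = filtered

    out_rec = Recording(
        subject_id=rec.subject_id,
        role=rec.role,
        condition=rec.condition,
        sampling_rate=rec.sampling_rate,
        signal_kind="oxyhb",
        data=data,
        channel_ids=list(rec.channel_ids),
        channel_gains=gains,
    )
    logger.debug("preprocessed %s: %d/%d channels kept", rec.subject_id, keep.sum(), keep.size)
    return out_rec, report


def preprocess_session(
    session: DyadSession,
    config: AnalysisConfig | None = None,
) -> tuple[DyadSession, QCReport]:
    """Preprocess both partners of a session with a shared QC report."""
    report = QCReport()
    mother, report = preprocess_recording(session.mother, config, report)
    father, report = preprocess_recording(session.father, config, report)
    return DyadSession(
        dyad_id=session.dyad_id,
        mother=mother,
        father=father,
        schedule=session.schedule,
        condition=session.condition,
    ), report
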