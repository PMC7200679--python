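"""Data model, file I/O, configuration and logging for the dyadic fNIRS pipeline.

The on-disk convention is deliberately plain: wide delimited tables (one
column per channel x chromophore/wavelength) for time-series, and small
TSV tables for events, covariates, synchrony indices and statistics
reports.  All types validate their invariants on construction.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Montage",
    "MontageChannel",
    "EventSchedule",
    "Recording",
    "DyadSession",
    "CovariateRecord",
    "AnalysisConfig",
    "FormatError",
    "DataError",
    "ValidationError",
    "STIMULI",
    "STIMULUS_FREQUENCIES",
    "PITCH_SHIFT_HZ",
    "high_pitched_cry_frequency",
    "default_montage",
    "load_extinction_table",
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "read_covariates",
    "write_covariates",
    "get_logger",
]

logger = logging.getLogger("dyadsync")


def get_logger(name: str = "dyadsync", verbose: bool = False) -> logging.Logger:
    """Package logger: plain-text lines with stage name and parameters."""
    log = logging.getLogger(name)
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    return log


class FormatError(ValueError):
    """A file does not follow the expected on-disk layout."""


class DataError(ValueError):
    """A file parses but its content is inconsistent (e.g. non-monotonic time)."""


class ValidationError(ValueError):
    """A domain-type invariant is violated."""


# --------------------------------------------------------------------------
# Stimulus catalogue
# --------------------------------------------------------------------------

#: The six auditory stimuli, in presentation-catalogue order.
STIMULI: tuple[str, ...] = (
    "adult_laughter",
    "infant_laughter",
    "infant_cry_low",
    "infant_cry_high",
    "adult_cry",
    "static",
)

#: Pitch shift applied to the low-pitched infant cry to construct the
#: high-pitched variant (Hz).
PITCH_SHIFT_HZ: float = 200.0

#: Fundamental frequency of each voiced stimulus (Hz); the static-noise
#: control has no fundamental.  The high-pitched cry is the low-pitched cry
#: shifted up by ``PITCH_SHIFT_HZ``.
_BASE_FREQUENCIES: dict[str, float | None] = {
    "adult_laughter": 348.9,
    "infant_laughter": 331.2,
    "infant_cry_low": 354.3,
    "adult_cry": 318.2,
    "static": None,
}


def high_pitched_cry_frequency() -> float:
    """Frequency of the high-pitched infant cry, built by pitch-shifting
    the low-pitched cry up by 200 Hz."""
    return _BASE_FREQUENCIES["infant_cry_low"] + PITCH_SHIFT_HZ


STIMULUS_FREQUENCIES: dict[str, float | None] = {
    **_BASE_FREQUENCIES,
    "infant_cry_high": high_pitched_cry_frequency(),
}

REGIONS: tuple[str, ...] = ("SFG", "MFG", "IFG", "aPFC")
HEMISPHERES: tuple[str, ...] = ("left", "right")
CONDITIONS: tuple[str, ...] = ("TOG", "SEP")
ROLES: tuple[str, ...] = ("mother", "father")
SIGNAL_KINDS: tuple[str, ...] = ("raw_intensity_2wavelength", "optical_density", "oxyhb")

N_CHANNELS = 20
N_SOURCES = 8
N_DETECTORS = 7


# --------------------------------------------------------------------------
# Montage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MontageChannel:
    channel_id: int
    source_id: int
    detector_id: int
    region: str
    hemisphere: str
    distance_cm: float = 3.0


@dataclass(frozen=True)
class Montage:
    """20-channel prefrontal source-detector layout with region labels.

    Channels pair one of 8 sources with one of 7 detectors and carry a
    cortical-region label (SFG, MFG, IFG or aPFC) and hemisphere.
    """

    channels: tuple[MontageChannel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise ValidationError(f"montage must have exactly {N_CHANNELS} channels, got {len(self.channels)}")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("channel ids must be unique")
        for c in self.channels:
            if not (1 <= c.channel_id <= N_CHANNELS):
                raise ValidationError(f"channel id {c.channel_id} outside 1..{N_CHANNELS}")
            if not (1 <= c.source_id <= N_SOURCES):
                raise ValidationError(f"channel {c.channel_id}: source {c.source_id} outside 1..{N_SOURCES}")
            if not (1 <= c.detector_id <= N_DETECTORS):
                raise ValidationError(f"channel {c.channel_id}: detector {c.detector_id} outside 1..{N_DETECTORS}")
            if c.region not in REGIONS:
                raise ValidationError(f"channel {c.channel_id}: unknown region {c.region!r}")
            if c.hemisphere not in HEMISPHERES:
                raise ValidationError(f"channel {c.channel_id}: unknown hemisphere {c.hemisphere!r}")
            if c.distance_cm <= 0:
                raise ValidationError(f"channel {c.channel_id}: non-positive source-detector distance")

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    def region_of(self, channel_id: int) -> str:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c.region
        raise KeyError(channel_id)

    def label_of(self, channel_id: int) -> str:
        """Human-readable area label, e.g. 'left IFG'."""
        for c in self.channels:
            if c.channel_id == channel_id:
                return f"{c.hemisphere} {c.region}"
        raise KeyError(channel_id)


def _data_path(name: str):
    return importlib.resources.files("dyadsync").joinpath("data", name)


def default_montage() -> Montage:
    """The packaged 20-channel prefrontal montage (8 sources, 7 detectors)."""
    with importlib.resources.as_file(_data_path("montage.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    channels = tuple(
        MontageChannel(
            channel_id=int(r.channel_id),
            source_id=int(r.source_id),
            detector_id=int(r.detector_id),
            region=str(r.region),
            hemisphere=str(r.hemisphere),
            distance_cm=float(r.distance_cm),
        )
        for r in df.itertuples()
    )
    return Montage(channels=channels)


def load_extinction_table() -> pd.DataFrame:
    """Molar extinction coefficients of oxy- and deoxy-hemoglobin.

    Returns a frame indexed by wavelength (nm) with columns ``ext_hbo`` and
    ``ext_hbr`` in cm^-1 mM^-1 (compiled literature values).
    """
    with importlib.resources.as_file(_data_path("extinction.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("wavelength_nm")


# --------------------------------------------------------------------------
# Event schedule
# --------------------------------------------------------------------------

STIMULUS_DURATION_S = 15.0
ISI_S = 10.0
N_TRIALS = 3
N_EVENTS = len(STIMULI) * N_TRIALS  # 18
SESSION_SPAN_S = N_EVENTS * STIMULUS_DURATION_S + (N_EVENTS - 1) * ISI_S  # 440 s


@dataclass(frozen=True)
class EventSchedule:
    """The auditory protocol: 6 stimuli x 3 trials, 15 s each, >= 10 s ISI.

    ``events`` is a DataFrame with columns stimulus_id, trial_index,
    onset (s), duration (s), sorted by onset.
    """

    events: pd.DataFrame
    strict: bool = True

    def __post_init__(self) -> None:
        ev = self.events
        required = {"stimulus_id", "trial_index", "onset", "duration"}
        missing = required - set(ev.columns)
        if missing:
            raise ValidationError(f"event table missing columns: {sorted(missing)}")
        if not ev["onset"].is_monotonic_increasing or ev["onset"].duplicated().any():
            raise ValidationError("event onsets must be strictly increasing")
        ends = ev["onset"] + ev["duration"]
        gaps = ev["onset"].to_numpy()[1:] - ends.to_numpy()[:-1]
        if (gaps < -1e-9).any():
            raise ValidationError("events overlap")
        unknown = set(ev["stimulus_id"]) - set(STIMULI)
        if unknown:
            raise ValidationError(f"unknown stimulus ids: {sorted(unknown)}")
        if not ev["trial_index"].isin(range(1, N_TRIALS + 1)).all():
            raise ValidationError(f"trial_index must be in 1..{N_TRIALS}")
        problems = []
        if len(ev) != N_EVENTS:
            problems.append(f"expected {N_EVENTS} events, got {len(ev)}")
        if not np.allclose(ev["duration"], STIMULUS_DURATION_S):
            problems.append(f"expected all durations {STIMULUS_DURATION_S} s")
        if (gaps < ISI_S - 1e-9).any():
            problems.append(f"inter-stimulus interval below {ISI_S} s")
        if problems:
            msg = "; ".join(problems)
            if self.strict:
                raise ValidationError(msg)
            logger.warning("event schedule deviates from the protocol: %s", msg)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def span_s(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset"] + last["duration"])


def read_events(path: str | Path, strict: bool = True) -> EventSchedule:
    """Read an event schedule from a TSV with columns
    stimulus_id, trial_index, onset, duration."""
    df = pd.read_csv(path, sep="\t")
    return EventSchedule(events=df.sort_values("onset").reset_index(drop=True), strict=strict)


def write_events(schedule: EventSchedule, path: str | Path) -> None:
    schedule.events.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Recording / DyadSession
# --------------------------------------------------------------------------

_KIND_LABELS = {
    "raw_intensity_2wavelength": ("wl760", "wl850"),
    "optical_density": ("od760", "od850"),
    "oxyhb": ("oxy", "deoxy"),
}


@dataclass
class Recording:
    """One subject's multi-channel fNIRS time-series on a shared time base.

    ``data`` maps a chromophore/wavelength label ('wl760', 'oxy', ...) to an
    array of shape (n_channels, n_samples).  A rejected channel stays
    present with all-NaN samples so per-channel N can shrink downstream.
    """

    subject_id: str
    role: str
    condition: str
    sampling_rate: float
    signal_kind: str
    data: dict[str, np.ndarray]
    channel_ids: list[int]
    channel_gains: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(f"unknown signal kind {self.signal_kind!r}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        lengths = {arr.shape for arr in self.data.values()}
        if len(lengths) > 1:
            raise ValidationError(f"inconsistent array shapes across chromophores: {lengths}")
        for label, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[0] != len(self.channel_ids):
                raise ValidationError(
                    f"{label}: expected shape (n_channels={len(self.channel_ids)}, n_samples), got {arr.shape}"
                )
        if self.channel_gains is not None:
            self.channel_gains = np.asarray(self.channel_gains, dtype=float)
            if self.channel_gains.shape != (len(self.channel_ids),):
                raise ValidationError("channel_gains must have one entry per channel")

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "Recording":
        return replace(self, data={k: v.copy() for k, v in self.data.items()},
                       channel_gains=None if self.channel_gains is None else self.channel_gains.copy())


_COLUMN_RE = re.compile(r"^ch(?P<ch>\d+)_(?P<label>[a-z0-9]+)$")


def write_timeseries(rec: Recording, path: str | Path) -> None:
    """Write a recording as a wide TSV: a time column plus one column per
    channel x chromophore named ``ch<k>_<label>``.  Gains go in a '#' header."""
    cols: dict[str, np.ndarray] = {"time": rec.times()}
    for label, arr in rec.data.items():
        for i, ch in enumerate(rec.channel_ids):
            cols[f"ch{ch}_{label}"] = arr[i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id} role={rec.role} condition={rec.condition}"
                 f" signal_kind={rec.signal_kind}\n")
        if rec.channel_gains is not None:
            gains = " ".join(f"{ch}:{g:g}" for ch, g in zip(rec.channel_ids, rec.channel_gains))
            fh.write(f"# gains {gains}\n")
        # %.17g guarantees float64 round-trips value-exactly through text
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g", na_rep="nan")


def read_timeseries(path: str | Path, signal_kind: str | None = None) -> Recording:
    """Read a wide delimited time-series table into a :class:`Recording`.

    The header row names columns ``ch<k>_<label>``; ``#`` comment lines may
    carry subject metadata and per-channel gains.  Missing cells become NaN.
    """
    meta: dict[str, str] = {}
    gains: dict[int, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("gains"):
                for tok in body.split()[1:]:
                    ch, g = tok.split(":")
                    gains[int(ch)] = float(g)
            else:
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")

    if "time" not in df.columns:
        raise FormatError("time-series table must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if (dt <= 0).any():
            raise DataError("time column must be strictly increasing")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = float(meta.get("sampling_rate", 1.0))

    parsed: dict[str, dict[int, np.ndarray]] = {}
    for col in df.columns:
        if col == "time":
            continue
        m = _COLUMN_RE.match(col)
        if m is None:
            raise FormatError(f"cannot parse column name {col!r}: expected ch<id>_<label>")
        parsed.setdefault(m["label"], {})[int(m["ch"])] = df[col].to_numpy(dtype=float)

    channel_ids = sorted({ch for chans in parsed.values() for ch in chans})
    data = {}
    n = len(t)
    for label, chans in parsed.items():
        arr = np.full((len(channel_ids), n), np.nan)
        for i, ch in enumerate(channel_ids):
            if ch in chans:
                arr[i] = chans[ch]
        data[label] = arr

    kind = signal_kind or meta.get("signal_kind")
    if kind is None:
        labels = set(parsed)
        for k, lbls in _KIND_LABELS.items():
            if labels <= set(lbls):
                kind = k
                break
        else:
            raise FormatError(f"cannot infer signal kind from column labels {sorted(labels)}")

    gains_arr = None
    if gains:
        gains_arr = np.array([gains.get(ch, np.nan) for ch in channel_ids])
    return Recording(
        subject_id=meta.get("subject_id", Path(path).stem),
        role=meta.get("role", "mother"),
        condition=meta.get("condition", "TOG"),
        sampling_rate=fs,
        signal_kind=kind,
        data=data,
        channel_ids=channel_ids,
        channel_gains=gains_arr,
    )


@dataclass
class DyadSession:
    """Paired mother/father recordings for one condition plus the schedule."""

    dyad_id: str
    mother: Recording
    father: Recording
    schedule: EventSchedule
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        for rec in (self.mother, self.father):
            if rec.condition != self.condition:
                raise ValidationError(
                    f"recording {rec.subject_id} condition {rec.condition} != session {self.condition}"
                )
        if not np.isclose(self.mother.sampling_rate, self.father.sampling_rate):
            raise ValidationError("partners must share a sampling rate")
        if self.mother.role != "mother" or self.father.role != "father":
            raise ValidationError("recordings assigned to wrong roles")


def read_study(directory: str | Path, strict_events: bool = True) -> list[DyadSession]:
    """Load every session from a study directory.

    Expects, per (dyad, condition), the files ``<dyad>_<COND>_mother.tsv``,
    ``<dyad>_<COND>_father.tsv`` and ``<dyad>_<COND>_events.tsv``.
    """
    directory = Path(directory)
    sessions = []
    for events_path in sorted(directory.glob("*_events.tsv")):
        stem = events_path.name[: -len("_events.tsv")]
        dyad_id, condition = stem.rsplit("_", 1)
        schedule = read_events(events_path, strict=strict_events)
        mother = read_timeseries(directory / f"{stem}_mother.tsv")
        father = read_timeseries(directory / f"{stem}_father.tsv")
        sessions.append(DyadSession(dyad_id=dyad_id, mother=mother, father=father,
                                    schedule=schedule, condition=condition))
    if not sessions:
        raise FormatError(f"no '*_events.tsv' session files found in {directory}")
    return sessions


# --------------------------------------------------------------------------
# Covariates
# --------------------------------------------------------------------------

RATIO_SCORES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class CovariateRecord:
    """Per-couple demographics: ages, parity and parent-ratio scores.

    The ratio score codes who typically takes the lead in attending to the
    child, from 0 (father always) to 1 (mother always), in steps of 0.2;
    the couple-level score is the mean of the two partners' answers.
    """

    dyad_id: str
    mother_age: float
    father_age: float
    parity: str  # primiparous | multiparous
    mother_ratio_score: float
    father_ratio_score: float

    def __post_init__(self) -> None:
        if self.parity not in ("primiparous", "multiparous"):
            raise ValidationError(f"unknown parity {self.parity!r}")
        for score in (self.mother_ratio_score, self.father_ratio_score):
            if not any(np.isclose(score, s) for s in RATIO_SCORES):
                raise ValidationError(f"ratio score {score} not among {RATIO_SCORES}")

    @property
    def average_parent_ratio(self) -> float:
        return (self.mother_ratio_score + self.father_ratio_score) / 2.0


def write_covariates(records: Sequence[CovariateRecord], path: str | Path) -> None:
    rows = [
        {
            "dyad_id": r.dyad_id,
            "mother_age": r.mother_age,
            "father_age": r.father_age,
            "parity": r.parity,
            "mother_ratio_score": r.mother_ratio_score,
            "father_ratio_score": r.father_ratio_score,
            "average_parent_ratio": r.average_parent_ratio,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> list[CovariateRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for r in df.itertuples():
        rec = CovariateRecord(
            dyad_id=str(r.dyad_id),
            mother_age=float(r.mother_age),
            father_age=float(r.father_age),
            parity=str(r.parity),
            mother_ratio_score=float(r.mother_ratio_score),
            father_ratio_score=float(r.father_ratio_score),
        )
        if hasattr(r, "average_parent_ratio") and not np.isclose(
            rec.average_parent_ratio, float(r.average_parent_ratio)
        ):
            raise ValidationError(
                f"dyad {rec.dyad_id}: stored average_parent_ratio inconsistent with individual scores"
            )
        records.append(rec)
    return records


# --------------------------------------------------------------------------
# Analysis configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the study defaults."""

    alpha: float = 0.05
    n_channels_tested: int = 20
    max_lag_s: float = 2.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.2
    filter_order: int = 3
    gain_threshold: float = 8.0
    cv_threshold: float = 7.5  # percent
    spike_mad_k: float = 5.0
    step_mad_k: float = 8.0
    max_spike_width: int = 3
    dpf: float = 6.0
    distance_cm: float = 3.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0.0 < self.band_low_hz < self.band_high_hz):
            raise ValidationError("filter band must satisfy 0 < low < high")
        if self.max_lag_s <= 0:
            raise ValidationError("max_lag_s must be positive")

    def validate_for_rate(self, fs: float) -> None:
        if self.band_high_hz >= fs / 2:
            raise ValidationError(f"band high {self.band_high_hz} Hz >= Nyquist {fs / 2} Hz")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
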