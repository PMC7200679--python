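"""The synchrony index: maximum lagged cross-correlation within +/-2 s (MCC2).

Partners' oxy-Hb series are cut into 15 s stimulus epochs; for each epoch
pair the normalized (Pearson) correlation is evaluated at every
integer-sample lag within the +/-2 s window (lags -15..+15 at 7.81 Hz, the
realizable grid closest to a 0.125 s step) and the signed maximum is kept.
Per-trial values are averaged across the (up to) three trials of a
stimulus.  Randomly re-paired mother-father "control dyads" — a fresh
derangement per (stimulus, channel, condition) — provide the couple-
specific null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    CONDITIONS,
    N_TRIALS,
    STIMULI,
    STIMULUS_DURATION_S,
    AnalysisConfig,
    DyadSession,
    ValidationError,
    get_logger,
)

__all__ = [
    "EpochSet",
    "PairingScheme",
    "extract_epochs",
    "compute_mcc2",
    "mcc2_many",
    "average_trials",
    "make_control_pairs",
    "build_synchrony_table",
    "write_synchrony_table",
    "read_synchrony_table",
]

logger = get_logger()

SYNCHRONY_COLUMNS = [
    "dyad_id", "condition", "channel", "stimulus",
    "mcc2", "best_lag_s", "n_trials_used", "pairing",
]


@dataclass
class EpochSet:
    """Stimulus-locked epochs for one subject.

    ``epochs`` has shape (n_channels, n_stimuli, n_trials, epoch_len),
    indexed by channel order, stimulus catalogue order and trial index;
    ``valid`` flags epochs that exist and belong to surviving channels.
    Epochs are demeaned at extraction.
    """

    subject_id: str
    epochs: np.ndarray
    valid: np.ndarray
    channel_keep: np.ndarray
    channel_ids: list[int]
    sampling_rate: float

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[-1]


def extract_epochs(
    session: DyadSession,
    channel_mask: dict[str, np.ndarray] | None = None,
) -> tuple[EpochSet, EpochSet]:
    """Cut both partners' oxy-Hb series into 15 s stimulus epochs.

    ``channel_mask`` optionally maps subject_id to a boolean keep-mask; by
    default a channel is kept when its samples are all finite (rejected
    channels arrive as all-NaN from preprocessing).  An event whose epoch
    would run past the end of the recording yields an invalid epoch.
    """
    out = []
    for rec in (session.mother, session.father):
        if "oxy" not in rec.data:
            raise ValidationError(
                f"recording {rec.subject_id} has no oxy-Hb channel data; preprocess first"
            )
        fs = rec.sampling_rate
        L = int(np.floor(STIMULUS_DURATION_S * fs))
        oxy = rec.data["oxy"]
        n_ch = oxy.shape[0]
        if channel_mask is not None and rec.subject_id in channel_mask:
            keep = np.asarray(channel_mask[rec.subject_id], dtype=bool)
        else:
            keep = np.isfinite(oxy).all(axis=1)
        epochs = np.full((n_ch, len(STIMULI), N_TRIALS, L), np.nan)
        valid = np.zeros((n_ch, len(STIMULI), N_TRIALS), dtype=bool)
        for ev in session.schedule.events.itertuples():
            s = STIMULI.index(ev.stimulus_id)
            t = int(ev.trial_index) - 1
            i0 = int(round(ev.onset * fs))
            if i0 + L > rec.n_samples:
                logger.warning("%s: event %s trial %d at %.1f s runs past the recording end; "
                               "epoch dropped", rec.subject_id, ev.stimulus_id,
                               ev.trial_index, ev.onset)
                continue
            seg = oxy[:, i0:i0 + L]
            epochs[:, s, t, :] = seg - seg.mean(axis=1, keepdims=True)
            valid[:, s, t] = keep & np.isfinite(seg).all(axis=1)
        epochs[~valid] = np.nan
        out.append(EpochSet(subject_id=rec.subject_id, epochs=epochs, valid=valid,
                            channel_keep=keep, channel_ids=list(rec.channel_ids),
                            sampling_rate=fs))
    return out[0], out[1]


def _lag_range(fs: float, max_lag_s: float) -> np.ndarray:
    max_shift = int(np.floor(max_lag_s * fs))
    return np.arange(-max_shift, max_shift + 1)


def mcc2_many(
    A: np.ndarray,
    B: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """MCC2 for a batch of epoch pairs (rows of A against rows of B).

    For each integer-sample lag ``l`` in the window, the overlapping
    segments ``A[:, :n-l]`` and ``B[:, l:]`` (and mirrored for negative
    lags) are demeaned and Pearson-correlated; the signed maximum over
    lags and its lag (seconds; positive = B delayed relative to A) are
    returned.  Pairs with a constant overlap at every lag come back NaN.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ValidationError(f"epoch batches must share a shape: {A.shape} vs {B.shape}")
    m, n = A.shape
    lags = _lag_range(fs, max_lag_s)
    if n <= lags.max() + 1:
        raise ValidationError("epochs shorter than the lag window")
    corr = np.full((m, lags.size), np.nan)
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = A[:, : n - lag], B[:, lag:]
        else:
            a, b = A[:, -lag:], B[:, : n + lag]
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        va = np.einsum("ij,ij->i", a, a)
        vb = np.einsum("ij,ij->i", b, b)
        ok = (va > 0) & (vb > 0)
        num = np.einsum("ij,ij->i", a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = num / np.sqrt(va * vb)
        corr[ok, k] = c[ok]

    any_ok = np.isfinite(corr).any(axis=1)
    mcc2 = np.full(m, np.nan)
    best_lag = np.full(m, np.nan)
    if any_ok.any():
        filled = np.where(np.isfinite(corr), corr, -np.inf)
        idx = filled.argmax(axis=1)  # first maximum -> most negative lag on ties
        mcc2[any_ok] = filled[any_ok, idx[any_ok]]
        best_lag[any_ok] = lags[idx[any_ok]] / fs
    return mcc2, best_lag


def compute_mcc2(
    epoch_a: np.ndarray,
    epoch_b: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
) -> tuple[float, float]:
    """MCC2 between two epochs: (signed max correlation, best lag in s).

    Positive lag means ``epoch_b`` is delayed relative to ``epoch_a``.
    A constant epoch has no defined correlation and yields (nan, nan).
    """
    mcc2, lag = mcc2_many(epoch_a[None, :], epoch_b[None, :], fs, max_lag_s)
    return float(mcc2[0]), float(lag[0])


def average_trials(per_trial: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of the valid per-trial MCC2 values.

    Returns (mean, n_trials_used); all-missing input yields (nan, 0).
    """
    x = np.asarray(per_trial, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        return float("nan"), 0
    return float(x[ok].mean()), int(ok.sum())


@dataclass(frozen=True)
class PairingScheme:
    """Mother->father assignment; control schemes are derangements of the
    true pairing (no mother keeps her own spouse)."""

    pairs: tuple[tuple[str, str], ...]
    pairing: str  # "true" | "control"
    seed: int | None = None

    def __post_init__(self) -> None:
        mothers = [m for m, _ in self.pairs]
        fathers = [f for _, f in self.pairs]
        if len(set(mothers)) != len(mothers) or len(set(fathers)) != len(fathers):
            raise ValidationError("each parent must appear exactly once in a scheme")
        if self.pairing == "control" and any(m == f for m, f in self.pairs):
            raise ValidationError("control scheme reproduces a true couple")


def make_control_pairs(dyad_ids: list[str], seed: int | np.random.Generator) -> PairingScheme:
    """Seeded random derangement of fathers against mothers.

    Rejection-sample uniform permutations until none maps a mother to her
    own spouse, which draws uniformly from the derangements.
    """
    if len(dyad_ids) < 2:
        raise ValidationError("need at least 2 dyads to build control pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = np.asarray(dyad_ids)
    while True:
        perm = rng.permutation(len(ids))
        if not np.any(perm == np.arange(len(ids))):
            break
    pairs = tuple((str(m), str(f)) for m, f in zip(ids, ids[perm]))
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    return PairingScheme(pairs=pairs, pairing="control", seed=seed_val)


def _epoch_index(sessions: list[DyadSession],
                 channel_mask: dict[str, np.ndarray] | None) -> dict:
    """(dyad_id, condition) -> (mother EpochSet, father EpochSet)."""
    index = {}
    for s in sessions:
        index[(s.dyad_id, s.condition)] = extract_epochs(s, channel_mask)
    return index


def build_synchrony_table(
    sessions: list[DyadSession],
    config: AnalysisConfig | None = None,
    channel_mask: dict[str, np.ndarray] | None = None,
    n_control: int = 1,
    control_seed: int | None = None,
) -> pd.DataFrame:
    """Trial-averaged MCC2 for every (dyad, condition, channel, stimulus).

    True-pair rows are computed for each session; control rows re-pair
    mothers with non-spouse fathers using an independent derangement per
    (stimulus, channel, condition), ``n_control`` times.  A row exists
    only when both partners' channels survived QC for at least one trial;
    rows where no trial was valid carry a missing mcc2.
    """
    config = config or AnalysisConfig()
    if control_seed is None:
        control_seed = config.random_seed
    index = _epoch_index(sessions, channel_mask)
    conditions = sorted({c for _, c in index}, key=CONDITIONS.index)
    dyads = sorted({d for d, _ in index})

    rows: list[dict] = []
    batch_a, batch_b, meta = [], [], []

    def _flush() -> None:
        if not batch_a:
            return
        fs = sessions[0].mother.sampling_rate
        mcc2, lag = mcc2_many(np.array(batch_a), np.array(batch_b), fs, config.max_lag_s)
        per_key: dict[tuple, list] = {}
        for (key, _), m_val, l_val in zip(meta, mcc2, lag):
            per_key.setdefault(key, []).append((m_val, l_val))
        for key, vals in per_key.items():
            dyad_id, condition, channel, stimulus, pairing = key
            trial_vals = np.array([v for v, _ in vals])
            mean, n_used = average_trials(trial_vals)
            best = np.nan
            if n_used:
                finite = [(v, l) for v, l in vals if np.isfinite(v)]
                best = max(finite)[1]
            rows.append({
                "dyad_id": dyad_id, "condition": condition, "channel": channel,
                "stimulus": stimulus, "mcc2": mean, "best_lag_s": best,
                "n_trials_used": n_used, "pairing": pairing,
            })
        batch_a.clear()
        batch_b.clear()
        meta.clear()

    def _queue(mother_set: EpochSet, father_set: EpochSet, ch_i: int, s_i: int,
               key: tuple) -> bool:
        queued = False
        for t in range(N_TRIALS):
            if mother_set.valid[ch_i, s_i, t] and father_set.valid[ch_i, s_i, t]:
                batch_a.append(mother_set.epochs[ch_i, s_i, t])
                batch_b.append(father_set.epochs[ch_i, s_i, t])
                meta.append((key, t))
                queued = True
        return queued

    rng = np.random.default_rng(control_seed)
    n_channels = next(iter(index.values()))[0].epochs.shape[0]
    empty_rows: list[dict] = []
    for condition in conditions:
        avail = [d for d in dyads if (d, condition) in index]
        for ch_i in range(n_channels):
            channel = ch_i + 1
            for s_i, stimulus in enumerate(STIMULI):
                for dyad_id in avail:
                    mset, fset = index[(dyad_id, condition)]
                    # a dyad whose channel failed QC for either partner
                    # contributes no row at all for that channel
                    if not (mset.channel_keep[ch_i] and fset.channel_keep[ch_i]):
                        continue
                    key = (dyad_id, condition, channel, stimulus, "true")
                    if not _queue(mset, fset, ch_i, s_i, key):
                        empty_rows.append({
                            "dyad_id": dyad_id, "condition": condition,
                            "channel": channel, "stimulus": stimulus,
                            "mcc2": np.nan, "best_lag_s": np.nan,
                            "n_trials_used": 0, "pairing": "true",
                        })
                for _ in range(n_control):
                    if len(avail) < 2:
                        continue
                    scheme = make_control_pairs(avail, rng)
                    for m_dyad, f_dyad in scheme.pairs:
                        mset, _ = index[(m_dyad, condition)]
                        _, fset = index[(f_dyad, condition)]
                        if not (mset.channel_keep[ch_i] and fset.channel_keep[ch_i]):
                            continue
                        key = (f"{m_dyad}x{f_dyad}", condition, channel, stimulus, "control")
                        _queue(mset, fset, ch_i, s_i, key)
    _flush()
    rows.extend(empty_rows)
    table = pd.DataFrame(rows, columns=SYNCHRONY_COLUMNS)
    bad = table["mcc2"].abs() > 1 + 1e-9
    if bad.any():
        raise AssertionError("mcc2 outside [-1, 1]")
    logger.info("synchrony table: %d rows (%d true, %d control)",
                len(table), (table.pairing == "true").sum(), (table.pairing == "control").sum())
    return table


def write_synchrony_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_synchrony_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
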