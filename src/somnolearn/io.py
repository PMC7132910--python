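"""Data model and I/O for sleep-conditioning polysomnography studies.

The study data model covers one participant-night of polysomnography
(two EEG channels C3/C4 referenced to opposite mastoids, a nasal airflow
channel, all sampled at a common rate), a table of tone events with
condition labels, and sleep-stage / arousal annotations.  This module
reads and writes the interchange formats (EDF for signals, TSV for event
tables and annotations, HDF5 for epoch containers), cuts trial-locked
epochs, applies every trial- and participant-level inclusion rule, and
splits trials into early/late training phases.

Conventions
-----------
* EEG is held in microvolts, airflow in litres/minute.
* Time within an epoch is milliseconds relative to tone onset; the epoch
  window is end-inclusive, so the default (-5500, +5000) ms window at
  1 kHz has 10 501 samples.
* A trial, once excluded, keeps its first exclusion reason; re-applying
  any rejection rule is a no-op (exclusion is idempotent).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

EEG_CHANNELS = ("C3", "C4")
AIRFLOW_CHANNEL = "airflow"

#: canonical epoch window (ms relative to tone onset), end-inclusive
EPOCH_WINDOW_MS = (-5500, 5000)

EVENT_COLUMNS = ["onset_s", "tone_hz", "condition", "reinforced", "block", "session"]
CONDITIONS = ("CSu", "CSp", "novel")
SESSIONS = ("night", "retention")
STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")

EXCLUSION_REASONS = ("edge", "artifact", "arousal", "stage", "reinforced")


class EventValidationError(ValueError):
    """An event table violates the experimental-design invariants."""


class FormatError(ValueError):
    """A signal file does not contain the expected channels/structure."""


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def validate_events(frame: pd.DataFrame, strict_blocks: bool = True) -> pd.DataFrame:
    """Validate an event table against the experimental-design invariants.

    Night blocks hold six trials: four reinforced (two per odor valence)
    and two non-reinforced, one per conditioned tone.  Onsets must be
    strictly increasing within a session.  Violations raise
    :class:`EventValidationError` naming the offending rows.

    Parameters
    ----------
    frame
        Table with columns ``onset_s, tone_hz, condition, reinforced,
        block, session``.
    strict_blocks
        Enforce the 4+2 block composition for night blocks.  Disable for
        partial tables (e.g. a truncated night).
    """
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise EventValidationError(f"missing required columns: {missing}")
    frame = frame.copy()
    frame["reinforced"] = frame["reinforced"].astype(bool)
    frame["block"] = frame["block"].astype(int)

    bad_cond = ~frame["condition"].isin(CONDITIONS)
    if bad_cond.any():
        rows = frame.index[bad_cond].tolist()
        raise EventValidationError(
            f"unknown condition label(s) {sorted(frame.loc[bad_cond, 'condition'].unique())} "
            f"in rows {rows}"
        )
    bad_sess = ~frame["session"].isin(SESSIONS)
    if bad_sess.any():
        raise EventValidationError(
            f"unknown session label(s) in rows {frame.index[bad_sess].tolist()}"
        )
    for sess, sub in frame.groupby("session"):
        onsets = sub["onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            row = sub.index[1:][np.diff(onsets) <= 0][0]
            raise EventValidationError(
                f"event onsets not strictly increasing in session {sess!r} at row {row}"
            )
    if strict_blocks:
        night = frame[frame["session"] == "night"]
        for blk, sub in night.groupby("block"):
            n_reinf = int(sub["reinforced"].sum())
            n_non = int((~sub["reinforced"]).sum())
            if len(sub) != 6 or n_reinf != 4 or n_non != 2:
                raise EventValidationError(
                    f"night block {blk} has {len(sub)} trials "
                    f"({n_reinf} reinforced + {n_non} non-reinforced); expected 6 = 4 + 2"
                )
            non = sub[~sub["reinforced"]]
            if non["tone_hz"].nunique() != 2:
                raise EventValidationError(
                    f"night block {blk}: the two non-reinforced trials must use "
                    f"distinct tones, got {non['tone_hz'].tolist()}"
                )
    return frame


def read_events(path, strict_blocks: bool = True) -> pd.DataFrame:
    """Read a TSV event table and validate it.

    Unknown extra columns are preserved.  An empty file yields an empty
    table with the canonical columns and logs a warning.
    """
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame()
    if frame.empty:
        warnings.warn(f"event file {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return validate_events(frame, strict_blocks=strict_blocks)


def write_events(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One participant-night of continuous polysomnography.

    ``signals`` is channels x samples; EEG channels in microvolts,
    airflow in litres/minute.  ``arousals`` is a list of (onset_s,
    offset_s); ``stages`` a list of (onset_s, offset_s, stage) with
    stage in {W, N1, N2, N3, REM}.
    """

    participant_id: str
    signals: np.ndarray
    channel_names: list[str]
    fs: float
    events: pd.DataFrame
    arousals: list[tuple[float, float]] = field(default_factory=list)
    stages: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.channel_names):
            raise ValueError("signals must be (n_channels, n_samples)")
        dur = self.duration_s
        for on, off in self.arousals:
            if not (0 <= on <= off <= dur + 1e-9):
                raise ValueError(f"arousal interval ({on}, {off}) outside recording")
        for on, off, st in self.stages:
            if st not in STAGES:
                raise ValueError(f"unknown sleep stage {st!r}")
            if not (0 <= on <= off <= dur + 1e-9):
                raise ValueError(f"stage interval ({on}, {off}) outside recording")

    @property
    def duration_s(self) -> float:
        return self.signals.shape[1] / self.fs

    def channel(self, name: str) -> np.ndarray:
        key = name.lower()
        for i, ch in enumerate(self.channel_names):
            if ch.lower() == key:
                return self.signals[i]
        raise KeyError(name)

    def stage_at(self, t_s: float) -> str | None:
        for on, off, st in self.stages:
            if on <= t_s < off:
                return st
        return None

    def require_eeg(self) -> None:
        have = {c.lower() for c in self.channel_names}
        missing = [c for c in EEG_CHANNELS if c.lower() not in have]
        if missing:
            raise FormatError(f"recording lacks EEG channel(s): {missing}")


# ---------------------------------------------------------------------------
# EDF reading/writing
# ---------------------------------------------------------------------------
# Reading goes through MNE; writing uses a minimal EDF encoder (16-bit,
# one-second data records) so studies round-trip without extra deps.

def write_edf(recording: Recording, path, units: dict[str, str] | None = None) -> None:
    """Write a recording to a plain EDF file (16-bit integer samples).

    Signals are padded with zeros to a whole number of one-second data
    records.  EEG channels carry the physical dimension ``uV`` and
    airflow ``L/min``; values round-trip to within one quantization step
    of the per-channel physical range.
    """
    if units is None:
        units = {AIRFLOW_CHANNEL: "L/min"}
    sig = np.asarray(recording.signals, dtype=float)
    n_ch, n_samp = sig.shape
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = int(np.ceil(n_samp / fs)) if n_samp else 0
    pad = n_rec * fs - n_samp
    if pad:
        sig = np.pad(sig, ((0, 0), (0, pad)))

    phys_min, phys_max, digital = [], [], []
    for x in sig:
        lim = max(np.max(np.abs(x)), 1e-6)
        lo, hi = -lim, lim
        scale = (hi - lo) / 65535.0
        d = np.clip(np.round((x - lo) / scale) - 32768, -32768, 32767).astype("<i2")
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(d)

    def f(val, width):
        s = str(val)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"0".ljust(8)
    hdr += f(f"participant {recording.participant_id}", 80)
    hdr += f("synthetic polysomnography", 80)
    hdr += f("01.01.24", 8) + f("00.00.00", 8)
    hdr += f(256 * (1 + n_ch), 8)
    hdr += b" " * 44
    hdr += f(n_rec, 8) + f(1, 8) + f(n_ch, 4)

    def per_sig(vals, width):
        return b"".join(f(v, width) for v in vals)

    labels = recording.channel_names
    hdr += per_sig(labels, 16)
    hdr += per_sig(["" for _ in labels], 80)
    hdr += per_sig([units.get(ch, "uV") for ch in labels], 8)
    hdr += per_sig([f"{v:.6g}" for v in phys_min], 8)
    hdr += per_sig([f"{v:.6g}" for v in phys_max], 8)
    hdr += per_sig([-32768] * n_ch, 8)
    hdr += per_sig([32767] * n_ch, 8)
    hdr += per_sig(["" for _ in labels], 80)
    hdr += per_sig([fs] * n_ch, 8)
    hdr += per_sig(["" for _ in labels], 32)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())


def read_edf(path, events: pd.DataFrame | None = None,
             arousals=None, stages=None, participant_id: str | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Channel names are matched case-insensitively; EEG channels are
    returned in microvolts regardless of the reader's internal unit
    conventions.  Raises :class:`FormatError` if C3/C4 are absent.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    lower = [n.lower() for n in names]
    for ch in EEG_CHANNELS:
        if ch.lower() not in lower:
            raise FormatError(f"EDF file {path} lacks required channel {ch!r}")
    data = raw.get_data()
    # MNE rescales channels whose physical dimension it recognises (uV -> V);
    # undo that so EEG comes back in microvolts.
    for i in range(len(names)):
        unit = raw._orig_units.get(names[i], "") if hasattr(raw, "_orig_units") else ""
        if str(unit).lower() in ("uv", "µv", "μv", "v"):
            factor = 1e6 if str(unit).lower() != "v" else 1.0
            data[i] = data[i] * factor
    canonical = []
    for n in names:
        if n.lower() in [c.lower() for c in EEG_CHANNELS]:
            canonical.append(n.upper())
        else:
            canonical.append(n)
    if events is None:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return Recording(
        participant_id=participant_id or "unknown",
        signals=data,
        channel_names=canonical,
        fs=float(raw.info["sfreq"]),
        events=events,
        arousals=list(arousals or []),
        stages=list(stages or []),
    )


def write_annotations(recording: Recording, path) -> None:
    """Write arousal and stage annotations as one TSV (onset, offset, label)."""
    rows = [(on, off, "arousal") for on, off in recording.arousals]
    rows += [(on, off, st) for on, off, st in recording.stages]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"]).sort_values(
        "onset_s"
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> tuple[list, list]:
    """Read the annotation TSV back into (arousals, stages)."""
    frame = pd.read_csv(path, sep="\t")
    arousals = [
        (r.onset_s, r.offset_s) for r in frame.itertuples() if r.label == "arousal"
    ]
    stages = [
        (r.onset_s, r.offset_s, r.label) for r in frame.itertuples() if r.label in STAGES
    ]
    return arousals, stages


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Trial-locked EEG windows with labels and inclusion flags.

    ``data`` is trials x channels x time.  ``times_ms`` runs from the
    window start to its end inclusive in steps of 1000/fs ms, with the
    tone-onset sample at exactly 0 ms.  ``events`` carries one row per
    trial (condition, reinforced, block, session, onset_s).  ``phase``
    is assigned only to included non-reinforced night trials.
    """

    participant_id: str
    data: np.ndarray
    times_ms: np.ndarray
    channel_names: list[str]
    fs: float
    events: pd.DataFrame
    included: np.ndarray
    exclusion_reason: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("included", "exclusion_reason", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            events=self.events.copy(),
            included=self.included.copy(),
            exclusion_reason=self.exclusion_reason.copy(),
            phase=self.phase.copy(),
        )

    def mark_excluded(self, mask: np.ndarray, reason: str) -> None:
        """Exclude trials in ``mask`` that are still included (first reason wins)."""
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        fresh = np.asarray(mask, bool) & self.included
        self.included[fresh] = False
        self.exclusion_reason[fresh] = reason
        self.phase[fresh] = "unassigned"

    def included_nonreinforced(self) -> np.ndarray:
        return self.included & ~self.events["reinforced"].to_numpy(bool)

    def decimate(self, factor: int) -> "EpochSet":
        """Low-pass and decimate the epoch data by an integer factor.

        Used to bring 1 kHz epochs to an analysis rate (e.g. 100 Hz) at
        which the per-bin filter bank and permutation machinery run at
        desk scale.  The onset sample stays at 0 ms.
        """
        from scipy.signal import decimate as _dec

        if factor == 1:
            return self.copy()
        onset = int(np.argmin(np.abs(self.times_ms)))
        start = onset % factor
        data = _dec(self.data[:, :, start:], factor, ftype="fir", zero_phase=True, axis=-1)
        times = self.times_ms[start::factor][: data.shape[-1]]
        return replace(
            self,
            data=data,
            times_ms=times,
            fs=self.fs / factor,
            events=self.events.copy(),
            included=self.included.copy(),
            exclusion_reason=self.exclusion_reason.copy(),
            phase=self.phase.copy(),
        )


def epoch(recording: Recording, window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
          channels: tuple[str, ...] = EEG_CHANNELS) -> EpochSet:
    """Cut one end-inclusive epoch per night event, time-locked to tone onset.

    Trials without full window support inside the recording are flagged
    excluded with reason ``edge`` rather than raising.
    """
    recording.require_eeg()
    ev = recording.events
    ev = ev[ev["session"] == "night"].reset_index(drop=True)
    fs = recording.fs
    start_off = int(round(window_ms[0] * fs / 1000.0))
    end_off = int(round(window_ms[1] * fs / 1000.0))
    n_time = end_off - start_off + 1
    times_ms = (np.arange(start_off, end_off + 1)) * 1000.0 / fs

    chans = [recording.channel(c) for c in channels]
    n_samp = recording.signals.shape[1]
    data = np.zeros((len(ev), len(channels), n_time))
    included = np.ones(len(ev), bool)
    reason = np.array([""] * len(ev), dtype=object)
    for i, onset_s in enumerate(ev["onset_s"].to_numpy(float)):
        onset_idx = int(round(onset_s * fs))
        lo, hi = onset_idx + start_off, onset_idx + end_off
        if lo < 0 or hi >= n_samp:
            included[i] = False
            reason[i] = "edge"
            continue
        for j, ch in enumerate(chans):
            data[i, j] = ch[lo:hi + 1]
    phase = np.array(["unassigned"] * len(ev), dtype=object)
    return EpochSet(
        participant_id=recording.participant_id,
        data=data,
        times_ms=times_ms,
        channel_names=list(channels),
        fs=fs,
        events=ev,
        included=included,
        exclusion_reason=reason,
        phase=phase,
    )


def reject_artifacts(epochs: EpochSet, amp_uv: float = 300.0,
                     flat_uv: float = 0.5) -> EpochSet:
    """Mark trials with amplitude artifacts or flat-line EEG as excluded.

    A trial is an artifact if any EEG sample exceeds ``amp_uv`` in
    absolute value on either channel, or if the peak-to-peak amplitude
    over the whole window falls below ``flat_uv`` (dead channel).  An
    amplitude rule is the standard deterministic choice for sleep EEG;
    both thresholds are configurable.
    """
    out = epochs.copy()
    over = np.any(np.abs(out.data) > amp_uv, axis=(1, 2))
    ptp = out.data.max(axis=2) - out.data.min(axis=2)
    flat = np.any(ptp < flat_uv, axis=1)
    out.mark_excluded(over | flat, "artifact")
    return out


def reject_arousal_trials(epochs: EpochSet, recording: Recording,
                          window_s: float = 30.0) -> EpochSet:
    """Exclude trials near wake/arousal and trials outside N2/N3 sleep.

    A trial is dropped (reason ``arousal``) if any arousal interval or
    wake-stage interval intersects [onset - window_s, onset + window_s],
    and dropped with reason ``stage`` if the tone onset does not fall in
    N2 or N3 (REM and unstaged trials are never analysed).
    """
    out = epochs.copy()
    onsets = out.events["onset_s"].to_numpy(float)
    wake = [(on, off) for on, off, st in recording.stages if st == "W"]
    bad_intervals = list(recording.arousals) + wake
    arous = np.zeros(len(onsets), bool)
    for on, off in bad_intervals:
        arous |= (on <= onsets + window_s) & (off >= onsets - window_s)
    out.mark_excluded(arous, "arousal")
    stage_ok = np.array(
        [recording.stage_at(t) in NREM_STAGES for t in onsets], bool
    )
    out.mark_excluded(~stage_ok, "stage")
    return out


def mark_reinforced(epochs: EpochSet) -> EpochSet:
    """Exclude reinforced trials from the EEG analysis stream."""
    out = epochs.copy()
    out.mark_excluded(out.events["reinforced"].to_numpy(bool), "reinforced")
    return out


def include_participants(studies: list[EpochSet], min_trials: int = 10
                         ) -> tuple[list[EpochSet], pd.DataFrame]:
    """Apply the participant-level minimum-trial rule.

    Participants with fewer than ``min_trials`` included (EEG-clean,
    arousal-free, NREM) non-reinforced trials are dropped.  Returns the
    kept studies and a report table with one row per participant
    (participant_id, n_clean_nonreinforced, kept).
    """
    rows, kept = [], []
    for ep in studies:
        n_clean = int(ep.included_nonreinforced().sum())
        ok = n_clean >= min_trials
        rows.append((ep.participant_id, n_clean, ok))
        if ok:
            kept.append(ep)
    report = pd.DataFrame(rows, columns=["participant_id", "n_clean_nonreinforced", "kept"])
    return kept, report


def split_phases(epochs: EpochSet, early_blocks: int = 5) -> EpochSet:
    """Tag included non-reinforced trials as early (block <= 5) or late (>= 6).

    Participants whose night ended before block 6 simply have an empty
    late set and contribute to early-phase analyses only.
    """
    out = epochs.copy()
    blocks = out.events["block"].to_numpy(int)
    nonreinf = out.included_nonreinforced()
    out.phase[:] = "unassigned"
    out.phase[nonreinf & (blocks <= early_blocks)] = "early"
    out.phase[nonreinf & (blocks > early_blocks)] = "late"
    return out


def exclusion_report(epochs: EpochSet) -> pd.DataFrame:
    """Per-trial inclusion ledger (trial index, labels, included, reason, phase)."""
    frame = epochs.events.copy()
    frame["included"] = epochs.included
    frame["exclusion_reason"] = epochs.exclusion_reason
    frame["phase"] = epochs.phase
    frame.insert(0, "participant_id", epochs.participant_id)
    return frame


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    """Store an EpochSet in an HDF5 file with a JSON metadata attribute."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, compression="gzip")
        fh.create_dataset("times_ms", data=epochs.times_ms)
        fh.create_dataset("included", data=epochs.included.astype(np.int8))
        meta = {
            "participant_id": epochs.participant_id,
            "fs": epochs.fs,
            "channel_names": epochs.channel_names,
            "exclusion_reason": list(map(str, epochs.exclusion_reason)),
            "phase": list(map(str, epochs.phase)),
            "events": epochs.events.to_json(orient="split"),
        }
        fh.attrs["meta"] = json.dumps(meta)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh.attrs["meta"])
        events = pd.read_json(__import__("io").StringIO(meta["events"]), orient="split")
        return EpochSet(
            participant_id=meta["participant_id"],
            data=fh["data"][()],
            times_ms=fh["times_ms"][()],
            channel_names=list(meta["channel_names"]),
            fs=float(meta["fs"]),
            events=events,
            included=fh["included"][()].astype(bool),
            exclusion_reason=np.array(meta["exclusion_reason"], dtype=object),
            phase=np.array(meta["phase"], dtype=object),
        )
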