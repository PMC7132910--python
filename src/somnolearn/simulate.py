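"""Synthetic polysomnography studies with planted, recoverable effects.

Generates complete participant-nights — two-channel EEG, nasal airflow,
tone event tables, sleep-stage and arousal annotations — plus a ground
truth object recording every planted quantity, so the whole analysis
chain (epoching, exclusion, time-frequency, cluster inference, sniff
behavior) can be exercised and validated without any real recording.

The emulated design: tones are presented in blocks of six trials (two
reinforced with a pleasant odor, two reinforced with an unpleasant odor,
two non-reinforced, one per conditioned tone), inter-trial onset gaps
uniform in 25-40 s, tone-to-valence mapping counterbalanced across
participants.  EEG is 1/f background plus a continuous slow oscillation
and event-locked band-limited bursts (K-complex-like delta transient,
~1 s sigma spindle, brief theta burst) whose amplitude differs between
conditions by a configurable multiplicative ratio per band and training
phase.  Nasal airflow is tidal breathing whose first post-tone
inhalation is scaled by a condition multiplier that ramps across blocks
(the conditioned sniff response).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Recording

NIGHT_BANDS = ("delta", "theta", "sigma")


@dataclass
class BurstSpec:
    """One event-locked oscillatory burst family.

    ``latency_ms`` is the uniform window for burst onset after the tone;
    ``amp_uv`` the base (CSp) peak amplitude; ``amp_jitter_sd`` the
    log-normal sigma of trial-to-trial multiplicative amplitude noise.
    The burst is a Gaussian-windowed tone (Morlet-style) whose full
    support is ``duration_ms`` = six envelope SDs — the Gaussian window
    keeps the burst's energy confined to its own frequency band, so a
    planted delta effect cannot leak into the theta analysis.
    """

    center_hz: float
    amp_uv: float
    latency_ms: tuple[float, float]
    duration_ms: float
    amp_jitter_sd: float = 0.2

    def window_ms(self) -> tuple[float, float]:
        """Planted-effect support (ms post-tone) at the 5 %-of-peak-power level.

        The burst's power profile is Gaussian with SD sigma/sqrt(2)
        (sigma = duration/6); it exceeds 5 % of its peak within
        +-sqrt(ln 20) of those SDs around the burst center.  The support
        is widened by the uniform onset-latency window.
        """
        sigma_ms = self.duration_ms / 6.0
        half = float(np.sqrt(np.log(20.0)) * sigma_ms / np.sqrt(2.0))
        center = self.duration_ms / 2.0
        return (self.latency_ms[0] + center - half,
                self.latency_ms[1] + center + half)


@dataclass
class SniffConfig:
    """Respiration and conditioned-sniff parameters.

    Volumes are in litres; flow in litres/minute.  The night learning
    effect is a CSp/CSu volume ratio that ramps linearly from
    ``ramp_start_block`` and saturates at ``ramp_saturate_block``.
    Retention-session means are on the normalized (nvu) scale.
    """

    breath_period_s: float = 4.0
    peak_flow_lpm: float = 6.0
    trial_noise_sd: float = 0.1
    night_ratio: float = 1.3
    ramp_start_block: int = 2
    ramp_saturate_block: int = 5
    retention_csu_mean: float = 1.15
    retention_csp_mean: float = 0.95
    retention_novel_mean: float = 1.0
    retention_participant_sd: float = 0.2
    retention_trial_sd: float = 0.1
    retention_repetitions: int = 8

    def night_multipliers(self, block: int) -> tuple[float, float]:
        """(CSp, CSu) volume multipliers for a night block."""
        lo, hi = self.ramp_start_block, self.ramp_saturate_block
        ramp = np.clip((block - lo + 1) / (hi - lo + 1), 0.0, 1.0)
        half = self.night_ratio ** (ramp / 2.0)
        return float(half), float(1.0 / half)


def default_bursts() -> dict[str, BurstSpec]:
    """Event-locked burst families: K-complex-like delta transient, brief
    theta burst, ~1.2 s spindle.  Peak amplitudes are set relative to the
    1/f background's in-band power (burst power a few background SDs), the
    regime in which per-trial z-scoring preserves multiplicative condition
    effects instead of normalising them away."""
    return {
        "delta": BurstSpec(center_hz=1.5, amp_uv=20.0, latency_ms=(200, 500), duration_ms=1800),
        "theta": BurstSpec(center_hz=5.5, amp_uv=3.0, latency_ms=(100, 300), duration_ms=1500),
        "sigma": BurstSpec(center_hz=13.0, amp_uv=1.5, latency_ms=(500, 800), duration_ms=1200),
    }


def default_effects() -> dict[str, dict[str, float]]:
    """CSu/CSp burst-amplitude ratios per band and training phase.

    The default plants the qualitative learning pattern under study:
    delta and sigma condition effects in early training, a theta effect
    only in late training, all with the unpleasant-associated tone (CSu)
    driving the larger response.
    """
    return {
        "delta": {"early": 2.0, "late": 1.0},
        "sigma": {"early": 1.6, "late": 1.0},
        "theta": {"early": 1.0, "late": 1.8},
    }


def null_effects() -> dict[str, dict[str, float]]:
    """Unit ratios everywhere: no planted condition effect (null studies)."""
    return {b: {"early": 1.0, "late": 1.0} for b in NIGHT_BANDS}


@dataclass
class SimConfig:
    """Full study-generation configuration (desk scale by default).

    The default 12 participants x 8 blocks keeps the whole pipeline
    runnable in minutes on one CPU; a full-scale study (43 x 10 at
    1 kHz) is a matter of changing these numbers.
    """

    n_participants: int = 12
    n_blocks: int = 8
    fs: float = 1000.0
    iti_s: tuple[float, float] = (25.0, 40.0)
    lead_in_s: float = 70.0
    tail_s: float = 30.0
    background_exponent: float = 1.5
    background_rms_uv: float = 20.0
    slow_osc_hz: float = 0.8
    slow_osc_amp_uv: float = 15.0
    bursts: dict[str, BurstSpec] = field(default_factory=default_bursts)
    effects: dict[str, dict[str, float]] = field(default_factory=default_effects)
    early_blocks: int = 5
    sniff: SniffConfig = field(default_factory=SniffConfig)
    arousal_rate_per_h: float = 2.0
    artifact_rate_per_h: float = 2.0
    n_low_quality: int = 0
    low_quality_clean_trials: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for rate in (self.arousal_rate_per_h, self.artifact_rate_per_h):
            if rate < 0:
                raise ValueError("nuisance rates must be >= 0")
        for band, per_phase in self.effects.items():
            for phase, ratio in per_phase.items():
                if ratio <= 0:
                    raise ValueError(f"effect ratio for {band}/{phase} must be > 0")


@dataclass
class ParticipantTruth:
    participant_id: str
    events: pd.DataFrame
    tone_map: dict[str, int]
    planted_windows: list[dict]
    arousal_intervals: list[tuple[float, float]]
    artifact_intervals: list[tuple[float, float]]
    sniff_volumes_l: np.ndarray
    sniff_multipliers: np.ndarray


@dataclass
class GroundTruth:
    """Oracle record of everything planted into a synthetic study."""

    participants: list[ParticipantTruth]
    config: SimConfig

    def clean_nonreinforced_counts(self, epoch_window_s=(5.5, 5.0),
                                   arousal_window_s: float = 30.0) -> pd.Series:
        """Brute-force per-participant recount of analysable trials.

        A non-reinforced night trial is clean iff no planted artifact
        intersects its epoch window and no planted arousal falls within
        the arousal exclusion window of its onset.  (All synthetic trials
        are in NREM by construction.)
        """
        counts = {}
        for p in self.participants:
            n = 0
            for row in p.events.itertuples():
                if row.reinforced or row.session != "night":
                    continue
                t = row.onset_s
                art = any(on <= t + epoch_window_s[1] and off >= t - epoch_window_s[0]
                          for on, off in p.artifact_intervals)
                aro = any(on <= t + arousal_window_s and off >= t - arousal_window_s
                          for on, off in p.arousal_intervals)
                if not art and not aro:
                    n += 1
            counts[p.participant_id] = n
        return pd.Series(counts, name="n_clean_nonreinforced")


def _participant_rng(config: SimConfig, idx: int) -> np.random.Generator:
    # fixed per-participant substream: participant i reproducible in isolation
    return np.random.default_rng([int(config.seed), 1000 + idx])


def _tone_map(idx: int) -> dict[str, int]:
    # counterbalanced across participants to within one
    return {"CSp": 1200, "CSu": 400} if idx % 2 == 0 else {"CSp": 400, "CSu": 1200}


def _night_events(config: SimConfig, rng: np.random.Generator,
                  tone_map: dict[str, int]) -> pd.DataFrame:
    rows = []
    t = config.lead_in_s
    for block in range(1, config.n_blocks + 1):
        trials = [("CSp", True), ("CSp", True), ("CSu", True), ("CSu", True),
                  ("CSp", False), ("CSu", False)]
        order = rng.permutation(len(trials))
        for k in order:
            cond, reinf = trials[k]
            # onsets snapped to the sample grid so epoch indexing is exact
            rows.append((round(t * config.fs) / config.fs, tone_map[cond],
                         cond, reinf, block, "night"))
            t += rng.uniform(*config.iti_s)
    return pd.DataFrame(rows, columns=["onset_s", "tone_hz", "condition",
                                       "reinforced", "block", "session"])


def _one_over_f(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    from scipy.fft import irfft, next_fast_len, rfft

    m = next_fast_len(n)  # pad to an FFT-friendly length, then truncate
    white = rng.standard_normal(m)
    spec = rfft(white)
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = irfft(spec * shape, m)[:n]
    return x * (rms / max(np.std(x), 1e-12))


def _burst_waveform(spec: BurstSpec, fs: float, phase: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = max(int(round(spec.duration_ms * fs / 1000.0)), 3)
    t = np.arange(n) / fs
    center = t[-1] / 2.0
    sigma = spec.duration_ms / 1000.0 / 6.0
    envelope = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return envelope * np.sin(2 * np.pi * spec.center_hz * t + phase)


def simulate_sniff_trace(config: SimConfig, airflow: np.ndarray, fs: float,
                         onset_s: float, multiplier: float,
                         min_duration_s: float = 0.2) -> tuple[float, float]:
    """Scale the first post-tone inhalation lobe of ``airflow`` in place.

    Returns (planted_volume_l, lobe_onset_s).  The conditioned sniff is
    modelled as a gain on the first inspiratory (positive-flow) lobe of
    at least ``min_duration_s`` beginning after tone onset; its planted
    volume is the time integral of the scaled lobe (flow in L/min,
    hence the /60).  Call this on the noise-free breathing waveform so
    lobe boundaries are well defined; measurement noise belongs on top.
    """
    n = airflow.size
    min_len = int(round(min_duration_s * fs))
    i = int(round(onset_s * fs))
    while i < n - 1:
        while i < n - 1 and not (airflow[i] <= 0 < airflow[i + 1]):
            i += 1
        start = i + 1
        j = start
        while j < n - 1 and airflow[j + 1] > 0:
            j += 1
        if j - start + 1 >= min_len:
            airflow[start:j + 1] *= multiplier
            volume = float(np.sum(airflow[start:j + 1]) / fs / 60.0)
            return volume, start / fs
        i = j + 1
    return 0.0, onset_s


def inject_nuisance(recording: Recording, config: SimConfig,
                    rng: np.random.Generator,
                    forced_artifact_onsets_s: list[float] | None = None
                    ) -> tuple[Recording, list, list]:
    """Add arousal episodes and high-amplitude artifact transients.

    Arousals are alpha-band bursts plus broadband noise, annotated in
    the recording; artifact transients are +-(400-700) uV slow blobs that
    the amplitude-based trial rejection must catch.  Returns the updated
    recording and the injected (arousal, artifact) interval lists.
    """
    fs = recording.fs
    dur_s = recording.duration_s
    dur_h = dur_s / 3600.0
    n_eeg = 2

    arousals = []
    for _ in range(rng.poisson(config.arousal_rate_per_h * dur_h)):
        on = rng.uniform(0, max(dur_s - 20, 1))
        length = rng.uniform(3.0, 15.0)
        off = min(on + length, dur_s)
        i0, i1 = int(on * fs), int(off * fs)
        t = np.arange(i1 - i0) / fs
        for ch in range(n_eeg):
            recording.signals[ch, i0:i1] += (
                30.0 * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
                + 15.0 * rng.standard_normal(i1 - i0)
            )
        arousals.append((on, off))

    artifact_onsets = [
        rng.uniform(0, max(dur_s - 3, 1))
        for _ in range(rng.poisson(config.artifact_rate_per_h * dur_h))
    ]
    artifact_onsets += list(forced_artifact_onsets_s or [])
    artifacts = []
    n_total = recording.signals.shape[1]
    for on in sorted(artifact_onsets):
        length = rng.uniform(0.5, 2.0)
        i0 = int(round(on * fs))
        i1 = min(i0 + int(round(length * fs)), n_total)
        if i1 <= i0:
            continue
        # rectangular transient, far above the +-300 uV rejection threshold,
        # so interval intersection and amplitude detection coincide exactly
        amp = rng.uniform(450.0, 700.0) * rng.choice([-1, 1])
        for ch in range(n_eeg):
            recording.signals[ch, i0:i1] += amp
        artifacts.append((i0 / fs, (i1 - 1) / fs))

    recording.arousals = sorted(recording.arousals + arousals)
    return recording, arousals, artifacts


def _phase_of_block(block: int, early_blocks: int) -> str:
    return "early" if block <= early_blocks else "late"


def simulate_participant(config: SimConfig, idx: int) -> tuple[Recording, ParticipantTruth]:
    rng = _participant_rng(config, idx)
    tone_map = _tone_map(idx)
    events = _night_events(config, rng, tone_map)
    fs = config.fs
    dur_s = float(np.ceil(events["onset_s"].iloc[-1] + config.tail_s))
    n = int(round(dur_s * fs))

    shared = _one_over_f(n, fs, config.background_exponent,
                         config.background_rms_uv * 0.6, rng)
    eeg = np.stack([
        shared + _one_over_f(n, fs, config.background_exponent,
                             config.background_rms_uv * 0.8, rng)
        for _ in range(2)
    ])
    t_axis = np.arange(n) / fs
    eeg += config.slow_osc_amp_uv * np.sin(
        2 * np.pi * config.slow_osc_hz * t_axis + rng.uniform(0, 2 * np.pi))

    planted_windows = [
        {"band": band, "phase": ph,
         "start_ms": spec.window_ms()[0], "end_ms": spec.window_ms()[1],
         "csu_csp_amp_ratio": config.effects[band][ph]}
        for band, spec in config.bursts.items()
        for ph in ("early", "late")
        if config.effects[band][ph] != 1.0
    ]

    for row in events.itertuples():
        phase = _phase_of_block(row.block, config.early_blocks)
        for band, spec in config.bursts.items():
            ratio = config.effects[band][phase]
            cond_gain = ratio if row.condition == "CSu" else 1.0
            amp = spec.amp_uv * cond_gain * rng.lognormal(
                -spec.amp_jitter_sd ** 2 / 2, spec.amp_jitter_sd)
            onset_ms = rng.uniform(*spec.latency_ms)
            i0 = int(round((row.onset_s + onset_ms / 1000.0) * fs))
            wave = amp * _burst_waveform(spec, fs, rng.uniform(0, 2 * np.pi), rng)
            i1 = min(i0 + wave.size, n)
            if i0 < n:
                for ch in range(2):
                    eeg[ch, i0:i1] += wave[: i1 - i0] * rng.normal(1.0, 0.05)

    # tidal breathing + conditioned sniffs (lobes located noise-free)
    airflow = config.sniff.peak_flow_lpm * np.sin(
        2 * np.pi * t_axis / config.sniff.breath_period_s)
    volumes = np.zeros(len(events))
    multipliers = np.zeros(len(events))
    for i, row in enumerate(events.itertuples()):
        m_csp, m_csu = config.sniff.night_multipliers(row.block)
        m = (m_csp if row.condition == "CSp" else m_csu)
        m *= rng.lognormal(-config.sniff.trial_noise_sd ** 2 / 2,
                           config.sniff.trial_noise_sd)
        volumes[i], _ = simulate_sniff_trace(config, airflow, fs, row.onset_s, m)
        multipliers[i] = m
    airflow = airflow + 0.1 * rng.standard_normal(n)

    # alternating N3/N2 ten-minute stretches, full-night NREM
    stages = []
    t0, toggle = 0.0, 0
    while t0 < dur_s:
        stages.append((t0, min(t0 + 600.0, dur_s), "N3" if toggle == 0 else "N2"))
        t0 += 600.0
        toggle ^= 1

    recording = Recording(
        participant_id=f"sub-{idx + 1:02d}",
        signals=np.vstack([eeg, airflow[None, :]]),
        channel_names=["C3", "C4", "airflow"],
        fs=fs,
        events=events,
        arousals=[],
        stages=stages,
    )

    forced = None
    if idx < config.n_low_quality:
        nonreinf = events[~events["reinforced"]]
        spoil = nonreinf["onset_s"].to_numpy(float)[config.low_quality_clean_trials:]
        forced = [t + 0.5 for t in spoil]
    recording, arous, arts = inject_nuisance(recording, config, rng, forced)

    truth = ParticipantTruth(
        participant_id=recording.participant_id,
        events=events,
        tone_map=tone_map,
        planted_windows=planted_windows,
        arousal_intervals=arous,
        artifact_intervals=arts,
        sniff_volumes_l=volumes,
        sniff_multipliers=multipliers,
    )
    return recording, truth


def simulate_study(config: SimConfig) -> tuple[list[Recording], GroundTruth]:
    """Generate a complete synthetic study, deterministic given the seed."""
    recordings, truths = [], []
    for idx in range(config.n_participants):
        rec, truth = simulate_participant(config, idx)
        recordings.append(rec)
        truths.append(truth)
    return recordings, GroundTruth(participants=truths, config=config)


# ---------------------------------------------------------------------------
# Envelope-level generator (fast path for error-rate studies)
# ---------------------------------------------------------------------------

#: envelope autocorrelation scale per band (s); roughly 1/bandwidth
_ENVELOPE_SMOOTHING_S = {"delta": 0.30, "theta": 0.30, "sigma": 0.20}


def simulate_envelope_pair(n_participants: int, times_ms: np.ndarray,
                           band: str, rng: np.random.Generator,
                           effect: float = 0.0,
                           effect_window_ms: tuple[float, float] | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Participant-level band-envelope stand-ins for two conditions.

    Draws smooth, unit-variance stationary noise per participant and
    condition with a band-appropriate autocorrelation — the form the
    z-scored band envelopes take after trial averaging.  Under
    ``effect = 0`` the two conditions are exchangeable (an exact null
    for the sign-flip machinery); a positive ``effect`` adds that offset
    to condition A inside ``effect_window_ms``.  Used for type-I-error
    and detection-power studies at desk scale without paying for
    waveform synthesis.
    """
    from scipy.ndimage import gaussian_filter1d

    fs = 1000.0 / float(times_ms[1] - times_ms[0])
    sigma = _ENVELOPE_SMOOTHING_S.get(band, 0.25) * fs
    n_t = times_ms.size

    def draw():
        x = gaussian_filter1d(rng.standard_normal((n_participants, n_t)),
                              sigma, axis=-1, mode="reflect")
        return x / x.std(axis=-1, keepdims=True)

    a, b = draw(), draw()
    if effect and effect_window_ms is not None:
        mask = (times_ms >= effect_window_ms[0]) & (times_ms <= effect_window_ms[1])
        a = a + effect * mask
    return a, b


# ---------------------------------------------------------------------------
# Volume-level sniff generators (fast path for behavioral statistics)
# ---------------------------------------------------------------------------

def simulate_night_sniff_volumes(config: SimConfig, seed: int | None = None
                                 ) -> pd.DataFrame:
    """Normalized night sniff volumes straight from the planted model.

    Emits one row per non-reinforced trial (participant, condition,
    block, repetition, volume_nvu) where volume_nvu is the condition
    multiplier times per-participant and per-trial log-normal noise —
    i.e. the quantity the trace-level pipeline measures, without paying
    for waveform synthesis.  Used for behavioral power/null studies.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    sn = config.sniff
    for p in range(config.n_participants):
        gain = rng.lognormal(0.0, 0.05)  # stable per-participant baseline bias
        for block in range(1, config.n_blocks + 1):
            m_csp, m_csu = sn.night_multipliers(block)
            for cond, m in (("CSp", m_csp), ("CSu", m_csu)):
                noise = rng.lognormal(-sn.trial_noise_sd ** 2 / 2, sn.trial_noise_sd)
                rows.append((f"sub-{p + 1:02d}", "night", cond, block, block,
                             m * gain * noise))
    return pd.DataFrame(rows, columns=["participant_id", "session", "condition",
                                       "block", "repetition", "volume_nvu"])


def simulate_retention_volumes(config: SimConfig, seed: int | None = None
                               ) -> pd.DataFrame:
    """Normalized retention-session sniff volumes from the planted model.

    Each participant gets a random condition-level offset (between-
    participant variability of the conditioned response) plus per-trial
    noise around the configured CSu/CSp/novel means.
    """
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    sn = config.sniff
    means = {"CSu": sn.retention_csu_mean, "CSp": sn.retention_csp_mean,
             "novel": sn.retention_novel_mean}
    rows = []
    for p in range(config.n_participants):
        offsets = {c: rng.normal(0.0, sn.retention_participant_sd) for c in means}
        for rep in range(1, sn.retention_repetitions + 1):
            for cond in ("CSp", "novel", "CSu"):
                v = means[cond] + offsets[cond] + rng.normal(0.0, sn.retention_trial_sd)
                rows.append((f"sub-{p + 1:02d}", "retention", cond, 0, rep, max(v, 0.0)))
    return pd.DataFrame(rows, columns=["participant_id", "session", "condition",
                                       "block", "repetition", "volume_nvu"])


def simulate_retention_trace(config: SimConfig, idx: int,
                             fs: float = 100.0) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Airflow trace for one participant's morning retention session.

    Twenty baseline breaths, then the three tones (CSp / novel / CSu,
    eight repetitions each, interleaved) with the first post-tone
    inhalation scaled by the planted retention multiplier.  Returns
    (airflow, event table, planted volumes in litres).
    """
    rng = np.random.default_rng([int(config.seed), 5000 + idx])
    sn = config.sniff
    tone_map = {**_tone_map(idx), "novel": 800}
    n_trials = 3 * sn.retention_repetitions
    baseline_s = 20 * sn.breath_period_s
    iti = 3 * sn.breath_period_s
    dur_s = baseline_s + n_trials * iti + 10
    n = int(round(dur_s * fs))
    t_axis = np.arange(n) / fs
    airflow = sn.peak_flow_lpm * np.sin(2 * np.pi * t_axis / sn.breath_period_s)

    conds = [c for _ in range(sn.retention_repetitions) for c in ("CSp", "novel", "CSu")]
    means = {"CSu": sn.retention_csu_mean, "CSp": sn.retention_csp_mean,
             "novel": sn.retention_novel_mean}
    offsets = {c: rng.normal(0.0, sn.retention_participant_sd) for c in means}
    rows, volumes = [], []
    t = baseline_s
    for k, cond in enumerate(conds):
        m = max(means[cond] + offsets[cond] + rng.normal(0.0, sn.retention_trial_sd), 0.05)
        v, _ = simulate_sniff_trace(config, airflow, fs, t, m)
        rows.append((t, tone_map[cond], cond, False, 0, "retention"))
        volumes.append(v)
        t += iti
    events = pd.DataFrame(rows, columns=["onset_s", "tone_hz", "condition",
                                         "reinforced", "block", "session"])
    return airflow, events, np.asarray(volumes)


def null_config(**overrides) -> SimConfig:
    """Desk-scale configuration with every planted effect switched off."""
    base = SimConfig(effects=null_effects())
    sn = replace(base.sniff, night_ratio=1.0,
                 retention_csu_mean=1.0, retention_csp_mean=1.0)
    return replace(base, sniff=sn, **overrides)
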