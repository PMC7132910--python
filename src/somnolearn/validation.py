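"""Operating-characteristic studies: type-I error, detection power, recovery.

These routines run the package against its own synthetic generator many
times and report error rates and recovery quality — the quantitative
evidence that the two-stage cluster machinery controls false positives
at its nominal level and finds the effects the generator plants, at
desk scale (around a dozen participants, 100 Hz analysis rate).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cluster as cl
from . import io as sio
from . import pipeline as pl
from . import simulate as sim
from . import sniff as sn

PLANTED_PATTERN = frozenset({("delta", "early"), ("sigma", "early"),
                             ("theta", "late")})


def _rep_seed(seed: int, stream: int, rep: int) -> int:
    return (seed % 1000) * 1_000_000 + stream * 100_000 + rep


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard overlap of two closed intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def type_one_error_study(n_replicates: int = 200, n_participants: int = 12,
                         n_permutations: int = 500, seed: int = 0,
                         bands: tuple[str, ...] = ("delta", "theta", "sigma"),
                         window_ms: tuple[float, float] = (0.0, 3000.0),
                         step_ms: float = 10.0, alpha: float = 0.05
                         ) -> dict[str, float]:
    """False-positive rate of the restricted condition test under the null.

    Each replicate draws exchangeable (no-effect) participant band
    envelopes for the two conditions at the analysis rate and runs the
    paired sign-flip cluster test on the restriction window.  Returns
    the per-band proportion of replicates with at least one significant
    cluster — nominally ``alpha``.
    """
    times = np.arange(window_ms[0], window_ms[1] + step_ms / 2, step_ms)
    rates: dict[str, float] = {}
    for b_idx, band in enumerate(bands):
        hits = 0
        for rep in range(n_replicates):
            rng = np.random.default_rng(_rep_seed(seed, b_idx, rep))
            env_a, env_b = sim.simulate_envelope_pair(n_participants, times,
                                                      band, rng)
            cfg = cl.ClusterTestConfig(
                n_permutations=n_permutations, alpha_cluster=alpha,
                test_window_ms=window_ms, seed=_rep_seed(seed, b_idx + 10, rep))
            res = cl.paired_condition_cluster_test(env_a, env_b, times, cfg,
                                                   window_ms=window_ms)
            hits += bool(res.significant)
        rates[band] = hits / n_replicates
    return rates


def recovery_study(n_replicates: int = 25, seed: int = 0,
                   n_participants: int = 12, n_blocks: int = 8,
                   n_permutations: int = 500, fs: float = 100.0,
                   jaccard_threshold: float = 0.5) -> dict:
    """End-to-end planted-effect recovery across band x phase cells.

    Each replicate simulates a full study with the default planted
    pattern (early delta and sigma CSu > CSp, late theta), runs the
    whole pipeline (epoch, exclusion, envelopes, pooled windows,
    restricted tests), and scores (a) whether significant positive
    clusters appear in exactly the planted cells and (b) the Jaccard
    overlap between each detected and planted window.
    """
    ana = pl.AnalysisConfig(n_permutations=n_permutations)
    successes = 0
    pattern_hits = 0
    jaccards: list[float] = []
    for rep in range(n_replicates):
        rep_seed = _rep_seed(seed, 20, rep)
        cfg = sim.SimConfig(n_participants=n_participants, n_blocks=n_blocks,
                            fs=fs, seed=rep_seed)
        recordings, truth = sim.simulate_study(cfg)
        epochs = [pl.prepare_epochs(rec, ana) for rec in recordings]
        kept, _ = sio.include_participants(epochs, min_trials=ana.min_trials)
        env = pl.study_band_envelopes(kept, ana)
        results = pl.run_inference(env, ana, seed=rep_seed)

        detected: dict[tuple[str, str], tuple[float, float]] = {}
        for key, entry in results["condition_tests"].items():
            band, phase = key.split("/")
            if entry.get("status") != "ok":
                continue
            sig = [c for c in entry["result"]["clusters"]
                   if c["significant"] and c["sign"] == "+"]
            if sig:
                best = max(sig, key=lambda c: abs(c["mass"]))
                detected[(band, phase)] = (best["start_ms"], best["end_ms"])
        planted = {(w["band"], w["phase"]): (w["start_ms"], w["end_ms"])
                   for w in truth.participants[0].planted_windows}
        cells_ok = set(detected) == set(planted) == PLANTED_PATTERN
        rep_jacs = [interval_jaccard(detected[k], planted[k])
                    for k in detected if k in planted]
        jaccards.extend(rep_jacs)
        pattern_hits += cells_ok
        successes += cells_ok and all(j >= jaccard_threshold for j in rep_jacs)
    return {
        "success_rate": successes / n_replicates,
        "pattern_rate": pattern_hits / n_replicates,
        "mean_jaccard": float(np.mean(jaccards)) if jaccards else 0.0,
        "n_replicates": n_replicates,
    }


def exclusion_ledger_study(seed: int = 0, n_participants: int = 43,
                           n_low_quality: int = 5, n_blocks: int = 8,
                           fs: float = 100.0, min_trials: int = 10) -> dict:
    """Participant gate vs ground truth on a study with spoiled participants.

    Simulates ``n_participants`` of whom ``n_low_quality`` are given too
    few clean non-reinforced trials, runs the exclusion chain, and
    compares the pipeline's per-participant clean counts and kept total
    with a direct recount from the planted annotation intervals.
    """
    cfg = sim.SimConfig(n_participants=n_participants, n_blocks=n_blocks,
                        fs=fs, n_low_quality=n_low_quality,
                        seed=(seed % 1000) * 1_000 + 17)
    recordings, truth = sim.simulate_study(cfg)
    ana = pl.AnalysisConfig(min_trials=min_trials)
    epochs = [pl.prepare_epochs(rec, ana) for rec in recordings]
    kept, report = sio.include_participants(epochs, min_trials=min_trials)
    oracle = truth.clean_nonreinforced_counts()
    pipeline_counts = {ep.participant_id: int(ep.included_nonreinforced().sum())
                       for ep in epochs}
    mismatches = sum(pipeline_counts[pid] != int(oracle[pid])
                     for pid in pipeline_counts)
    return {
        "n_simulated": n_participants,
        "n_kept": len(kept),
        "n_kept_oracle": int((oracle >= min_trials).sum()),
        "count_mismatches": mismatches,
        "report": report,
    }


def sniff_learning_study(n_replicates: int = 50, night_ratio: float = 1.3,
                         n_participants: int = 12, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Rejection rate of the blocks 4-5 vs 1-2 sniff contrast.

    With the planted learning ramp this is detection power; with
    ``night_ratio=1`` it is the false-positive rate (nominally alpha).
    """
    hits = 0
    for rep in range(n_replicates):
        cfg = sim.SimConfig(n_participants=n_participants)
        cfg = dataclasses.replace(
            cfg, sniff=dataclasses.replace(cfg.sniff, night_ratio=night_ratio))
        table = sim.simulate_night_sniff_volumes(
            cfg, seed=_rep_seed(seed, 30 + int(night_ratio * 10), rep))
        res = sn.learning_curve(table)
        if res.p_value is None or res.p_value >= alpha:
            continue
        if night_ratio > 1.0:
            hits += res.contrast["late_minus_early"].mean() > 0
        else:
            hits += 1
    return hits / n_replicates


def spectral_fidelity_checks(fs: float = 1000.0) -> dict[str, float]:
    """Closed-form checks of the analytic band-power engine.

    A pure 13 Hz tone of amplitude A must give flat power A^2 over the
    central 8 s; a 0.5 Hz amplitude modulator must be recovered from
    the 13 Hz bin envelope; z-scored trials must have per-bin mean 0
    and SD 1 to numerical precision.
    """
    import pandas as pd

    from . import spectral as sp

    n = int(10.5 * fs) + 1
    times = np.arange(n) / fs
    events = pd.DataFrame([[0, 400, "CSu", False, 1, "night"]],
                          columns=sio.EVENT_COLUMNS)

    def one_trial(signal):
        return sio.EpochSet(
            participant_id="check",
            data=np.repeat(signal[None, None, :], 2, axis=1),
            times_ms=(times - 5.5) * 1000.0, channel_names=["C3", "C4"],
            fs=fs, events=events, included=np.ones(1, bool),
            exclusion_reason=np.array([""], object),
            phase=np.array(["unassigned"], object))

    amp = 2.0
    tone = amp * np.sin(2 * np.pi * 13.0 * times)
    power, _ = sp.hilbert_power(one_trial(tone), freqs=np.array([13.0]))
    central = slice(int(1.25 * fs), int(9.25 * fs))
    p13 = power[0, 0, 0, central]
    ripple_pct = 100.0 * (p13.max() - p13.min()) / p13.mean()

    modulator = 1 + 0.5 * np.sin(2 * np.pi * 0.5 * times)
    am = modulator * np.sin(2 * np.pi * 13.0 * times)
    power_am, _ = sp.hilbert_power(one_trial(am), freqs=np.array([13.0]))
    envelope = np.sqrt(power_am[0, 0, 0])
    am_corr = float(np.corrcoef(envelope[central], modulator[central])[0, 1])

    rng = np.random.default_rng(0)
    z = sp.zscore_trials(rng.gamma(2.0, 1.0, (4, 2, 6, 2000)))
    return {
        "tone_ripple_pct": float(ripple_pct),
        "tone_power_rel_err": float(abs(p13.mean() - amp ** 2) / amp ** 2),
        "am_corr": am_corr,
        "zscore_max_abs_mean": float(np.abs(z.mean(axis=-1)).max()),
        "zscore_max_sd_dev": float(np.abs(z.std(axis=-1) - 1).max()),
    }
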