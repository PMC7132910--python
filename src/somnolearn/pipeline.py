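"""End-to-end orchestration: simulate/ingest -> epochs -> TFR -> inference -> behavior.

Sequences the full analysis: build or load a study, epoch and apply
every inclusion rule, split training phases, compute band power
envelopes, localise pooled-power windows, run the restricted CSu-vs-CSp
and phase-interaction cluster tests with effect sizes, and run the
sniff-response analyses.  Every result file echoes the configuration
and seed (plus a config hash), so a run is reproducible from its own
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import io as sio
from . import simulate as sim
from . import sniff as sn
from . import spectral as sp

log = logging.getLogger("somnolearn")

PHASES = ("early", "late")
CONDITIONS = ("CSu", "CSp")


@dataclass
class AnalysisConfig:
    """Analysis-stage knobs (epoching, exclusion, spectral, inference)."""

    epoch_window_ms: tuple[float, float] = sio.EPOCH_WINDOW_MS
    amp_uv: float = 300.0
    flat_uv: float = 0.5
    arousal_window_s: float = 30.0
    min_trials: int = 10
    early_blocks: int = 5
    decimate_to_hz: float = 100.0
    pad_s: float = 2.0
    bands: tuple[str, ...] = ("delta", "theta", "sigma")
    alpha_cluster: float = 0.05
    cluster_forming_alpha: float = 0.05
    n_permutations: int = 1000
    baseline_ms: tuple[float, float] = (-5500.0, -500.0)
    test_window_ms: tuple[float, float] = (0.0, 5000.0)

    def cluster_config(self, seed: int | None) -> cl.ClusterTestConfig:
        return cl.ClusterTestConfig(
            alpha_cluster=self.alpha_cluster,
            cluster_forming_alpha=self.cluster_forming_alpha,
            n_permutations=self.n_permutations,
            baseline_ms=tuple(self.baseline_ms),
            test_window_ms=tuple(self.test_window_ms),
            seed=seed,
        )


@dataclass
class PipelineConfig:
    simulate: sim.SimConfig = field(default_factory=sim.SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    input_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0


def _dataclass_from_mapping(cls, mapping: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in mapping.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path + key!r}")
        ftype = fields[key].type
        if isinstance(val, dict) and key in ("simulate", "analysis", "sniff"):
            sub = {"simulate": sim.SimConfig, "analysis": AnalysisConfig,
                   "sniff": sim.SniffConfig}[key]
            kwargs[key] = _dataclass_from_mapping(sub, val, path + key + ".")
        elif key == "bursts" and isinstance(val, dict):
            kwargs[key] = {b: sim.BurstSpec(**v) for b, v in val.items()}
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
        del ftype
    return cls(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Load a YAML key-value config; defaults fill gaps, unknown keys fail."""
    text = Path(path).read_text()
    try:
        mapping = yaml.safe_load(text) or {}
    except yaml.YAMLError as err:
        raise ValueError(f"malformed config {path}: {err}") from err
    if not isinstance(mapping, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    config = _dataclass_from_mapping(PipelineConfig, mapping)
    ana = config.analysis
    win = tuple(ana.epoch_window_ms)
    for name, sub in (("baseline_ms", ana.baseline_ms),
                      ("test_window_ms", ana.test_window_ms)):
        if sub[0] < win[0] or sub[1] > win[1]:
            raise ValueError(f"{name} {sub} outside epoch window {win}")
    for band in ana.bands:
        if band not in sp.BANDS:
            log.warning("nonstandard band name %r accepted", band)
    return config


def config_hash(config: PipelineConfig) -> str:
    payload = _serialize(config)
    payload.pop("out_dir", None)  # where results land is not part of the science
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _serialize(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Study persistence (EDF + TSV + ground-truth JSON)
# ---------------------------------------------------------------------------

def write_study(recordings: list[sio.Recording], truth: sim.GroundTruth,
                out_dir) -> None:
    """Persist a synthetic study as EDF + events/annotations TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        stem = out / rec.participant_id
        sio.write_edf(rec, stem.with_suffix(".edf"))
        sio.write_events(rec.events, f"{stem}_events.tsv")
        sio.write_annotations(rec, f"{stem}_annotations.tsv")
    gt = {
        "participants": [
            {
                "participant_id": p.participant_id,
                "tone_map": p.tone_map,
                "planted_windows": p.planted_windows,
                "arousal_intervals": [list(x) for x in p.arousal_intervals],
                "artifact_intervals": [list(x) for x in p.artifact_intervals],
                "sniff_volumes_l": p.sniff_volumes_l.tolist(),
            }
            for p in truth.participants
        ],
        "config": _serialize(truth.config),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def read_study(in_dir) -> list[sio.Recording]:
    """Load every participant (EDF + TSVs) from a study directory."""
    recs = []
    for edf in sorted(Path(in_dir).glob("*.edf")):
        stem = edf.with_suffix("")
        events = sio.read_events(f"{stem}_events.tsv")
        arousals, stages = sio.read_annotations(f"{stem}_annotations.tsv")
        recs.append(sio.read_edf(edf, events=events, arousals=arousals,
                                 stages=stages, participant_id=edf.stem))
    if not recs:
        raise FileNotFoundError(f"no EDF recordings in {in_dir}")
    return recs


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def prepare_epochs(recording: sio.Recording, ana: AnalysisConfig) -> sio.EpochSet:
    """Epoch one recording and apply every trial-level inclusion rule."""
    ep = sio.epoch(recording, window_ms=tuple(ana.epoch_window_ms))
    ep = sio.reject_artifacts(ep, amp_uv=ana.amp_uv, flat_uv=ana.flat_uv)
    ep = sio.reject_arousal_trials(ep, recording, window_s=ana.arousal_window_s)
    ep = sio.mark_reinforced(ep)
    ep = sio.split_phases(ep, early_blocks=ana.early_blocks)
    return ep


def study_band_envelopes(epochs_list: list[sio.EpochSet], ana: AnalysisConfig
                         ) -> dict:
    """Per-band, per-cell participant envelopes on the (decimated) time axis.

    Returns {"times_ms": ..., "participant_ids": ..., band: {(cond, phase):
    participants x time array with NaN rows for missing cells}}.
    """
    freqs = np.unique(np.concatenate([sp.band_bins(b) for b in ana.bands]))
    decimated = []
    for ep in epochs_list:
        factor = int(round(ep.fs / ana.decimate_to_hz))
        dep = ep.decimate(factor) if factor > 1 else ep
        decimated.append(dep)
    times = decimated[0].times_ms
    n_p = len(decimated)
    out = {"times_ms": times,
           "participant_ids": [ep.participant_id for ep in decimated]}
    cells = {b: {(c, ph): np.full((n_p, times.size), np.nan)
                 for c in CONDITIONS for ph in PHASES} for b in ana.bands}
    for i, ep in enumerate(decimated):
        mask = ep.included_nonreinforced()
        if not mask.any():
            continue
        sub = dataclasses.replace(
            ep, data=ep.data[mask], events=ep.events[mask].reset_index(drop=True),
            included=ep.included[mask], exclusion_reason=ep.exclusion_reason[mask],
            phase=ep.phase[mask])
        power, _ = sp.hilbert_power(sub, freqs=freqs, pad_s=ana.pad_s)
        z = sp.zscore_trials(power)
        cond = sub.events["condition"].to_numpy()
        for band in ana.bands:
            env = sp.band_envelope(z, freqs, band).mean(axis=1)  # trials x time
            for c in CONDITIONS:
                for ph in PHASES:
                    sel = (cond == c) & (sub.phase == ph)
                    if sel.any():
                        cells[band][(c, ph)][i] = env[sel].mean(axis=0)
    out.update(cells)
    return out


def run_inference(envelopes: dict, ana: AnalysisConfig, seed: int) -> dict:
    """Stage-1 pooled windows, stage-2 restricted contrasts, interactions."""
    times = envelopes["times_ms"]
    cfg = ana.cluster_config(seed)
    results: dict = {"pooled_windows": {}, "condition_tests": {},
                     "interaction_tests": {}}
    for band in ana.bands:
        cells = envelopes[band]
        pooled = cl.pooled_window(cells, times, cfg)
        results["pooled_windows"][band] = {
            "status": pooled["status"],
            "window_ms": pooled["window_ms"],
            "p": (pooled["result"].significant[0].p_perm
                  if pooled["status"] == "ok" else None),
        }
        corrected = {key: cl.baseline_correct(arr, times, cfg.baseline_ms)
                     for key, arr in cells.items()}
        for ph in PHASES:
            key = f"{band}/{ph}"
            if pooled["status"] != "ok":
                results["condition_tests"][key] = {"status": "skipped"}
                continue
            try:
                res, effects = cl.restricted_condition_test(
                    corrected[("CSu", ph)], corrected[("CSp", ph)], times,
                    pooled, cfg)
            except ValueError as err:
                results["condition_tests"][key] = {"status": f"error: {err}"}
                continue
            results["condition_tests"][key] = {
                "status": "ok", "result": res.to_dict(),
                "effect_sizes": [e.to_dict() for e in effects],
            }
        if pooled["status"] != "ok":
            results["interaction_tests"][band] = {"status": "skipped"}
            continue
        d_early = corrected[("CSu", "early")] - corrected[("CSp", "early")]
        d_late = corrected[("CSu", "late")] - corrected[("CSp", "late")]
        try:
            inter = cl.phase_interaction_test(d_early, d_late, times, cfg,
                                              window_ms=pooled["window_ms"])
            results["interaction_tests"][band] = {"status": "ok",
                                                  "result": inter.to_dict()}
        except ValueError as err:
            results["interaction_tests"][band] = {"status": f"error: {err}"}
    return results


def night_sniff_table(recordings: list[sio.Recording],
                      epochs_list: list[sio.EpochSet]) -> pd.DataFrame:
    """Night sniff table from airflow traces (clean non-reinforced trials).

    Repetition numbers count clean non-reinforced presentations per
    condition in onset order, so a trial lost to an arousal never
    contributes — the "up to the fifth presentation or first arousal"
    truncation applied at the trial level.
    """
    rows = []
    by_id = {ep.participant_id: ep for ep in epochs_list}
    for rec in recordings:
        ep = by_id.get(rec.participant_id)
        if ep is None:
            continue
        airflow = rec.channel(sio.AIRFLOW_CHANNEL)
        clean = ep.included_nonreinforced()
        ev = ep.events
        nvu = sn.night_nvu(airflow, rec.fs, ev["onset_s"].to_numpy(float))
        reps = {c: 0 for c in CONDITIONS}
        for i in ev.index:
            if not clean[i]:
                continue
            cond = ev.loc[i, "condition"]
            reps[cond] += 1
            vol = sn.sniff_volume(airflow, rec.fs, float(ev.loc[i, "onset_s"]))
            rows.append((rec.participant_id, "night", cond,
                         int(ev.loc[i, "block"]), reps[cond], vol, nvu[i]))
    return pd.DataFrame(rows, columns=sn.SNIFF_COLUMNS)


def retention_sniff_table(config: sim.SimConfig, fs: float = 100.0) -> pd.DataFrame:
    """Simulated retention session measured through the trace pipeline."""
    rows = []
    for idx in range(config.n_participants):
        airflow, events, _ = sim.simulate_retention_trace(config, idx, fs=fs)
        baseline = [v for s, e, v in sn.detect_inhalations(airflow, fs)
                    if e / fs <= events["onset_s"].iloc[0]]
        vols = np.array([sn.sniff_volume(airflow, fs, t)
                         for t in events["onset_s"]])
        nvu = sn.normalize_retention(vols, np.array(baseline))
        for k, row in enumerate(events.itertuples()):
            rows.append((f"sub-{idx + 1:02d}", "retention", row.condition, 0,
                         k // 3 + 1, vols[k], nvu[k]))
    return pd.DataFrame(rows, columns=sn.SNIFF_COLUMNS)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns (and optionally writes) results.

    Stages: simulate/ingest -> epoch + exclusion -> phase split ->
    participant gate -> band envelopes -> pooled windows -> restricted
    condition tests (+ effect sizes) -> phase interactions -> night
    learning curve -> retention test.
    """
    t0 = time.time()
    ana = config.analysis
    out_dir = Path(config.out_dir) if config.out_dir else None
    prev_level = log.level
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        if log.getEffectiveLevel() > logging.INFO:
            log.setLevel(logging.INFO)  # the run log always gets stage counts
    try:
        if config.input_dir:
            recordings = read_study(config.input_dir)
            truth = None
        else:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            recordings, truth = sim.simulate_study(sim_cfg)
        log.info("stage=simulate participants=%d", len(recordings))

        epochs_list = [prepare_epochs(rec, ana) for rec in recordings]
        n_trials = sum(ep.n_trials for ep in epochs_list)
        n_clean = sum(int(ep.included_nonreinforced().sum()) for ep in epochs_list)
        log.info("stage=epoch trials=%d clean_nonreinforced=%d", n_trials, n_clean)

        kept, drop_report = sio.include_participants(epochs_list,
                                                     min_trials=ana.min_trials)
        log.info("stage=include kept=%d dropped=%d", len(kept),
                 int((~drop_report["kept"]).sum()))

        envelopes = study_band_envelopes(kept, ana)
        log.info("stage=tfr bands=%s fs=%g", ",".join(ana.bands),
                 ana.decimate_to_hz)

        inference = run_inference(envelopes, ana, seed=config.seed)
        log.info("stage=test pooled=%s",
                 {b: v["status"] for b, v in inference["pooled_windows"].items()})

        night = night_sniff_table(recordings, epochs_list)
        curve = sn.learning_curve(night)
        retention = None
        if truth is not None:
            ret_table = retention_sniff_table(
                dataclasses.replace(config.simulate, seed=config.seed))
            retention = sn.retention_test(ret_table)
            night = pd.concat([night, ret_table], ignore_index=True)
        log.info("stage=sniff night_trials=%d", len(night))

        results = {
            "config": _serialize(config),
            "config_hash": config_hash(config),
            "seed": config.seed,
            "participants": {
                "simulated": len(recordings),
                "kept": len(kept),
                "drop_report": drop_report.to_dict(orient="records"),
            },
            **inference,
            "sniff": {
                "learning_curve": curve.to_dict(),
                "retention": retention.to_dict() if retention else None,
            },
            "runtime_s": round(time.time() - t0, 2),
        }
        if out_dir:
            (out_dir / "results.json").write_text(json.dumps(results, indent=1))
            cluster_table(results).to_csv(out_dir / "clusters.tsv", sep="\t",
                                          index=False)
            night.to_csv(out_dir / "sniff.tsv", sep="\t", index=False)
            pd.concat([sio.exclusion_report(ep) for ep in epochs_list]).to_csv(
                out_dir / "exclusions.tsv", sep="\t", index=False)
        return results
    finally:
        if out_dir:
            log.removeHandler(handler)
            handler.close()
            log.setLevel(prev_level)


def cluster_table(results: dict) -> pd.DataFrame:
    """Summary table in reporting style: band, phase, start-end ms, P, r."""
    rows = []
    for key, entry in results.get("condition_tests", {}).items():
        band, phase = key.split("/")
        if entry.get("status") != "ok":
            rows.append((band, phase, None, None, None, None, entry.get("status")))
            continue
        sig = [c for c in entry["result"]["clusters"] if c["significant"]]
        effects = entry.get("effect_sizes", [])
        if not sig:
            rows.append((band, phase, None, None, None, None, "no cluster"))
        for k, c in enumerate(sig):
            r = effects[k]["r"] if k < len(effects) else None
            rows.append((band, phase, c["start_ms"], c["end_ms"], c["p_perm"], r,
                         "significant"))
    return pd.DataFrame(rows, columns=["band", "phase", "start_ms", "end_ms",
                                       "P_cluster", "r", "status"])
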