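"""Cluster-based nonparametric permutation inference for paired designs.

Implements the two-stage statistical machinery used for event-related
sleep-EEG power: pointwise t statistics across participants, cluster
formation above a cluster-forming threshold, a max-statistic null built
from participant-level sign flips (the exchangeability move for
within-participant designs), pooled-condition window localisation,
restricted condition contrasts within those windows, phase-interaction
contrasts, and the nonparametric effect size r = z / sqrt(n) from a
Wilcoxon signed-rank z.

The permutation engine enumerates all 2^n sign patterns exactly when
that is no more work than the requested Monte-Carlo count, and falls
back to random sign patterns otherwise.  Exact mode reports
p = #{null >= observed} / 2^n; Monte-Carlo mode the standard
(1 + #{null >= observed}) / (n_permutations + 1), whose floor is
1 / (n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

#: 4-neighbour (time, frequency) adjacency — no diagonals
_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class ClusterTestConfig:
    alpha_cluster: float = 0.05
    cluster_forming_alpha: float = 0.05
    tail: str = "two"  # {"two", "pos", "neg"}
    n_permutations: int = 1000
    adjacency: str = "time"  # {"time", "time-frequency"}
    baseline_ms: tuple[float, float] = (-5500.0, -500.0)
    test_window_ms: tuple[float, float] = (0.0, 5000.0)
    cluster_stat: str = "mass"  # {"mass", "max"}
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail not in ("two", "pos", "neg"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p_perm: float
    sign: str
    significant: bool
    freq_lo: float | None = None
    freq_hi: float | None = None
    time_slice: tuple[int, int] = (0, 0)  # [start, end) indices in the tested window

    def to_dict(self) -> dict:
        return {
            "start_ms": self.start_ms, "end_ms": self.end_ms,
            "freq_lo": self.freq_lo, "freq_hi": self.freq_hi,
            "mass": self.mass, "p_perm": self.p_perm,
            "sign": self.sign, "significant": self.significant,
        }


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n: int
    config: ClusterTestConfig
    exact: bool
    n_null: int
    null_max_summary: dict
    times_ms: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "exact": self.exact,
            "n_null": self.n_null,
            "clusters": [c.to_dict() for c in self.clusters],
            "null_max_summary": self.null_max_summary,
        }


@dataclass
class EffectSize:
    """Rosenthal-convention effect size r = z / sqrt(n), signed by the median."""

    r: float
    z: float
    n: int
    p: float
    status: str = "ok"

    def to_dict(self) -> dict:
        return {"r": self.r, "z": self.z, "n": self.n, "p": self.p,
                "status": self.status}


# ---------------------------------------------------------------------------
# Baseline correction and window handling
# ---------------------------------------------------------------------------

def window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean mask over the time axis for a closed [start, end] ms window."""
    lo, hi = window_ms
    mask = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms not covered by the time axis")
    return mask


def baseline_correct(values: np.ndarray, times_ms: np.ndarray,
                     baseline_ms: tuple[float, float] = (-5500.0, -500.0)
                     ) -> np.ndarray:
    """Subtract the mean over the baseline window along the time axis.

    Applied per participant (and per frequency bin for 2-D maps), so
    post-onset values express deviation from the pre-tone baseline.
    """
    mask = window_mask(times_ms, baseline_ms)
    return values - values[..., mask].mean(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

def _t_one_sample(X: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t across the first axis (ddof=1), 0 where degenerate."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _forming_threshold(n: int, config: ClusterTestConfig) -> float:
    alpha = config.cluster_forming_alpha
    df = n - 1
    if config.tail == "two":
        return float(stats.t.ppf(1 - alpha / 2, df))
    return float(stats.t.ppf(1 - alpha, df))


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a 1-D boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _cluster_masses_1d(t: np.ndarray, thr: float, tail: str,
                       stat: str) -> list[tuple[tuple[int, int], float, str]]:
    out = []
    if tail in ("two", "pos"):
        for s, e in _segments(t > thr):
            mass = float(t[s:e].max()) if stat == "max" else float(t[s:e].sum())
            out.append(((s, e), mass, "+"))
    if tail in ("two", "neg"):
        for s, e in _segments(t < -thr):
            mass = float(t[s:e].min()) if stat == "max" else float(t[s:e].sum())
            out.append(((s, e), mass, "-"))
    return out


def _clusters_2d(t: np.ndarray, thr: float, tail: str, stat: str):
    """Connected suprathreshold components under 4-neighbour adjacency."""
    out = []
    signs = []
    if tail in ("two", "pos"):
        signs.append(("+", t > thr))
    if tail in ("two", "neg"):
        signs.append(("-", t < -thr))
    for sign, mask in signs:
        labels, n_lab = ndimage.label(mask, structure=_STRUCTURE_2D)
        for lab in range(1, n_lab + 1):
            where = labels == lab
            vals = t[where]
            mass = float(vals.max() if sign == "+" else vals.min()) if stat == "max" \
                else float(vals.sum())
            fi, ti = np.nonzero(where)
            out.append(((fi.min(), fi.max() + 1, ti.min(), ti.max() + 1), mass, sign,
                        where))
    return out


def _max_abs_mass(t: np.ndarray, thr: float, tail: str, stat: str) -> float:
    if t.ndim == 1:
        masses = [abs(m) for _, m, _ in _cluster_masses_1d(t, thr, tail, stat)]
    else:
        masses = [abs(m) for _, m, _, _ in _clusters_2d(t, thr, tail, stat)]
    return max(masses, default=0.0)


def _sign_patterns(n: int, config: ClusterTestConfig) -> tuple[np.ndarray, bool]:
    """All 2^n sign patterns when affordable, else Monte-Carlo draws."""
    if 2 ** n <= config.n_permutations:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        return 2.0 * bits - 1.0, True
    rng = np.random.default_rng(config.seed)
    return rng.choice([-1.0, 1.0], size=(config.n_permutations, n)), False


def _null_max_1d(X: np.ndarray, flips: np.ndarray, thr: float,
                 config: ClusterTestConfig) -> np.ndarray:
    """Max |cluster mass| per sign pattern, vectorised over permutations."""
    n = X.shape[0]
    mean_f = flips @ X / n
    ssq = (X ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_f = np.maximum(ssq - n * mean_f ** 2, 0.0) / (n - 1)
        t_f = mean_f / np.sqrt(var_f / n)
    t_f = np.nan_to_num(t_f, nan=0.0, posinf=0.0, neginf=0.0)
    return np.array([
        _max_abs_mass(row, thr, config.tail, config.cluster_stat) for row in t_f
    ])


def one_sample_cluster_test(X: np.ndarray, times_ms: np.ndarray,
                            config: ClusterTestConfig,
                            freqs: np.ndarray | None = None) -> ClusterTestResult:
    """Sign-flip max-statistic cluster test of H0: mean map = 0.

    ``X`` is participants x time (1-D signals) or participants x
    frequencies x time (2-D maps, 4-neighbour adjacency).  The null
    flips the sign of whole participant maps; cluster p-values compare
    each observed |mass| with the distribution of the per-permutation
    maximum |mass|.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("cluster test needs at least 2 participants")
    if X.shape[-1] != times_ms.size:
        raise ValueError("time axis mismatch")
    thr = _forming_threshold(n, config)
    t_obs = _t_one_sample(X)

    flips, exact = _sign_patterns(n, config)
    if X.ndim == 2:
        observed = _cluster_masses_1d(t_obs, thr, config.tail, config.cluster_stat)
        null_max = _null_max_1d(X, flips, thr, config)
    else:
        obs2d = _clusters_2d(t_obs, thr, config.tail, config.cluster_stat)
        observed = obs2d
        Xf = X.reshape(n, -1)
        shape = X.shape[1:]
        n_p = flips.shape[0]
        mean_f = flips @ Xf / n
        ssq = (Xf ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_f = np.maximum(ssq - n * mean_f ** 2, 0.0) / (n - 1)
            t_f = np.nan_to_num(mean_f / np.sqrt(var_f / n),
                                nan=0.0, posinf=0.0, neginf=0.0)
        null_max = np.array([
            _max_abs_mass(t_f[i].reshape(shape), thr, config.tail, config.cluster_stat)
            for i in range(n_p)
        ])

    def p_of(mass: float) -> float:
        count = int(np.sum(null_max >= abs(mass) - 1e-12))
        if exact:
            return count / null_max.size
        return (1 + count) / (null_max.size + 1)

    clusters = []
    for item in observed:
        if X.ndim == 2:
            (s, e), mass, sign = item
            start_ms, end_ms = float(times_ms[s]), float(times_ms[e - 1])
            flo = fhi = None
        else:
            (f0, f1, s, e), mass, sign, _ = item
            start_ms, end_ms = float(times_ms[s]), float(times_ms[e - 1])
            flo = float(freqs[f0]) if freqs is not None else float(f0)
            fhi = float(freqs[f1 - 1]) if freqs is not None else float(f1 - 1)
        p = p_of(mass)
        clusters.append(Cluster(
            start_ms=start_ms, end_ms=end_ms, mass=mass, p_perm=p, sign=sign,
            significant=p <= config.alpha_cluster, freq_lo=flo, freq_hi=fhi,
            time_slice=(int(s), int(e)),
        ))
    clusters.sort(key=lambda c: -abs(c.mass))
    summary = {
        "mean": float(null_max.mean()),
        "p95": float(np.percentile(null_max, 95)),
        "max": float(null_max.max()),
    }
    return ClusterTestResult(clusters=clusters, n=n, config=config, exact=exact,
                             n_null=int(null_max.size), null_max_summary=summary,
                             times_ms=times_ms)


# ---------------------------------------------------------------------------
# Study-level tests
# ---------------------------------------------------------------------------

def _complete_rows(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(arrays[0].shape[0], bool)
    for a in arrays:
        ok &= ~np.isnan(a.reshape(a.shape[0], -1)).any(axis=1)
    return ok


def vs_baseline_cluster_test(maps: np.ndarray, times_ms: np.ndarray,
                             config: ClusterTestConfig,
                             freqs: np.ndarray | None = None) -> ClusterTestResult:
    """Test for deviation from the pre-tone baseline in the post-onset window.

    ``maps`` must already be baseline-corrected (participants x [freq x]
    time on the full epoch axis); the test runs on the configured
    post-onset window.
    """
    mask = window_mask(times_ms, config.test_window_ms)
    keep = _complete_rows(maps)
    return one_sample_cluster_test(maps[keep][..., mask], times_ms[mask],
                                   config, freqs=freqs)


def paired_condition_cluster_test(maps_a: np.ndarray, maps_b: np.ndarray,
                                  times_ms: np.ndarray, config: ClusterTestConfig,
                                  window_ms: tuple[float, float] | None = None,
                                  freqs: np.ndarray | None = None
                                  ) -> ClusterTestResult:
    """Paired (condition-swap) cluster test on per-participant a - b maps.

    Condition-label exchange within participants is equivalent to sign
    flips of the paired differences, so the one-sample engine applies.
    Participants with a missing cell (NaN) are dropped.
    """
    diffs = np.asarray(maps_a, float) - np.asarray(maps_b, float)
    keep = _complete_rows(diffs)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 cell-complete participants")
    window = window_ms or config.test_window_ms
    mask = window_mask(times_ms, window)
    return one_sample_cluster_test(diffs[keep][..., mask], times_ms[mask],
                                   config, freqs=freqs)


def pooled_window(cells: dict[tuple[str, str], np.ndarray], times_ms: np.ndarray,
                  config: ClusterTestConfig) -> dict:
    """Stage 1: localise where pooled post-tone power exceeds baseline.

    ``cells`` maps (condition, phase) to participants x time envelopes
    on the full epoch axis (NaN rows mark missing participants).  Cells
    are averaged per participant over whatever cells that participant
    has, baseline-corrected, and submitted to a positive-tail cluster
    test.  Returns a dict with ``status`` ("ok"/"untestable"), the
    largest significant cluster's inclusive ``window_ms``, and the full
    test result; downstream condition contrasts are restricted to that
    window.
    """
    stack = np.stack(list(cells.values()))  # cells x participants x time
    with np.errstate(invalid="ignore"):
        pooled = np.nanmean(stack, axis=0)
    keep = ~np.isnan(pooled).any(axis=1)
    pooled = baseline_correct(pooled[keep], times_ms, config.baseline_ms)
    cfg = replace(config, tail="pos")
    result = vs_baseline_cluster_test(pooled, times_ms, cfg)
    sig = result.significant
    if not sig:
        return {"status": "untestable", "window_ms": None, "result": result}
    best = max(sig, key=lambda c: abs(c.mass))
    return {"status": "ok", "window_ms": (best.start_ms, best.end_ms),
            "result": result}


def restricted_condition_test(env_a: np.ndarray, env_b: np.ndarray,
                              times_ms: np.ndarray,
                              band_window: dict | tuple[float, float] | None,
                              config: ClusterTestConfig
                              ) -> tuple[ClusterTestResult | None, list[EffectSize]]:
    """Stage 2: condition contrast restricted to the pooled-power window.

    Returns the cluster test result and one effect size per significant
    cluster, computed from participant-level mean differences over the
    cluster's time extent.  If the band was untestable at stage 1 the
    test is skipped and ``(None, [])`` returned.
    """
    if isinstance(band_window, dict):
        if band_window.get("status") != "ok":
            return None, []
        band_window = band_window["window_ms"]
    if band_window is None:
        return None, []
    diffs_full = np.asarray(env_a, float) - np.asarray(env_b, float)
    keep = _complete_rows(diffs_full)
    result = paired_condition_cluster_test(env_a, env_b, times_ms, config,
                                           window_ms=tuple(band_window))
    mask = window_mask(times_ms, tuple(band_window))
    windowed = diffs_full[keep][..., mask]
    effects = []
    for c in result.significant:
        s, e = c.time_slice
        effects.append(effect_size_r(windowed[:, s:e].mean(axis=1)))
    return result, effects


def phase_interaction_test(diff_early: np.ndarray, diff_late: np.ndarray,
                           times_ms: np.ndarray, config: ClusterTestConfig,
                           window_ms: tuple[float, float] | None = None
                           ) -> ClusterTestResult:
    """Does the condition difference change between training phases?

    Paired cluster test on (a-b)_early - (a-b)_late for participants
    observed in both phases.
    """
    return paired_condition_cluster_test(diff_early, diff_late, times_ms,
                                         config, window_ms=window_ms)


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def effect_size_r(diffs: np.ndarray) -> EffectSize:
    """Wilcoxon signed-rank z, normal approximation, as r = z / sqrt(n).

    Zero differences are dropped; ties get mid-ranks with the usual
    variance correction; a 0.5 continuity correction pulls the statistic
    toward the null.  The sign of r follows the median difference, and
    n is the full participant count (the convention of the r = z/sqrt(n)
    effect-size formula).
    """
    d = np.asarray(diffs, float)
    n = d.size
    if n < 2:
        raise ValueError("effect size needs at least 2 differences")
    nz = d[d != 0]
    m = nz.size
    if m == 0:
        return EffectSize(r=float("nan"), z=0.0, n=n, p=1.0, status="undefined")
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float(np.sum(counts ** 3 - counts)) / 48.0
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - tie_corr
    if sigma2 <= 0:
        return EffectSize(r=float("nan"), z=0.0, n=n, p=1.0, status="undefined")
    delta = w_pos - mu
    if delta == 0:
        z = 0.0
    else:
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(sigma2)
    p = float(2 * stats.norm.sf(abs(z)))
    med = np.median(d)
    sign = np.sign(med) if med != 0 else (np.sign(delta) or 1.0)
    r = float(sign * abs(z) / np.sqrt(n))
    return EffectSize(r=r, z=float(z), n=n, p=p)


def r_from_z(z: float, n: int) -> float:
    """The printed-formula arithmetic: r = z / sqrt(n)."""
    return float(z / np.sqrt(n))
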