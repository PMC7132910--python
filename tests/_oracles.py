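"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — plain loops, exhaustive
enumeration, direct integration — and shares no code with the
implementation under test.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats


def brute_force_cluster_p(X: np.ndarray, alpha_form: float = 0.05,
                          tail: str = "two"):
    """Exhaustive sign-flip cluster test on 1-D signals (loop-based).

    Returns a list of ((start, end_inclusive), mass, exact_p) for every
    suprathreshold run of the observed pointwise t, with the null being
    the max |cluster mass| over all 2^n sign patterns.
    """
    n, T = X.shape
    if tail == "two":
        thr = stats.t.ppf(1 - alpha_form / 2, n - 1)
    else:
        thr = stats.t.ppf(1 - alpha_form, n - 1)

    def tvals(Y):
        return stats.ttest_1samp(Y, 0.0, axis=0).statistic

    def clusters(t):
        out, cur = [], None
        for i in range(T):
            if tail == "pos":
                s = 1 if t[i] > thr else 0
            elif tail == "neg":
                s = -1 if t[i] < -thr else 0
            else:
                s = 1 if t[i] > thr else (-1 if t[i] < -thr else 0)
            if s and cur and cur[2] == s:
                cur = (cur[0], i, s, cur[3] + t[i])
            elif s:
                if cur:
                    out.append(cur)
                cur = (i, i, s, t[i])
            else:
                if cur:
                    out.append(cur)
                cur = None
        if cur:
            out.append(cur)
        return out

    observed = clusters(tvals(X))
    null = []
    for signs in product([1.0, -1.0], repeat=n):
        cs = clusters(tvals(X * np.array(signs)[:, None]))
        null.append(max((abs(c[3]) for c in cs), default=0.0))
    null = np.array(null)
    return [((c[0], c[1]), c[3],
             float(np.sum(null >= abs(c[3]) - 1e-12) / null.size))
            for c in observed]


def exact_signed_rank_distribution(m: int) -> np.ndarray:
    """Exact null distribution of the positive-rank sum W+ for m untied values."""
    dist = np.zeros(m * (m + 1) // 2 + 1)
    dist[0] = 1.0
    for rank in range(1, m + 1):
        new = dist.copy()
        new[rank:] += dist[:-rank] if rank else dist
        dist = new
    return dist / dist.sum()


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by full enumeration of sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    m = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = m * (m + 1) / 4.0
    count = 0
    total = 2 ** m
    for signs in product([1, 0], repeat=m):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def band_energy_ratio(recordings, truth, band_hz, window_ms, phase,
                      early_blocks=5):
    """Direct event-locked band-energy ratio CSu/CSp (generator oracle).

    Band-limits the raw EEG with a plain FFT brick-wall filter, then
    integrates energy in the planted window per trial and compares
    condition means — no Hilbert transform, no z-scoring.
    """
    from scipy.fft import irfft, rfft, rfftfreq

    energies = {"CSu": [], "CSp": []}
    for rec in recordings:
        fs = rec.fs
        filtered = []
        for name in ("C3", "C4"):
            x = rec.channel(name)
            spec = rfft(x)
            f = rfftfreq(x.size, 1 / fs)
            spec[(f < band_hz[0]) | (f > band_hz[1])] = 0
            filtered.append(irfft(spec, x.size))
        for row in rec.events.itertuples():
            ph = "early" if row.block <= early_blocks else "late"
            if ph != phase or row.reinforced:
                continue
            i0 = int(round((row.onset_s + window_ms[0] / 1000.0) * fs))
            i1 = int(round((row.onset_s + window_ms[1] / 1000.0) * fs))
            e = sum(float(np.sum(ch[i0:i1] ** 2)) for ch in filtered)
            energies[row.condition].append(e)
    return np.mean(energies["CSu"]) / np.mean(energies["CSp"])
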