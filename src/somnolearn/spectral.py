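"""Hilbert time-frequency decomposition and band power envelopes.

The decomposition follows the sleep-EEG recipe: for each 0.5 Hz
frequency bin a Hamming-windowed-sinc FIR bandpass (transition width
25% of the lower band edge, but never below 2 Hz where feasible) is
applied with zero phase, the analytic signal's squared magnitude gives
instantaneous power, edges are trimmed after mirror padding, each
trial's power is z-scored per frequency bin, and trials are averaged
across the two electrodes and then across trials into one
time-frequency representation per participant, condition and training
phase.  Band envelopes (delta 0.5-4, theta 4-7, sigma 11-16 Hz) are
means of the z-scored bin powers whose centers fall inside the closed
band interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

from .io import EpochSet

#: analysis bands (closed intervals, Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "sigma": (11.0, 16.0),
}

#: half-width of each 0.5 Hz analysis bin
BIN_HALF_WIDTH_HZ = 0.25


def frequency_grid(f_max: float = 40.0) -> np.ndarray:
    """Bin centers 0.5 ... f_max Hz in 0.5 Hz steps (80 bins by default)."""
    return np.arange(0.5, f_max + 1e-9, 0.5)


def band_bins(band: str | tuple[float, float], f_max: float = 40.0) -> np.ndarray:
    """Bin centers lying inside the closed band interval."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    grid = frequency_grid(f_max)
    sel = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
    if sel.size == 0:
        raise ValueError(f"band ({lo}, {hi}) Hz has no bins on the analysis grid")
    return sel


@dataclass
class FilterSpec:
    """A zero-phase Hamming-sinc FIR band (or degraded low-pass) filter.

    ``transition_hz`` follows the 25%-of-lower-edge rule with a 2 Hz
    floor; when even the floor cannot fit above DC the filter degrades
    to a low-pass over the band's upper edge (``lowpass`` True), the
    "where possible" escape of the design rule.
    """

    low_hz: float
    high_hz: float
    fs: float
    transition_hz: float
    numtaps: int
    taps: np.ndarray
    lowpass: bool = False
    window: str = "Hamming-sinc"


def design_fir(low_hz: float, high_hz: float, fs: float) -> FilterSpec:
    """Design the per-band FIR filter (order 3.3 / transition-width cycles)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz infeasible at fs={fs}")
    transition = max(0.25 * low_hz, 2.0)
    numtaps = int(3.3 * fs / transition) // 2 * 2 + 1
    lo_cut = low_hz - transition / 2.0
    hi_cut = high_hz + transition / 2.0
    if hi_cut >= fs / 2:
        hi_cut = (high_hz + fs / 2) / 2.0
    if lo_cut <= 0:
        taps = firwin(numtaps, hi_cut, window="hamming", fs=fs)
        return FilterSpec(low_hz, high_hz, fs, transition, numtaps, taps, lowpass=True)
    taps = firwin(numtaps, [lo_cut, hi_cut], window="hamming",
                  pass_zero=False, fs=fs)
    return FilterSpec(low_hz, high_hz, fs, transition, numtaps, taps)


def apply_fir(data: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the (odd-length, linear-phase) filter with zero net delay."""
    return fftconvolve(data, _shaped(spec.taps, data.ndim), mode="same", axes=-1)


def _shaped(taps: np.ndarray, ndim: int) -> np.ndarray:
    return taps.reshape((1,) * (ndim - 1) + (-1,))


def _analytic_band_power(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Squared magnitude of the analytic band signal via complex demodulation.

    The Hamming-sinc bandpass over [lo_cut, hi_cut] is exactly a
    low-pass prototype modulated to the band center, so the analytic
    signal of the band-passed data equals ``2 exp(i w_c t) *
    (x exp(-i w_c t)) * l`` with ``l`` the low-pass kernel.  Computing
    power this way uses one strictly local convolution — every output
    sample depends only on data within half a kernel length — so
    trimmed values are independent of how far the input was padded.
    """
    fs = spec.fs
    transition = spec.transition_hz
    lo_cut = 0.0 if spec.lowpass else spec.low_hz - transition / 2.0
    hi_cut = min(spec.high_hz + transition / 2.0, (spec.high_hz + fs / 2) / 2.0)
    f_center = (lo_cut + hi_cut) / 2.0
    lp = firwin(spec.numtaps, (hi_cut - lo_cut) / 2.0, window="hamming", fs=fs)
    n = np.arange(x.shape[-1])
    carrier = np.exp(-2j * np.pi * f_center / fs * n)
    demod = fftconvolve(x * carrier, _shaped(lp, x.ndim), mode="same", axes=-1)
    return 4.0 * np.abs(demod) ** 2


def hilbert_power(epochs: EpochSet, freqs: np.ndarray | None = None,
                  pad_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial, per-channel analytic (Hilbert) band power per 0.5 Hz bin.

    Each epoch is mirror-padded by ``pad_s`` seconds, band-passed per
    bin (bin = center +- 0.25 Hz) with the Hamming-sinc design, the
    analytic signal's squared magnitude is taken, and the padding is
    trimmed, so edge artifacts fall in the discarded samples.  The
    analytic signal is evaluated by complex demodulation (see
    :func:`_analytic_band_power`), which is numerically equivalent for
    band-limited data and keeps every trimmed sample independent of the
    pad length.

    Returns ``(power, freqs)`` with power shaped
    (trials, channels, n_bins, n_times).
    """
    if freqs is None:
        freqs = frequency_grid()
    freqs = np.atleast_1d(np.asarray(freqs, float))
    data = epochs.data
    fs = epochs.fs
    pad = int(round(pad_s * fs))
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    n_tr, n_ch, n_t = data.shape
    out = np.empty((n_tr, n_ch, freqs.size, n_t))
    flat = padded.reshape(n_tr * n_ch, -1)
    for k, f in enumerate(freqs):
        spec = design_fir(max(f - BIN_HALF_WIDTH_HZ, 1e-3), f + BIN_HALF_WIDTH_HZ, fs)
        power = _analytic_band_power(flat, spec)
        out[:, :, k, :] = power[:, pad:pad + n_t].reshape(n_tr, n_ch, n_t)
    return out, freqs


def zscore_trials(power: np.ndarray, ddof: int = 0,
                  baseline_mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score power per trial, channel and frequency bin over time.

    By default the normalization window is the whole epoch; pass a
    boolean ``baseline_mask`` over the time axis to normalize against a
    sub-window instead.  Constant bins map to zero with a warning.
    """
    ref = power if baseline_mask is None else power[..., baseline_mask]
    mean = ref.mean(axis=-1, keepdims=True)
    sd = ref.std(axis=-1, ddof=ddof, keepdims=True)
    flat = sd <= 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant power bin(s) mapped to zero",
                      stacklevel=2)
    sd = np.where(flat, 1.0, sd)
    z = (power - mean) / sd
    return np.where(np.broadcast_to(flat, z.shape), 0.0, z)


@dataclass
class TimeFrequencyMap:
    """Z-scored power, participants x frequencies x time, for one cell."""

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    condition: str
    phase: str
    participant_ids: list[str]


@dataclass
class BandEnvelope:
    """Band-mean z-scored power, participants x time, for one cell."""

    values: np.ndarray
    band: str
    times_ms: np.ndarray
    condition: str
    phase: str
    participant_ids: list[str]


def average_tfr(z_power: np.ndarray, epochs: EpochSet
                ) -> dict[tuple[str, str], np.ndarray | None]:
    """Average z-scored per-trial power into one map per condition x phase.

    The mean is taken across the two electrodes first, then across the
    included non-reinforced trials of the cell.  Cells without trials
    are returned as ``None`` (explicit missing marker), never as silent
    zeros.
    """
    cond = epochs.events["condition"].to_numpy()
    out: dict[tuple[str, str], np.ndarray | None] = {}
    chan_mean = z_power.mean(axis=1)
    nonreinf = epochs.included_nonreinforced()
    for c in ("CSu", "CSp"):
        for ph in ("early", "late"):
            mask = nonreinf & (cond == c) & (epochs.phase == ph)
            out[(c, ph)] = chan_mean[mask].mean(axis=0) if mask.any() else None
    return out


def band_envelope(values: np.ndarray, freqs: np.ndarray,
                  band: str | tuple[float, float]) -> np.ndarray:
    """Mean of z-scored power over the bins inside the closed band interval.

    ``values`` may have any leading shape; the frequency axis is -2 and
    time -1.
    """
    centers = band_bins(band, f_max=float(np.max(freqs)))
    idx = [int(np.argmin(np.abs(freqs - f))) for f in centers]
    missing = [f for f, i in zip(centers, idx) if abs(freqs[i] - f) > 1e-6]
    if missing:
        raise ValueError(f"band bins {missing} not present in the frequency axis")
    return values[..., idx, :].mean(axis=-2)


def trial_band_power(epochs: EpochSet, band: str | tuple[float, float],
                     pad_s: float = 2.0, ddof: int = 0) -> np.ndarray:
    """Per-trial band envelope: bin powers -> per-trial z-score -> band mean.

    Convenience path used by the pipeline when only the three analysis
    bands (not the full 80-bin map) are needed.  Returns
    (trials, channels, n_times).
    """
    freqs = band_bins(band)
    power, freqs = hilbert_power(epochs, freqs=freqs, pad_s=pad_s)
    z = zscore_trials(power, ddof=ddof)
    return z.mean(axis=2)


def tfr_to_long_frame(tfr: TimeFrequencyMap):
    """Export a TimeFrequencyMap to a long-format table (TSV-ready)."""
    import pandas as pd

    p, f, t = tfr.values.shape
    idx = pd.MultiIndex.from_product(
        [tfr.participant_ids, tfr.freqs, tfr.times_ms],
        names=["participant_id", "freq_hz", "time_ms"],
    )
    frame = pd.DataFrame({"z": tfr.values.reshape(-1)}, index=idx).reset_index()
    frame["condition"] = tfr.condition
    frame["phase"] = tfr.phase
    return frame
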