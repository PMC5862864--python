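"""Post-simulation analysis: firing rates, power spectra, coherence, rasters.

All operations take a :class:`~neusim.solver.SimData` and are usable either
standalone or as batch hooks (see :data:`HOOKS`). Spectral estimators use
scipy: a rectangular-window periodogram for power (mean-subtracted by
default) and Welch magnitude-squared coherence with a Hann window and 50%
overlap. Firing rates are whole-window spike counts over the analysis
window, which by default drops an onset transient of 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .solver import SimData

__all__ = [
    "RateResult",
    "SpectrumResult",
    "firing_rate",
    "power_spectrum",
    "coherence",
    "raster",
    "HOOKS",
]

DEFAULT_TRANSIENT_MS = 50.0


@dataclass
class RateResult:
    population: str
    rates: np.ndarray  # spikes/s per cell
    mean_rate: float
    window: tuple  # (t_start, t_end) ms
    bin_edges: np.ndarray | None = None
    binned: np.ndarray | None = None  # (bins, cells) rates if bin_ms given


@dataclass
class SpectrumResult:
    freqs: np.ndarray  # Hz
    power: np.ndarray  # density, averaged over cells
    peak_frequency: float
    signal: str = ""
    per_cell: np.ndarray | None = None  # (freqs, cells)


def _window(data: SimData, window, transient: float):
    t0, t1 = float(data.time[0]), float(data.time[-1])
    if window is None:
        # drop the onset transient, but never empty the window outright
        window = (t0 + transient, t1) if t0 + transient < t1 else (t0, t1)
    w0, w1 = float(window[0]), float(window[1])
    if not w1 > w0:
        raise ValueError(f"empty analysis window ({w0}, {w1})")
    return w0, w1


def firing_rate(data: SimData, population: str, window=None,
                transient: float = DEFAULT_TRANSIENT_MS,
                bin_ms: float | None = None) -> RateResult:
    """Per-cell and mean firing rates (spikes/s) over an analysis window.

    The window defaults to the full recorded span minus the onset
    transient. ``bin_ms`` additionally returns binned rates.
    """
    if population not in data.spikes:
        raise KeyError(
            f"no spikes recorded for population {population!r}; "
            f"available: {sorted(data.spikes)}"
        )
    w0, w1 = _window(data, window, transient)
    dur_s = (w1 - w0) / 1000.0
    cells = data.spikes[population]
    counts = np.array(
        [np.count_nonzero((c >= w0) & (c < w1)) for c in cells], dtype=float
    )
    rates = counts / dur_s
    result = RateResult(population, rates, float(rates.mean()), (w0, w1))
    if bin_ms is not None:
        edges = np.arange(w0, w1 + bin_ms, bin_ms)
        binned = np.stack(
            [np.histogram(c, bins=edges)[0] / (bin_ms / 1000.0) for c in cells],
            axis=1,
        )
        result.bin_edges = edges
        result.binned = binned
    return result


def _get_signal(data: SimData, name: str):
    if name not in data.series:
        raise KeyError(
            f"signal {name!r} was not recorded; available: {sorted(data.series)}"
        )
    return np.atleast_2d(np.asarray(data.series[name]).T).T


def power_spectrum(data: SimData, signal: str, detrend: bool = True,
                   window=None, transient: float = DEFAULT_TRANSIENT_MS,
                   fmin: float = 1.0, fmax: float | None = None,
                   average_cells: bool = True) -> SpectrumResult:
    """Rectangular-window periodogram, averaged over cells.

    ``detrend`` subtracts the mean of each trace. The reported peak
    frequency is the argmax of the averaged density on [fmin, fmax].
    With ``average_cells=False`` the population-mean trace is analyzed
    instead of averaging per-cell spectra.
    """
    w0, w1 = _window(data, window, transient)
    mask = (data.time >= w0) & (data.time <= w1)
    x = _get_signal(data, signal)[mask]
    if x.shape[0] < 4:
        raise ValueError("analysis window too short for a spectrum")
    fs = 1000.0 / float(data.time[1] - data.time[0])
    if not average_cells:
        x = x.mean(axis=1, keepdims=True)
    freqs, pxx = _sig.periodogram(
        x, fs=fs, window="boxcar",
        detrend=("constant" if detrend else False), axis=0,
    )
    mean_p = pxx.mean(axis=1)
    sel = freqs >= fmin
    if fmax is not None:
        sel &= freqs <= fmax
    if not sel.any():
        raise ValueError("no frequencies in the requested band")
    peak = float(freqs[sel][np.argmax(mean_p[sel])])
    return SpectrumResult(freqs, mean_p, peak, signal, per_cell=pxx)


def coherence(data: SimData, signal_a: str, signal_b: str,
              window=None, transient: float = DEFAULT_TRANSIENT_MS,
              nperseg: int | None = None, noverlap: int | None = None):
    """Welch magnitude-squared coherence between the population means of
    two recorded signals (Hann window, 50% overlap by default).

    Returns (freqs, coherence) with coherence values in [0, 1].
    """
    w0, w1 = _window(data, window, transient)
    mask = (data.time >= w0) & (data.time <= w1)
    a = _get_signal(data, signal_a)[mask].mean(axis=1)
    b = _get_signal(data, signal_b)[mask].mean(axis=1)
    if len(a) != len(b):
        raise ValueError("signals have different lengths")
    fs = 1000.0 / float(data.time[1] - data.time[0])
    if nperseg is None:
        nperseg = max(8, len(a) // 8)
    if nperseg * 2 > len(a):
        raise ValueError(
            f"fewer than 2 segments of {nperseg} samples in the window"
        )
    freqs, cxy = _sig.coherence(a, b, fs=fs, window="hann",
                                nperseg=nperseg, noverlap=noverlap)
    return freqs, np.clip(cxy, 0.0, 1.0)


def raster(data: SimData, population: str):
    """Flatten spikes to a time-sorted list of (cell index, spike time)."""
    if population not in data.spikes:
        return []
    pairs = [
        (i, float(t))
        for i, cell in enumerate(data.spikes[population])
        for t in cell
    ]
    pairs.sort(key=lambda p: (p[1], p[0]))
    return pairs


# ---------------------------------------------------------------------------
# hook registry (batch post-simulation analyses addressable by name)
# ---------------------------------------------------------------------------


def _hook_firing_rate(data: SimData) -> dict:
    out = {}
    for pop in sorted(data.spikes):
        r = firing_rate(data, pop)
        out[f"{pop}_mean_rate"] = r.mean_rate
        out[f"{pop}_rates"] = r.rates.tolist()
    return out


def _hook_power(data: SimData) -> dict:
    out = {}
    for name in sorted(data.series):
        try:
            s = power_spectrum(data, name)
        except (ValueError, KeyError):
            continue
        out[f"{name}_peak_frequency"] = s.peak_frequency
    return out


def _hook_coherence(data: SimData) -> dict:
    names = sorted(data.series)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                freqs, cxy = coherence(data, a, b)
            except ValueError:
                continue
            out[f"{a}__{b}_peak_coherence"] = float(np.max(cxy[freqs > 0]))
            out[f"{a}__{b}_peak_frequency"] = float(
                freqs[freqs > 0][np.argmax(cxy[freqs > 0])]
            )
    return out


#: built-in hooks addressable by name from run_batch and the CLI
HOOKS = {
    "firing_rate": _hook_firing_rate,
    "power": _hook_power,
    "coherence": _hook_coherence,
}
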