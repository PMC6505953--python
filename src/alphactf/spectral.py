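"""Band-limited instantaneous power from epoched time series.

Each trial and electrode is band-pass filtered with a zero-phase (two-pass
forward-backward) Hamming-window FIR filter of order ~3 x (sampling rate /
low cutoff), the analytic signal is obtained with a Hilbert transform on the
filtered epoch, and instantaneous power is the squared complex magnitude.
Downsampling keeps every k-th already-computed power sample (decimation
after power computation), so retained values are an exact subsequence of the
full-rate power.  Samples within one filter length of the epoch boundary are
flagged (``n_edge``) as unreliable.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sig

from .containers import EpochedPower, EpochedTimeseries

__all__ = ["band_power", "downsample_power", "band_sweep"]


def band_power(
    ts: EpochedTimeseries, low: float, high: float, order: int | None = None
) -> EpochedPower:
    """Instantaneous power in [low, high] Hz, at the native sampling rate."""
    nyq = ts.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band [{low}, {high}] must satisfy 0 < low < high < Nyquist ({nyq})")
    if order is None:
        order = int(3 * ts.sfreq / low)
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # type-I FIR: odd tap count keeps a band-pass response
    n_samples = ts.data.shape[2]
    padlen = 3 * numtaps
    if n_samples <= padlen:
        raise ValueError(
            f"epoch of {n_samples} samples is shorter than the filter transient "
            f"({padlen} samples for a {numtaps}-tap filter at {low} Hz)"
        )
    taps = sig.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=ts.sfreq)
    filtered = sig.filtfilt(taps, [1.0], ts.data, axis=-1, padlen=padlen)
    analytic = sig.hilbert(filtered, axis=-1)
    power = np.abs(analytic) ** 2
    return EpochedPower(
        power=power, times=ts.times.copy(), band=(low, high), sfreq=ts.sfreq, n_edge=numtaps
    )


def downsample_power(ep: EpochedPower, interval_ms: float) -> EpochedPower:
    """Keep one power sample every ``interval_ms`` (no re-averaging)."""
    if ep.sfreq is None:
        raise ValueError("power container carries no sampling rate")
    step = interval_ms * ep.sfreq / 1000.0
    if abs(step - round(step)) > 1e-9 or round(step) < 1:
        raise ValueError(
            f"interval of {interval_ms} ms is not an integer multiple of the "
            f"native sample period ({1000.0 / ep.sfreq} ms)"
        )
    step = int(round(step))
    return EpochedPower(
        power=ep.power[:, :, ::step],
        times=ep.times[::step],
        band=ep.band,
        sfreq=ep.sfreq / step,
        n_edge=int(np.ceil(ep.n_edge / step)),
    )


def band_sweep(
    ts: EpochedTimeseries, low: float = 4.0, high: float = 50.0, width: float = 1.0
) -> list[EpochedPower]:
    """Power in successive ``width``-Hz bands from ``low`` to ``high``.

    Defaults give 46 bands: [4, 5], [5, 6], ..., [49, 50] Hz.
    """
    edges = np.arange(low, high + 1e-9, width)
    if len(edges) < 2:
        raise ValueError("sweep needs at least one band")
    return [band_power(ts, edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
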