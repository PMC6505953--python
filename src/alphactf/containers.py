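"""In-memory containers and on-disk formats for epoched EEG-like data.

The package moves data around in three plain containers:

* :class:`EpochedTimeseries` -- voltage-like trials x electrodes x samples,
  the input to the spectral stage.
* :class:`EpochedPower` -- instantaneous band-limited power on the same
  trial/electrode grid, possibly downsampled in time.
* a trial-metadata table (a plain :class:`pandas.DataFrame`; see
  :mod:`alphactf.synth` for the column contract).

Epoched power travels as HDF5 (datasets ``power`` and ``times``, plus band
attributes); trial tables travel as CSV.  Both formats are deliberately
minimal so that real epoched EEG exported from any toolbox can be fed in.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochedTimeseries",
    "EpochedPower",
    "save_epoched_power",
    "load_epoched_power",
    "save_trials",
    "load_trials",
]


@dataclasses.dataclass
class EpochedTimeseries:
    """Epoched voltage-like data: ``data`` is (n_trials, n_electrodes, n_samples)."""

    data: np.ndarray
    sfreq: float
    times: np.ndarray  # milliseconds relative to stimulus onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must equal the number of samples")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class EpochedPower:
    """Instantaneous band power: ``power`` is (n_trials, n_electrodes, n_samples).

    ``n_edge`` marks how many samples at each end of the epoch lie within one
    filter length of the epoch boundary and are therefore unreliable; it is 0
    for synthetic power that never went through a filter.  Power produced by
    the spectral stage is non-negative; synthetic "power-like" data generated
    with additive Gaussian noise may contain negative values.
    """

    power: np.ndarray
    times: np.ndarray
    band: tuple[float, float] | None = None
    sfreq: float | None = None
    n_edge: int = 0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be trials x electrodes x samples")
        if self.times.shape != (self.power.shape[2],):
            raise ValueError("times length must equal the number of samples")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def interior(self) -> np.ndarray:
        """Power with edge-contaminated samples dropped."""
        if self.n_edge == 0:
            return self.power
        return self.power[:, :, self.n_edge : self.power.shape[2] - self.n_edge]


def save_epoched_power(path: str | Path, ep: EpochedPower) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=ep.power)
        f.create_dataset("times", data=ep.times)
        if ep.band is not None:
            f.attrs["band_low"] = float(ep.band[0])
            f.attrs["band_high"] = float(ep.band[1])
        if ep.sfreq is not None:
            f.attrs["sfreq"] = float(ep.sfreq)
        f.attrs["n_edge"] = int(ep.n_edge)


def load_epoched_power(path: str | Path) -> EpochedPower:
    with h5py.File(path, "r") as f:
        power = f["power"][()]
        times = f["times"][()]
        band = None
        if "band_low" in f.attrs:
            band = (float(f.attrs["band_low"]), float(f.attrs["band_high"]))
        sfreq = float(f.attrs["sfreq"]) if "sfreq" in f.attrs else None
        n_edge = int(f.attrs.get("n_edge", 0))
    return EpochedPower(power=power, times=times, band=band, sfreq=sfreq, n_edge=n_edge)


def save_trials(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
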