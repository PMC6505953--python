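"""The switching-account null: CTFs expected if items alternate in and out
of an active state.

If only one of two stored items is neurally active at any moment, each item
is represented at most half the time on average.  The expected CTF under
that account is simulated from one-item data by redrawing the position
labels of a random fraction (default 50%) of the one-item trials before
each IEM run; scrambled labels are redrawn uniformly over all 8 bins (a
redrawn label may coincide with the true bin).  The scramble is
re-randomized for every partition iteration.  The resulting slope series is
then compared with the observed two-item slopes over delay-period windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import BasisSet, IEMResult, N_BINS, run_iem
from .stats import WindowComparison, window_compare

__all__ = [
    "scramble_labels",
    "simulate_switching",
    "run_switching_analysis",
    "compare_switching",
]

DEFAULT_WINDOWS = ((250.0, 1250.0), (800.0, 1250.0))


def scramble_labels(
    trials: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
    redraw_over_all_bins: bool = True,
) -> pd.DataFrame:
    """Copy of ``trials`` with a random fraction of position labels redrawn.

    ``redraw_over_all_bins=False`` redraws over the 7 non-true bins instead
    of all 8.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = trials.copy()
    n = len(out)
    pick = rng.random(n) < fraction
    if pick.any():
        old = out.loc[pick, "bin_probed"].to_numpy()
        if redraw_over_all_bins:
            new = rng.integers(0, N_BINS, size=pick.sum())
        else:
            shift = rng.integers(1, N_BINS, size=pick.sum())
            new = (old + shift) % N_BINS
        out.loc[pick, "bin_probed"] = new
    return out


def simulate_switching(
    power: np.ndarray,
    trials: pd.DataFrame,
    fraction: float = 0.5,
    n_iterations: int = 10,
    seed: np.random.Generator | int | None = None,
    basis: BasisSet | None = None,
    times: np.ndarray | None = None,
    redraw_over_all_bins: bool = True,
) -> IEMResult:
    """CTF time series expected under the switching account.

    ``power`` and ``trials`` are a subject's one-item data.  Before each of
    the ``n_iterations`` IEM runs a fresh random ``fraction`` of trials get
    their position labels redrawn; the standard partitioning/cross-validation
    pipeline then runs unchanged on the relabeled table, and results are
    averaged over iterations.  ``fraction=0`` reduces exactly to the
    standard one-item analysis.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if fraction == 0.0:
        # identity scramble: reduces exactly to the standard analysis
        return run_iem(
            power, trials, regime="condition_neutral", n_iterations=n_iterations,
            seed=rng, basis=basis, times=times,
        )
    acc_ctf = None
    conditions = None
    for _ in range(n_iterations):
        scrambled = scramble_labels(trials, fraction, rng, redraw_over_all_bins)
        res = run_iem(
            power,
            scrambled,
            regime="condition_neutral",
            n_iterations=1,
            seed=rng,
            basis=basis,
            times=times,
        )
        if acc_ctf is None:
            acc_ctf = res.ctf.copy()
            conditions = res.conditions
            offsets = res.offsets
            out_times = res.times
        else:
            acc_ctf += res.ctf
    acc_ctf /= n_iterations
    from .stats import ctf_slope

    return IEMResult(
        ctf=acc_ctf,
        slopes=ctf_slope(acc_ctf),
        conditions=conditions,
        offsets=offsets,
        times=out_times,
    )


def run_switching_analysis(
    power: np.ndarray,
    trials: pd.DataFrame,
    fraction: float = 0.5,
    n_iterations: int = 10,
    seed: np.random.Generator | int | None = None,
    basis: BasisSet | None = None,
    times: np.ndarray | None = None,
    redraw_over_all_bins: bool = True,
) -> IEMResult:
    """Joint two-item vs simulated-switching analysis under one shared model.

    ``power``/``trials`` hold a subject's full dataset (both load
    conditions).  Per iteration, the one-item trials' position labels are
    scrambled (fraction as in :func:`simulate_switching`) and relabeled as a
    ``switching`` condition; a single condition-neutral IEM is then trained
    on equal trial counts from the switching and two-item conditions and
    tested on each separately.  Training matrices are byte-identical for
    both conditions' tests, so the comparison isolates differences in test
    content -- the design under which a strict-alternation ground truth
    predicts no two-item vs switching difference.
    """
    rng = np.random.default_rng(seed)
    one = trials["condition"] == "one_item"
    if not one.any() or not (trials["condition"] == "two_item").any():
        raise ValueError("joint switching analysis needs both load conditions")
    acc_ctf = None
    for _ in range(n_iterations):
        tbl = trials.copy()
        scrambled = scramble_labels(tbl.loc[one], fraction, rng, redraw_over_all_bins)
        tbl.loc[one, "bin_probed"] = scrambled["bin_probed"].to_numpy()
        tbl.loc[one, "condition"] = "switching"
        res = run_iem(
            power,
            tbl,
            regime="condition_neutral",
            n_iterations=1,
            seed=rng,
            basis=basis,
            times=times,
        )
        if acc_ctf is None:
            acc_ctf = res.ctf.copy()
            conditions = res.conditions
            offsets = res.offsets
            out_times = res.times
        else:
            acc_ctf += res.ctf
    acc_ctf /= n_iterations
    from .stats import ctf_slope

    return IEMResult(
        ctf=acc_ctf,
        slopes=ctf_slope(acc_ctf),
        conditions=conditions,
        offsets=offsets,
        times=out_times,
    )


def compare_switching(
    two_item_slopes: np.ndarray,
    switching_slopes: np.ndarray,
    times: np.ndarray | None = None,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
) -> dict[tuple[float, float], WindowComparison]:
    """Paired comparison of two-item vs switching slopes per delay window.

    ``two_item_slopes`` and ``switching_slopes`` are (n_subjects, n_times)
    arrays (or (n_subjects,) for single-time data, in which case windows are
    ignored).
    """
    two = np.asarray(two_item_slopes, dtype=float)
    sw = np.asarray(switching_slopes, dtype=float)
    if two.ndim == 1 or times is None:
        return {(np.nan, np.nan): window_compare(two, sw)}
    return {w: window_compare(two, sw, times=times, window=w) for w in windows}
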