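"""Inverted encoding model (IEM) for spatial channel-tuning functions.

The model assumes the band-limited power at each electrode is a weighted sum
of ``k`` spatially tuned channels.  Each channel's response profile across
angular position is a half sinusoid raised to a power (default 25),
circularly shifted so channel centers sit on the 8 position-bin centers
(0, 45, ..., 315 deg).  Training estimates the electrode-by-channel weight
matrix by ordinary least squares,

    W_hat = B1 C1' (C1 C1')^-1,

and testing inverts the mapping on held-out data,

    C2_hat = (W_hat' W_hat)^-1 W_hat' B2,

where B are electrodes-by-measurements power matrices and C1 holds the
channels' predicted responses for each training measurement.  Measurements
are bin averages: trials are partitioned into three sets with equal trial
counts per position bin (and per condition where applicable), each set's
trials are averaged within bin, two sets train and one tests, and every set
serves once as the test set.  Estimated channel-response profiles are
circularly shifted so the channel tuned to the probed bin sits at offset 0,
then averaged over bins, folds, and partition iterations to give the
channel-tuning function (CTF).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "N_BINS",
    "BIN_WIDTH",
    "OFFSETS_DEG",
    "BasisSet",
    "make_basis",
    "channel_response",
    "predicted_responses",
    "average_by_bin",
    "train_weights",
    "invert_model",
    "PartitionScheme",
    "partition_trials",
    "IEMResult",
    "run_iem",
    "distance_profile",
]

N_BINS = 8
BIN_WIDTH = 45.0

# Channel-offset grid of the aligned CTF, in degrees.  Offsets are defined as
# (channel center - probed bin center) mod 360 mapped to (-180, 180]; +180 is
# its own fold partner.
OFFSETS_DEG = np.array([-135, -90, -45, 0, 45, 90, 135, 180], dtype=float)

# shift index s (channel index relative to probed bin, mod 8) for each entry
# of OFFSETS_DEG: offset = ((45*s + 180) % 360) - 180
_SHIFT_FOR_OFFSET = np.array([5, 6, 7, 0, 1, 2, 3, 4])


def _ipow(x: np.ndarray, n: float) -> np.ndarray:
    """x**n, using multiply chains for small integer exponents (hot path)."""
    if float(n).is_integer() and 0 < n <= 64:
        n = int(n)
        out = np.ones_like(x)
        base = x
        while n:
            if n & 1:
                out = out * base
            base = base * base
            n >>= 1
        return out
    return np.power(x, n)


def channel_response(distance_deg: np.ndarray | float, exponent: float = 25) -> np.ndarray:
    """Idealized channel response at an angular distance from the channel center.

    Equals ``cos(d/2)**exponent`` for the wrapped distance ``d``; this is the
    half sinusoid ``sin(0.5*theta)**exponent`` expressed as a function of
    distance from the peak.  Peak response 1 at distance 0, response 0 at
    180 deg.
    """
    # |cos(d/2)| equals cos(d_wrapped/2) for any unwrapped distance, sparing
    # an explicit modular wrap on this hot path
    return _ipow(np.abs(np.cos(np.asarray(distance_deg) * (np.pi / 360.0))), exponent)


@dataclasses.dataclass
class BasisSet:
    """Predicted channel responses over integer angles 0..359.

    ``responses[c, theta]`` is channel ``c``'s predicted response to a
    stimulus at angle ``theta``; ``centers`` holds the channel-center angles.
    """

    responses: np.ndarray
    centers: np.ndarray
    exponent: float

    @property
    def n_channels(self) -> int:
        return self.responses.shape[0]

    def design_matrix(self, bins: np.ndarray) -> np.ndarray:
        """Channels x len(bins) predicted responses at the given bin centers."""
        return predicted_responses(self.centers[np.asarray(bins)], self.centers, self.exponent)


def make_basis(k: int = N_BINS, exponent: float = 25) -> BasisSet:
    if k < 2:
        raise ValueError("need at least 2 channels")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    centers = np.arange(k) * (360.0 / k)
    theta = np.arange(360.0)
    responses = channel_response(theta[None, :] - centers[:, None], exponent)
    return BasisSet(responses=responses, centers=centers, exponent=exponent)


def predicted_responses(
    angles_deg: np.ndarray, centers: np.ndarray, exponent: float = 25
) -> np.ndarray:
    """Channels x n matrix of idealized responses to stimuli at ``angles_deg``."""
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    return channel_response(angles[None, :] - np.asarray(centers)[:, None], exponent)


# ---------------------------------------------------------------------------
# training / inversion
# ---------------------------------------------------------------------------


def average_by_bin(
    power: np.ndarray, bins: np.ndarray, trial_idx: np.ndarray | None = None, n_bins: int = N_BINS
) -> np.ndarray:
    """Mean power per position bin: electrodes x n_bins (x time).

    ``power`` is (n_trials, n_electrodes[, n_times]); ``trial_idx`` selects a
    subset (e.g. one partition set).  Raises if any bin is empty in the
    selection.
    """
    power = np.asarray(power)
    bins = np.asarray(bins)
    if trial_idx is not None:
        power = power[trial_idx]
        bins = bins[trial_idx]
    out = np.empty((power.shape[1], n_bins) + power.shape[2:], dtype=float)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            raise ValueError(f"position bin {b} has no trials in this selection")
        out[:, b] = power[mask].mean(axis=0)
    return out


def train_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares weights W_hat (electrodes x channels) from training data.

    Solves ``B1 = W C1`` row-wise per electrode; the value equals
    ``B1 C1' (C1 C1')^-1`` but is computed via a least-squares factorization.
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    if B1.shape[1] != C1.shape[1]:
        raise ValueError("B1 and C1 must share the measurement dimension")
    k = C1.shape[0]
    if np.linalg.matrix_rank(C1) < k:
        raise np.linalg.LinAlgError(
            "training design C1 is rank deficient: the training bins do not "
            f"span all {k} channels"
        )
    W, *_ = np.linalg.lstsq(C1.T, B1.T, rcond=None)
    return W.T


def invert_model(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Estimated channel responses (channels x n2) from test data B2.

    Computes ``(W' W)^-1 W' B2`` via a least-squares factorization.
    """
    W = np.asarray(W, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if W.shape[0] < W.shape[1] or np.linalg.matrix_rank(W) < W.shape[1]:
        raise np.linalg.LinAlgError(
            "weight matrix is rank deficient; cannot invert the encoding model"
        )
    C2, *_ = np.linalg.lstsq(W, B2, rcond=None)
    return C2


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

REGIMES = ("condition_neutral", "within_condition", "cross_training")


@dataclasses.dataclass
class PartitionScheme:
    """Assignment of trials to sets; -1 marks excess (unassigned) trials."""

    set_id: np.ndarray
    n_sets: int
    n_per_cell: int | dict

    def trials_in(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.set_id == s)

    @property
    def n_unassigned(self) -> int:
        return int((self.set_id == -1).sum())


def partition_trials(
    trials: pd.DataFrame,
    n_sets: int = 3,
    regime: str = "condition_neutral",
    rng: np.random.Generator | int | None = None,
) -> PartitionScheme:
    """Randomly partition trials into sets with equal per-bin trial counts.

    In the ``condition_neutral`` regime the per-bin count is additionally
    equated across conditions (so condition-combined training sets are
    balanced); the other regimes equate counts within each condition
    separately.  Excess trials beyond the largest common per-cell count are
    left unassigned; re-randomizing draws a different excess.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    rng = np.random.default_rng(rng)
    bins = trials["bin_probed"].to_numpy()
    conds = trials["condition"].to_numpy()
    n = len(bins)
    set_id = np.full(n, -1, dtype=int)

    cells = {}
    for c in pd.unique(conds):
        for b in range(N_BINS):
            idx = np.flatnonzero((conds == c) & (bins == b))
            cells[(c, b)] = idx

    short = [key for key, idx in cells.items() if len(idx) < n_sets]
    if short:
        raise ValueError(f"not enough trials to fill {n_sets} sets in cells: {short}")

    if regime == "condition_neutral":
        n_per = min(len(idx) // n_sets for idx in cells.values())
        per_cell: int | dict = n_per
        n_per_map = {key: n_per for key in cells}
    else:
        n_per_map = {}
        for c in pd.unique(conds):
            n_c = min(len(cells[(c, b)]) // n_sets for b in range(N_BINS))
            for b in range(N_BINS):
                n_per_map[(c, b)] = n_c
        per_cell = {c: n_per_map[(c, 0)] for c in pd.unique(conds)}

    for key, idx in cells.items():
        n_per = n_per_map[key]
        chosen = rng.permutation(idx)[: n_per * n_sets]
        set_id[chosen] = np.repeat(np.arange(n_sets), n_per)

    return PartitionScheme(set_id=set_id, n_sets=n_sets, n_per_cell=per_cell)


# ---------------------------------------------------------------------------
# the full IEM routine
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class IEMResult:
    """Aligned CTFs and their slopes per condition and time point.

    ``ctf`` is (n_conditions, n_times, 8) on the :data:`OFFSETS_DEG` grid;
    ``slopes`` is (n_conditions, n_times).
    """

    ctf: np.ndarray
    slopes: np.ndarray
    conditions: list[str]
    offsets: np.ndarray
    times: np.ndarray | None = None

    def condition(self, name: str) -> int:
        return self.conditions.index(name)


def _align(C2: np.ndarray, test_bins: np.ndarray) -> np.ndarray:
    """Average circularly shifted channel-response columns onto OFFSETS_DEG.

    ``C2`` is (k, n_bins[, n_times]); column j was tested on ``test_bins[j]``.
    Offset o picks channel ``(bin + o/45) mod 8`` from each column.
    """
    k = C2.shape[0]
    chan = (np.asarray(test_bins)[None, :] + _SHIFT_FOR_OFFSET[:, None]) % k
    # gather -> (8 offsets, n_bins[, n_times]), average over bins
    return C2[chan, np.arange(C2.shape[1])[None, :]].mean(axis=1)


def _bin_means_per_set(
    power: np.ndarray,
    bins: np.ndarray,
    conds: np.ndarray,
    part: PartitionScheme,
    condition_names: list[str],
) -> np.ndarray:
    """(n_cond, n_sets, n_elec, N_BINS, n_times) set-wise bin means."""
    n_cond = len(condition_names)
    out = np.zeros((n_cond, part.n_sets, power.shape[1], N_BINS, power.shape[2]))
    for ci, c in enumerate(condition_names):
        for s in range(part.n_sets):
            sel = np.flatnonzero((part.set_id == s) & (conds == c))
            out[ci, s] = average_by_bin(power, bins, sel)
    return out


def _permute_labels_within_sets(
    bins: np.ndarray, conds: np.ndarray, part: PartitionScheme, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle position labels among the trials of each (set, condition) cell."""
    out = bins.copy()
    for s in range(part.n_sets):
        for c in np.unique(conds):
            sel = np.flatnonzero((part.set_id == s) & (conds == c))
            out[sel] = rng.permutation(out[sel])
    return out


def run_iem(
    power: np.ndarray,
    trials: pd.DataFrame,
    regime: str = "condition_neutral",
    n_iterations: int = 10,
    seed: np.random.Generator | int | None = None,
    basis: BasisSet | None = None,
    times: np.ndarray | None = None,
    permute_labels: bool = False,
) -> IEMResult:
    """Full cross-validated IEM for one subject.

    ``power`` is (n_trials, n_electrodes) or (n_trials, n_electrodes,
    n_times); ``trials`` must carry ``condition`` and ``bin_probed`` columns.
    ``regime`` selects how training and test sets are built:

    * ``condition_neutral`` -- training sets combine equal trial counts from
      every condition (a single encoding model); each condition is tested
      separately on the held-out set.
    * ``within_condition`` -- train and test within each condition.
    * ``cross_training`` -- train on one-item sets, test on the held-out
      two-item set (result carries only the two-item condition).

    ``permute_labels`` shuffles position labels within every training and
    test set before each iteration's model fit; this is the label
    randomization used to build the cluster-test null distribution.
    """
    rng = np.random.default_rng(seed)
    power = np.asarray(power, dtype=float)
    squeeze = power.ndim == 2
    if squeeze:
        power = power[:, :, None]
    if basis is None:
        basis = make_basis()
    if power.shape[1] < basis.n_channels:
        raise ValueError("need at least as many electrodes as channels")

    bins_true = trials["bin_probed"].to_numpy().astype(int)
    conds = trials["condition"].to_numpy()
    if regime == "cross_training":
        test_conditions = ["two_item"]
    else:
        test_conditions = [str(c) for c in pd.unique(conds)]
    all_conditions = [str(c) for c in pd.unique(conds)]

    C0 = basis.design_matrix(np.arange(N_BINS))
    n_times = power.shape[2]
    acc = np.zeros((len(test_conditions), len(OFFSETS_DEG), n_times))

    for _ in range(n_iterations):
        part = partition_trials(trials, 3, regime, rng)
        bins = bins_true
        if permute_labels:
            bins = _permute_labels_within_sets(bins_true, conds, part, rng)
        means = _bin_means_per_set(power, bins, conds, part, all_conditions)

        for f in range(part.n_sets):
            train_sets = [s for s in range(part.n_sets) if s != f]
            if regime == "condition_neutral":
                # combine conditions before averaging; equal counts per cell
                # make this the plain average of the per-condition bin means
                train_blocks = [means[:, s].mean(axis=0) for s in train_sets]
                B1 = np.concatenate(train_blocks, axis=1)
                C1 = np.concatenate([C0] * len(train_sets), axis=1)
                for t in range(n_times):
                    W = train_weights(B1[:, :, t], C1)
                    for ci, c in enumerate(test_conditions):
                        B2 = means[all_conditions.index(c), f, :, :, t]
                        C2 = invert_model(W, B2)
                        acc[ci, :, t] += _align(C2, np.arange(N_BINS))
            elif regime == "within_condition":
                for ci, c in enumerate(test_conditions):
                    mi = all_conditions.index(c)
                    B1 = np.concatenate([means[mi, s] for s in train_sets], axis=1)
                    C1 = np.concatenate([C0] * len(train_sets), axis=1)
                    for t in range(n_times):
                        W = train_weights(B1[:, :, t], C1)
                        C2 = invert_model(W, means[mi, f, :, :, t])
                        acc[ci, :, t] += _align(C2, np.arange(N_BINS))
            else:  # cross_training
                one = all_conditions.index("one_item")
                two = all_conditions.index("two_item")
                B1 = np.concatenate([means[one, s] for s in train_sets], axis=1)
                C1 = np.concatenate([C0] * len(train_sets), axis=1)
                for t in range(n_times):
                    W = train_weights(B1[:, :, t], C1)
                    C2 = invert_model(W, means[two, f, :, :, t])
                    acc[0, :, t] += _align(C2, np.arange(N_BINS))

    ctf = acc / (n_iterations * 3)
    # slope computed here to spare callers the import; stats.ctf_slope is the
    # canonical definition
    from .stats import ctf_slope

    slopes = ctf_slope(np.moveaxis(ctf, 1, -1))
    times_out = times if times is not None else (None if squeeze else np.arange(n_times))
    return IEMResult(
        ctf=np.transpose(ctf, (0, 2, 1)),
        slopes=slopes,
        conditions=test_conditions,
        offsets=OFFSETS_DEG.copy(),
        times=times_out,
    )


def distance_profile(
    power: np.ndarray,
    trials: pd.DataFrame,
    n_iterations: int = 10,
    seed: np.random.Generator | int | None = None,
    basis: BasisSet | None = None,
) -> dict[int, np.ndarray]:
    """Channel-response profile per inter-item bin distance (0..180 deg).

    Trains on two sets of one-item data and tests on the held-out two-item
    set, separately for each bin distance between the probed and unprobed
    item.  Profiles are aligned so the unprobed item always lies clockwise
    (positive offsets): counterclockwise cases are mirrored before pooling
    with their clockwise partner.  Distances with no test trials in a fold
    are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    power = np.asarray(power, dtype=float)
    if power.ndim == 3:
        if power.shape[2] != 1:
            raise ValueError("distance_profile expects a single time point")
        power = power[:, :, 0]
    if basis is None:
        basis = make_basis()
    bins = trials["bin_probed"].to_numpy().astype(int)
    conds = trials["condition"].to_numpy()
    ub = trials["bin_unprobed"].to_numpy()
    C0 = basis.design_matrix(np.arange(N_BINS))

    signed = np.full(len(bins), -1, dtype=int)
    two = conds == "two_item"
    signed[two] = (ub[two].astype(int) - bins[two]) % N_BINS

    acc: dict[int, np.ndarray] = {d: np.zeros(len(OFFSETS_DEG)) for d in range(5)}
    cnt: dict[int, int] = {d: 0 for d in range(5)}

    for _ in range(n_iterations):
        part = partition_trials(trials, 3, "cross_training", rng)
        for f in range(3):
            train_sets = [s for s in range(3) if s != f]
            B1 = np.concatenate(
                [
                    average_by_bin(power, bins, np.flatnonzero((part.set_id == s) & (conds == "one_item")))
                    for s in train_sets
                ],
                axis=1,
            )
            W = train_weights(B1, np.concatenate([C0, C0], axis=1))
            for sd in range(N_BINS):
                sel = np.flatnonzero((part.set_id == f) & two & (signed == sd))
                if sel.size == 0:
                    warnings.warn(f"no two-item test trials at signed bin distance {sd}; skipped")
                    continue
                present = np.unique(bins[sel])
                prof = np.zeros(len(OFFSETS_DEG))
                for b in present:
                    col = power[sel[bins[sel] == b]].mean(axis=0)[:, None]
                    C2 = invert_model(W, col)
                    prof += _align(C2, np.array([b]))
                prof /= len(present)
                d = min(sd, N_BINS - sd)  # 0..4 -> 0,45,90,135,180 deg
                if sd > N_BINS - sd:
                    # mirror so the unprobed item sits at positive offsets
                    prof = _mirror_profile(prof)
                acc[d] += prof
                cnt[d] += 1

    out = {}
    for d in range(5):
        if cnt[d]:
            out[d * 45] = acc[d] / cnt[d]
        else:
            warnings.warn(f"inter-item distance {d * 45} deg never observed; omitted")
    return out


def _mirror_profile(prof: np.ndarray) -> np.ndarray:
    """Reflect a profile on OFFSETS_DEG about offset 0 (offset o -> -o)."""
    mirrored = np.empty_like(prof)
    for i, o in enumerate(OFFSETS_DEG):
        target = -o if o != 180 else 180.0
        j = int(np.flatnonzero(OFFSETS_DEG == target)[0])
        mirrored[j] = prof[i]
    return mirrored
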