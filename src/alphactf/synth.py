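"""Synthetic subjects, trials, electrode data, and behavioral errors.

The generator emulates a spatial delayed-estimation experiment: on each
trial one or two items appear at angular positions drawn from 8 position
bins (45-deg wedges centered at 0, 45, ..., 315 deg) with uniform jitter
inside the wedge.  On two-item trials the ordered pair of position bins is
exactly counterbalanced (each of the 64 ordered pairs occurs equally often)
and the two exact positions respect a minimum angular separation.

Electrode data follow the forward model the encoding stage assumes: each of
30 electrodes is a random nonnegative weighted sum (weights uniform on
[0, 1]) of 8 spatially tuned channels whose response to a stimulus at
distance ``d`` from their center is ``cos(d/2)**25``.  Two-item responses
are additive by default (optionally scaled, or replaced by a strict
single-item alternation), and i.i.d. Gaussian noise of a per-condition SD
is added per electrode and trial.

All randomness flows through one :class:`numpy.random.Generator` per run;
per-subject streams are split off the run's seed sequence so subjects are
independent and reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import EpochedPower
from .encoding import BIN_WIDTH, N_BINS, predicted_responses

__all__ = [
    "CONDITIONS",
    "bin_centers",
    "sample_trial_positions",
    "SimulatedSubject",
    "generate_subject",
    "BehavioralGenerator",
    "generate_behavioral_errors",
    "generate_timecourse_dataset",
]

CONDITIONS = ("one_item", "two_item")


def bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    return np.arange(n_bins) * (360.0 / n_bins)


def _jitter(rng: np.random.Generator, size, width: float = BIN_WIDTH) -> np.ndarray:
    # uniform over the wedge: maximum-entropy jitter covering all 360 deg
    if width == 0:
        return np.zeros(size)
    return rng.uniform(-width / 2, width / 2, size=size)


def _circdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def sample_trial_positions(
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator | int | None = None,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Trial table for one condition with exact bin-pair counterbalancing.

    One-item trials place each bin ``n/8`` times; two-item trials place each
    ordered (probed, unprobed) bin pair exactly ``n/64`` times.  Exact
    angles are the bin center plus uniform jitter over the wedge; two-item
    jitters are redrawn until the items are at least
    ``config.min_item_separation`` degrees apart.  Row order is shuffled.
    """
    rng = np.random.default_rng(rng)
    n = config.n_trials_per_condition
    if condition == "one_item":
        if n % N_BINS:
            raise ValueError(f"one-item trial count must be divisible by {N_BINS}")
        bins = np.repeat(np.arange(N_BINS), n // N_BINS)
        df = pd.DataFrame(
            {
                "subject_id": subject_id,
                "condition": condition,
                "bin_probed": bins,
                "angle_probed": (bin_centers()[bins] + _jitter(rng, n, config.jitter_width)) % 360.0,
                "bin_unprobed": np.nan,
                "angle_unprobed": np.nan,
            }
        )
    elif condition == "two_item":
        n_pairs = N_BINS * N_BINS
        if n % n_pairs:
            raise ValueError(f"two-item trial count must be divisible by {n_pairs}")
        per = n // n_pairs
        probed = np.repeat(np.arange(N_BINS), N_BINS * per)
        unprobed = np.tile(np.repeat(np.arange(N_BINS), per), N_BINS)
        ang_p = (bin_centers()[probed] + _jitter(rng, n, config.jitter_width)) % 360.0
        ang_u = (bin_centers()[unprobed] + _jitter(rng, n, config.jitter_width)) % 360.0
        # separation is enforceable only when jitter can move the items apart
        if config.jitter_width > config.min_item_separation:
            for _ in range(200):
                bad = _circdist(ang_p, ang_u) < config.min_item_separation
                if not bad.any():
                    break
                ang_p[bad] = (bin_centers()[probed[bad]] + _jitter(rng, bad.sum(), config.jitter_width)) % 360.0
                ang_u[bad] = (bin_centers()[unprobed[bad]] + _jitter(rng, bad.sum(), config.jitter_width)) % 360.0
            else:  # pragma: no cover - unreachable for sane separations
                raise RuntimeError("could not satisfy the minimum item separation")
        df = pd.DataFrame(
            {
                "subject_id": subject_id,
                "condition": condition,
                "bin_probed": probed,
                "angle_probed": ang_p,
                "bin_unprobed": unprobed.astype(float),
                "angle_unprobed": ang_u,
            }
        )
    else:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


@dataclasses.dataclass
class SimulatedSubject:
    """One synthetic subject: power-like electrode data plus ground truth."""

    electrode_data: np.ndarray  # (n_trials, n_electrodes)
    true_weights: np.ndarray  # (n_electrodes, n_channels)
    trials: pd.DataFrame


def _channel_responses(config: SimulationConfig, trials: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Noiseless channel responses C (n_channels x n_trials) for a trial table."""
    centers = bin_centers(config.n_channels)
    C = predicted_responses(trials["angle_probed"].to_numpy(), centers, config.basis_exponent)
    two = (trials["condition"] == "two_item").to_numpy()
    if two.any():
        C2 = predicted_responses(
            trials.loc[two, "angle_unprobed"].to_numpy(), centers, config.basis_exponent
        )
        if config.two_item_encoding == "additive":
            C[:, two] += C2
        else:  # alternating: each trial carries exactly one of the two items
            use_unprobed = rng.random(two.sum()) < 0.5
            block = C[:, two]
            block[:, use_unprobed] = C2[:, use_unprobed]
            C[:, two] = block
        C[:, two] *= config.amplitude_scale_two_item
    return C


def generate_subject(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    subject_id: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> SimulatedSubject:
    """Generate one subject's trials and noisy electrode data.

    A subject has a single weight matrix (one head): the same weights map
    channels to electrodes in every condition.  Electrode data are
    ``(W C)' + noise`` with per-condition noise SD.
    """
    rng = np.random.default_rng(rng)
    trials = pd.concat(
        [sample_trial_positions(config, c, rng, subject_id) for c in conditions],
        ignore_index=True,
    )
    W = rng.uniform(0.0, 1.0, size=(config.n_electrodes, config.n_channels))
    C = _channel_responses(config, trials, rng)
    data = (W @ C).T
    sd = np.where(
        (trials["condition"] == "two_item").to_numpy(),
        config.noise_sd_two_item,
        config.noise_sd_one_item,
    )
    data = data + rng.standard_normal(data.shape) * sd[:, None]
    return SimulatedSubject(electrode_data=data, true_weights=W, trials=trials)


# ---------------------------------------------------------------------------
# behavioral generator
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BehavioralGenerator:
    """Generative twin of the response-error mixture model.

    With probability ``p_guess`` the response is uniform on the circle; with
    probability ``p_swap`` it is a von Mises centered on the unprobed item's
    offset; otherwise a von Mises centered on the target.  ``sd_target`` is
    the circular SD (degrees) of the von Mises components.
    """

    sd_target: float = 15.0
    p_guess: float = 0.0
    p_swap: float = 0.0
    n_trials: int = 576
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd_target <= 0:
            raise ValueError("sd_target must be positive")
        if self.p_guess < 0 or self.p_swap < 0 or self.p_guess + self.p_swap > 1:
            raise ValueError("need p_guess, p_swap >= 0 and p_guess + p_swap <= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def generate_behavioral_errors(
    gen: BehavioralGenerator,
    rng: np.random.Generator | int | None = None,
    nontarget_offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed response errors (degrees) plus component labels and offsets.

    Returns ``(errors, labels, nontarget_offsets)`` with labels in
    {"target", "guess", "swap"}.  If ``nontarget_offsets`` is not supplied,
    unprobed-item offsets are drawn from the counterbalanced two-item trial
    structure (a uniformly random non-identical bin plus jitter), mirroring
    the task.
    """
    from .behavior import kappa_from_sd, wrap_error

    rng = np.random.default_rng(rng if rng is not None else gen.seed)
    n = gen.n_trials
    if nontarget_offsets is None:
        probed = rng.integers(0, N_BINS, size=n)
        unprobed = rng.integers(0, N_BINS, size=n)
        off = (unprobed - probed) * BIN_WIDTH + _jitter(rng, n) - _jitter(rng, n)
        nontarget_offsets = wrap_error(off)
    kappa = kappa_from_sd(gen.sd_target)
    labels = rng.choice(
        np.array(["target", "guess", "swap"]),
        size=n,
        p=[1.0 - gen.p_guess - gen.p_swap, gen.p_guess, gen.p_swap],
    )
    errors = np.empty(n)
    t = labels == "target"
    g = labels == "guess"
    s = labels == "swap"
    errors[t] = np.rad2deg(rng.vonmises(0.0, kappa, size=int(t.sum())))
    errors[g] = rng.uniform(-180.0, 180.0, size=int(g.sum()))
    errors[s] = nontarget_offsets[s] + np.rad2deg(rng.vonmises(0.0, kappa, size=int(s.sum())))
    return wrap_error(errors), labels, np.asarray(nontarget_offsets)


# ---------------------------------------------------------------------------
# time-resolved fixture generator
# ---------------------------------------------------------------------------


def generate_timecourse_dataset(
    config: SimulationConfig,
    tuning_onset: float,
    tuning_offset: float,
    rng: np.random.Generator | int | None = None,
    times: np.ndarray | None = None,
    conditions: tuple[str, ...] = ("one_item",),
    subject_id: int = 0,
) -> tuple[EpochedPower, pd.DataFrame]:
    """Epoched power with spatial tuning confined to a known time window.

    Outside ``[tuning_onset, tuning_offset]`` (ms) electrode samples are pure
    Gaussian noise; inside, they follow the forward model of
    :func:`generate_subject` (one shared weight matrix across conditions).
    Gives the time-resolved pipeline and the cluster test a ground-truth
    effect window.
    """
    if tuning_onset >= tuning_offset:
        raise ValueError("tuning_onset must precede tuning_offset")
    rng = np.random.default_rng(rng)
    if times is None:
        times = np.arange(-500.0, 1500.0, 20.0)
    times = np.asarray(times, dtype=float)
    trials = pd.concat(
        [sample_trial_positions(config, c, rng, subject_id) for c in conditions],
        ignore_index=True,
    )
    W = rng.uniform(0.0, 1.0, size=(config.n_electrodes, config.n_channels))
    C = _channel_responses(config, trials, rng)
    signal = (W @ C).T  # (n_trials, n_electrodes)
    sd = np.where(
        (trials["condition"] == "two_item").to_numpy(),
        config.noise_sd_two_item,
        config.noise_sd_one_item,
    )
    n_t = len(times)
    power = rng.standard_normal((len(trials), config.n_electrodes, n_t)) * sd[:, None, None]
    inside = (times >= tuning_onset) & (times <= tuning_offset)
    power[:, :, inside] += signal[:, :, None]
    ep = EpochedPower(power=power, times=times, band=None, sfreq=1000.0 / np.diff(times).mean())
    return ep, trials
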