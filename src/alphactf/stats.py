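"""Selectivity quantification and inference for channel-tuning functions.

CTF slope
    The aligned 8-point CTF is folded by averaging channels equidistant from
    the tuned channel (offsets +-45, +-90, +-135), giving 5 values at
    distances 180, 135, 90, 45, 0.  The slope is the OLS regression slope of
    those values (ordered by decreasing distance) against the unit-spaced
    ranks 1..5.  The x-axis is rank, not degrees, so slope magnitudes are
    scale-free; this is the convention under which delay-period selectivity
    for real alpha-band data falls in the ~0.06-0.09 range.

Cluster-based permutation test
    One-sample t tests against zero at each time (or time-frequency) point;
    contiguous suprathreshold points form clusters whose mass is the summed
    t; the observed masses are compared against the null distribution of the
    maximum cluster mass over label-randomized re-runs (one-tailed, 95th
    percentile).  The default threshold is the one-sided p=.05 critical t
    recomputed from the subject count (1.703 at df=27).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "fold_profile",
    "ctf_slope",
    "t_threshold",
    "ClusterResult",
    "cluster_permutation_test",
    "WindowComparison",
    "window_compare",
    "window_average",
]

# fold ordering: distances [180, 135, 90, 45, 0]
_FOLD_X = np.arange(1, 6, dtype=float)
_FOLD_XC = _FOLD_X - _FOLD_X.mean()
_FOLD_DEN = float((_FOLD_XC**2).sum())


def fold_profile(profile: np.ndarray) -> np.ndarray:
    """Collapse an aligned 8-point CTF over equidistant channels.

    ``profile[..., j]`` follows the offset grid [-135, -90, -45, 0, 45, 90,
    135, 180]; returns values at distances [180, 135, 90, 45, 0] (decreasing
    distance), with +-45/+-90/+-135 averaged and 0/180 passed through.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape[-1] != 8:
        raise ValueError("expected an 8-point aligned profile")
    d180 = p[..., 7]
    d135 = 0.5 * (p[..., 0] + p[..., 6])
    d90 = 0.5 * (p[..., 1] + p[..., 5])
    d45 = 0.5 * (p[..., 2] + p[..., 4])
    d0 = p[..., 3]
    return np.stack([d180, d135, d90, d45, d0], axis=-1)


def ctf_slope(profile: np.ndarray) -> np.ndarray:
    """CTF selectivity: OLS slope of the folded profile against ranks 1..5.

    Accepts any leading batch shape; the last axis must be the 8-point
    aligned profile.  Linear in the profile.
    """
    folded = fold_profile(profile)
    return folded @ _FOLD_XC / _FOLD_DEN


def t_threshold(n_subjects: int, alpha: float = 0.05) -> float:
    """One-sided critical t for a one-sample test with n_subjects - 1 df."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return float(sps.t.ppf(1.0 - alpha, n_subjects - 1))


@dataclasses.dataclass
class ClusterResult:
    clusters: list[np.ndarray]  # member indices per cluster (flat or 2-D)
    masses: np.ndarray
    null_max_mass: np.ndarray
    significant: np.ndarray
    threshold: float
    alpha: float
    t_obs: np.ndarray

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


def _one_sample_t(slopes: np.ndarray) -> np.ndarray:
    """t against 0 over axis 0; zero-variance points yield t=0 (sub-threshold)."""
    n = slopes.shape[0]
    mean = slopes.mean(axis=0)
    sd = slopes.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _clusters(t: np.ndarray, threshold: float) -> tuple[list[np.ndarray], np.ndarray]:
    above = t > threshold
    if t.ndim == 1:
        labels, n = ndimage.label(above)
    else:
        # 4-connectivity in time x frequency
        structure = ndimage.generate_binary_structure(t.ndim, 1)
        labels, n = ndimage.label(above, structure=structure)
    members, masses = [], []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        members.append(idx[:, 0] if t.ndim == 1 else idx)
        masses.append(t[labels == lab].sum())
    return members, np.asarray(masses, dtype=float)


def _max_mass_batch_1d(t_null: np.ndarray, threshold: float) -> np.ndarray:
    """Max cluster mass per row of a (n_perm, n_points) t array (vectorized)."""
    above = t_null > threshold
    starts = above & ~np.pad(above, ((0, 0), (1, 0)))[:, :-1]
    cluster_id = np.cumsum(starts, axis=1) * above  # 0 = background
    n_perm, _ = t_null.shape
    max_k = int(cluster_id.max()) if cluster_id.size else 0
    out = np.zeros(n_perm)
    if max_k == 0:
        return out
    flat = (np.arange(n_perm)[:, None] * (max_k + 1) + cluster_id).ravel()
    sums = np.bincount(flat, weights=(t_null * above).ravel(), minlength=n_perm * (max_k + 1))
    sums = sums.reshape(n_perm, max_k + 1)
    sums[:, 0] = 0.0
    return sums.max(axis=1)


def cluster_permutation_test(
    subject_slopes: np.ndarray,
    null_runner=None,
    null_slopes: np.ndarray | None = None,
    n_perm: int = 1000,
    t_thresh: float | None = None,
    alpha: float = 0.05,
    seed: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test of CTF selectivity against zero.

    ``subject_slopes`` is (n_subjects, n_points) or (n_subjects, n_freq,
    n_time).  The null is supplied either as ``null_slopes`` -- an array of
    shape (n_perm, n_subjects, ...) of slope series from label-randomized
    re-runs of the IEM -- or as ``null_runner(rng)``, a callable returning
    one such (n_subjects, ...) array per call.  Each permutation contributes
    the mass of its largest cluster; observed clusters are significant when
    their mass exceeds the 95th percentile (at ``alpha=0.05``) of that null.
    """
    slopes = np.asarray(subject_slopes, dtype=float)
    n_subjects = slopes.shape[0]
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if t_thresh is None:
        t_thresh = t_threshold(n_subjects, alpha)
    if null_slopes is not None:
        n_perm = np.asarray(null_slopes).shape[0]
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse null distribution")

    rng = np.random.default_rng(seed)
    t_obs = _one_sample_t(slopes)
    members, masses = _clusters(t_obs, t_thresh)

    if null_slopes is not None:
        null_slopes = np.asarray(null_slopes, dtype=float)
        n_perm = null_slopes.shape[0]
        # move subjects first so the t reduces over axis 0, leaving (n_perm, ...)
        t_null = _one_sample_t(np.moveaxis(null_slopes, 1, 0))
        if t_obs.ndim == 1:
            null_max = _max_mass_batch_1d(t_null.reshape(n_perm, -1), t_thresh)
        else:
            null_max = np.array([_clusters(t_null[i], t_thresh)[1].max(initial=0.0) for i in range(n_perm)])
    elif null_runner is not None:
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            t_i = _one_sample_t(np.asarray(null_runner(rng), dtype=float))
            _, m = _clusters(t_i, t_thresh)
            null_max[i] = m.max(initial=0.0)
    else:
        raise ValueError("provide either null_slopes or null_runner")

    crit = np.quantile(null_max, 1.0 - alpha)
    significant = masses > crit
    return ClusterResult(
        clusters=members,
        masses=masses,
        null_max_mass=null_max,
        significant=significant,
        threshold=float(t_thresh),
        alpha=alpha,
        t_obs=t_obs,
    )


@dataclasses.dataclass
class WindowComparison:
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float


def window_average(slopes: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Per-subject mean slope over time points inside ``window`` (inclusive)."""
    times = np.asarray(times, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"no time points inside window {window}")
    return np.asarray(slopes)[..., mask].mean(axis=-1)


def window_compare(
    slopes_a: np.ndarray,
    slopes_b: np.ndarray,
    times: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> WindowComparison:
    """Two-sided paired t test on (window-averaged) per-subject slopes."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison requires matching subject sets")
    if window is not None:
        if times is None:
            raise ValueError("window comparison needs the time axis")
        a = window_average(a, times, window)
        b = window_average(b, times, window)
    d = a - b
    n = d.shape[0]
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
        p = 1.0 if t == 0 else 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    return WindowComparison(t=t, df=n - 1, p=p, mean_a=float(a.mean()), mean_b=float(b.mean()))
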