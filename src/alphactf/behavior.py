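"""Continuous-report behavioral modeling.

Response errors on a 360-deg circle are decomposed with mixture models fit
by maximum likelihood:

* two components -- a von Mises centered on the target (precision expressed
  as circular SD in degrees; larger SD = lower precision) plus a uniform
  guessing component of height ``p_guess``;
* three components -- additionally a von Mises of the same concentration
  centered on the unprobed item's offset, with weight ``p_swap`` (swap
  errors).

Optimization is multi-start quasi-Newton over an unconstrained
parameterization (log concentration; mixture weights through a softmax), so
weight constraints (non-negative, summing to at most 1) hold by
construction.  The concentration is capped at the value corresponding to a
0.5-deg circular SD so the likelihood stays finite on degenerate
(all-identical) samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap_error",
    "response_error",
    "sd_from_kappa",
    "kappa_from_sd",
    "MixtureFit",
    "fit_mixture2",
    "fit_mixture3",
    "SameBinResult",
    "same_bin_analysis",
]

SD_FLOOR_DEG = 0.5
_LOGK_MAX = None  # computed lazily from SD_FLOOR_DEG
_LOGK_MIN = np.log(1e-3)


def wrap_error(err_deg: np.ndarray | float) -> np.ndarray | float:
    """Map angular differences to the signed interval (-180, 180]."""
    return -((180.0 - np.asarray(err_deg)) % 360.0 - 180.0)


def response_error(reported_angle: np.ndarray | float, true_angle: np.ndarray | float):
    """Signed response error in degrees: reported minus true, wrapped."""
    return wrap_error(np.asarray(reported_angle, dtype=float) - np.asarray(true_angle, dtype=float))


def sd_from_kappa(kappa: float) -> float:
    """Circular SD (degrees) of a von Mises with concentration ``kappa``."""
    r = special.i1e(kappa) / special.i0e(kappa)
    r = min(max(r, 1e-300), 1 - 1e-16)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


def kappa_from_sd(sd_deg: float) -> float:
    """Concentration of the von Mises with the given circular SD (degrees)."""
    if sd_deg <= 0:
        raise ValueError("sd must be positive")
    sd_deg = max(sd_deg, SD_FLOOR_DEG)
    target = float(np.exp(-0.5 * np.deg2rad(sd_deg) ** 2))

    def f(log_k):
        k = np.exp(log_k)
        return special.i1e(k) / special.i0e(k) - target

    return float(np.exp(optimize.brentq(f, -25.0, 25.0, xtol=1e-12)))


def _logk_max() -> float:
    global _LOGK_MAX
    if _LOGK_MAX is None:
        _LOGK_MAX = float(np.log(kappa_from_sd(SD_FLOOR_DEG)))
    return _LOGK_MAX


def _vm_logpdf_deg(err_deg: np.ndarray, kappa: float) -> np.ndarray:
    """log density (per degree) of a von Mises centered at 0."""
    x = np.deg2rad(err_deg)
    # log I0(k) = log i0e(k) + k  (scaled Bessel for numerical stability)
    return kappa * np.cos(x) - (np.log(special.i0e(kappa)) + kappa) - np.log(360.0 / (2 * np.pi) * 2 * np.pi)


@dataclasses.dataclass
class MixtureFit:
    sd: float
    p_guess: float
    p_swap: float
    log_likelihood: float
    converged: bool
    n: int

    def __post_init__(self) -> None:
        assert self.p_guess >= 0 and self.p_swap >= 0
        assert self.p_guess + self.p_swap <= 1 + 1e-9
        assert self.sd > 0


def _softmax3(q1: float, q2: float) -> tuple[float, float, float]:
    z = np.array([0.0, q1, q2])
    z = np.exp(z - z.max())
    z /= z.sum()
    return float(z[0]), float(z[1]), float(z[2])


_START_SDS = (3.0, 8.0, 15.0, 30.0, 60.0)
_START_WEIGHTS = (-3.0, -1.0, 0.5)


def _fit(nll, x0s) -> tuple[np.ndarray, float, bool]:
    best_x, best_f, ok = None, np.inf, False
    for x0 in x0s:
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f, ok = res.x, float(res.fun), bool(res.success)
    return best_x, best_f, ok


def fit_mixture2(errors_deg: np.ndarray) -> MixtureFit:
    """MLE of the two-component (target von Mises + uniform guess) mixture."""
    err = np.asarray(errors_deg, dtype=float)
    if err.size < 20:
        raise ValueError("need at least 20 observations to fit the mixture")
    lo, hi = _LOGK_MIN, _logk_max()

    def nll(x):
        logk = np.clip(x[0], lo, hi)
        pg = 1.0 / (1.0 + np.exp(-np.clip(x[1], -15, 15)))
        dens = (1 - pg) * np.exp(_vm_logpdf_deg(err, np.exp(logk))) + pg / 360.0
        return -np.log(np.maximum(dens, 1e-300)).sum()

    x0s = [
        np.array([np.log(kappa_from_sd(sd)), w])
        for sd in _START_SDS
        for w in _START_WEIGHTS
    ]
    x, f, ok = _fit(nll, x0s)
    logk = float(np.clip(x[0], lo, hi))
    pg = float(1.0 / (1.0 + np.exp(-np.clip(x[1], -15, 15))))
    return MixtureFit(
        sd=sd_from_kappa(np.exp(logk)),
        p_guess=pg,
        p_swap=0.0,
        log_likelihood=-f,
        converged=ok,
        n=err.size,
    )


def fit_mixture3(errors_deg: np.ndarray, nontarget_offsets_deg: np.ndarray) -> MixtureFit:
    """MLE of the three-component mixture (target, guess, swap).

    ``nontarget_offsets_deg`` gives, per trial, the unprobed item's angular
    offset from the probed item; the swap component is a von Mises (shared
    concentration with the target component) centered there.
    """
    err = np.asarray(errors_deg, dtype=float)
    off = np.asarray(nontarget_offsets_deg, dtype=float)
    if err.shape != off.shape:
        raise ValueError("need one non-target offset per trial")
    if err.size < 20:
        raise ValueError("need at least 20 observations to fit the mixture")
    lo, hi = _LOGK_MIN, _logk_max()
    err_sw = wrap_error(err - off)

    def nll(x):
        logk = np.clip(x[0], lo, hi)
        k = np.exp(logk)
        pt, pg, ps = _softmax3(np.clip(x[1], -15, 15), np.clip(x[2], -15, 15))
        dens = (
            pt * np.exp(_vm_logpdf_deg(err, k))
            + pg / 360.0
            + ps * np.exp(_vm_logpdf_deg(err_sw, k))
        )
        return -np.log(np.maximum(dens, 1e-300)).sum()

    x0s = [
        np.array([np.log(kappa_from_sd(sd)), wg, ws])
        for sd in _START_SDS
        for wg in _START_WEIGHTS
        for ws in (-3.0, -1.0)
    ]
    x, f, ok = _fit(nll, x0s)
    logk = float(np.clip(x[0], lo, hi))
    _, pg, ps = _softmax3(float(np.clip(x[1], -15, 15)), float(np.clip(x[2], -15, 15)))
    return MixtureFit(
        sd=sd_from_kappa(np.exp(logk)),
        p_guess=pg,
        p_swap=ps,
        log_likelihood=-f,
        converged=ok,
        n=err.size,
    )


# ---------------------------------------------------------------------------
# same-bin probed vs unprobed error analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SameBinResult:
    """Absolute response error relative to the probed vs the unprobed item."""

    mean_err_probed: float
    mean_err_unprobed: float
    t: float
    df: int
    p: float
    per_subject: "np.ndarray"  # (n_subjects, 2) [vs probed, vs unprobed]
    n_trials: int


def _paired_subject_t(per_subject: np.ndarray) -> tuple[float, int, float]:
    from .stats import window_compare

    cmp = window_compare(per_subject[:, 0], per_subject[:, 1])
    return cmp.t, cmp.df, cmp.p


def same_bin_analysis(
    trials: "pd.DataFrame",
    responses_deg: np.ndarray,
    max_separation: float | None = None,
) -> SameBinResult:
    """Compare |error| vs the probed and unprobed item on same-bin trials.

    Restricted to two-item trials in which both items occupy the same
    position bin; ``max_separation`` (degrees of angular position) further
    restricts to trials where the items are closer than that.  Errors are
    aggregated per subject and compared with a paired t test.
    """
    import pandas as pd  # local: keeps module import light

    responses = np.asarray(responses_deg, dtype=float)
    if len(responses) != len(trials):
        raise ValueError("one response per trial required")
    two = trials["condition"] == "two_item"
    same = two & (trials["bin_probed"] == trials["bin_unprobed"])
    if max_separation is not None:
        sep = np.abs(
            wrap_error(trials["angle_probed"].to_numpy() - trials["angle_unprobed"].to_numpy())
        )
        same = same & (sep < max_separation)
    sel = same.to_numpy()
    if not sel.any():
        raise ValueError("no qualifying same-bin trials")
    err_p = np.abs(response_error(responses[sel], trials.loc[sel, "angle_probed"].to_numpy()))
    err_u = np.abs(response_error(responses[sel], trials.loc[sel, "angle_unprobed"].to_numpy()))
    subj = trials.loc[sel, "subject_id"].to_numpy()
    frame = pd.DataFrame({"subject": subj, "err_p": err_p, "err_u": err_u})
    per = frame.groupby("subject")[["err_p", "err_u"]].mean().to_numpy()
    if per.shape[0] >= 2:
        t, df, p = _paired_subject_t(per)
    else:
        t, df, p = np.nan, 0, np.nan
    return SameBinResult(
        mean_err_probed=float(per[:, 0].mean()),
        mean_err_unprobed=float(per[:, 1].mean()),
        t=t,
        df=df,
        p=p,
        per_subject=per,
        n_trials=int(sel.sum()),
    )
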