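"""Config-driven orchestration of the analysis stages.

A run is described by a JSON config (schema below), executes spectral ->
encoding -> stats (-> switching, as configured) or a simulation study, and
writes all results plus a run log capturing the config echo and every seed.
Deterministic given the config: rerunning with the same config reproduces
the same outputs.

Config schema (version 1)::

    {
      "schema_version": 1,
      "mode": "study" | "iem",
      "seed": 1,
      "out": "results/run1",          # optional; CLI --out overrides

      # mode "study"
      "study": {"simulation": "simulation1", "n_samples": 1000,
                "method": "collapsed", "overrides": {...}},

      # mode "iem"
      "input": {"power_h5": "...", "trials_csv": "..."}   # real data, or
      "input": {"generator": {<SimulationConfig fields>},
                "tuning_window_ms": [250, 1250],
                "times_ms": [-500, 1500, 20]},            # synthetic
      "spectral": {"band": [8, 12], "downsample_ms": 20}, # only for raw input
      "encoding": {"regime": "condition_neutral", "n_iterations": 10},
      "stats": {"windows": [[250, 1250], [800, 1250]],
                "cluster": {"n_perm": 1000, "alpha": 0.05}},
      "switching": {"fraction": 0.5}                      # optional block
    }
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, simulation1, simulation2, simulation3
from .containers import EpochedPower, load_epoched_power, load_trials
from .encoding import make_basis, run_iem
from .stats import cluster_permutation_test, window_average
from .switching import compare_switching, run_switching_analysis
from .synth import generate_timecourse_dataset
from .study import run_simulation_study

__all__ = ["run_pipeline"]

_SIM_PRESETS = {
    "simulation1": simulation1,
    "simulation2": simulation2,
    "simulation3": simulation3,
}


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a dict or a path to a JSON file")
    if config.get("schema_version", 1) != 1:
        raise ValueError("unsupported config schema_version")
    if config.get("mode") not in ("study", "iem"):
        raise ValueError("config must set mode to 'study' or 'iem'")
    return config


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the configured run; returns the artifact directory.

    Missing input files fail before any computation; all written artifacts
    are listed in ``run_log.json`` along with the config echo and the seeds
    consumed by each stage.
    """
    cfg = _load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out", "alphactf_run"))
    seed = cfg.get("seed")
    log: dict = {"package_version": __version__, "config": cfg, "seed": seed, "artifacts": []}

    # fail-fast file checks
    inp = cfg.get("input", {})
    for key in ("power_h5", "trials_csv"):
        if key in inp and not Path(inp[key]).exists():
            raise FileNotFoundError(f"input file for '{key}' not found: {inp[key]}")

    out.mkdir(parents=True, exist_ok=True)
    if cfg["mode"] == "study":
        _run_study_mode(cfg, out, seed, log)
    else:
        _run_iem_mode(cfg, out, seed, log)

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


def _run_study_mode(cfg: dict, out: Path, seed, log: dict) -> None:
    block = cfg.get("study", {})
    preset = block.get("simulation", "simulation1")
    if preset not in _SIM_PRESETS:
        raise ValueError(f"unknown simulation preset {preset!r}")
    sim_cfg = _SIM_PRESETS[preset](**block.get("overrides", {}))
    res = run_simulation_study(
        sim_cfg,
        n_samples=int(block.get("n_samples", 1000)),
        seed=seed,
        method=block.get("method", "collapsed"),
        n_iterations=int(block.get("n_iterations", 1)),
    )
    payload = res.summary()
    payload["config"] = sim_cfg.to_dict()
    (out / "study.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        {
            "t": res.t,
            "p": res.p,
            "mean_slope_one": res.mean_slope_one,
            "mean_slope_two": res.mean_slope_two,
        }
    ).to_csv(out / "study_samples.csv", index=False)
    log["artifacts"] += ["study.json", "study_samples.csv"]


def _synthetic_cohort(inp: dict, seed) -> list[tuple[EpochedPower, pd.DataFrame]]:
    gen = SimulationConfig(**inp.get("generator", {}))
    lo, hi = inp.get("tuning_window_ms", [250, 1250])
    t0, t1, dt = inp.get("times_ms", [-500, 1500, 20])
    conditions = tuple(inp.get("conditions", ["one_item"]))
    times = np.arange(float(t0), float(t1), float(dt))
    ss = np.random.SeedSequence(seed)
    cohort = []
    for s, child in enumerate(ss.spawn(gen.n_subjects)):
        rng = np.random.default_rng(child)
        ep, trials = generate_timecourse_dataset(
            gen, lo, hi, rng, times=times, conditions=conditions, subject_id=s
        )
        cohort.append((ep, trials))
    return cohort


def _run_iem_mode(cfg: dict, out: Path, seed, log: dict) -> None:
    inp = cfg.get("input", {})
    enc = cfg.get("encoding", {})
    st = cfg.get("stats", {})
    regime = enc.get("regime", "condition_neutral")
    n_iter = int(enc.get("n_iterations", 10))

    if "generator" in inp:
        cohort = _synthetic_cohort(inp, seed)
    else:
        ep = load_epoched_power(inp["power_h5"])
        trials = load_trials(inp["trials_csv"])
        if "spectral" in cfg:
            from .containers import EpochedTimeseries
            from .spectral import band_power, downsample_power

            sp = cfg["spectral"]
            ts = EpochedTimeseries(data=ep.power, sfreq=ep.sfreq, times=ep.times)
            band = sp.get("band", [8, 12])
            ep = band_power(ts, float(band[0]), float(band[1]))
            if "downsample_ms" in sp:
                ep = downsample_power(ep, float(sp["downsample_ms"]))
        cohort = [
            (
                EpochedPower(
                    power=ep.power[(trials["subject_id"] == s).to_numpy()],
                    times=ep.times,
                    band=ep.band,
                    sfreq=ep.sfreq,
                    n_edge=ep.n_edge,
                ),
                trials[trials["subject_id"] == s].reset_index(drop=True),
            )
            for s in pd.unique(trials["subject_id"])
        ]

    basis = make_basis()
    ss = np.random.SeedSequence(0 if seed is None else seed)
    subj_seeds = ss.spawn(len(cohort))
    results = []
    for (ep, trials), child in zip(cohort, subj_seeds):
        rng = np.random.default_rng(child)
        res = run_iem(ep.power, trials, regime=regime, n_iterations=n_iter, seed=rng,
                      basis=basis, times=ep.times)
        results.append(res)
    times = results[0].times
    conditions = results[0].conditions
    slopes = np.stack([r.slopes for r in results])  # (subjects, cond, time)

    rows = []
    for si, r in enumerate(results):
        for ci, c in enumerate(conditions):
            for ti, t in enumerate(np.atleast_1d(times)):
                rows.append({"subject": si, "condition": c, "time_ms": t, "slope": slopes[si, ci, ti]})
    pd.DataFrame(rows).to_csv(out / "slopes.csv", index=False)
    log["artifacts"].append("slopes.csv")

    import h5py

    with h5py.File(out / "ctf.h5", "w") as f:
        f.create_dataset("ctf", data=np.stack([r.ctf for r in results]))
        f.create_dataset("offsets_deg", data=results[0].offsets)
        f.create_dataset("times_ms", data=np.atleast_1d(times).astype(float))
        f.attrs["conditions"] = json.dumps(conditions)
        f.attrs["regime"] = regime
        f.attrs["n_iterations"] = n_iter
    log["artifacts"].append("ctf.h5")

    # cluster-based permutation inference per condition, null from
    # label-randomized re-runs of the IEM
    cl = st.get("cluster", {})
    n_perm = int(cl.get("n_perm", 1000))
    alpha = float(cl.get("alpha", 0.05))
    cluster_out = {}
    perm_ss = ss.spawn(1)[0]
    for ci, c in enumerate(conditions):
        def null_runner(rng, _ci=ci):
            perm = []
            for ep_t, trials_t in cohort:
                r = run_iem(ep_t.power, trials_t, regime=regime, n_iterations=1,
                            seed=rng, basis=basis, times=ep_t.times, permute_labels=True)
                perm.append(r.slopes[min(_ci, len(r.conditions) - 1)])
            return np.stack(perm)

        res = cluster_permutation_test(
            slopes[:, ci], null_runner=null_runner, n_perm=n_perm, alpha=alpha,
            seed=np.random.default_rng(perm_ss),
        )
        cluster_out[c] = {
            "threshold_t": res.threshold,
            "masses": res.masses.tolist(),
            "significant": res.significant.tolist(),
            "null_95th": float(np.quantile(res.null_max_mass, 1 - alpha)) if len(res.null_max_mass) else None,
            "clusters_time_idx": [m.tolist() for m in res.clusters],
        }
    (out / "cluster_test.json").write_text(json.dumps(cluster_out, indent=2))
    log["artifacts"].append("cluster_test.json")

    # window averages
    windows = [tuple(w) for w in st.get("windows", [[250, 1250], [800, 1250]])]
    win_out = {}
    if times is not None and np.ndim(times) > 0:
        for w in windows:
            try:
                win_out[str(list(w))] = {
                    c: window_average(slopes[:, ci], np.asarray(times), w).tolist()
                    for ci, c in enumerate(conditions)
                }
            except ValueError:
                win_out[str(list(w))] = None  # window outside the epoch
    (out / "window_slopes.json").write_text(json.dumps(win_out, indent=2))
    log["artifacts"].append("window_slopes.json")

    # optional switching comparison (joint shared-model analysis)
    if "switching" in cfg and "two_item" in conditions and "one_item" in conditions:
        frac = float(cfg["switching"].get("fraction", 0.5))
        sw_ss = ss.spawn(1)[0]
        sw_rng = np.random.default_rng(sw_ss)
        two_sl, sw_sl = [], []
        for ep_t, trials_t in cohort:
            r = run_switching_analysis(ep_t.power, trials_t, fraction=frac,
                                       n_iterations=n_iter, seed=sw_rng, basis=basis,
                                       times=ep_t.times)
            two_sl.append(r.slopes[r.condition("two_item")])
            sw_sl.append(r.slopes[r.condition("switching")])
        two_sl = np.stack(two_sl)
        sw_sl = np.stack(sw_sl)
        cmps = compare_switching(two_sl, sw_sl, times=np.asarray(times), windows=tuple(windows))
        (out / "switching.json").write_text(
            json.dumps(
                {str(list(w)): dataclasses.asdict(c) for w, c in cmps.items()}, indent=2
            )
        )
        log["artifacts"].append("switching.json")
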