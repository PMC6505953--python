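# alphactf

Inverted encoding models (IEMs) for spatial working memory, reconstructing
**channel-tuning functions (CTFs)** from the scalp topography of
band-limited EEG power — plus everything needed to interpret them:
CTF-slope selectivity statistics, cluster-based permutation inference, a
simulated "switching-account" null, von Mises mixture models of
continuous-report behavior, and synthetic-cohort simulation studies that
characterize the estimator's behavior under added representations, extra
noise, and reduced amplitude.

It is written for cognitive/computational neuroscientists who track
remembered spatial positions through oscillatory (e.g. alpha-band,
8–12 Hz) power and need the full analysis path — spectral extraction,
encoding-model cross-validation, inference — as tested, scriptable
library code.

## The model

Power at each of *m* electrodes is a weighted sum of *k* = 8 spatial
channels tuned to the 8 position bins (45° wedges centered at 0°, 45°, …,
315°). A channel's response at angular distance *d* from its preferred
position is a half sinusoid raised to the 25th power, `r(d) = cos(d/2)^25`.
With training power `B1` (m × n), predicted channel responses `C1` (k × n),
and weights `W` (m × k):

    B1 = W C1                      (forward model)
    Ŵ  = B1 C1ᵀ (C1 C1ᵀ)⁻¹         (least-squares training)
    Ĉ2 = (Ŵᵀ Ŵ)⁻¹ Ŵᵀ B2            (inversion on held-out data)

Measurements are bin averages over a three-way trial partition with equal
per-bin counts (leave-one-set-out cross-validation); estimated channel
responses are circularly aligned to the probed position and averaged into
a CTF. Selectivity is the **CTF slope**: fold the 8-point CTF over
equidistant channels and regress the 5 folded values (distance 180 → 0)
on ranks 1…5. A perfect noiseless CTF has slope ≈ 0.2138; real delay-period
alpha-band data live around 0.06–0.09. See `docs/methods.md` for the
complete account.

## Worked example

Reconstruct one synthetic subject's CTFs under both memory loads, then run
a 1,000-sample cohort study of the load comparison:

```python
import numpy as np
from alphactf import (SimulationConfig, generate_subject, run_iem,
                      run_simulation_study, simulation1)

subj = generate_subject(SimulationConfig(n_subjects=1), 0)
res = run_iem(subj.electrode_data, subj.trials, n_iterations=10, seed=0)
print(res.conditions)                  # ['one_item', 'two_item']
print(np.round(res.ctf[0, 0], 3))      # one-item CTF over offsets -135..180
print(np.round(res.slopes[:, 0], 3))   # CTF slope per condition

study = run_simulation_study(simulation1(), 1000, seed=7)
print(round(study.prop_significant, 3),
      round(study.prop_one_gt_two, 3), round(study.prop_two_gt_one, 3))
```

Output:

```
['one_item', 'two_item']
[-0.031 -0.037  0.12   0.773  0.136  0.004 -0.052 -0.061]
[0.184 0.181]
0.048 0.027 0.021
```

The one-item CTF peaks at channel offset 0° (the channel tuned to the
remembered position) and falls off steeply — the graded profile the slope
summarizes. Both conditions show near-identical selectivity here because
this generator adds the same noise and amplitude to both loads; the study
confirms that under that matched configuration the paired t test on slope
is correctly calibrated: 4.8% of 1,000 cohorts significant at α = .05,
split almost evenly between directions. Swapping in `simulation2()`
(extra two-item noise) keeps the rate at ~5% while widening the two-item
sampling distribution; `simulation3()` (two-item amplitude × 0.9) is
detected in every cohort.

A command-line layer wraps the same functions:

```bash
alphactf study --simulation simulation3 --n-samples 1000 --seed 1 --out results/sim3
alphactf simulate --seed 2 --out data/synth           # HDF5 power + CSV trials
alphactf behavior --errors-csv errors.csv --out fit.json
```

Real epoched EEG enters through the same containers: an HDF5 file with
`power` (trials × electrodes × time) and `times` datasets plus a CSV trial
table (`subject_id, condition, bin_probed, angle_probed, bin_unprobed,
angle_unprobed`), driven by a JSON config through `alphactf iem --config …`
(see `alphactf.pipeline` for the schema).

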