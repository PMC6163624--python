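# riskpipe

One-class personal-risk detection from wearable sensor streams.

A wrist band records a person's ordinary life — accelerometer and gyroscope
at 8 Hz, heart rate, pedometer, distance and calories at 1 Hz, skin
temperature every 30 s, ultraviolet exposure every minute.  People express
regular physical and behavioural patterns, so a model trained *only* on a
user's normal week can flag windows that deviate from it: a sprint, a fall, a
breathing crisis.  `riskpipe` implements this pipeline end to end for
researchers who want to study the approach without access to the original
recordings:

* **synthetic cohorts** (`riskpipe.synth`) — per-user normal-conditions
  streams (a diurnal rest/walk mixture with a personal gait signature and
  mean-reverting vitals) plus five staged anomaly scenarios: sprinting,
  stair climbing, boxing, falls and breath holding, each with tunable
  intensity that collapses to ordinary behaviour at zero effect;
* **window features** (`riskpipe.features`) — non-overlapping 1 s windows;
  the 26-dimensional time-domain vector (mean x̄ and sample standard
  deviation s of the nine motion axes, plus vitals and counter increments
  Δsteps/Δdistance/Δcalories) and the 98-dimensional extension with ten
  frequency-domain descriptors per motion axis (FFT energy, spectral
  entropy, peak frequency, ... from the one-sided 8-point DFT);
* **two-phase feature selection** (`riskpipe.select`,
  `TwoPhaseFeatureSelector`) — per-user greedy correlation filtering at
  |r| ≥ 0.75 with a cross-user vote (remove when ≥ *U*−1 of *U* users
  agree), then correlation-matrix PCA keeping the dimensions that explain
  ≥ 60 % of variance and removing features whose contribution never exceeds
  the uniform benchmark 100/p %;
* **one-class scorers** (`riskpipe.models`) — `OckraDetector`, a
  random-subspace k-means ensemble scoring
  1 − mean_m exp(−½ (d_m/δ_m)²) ∈ [0, 1], and `OneClassSVMDetector`, an RBF
  one-class SVM with γ = 0.038, ν = 0.5.  Both follow the scikit-learn
  estimator API (`fit` / `anomaly_score` / `get_params`);
* **evaluation** (`riskpipe.eval`) — per-user five-fold chronological
  cross-validation with anomaly-augmented test folds, ROC-AUC (anomaly as
  positive class), AUC-table arithmetic, an exact Wilcoxon signed-rank test
  and Kruskal–Wallis.

## Worked example

```python
from riskpipe.pipeline import RunConfig, run_study

cfg = RunConfig(seed=7, n_users=3, ncds_seconds=3600,
                datasets=("DS-1", "DS-2"), n_rotations=2)
report = run_study(cfg)
print(report.table)
sel = report.selection["DS-2"]
print("removed:", len(sel.removed), "retained:", len(sel.retained))
```

prints

```
classifier OCKRA        ocSVM       
dataset     DS-1  DS-2   DS-1   DS-2
user_id                             
user01      90.7  89.5  93.40  95.00
user02      91.2  89.4  93.50  93.70
user03      85.4  81.5  85.40  89.60
Average     89.1  86.8  90.77  92.77
removed: 13 retained: 13
```

Three simulated users, one hour of normal data each: cells are per-user
AUC × 100 averaged over two chronological cross-validation rotations — the
model trains on four-fifths of a user's normal windows and must rank the
held-out normal fifth below the five staged scenarios.  DS-1 is the full
26-feature time-domain dataset; DS-2 is the same data after the two-phase
selection, which here drops 13 redundant columns (highly inter-correlated
motion deviations and the step/distance/calorie increments that duplicate
one another) at a cost of a few AUC points.

The same pipeline is scriptable from the shell:

```sh
riskpipe synth --users 4 --hours 6 --seed 1 --out raw/
riskpipe extract --raw raw/ --mode time --out feats/
riskpipe select --features feats/ --out selection.yml
riskpipe train --features feats/ --user user01 --model ockra --out model.pkl
riskpipe run --users 4 --hours 6 --seed 1 --out study/
riskpipe verify-tables
```

`verify-tables` recomputes, from the bundled per-user benchmark table, the
printed column averages (e.g. ocSVM DS-1 = 86.44, OCKRA DS-1 = 89.1) and the
signed-rank statistics comparing the two classifiers (R⁺ = 221, R⁻ = 55 on
DS-1).

## Scope

The original per-user recordings are not redistributed and their per-user
AUC values are not reproduction targets; they enter only as printed inputs
to the verification arithmetic.  Training-time benchmarking is out of scope.
See `docs/methods.md` for the generative model, parameter choices and known
limitations.
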