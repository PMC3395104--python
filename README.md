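# somkit

Self-organising maps (SOMs) for chemometrics: spectroscopy, metabolomics
and process data.  `somkit` is for analysts who want the full SOM
workflow — not just the trained map but the displays and decisions built
on it: BMU and hit-histogram views, class maps, U-matrices, component
planes, supervised classification with an adjustable class weight,
SOMDI marker ranking with reform-based significance, and one-class
monitoring of process data against a Normal Operating Conditions (NOC)
model.

## The model

A map is a rectangle of hexagonal cells; behind each cell sits a weight
vector `W_c` over the measured variables (a "spectrum" per cell).
Training is the classical online algorithm: at iteration `t` a sample
`x` is drawn uniformly with replacement, its best matching unit (BMU)
`b = argmin_c ||x − W_c||` is found, and every cell is pulled toward it,

    W_c ← W_c + α(t) · exp(−d(c,b)² / 2σ(t)²) · (x − W_c),

with the learning rate `α` and neighbourhood width `σ` decaying over the
run.  The chance a sample is never drawn is `((N−1)/N)^T`, which fixes
how many iterations a dataset of `N` samples needs.

Supervised maps append one class-membership plane per class and train on
the joint vector with BMU distance
`(1−w)·d²_X/ν_X + w·d²_C/ν_C`; `w = 0` reproduces the unsupervised map
bitwise, `w → 1` forces class structure (and overfits — check held-out
%CC, which apportions boundary samples fractionally).  The SOMDI index
of a variable for a class is `Σ_c p_c q_c` (scaled component plane times
class component plane); the sign of the difference against the merged
complement classes marks positive/negative markers, and reforming the
map `R` times from fresh random starts gives a `1 − 1/R` confidence
criterion for markers positive in every reform.  For process data, a
map trained on the NOC window plus a minimum-distance fit statistic and
a leave-one-out-calibrated control limit gives an in/out-of-control
decision for every new sample.

See `docs/methods.md` for the full account of the conventions and
defaults.

## Worked example

Synthetic 96-sample metabolomics study (2 treatments × 16 donors × 3
sampling days, 100 spectral buckets, 5 planted treatment markers):

```python
import somkit as sk

sim = sk.gen_saliva_like(seed=1)

grid = sk.GridSpec(18, 16)
schedule = sk.TrainingSchedule(T=10_000, sigma0=4.5, seed=1)
som = sk.train_supervised(
    sim.data, sim.factors["treatment"], grid=grid,
    schedule=schedule, class_weight=0.5,
)
cc = sk.percent_cc(som.predict(sim.data.X), sim.factors["treatment"])
print(f"training %CC (treatment): {cc:.2f}")

table = sk.somdi_table(som.codebook, som.training_bmus, som.training_labels)
top = table.sort_values("score_mouthwash", ascending=False).head(5)
print("top treatment markers:", ", ".join(top.index))
print("planted markers:      ", ", ".join(f"v{j}" for j in sim.truth["treatment_markers"]))
```

prints

```
training %CC (treatment): 100.00
top treatment markers: v8, v81, v48, v16, v6
planted markers:       v6, v8, v16, v48, v81
```

The supervised map separates the treatment groups on the training set
(100 %CC here is a *training* figure — always confirm on a held-out
set), and the five top-ranked SOMDI marker variables are exactly the
five planted ones.  `sk.marker_stability(...)` repeats the whole fit
from fresh random starts to attach a confidence level to that ranking,
and `sk.plot_map(...)` renders any per-cell view (U-matrix, hit
histogram, component plane) as a hexagonal heat map.

The same workflow is available from the shell:

```
somkit simulate --design saliva --seed 1 --out run/
somkit supervised run/data.csv --factor treatment --meta donor --meta day \
       --class-weight 0.5 --out run/som/
somkit somdi --model run/som/model.json --out run/somdi/
somkit significance run/data.csv --factor treatment --meta donor --meta day \
       --class-id mouthwash -R 100 --out run/sig/
```

plus `train`, `views`, `predict`, and `qc fit` / `qc monitor` for
one-class process monitoring.  Every subcommand writes a
`run_log.json` (config, seed, versions) so a run is reproducible from
its inputs and log alone.

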