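# scanpathml

Spatiotemporal encoding of eye-fixation scanpaths, and a benchmarking
harness for classifying reader expertise from gaze behaviour.

## The problem

When a radiologist reads a chest x-ray, their gaze traces a *scanpath*: an
ordered sequence of fixations over the image. Experienced readers tend to
search broadly and systematically; trainees tend to dwell on a few
suspected regions and revisit them. Classical summaries of this behaviour
(total scan time, fixation count, saccade path length, regressions,
coverage) compress the whole trial into five numbers and discard where and
when the gaze actually went.

`scanpathml` implements a discretized **spatiotemporal vector encoding**
that keeps that structure. A trial's fixations are split into `t` ordered
temporal groups; within each group, fixations are counted over an
`x × y` grid tiling the display; the `t` count grids are flattened into a
single vector

```
V ∈ N^(x·y·t),   V[b·xy + i·x + j] = #{fixations in temporal group b
                                       nearest to grid cell (i, j)}
```

Each fixation is assigned to the grid cell with the nearest centroid
(Euclidean `argmin`, ties to the lowest row-major index, off-display
points clamped to the nearest edge cell). The vector length is fixed by
the configuration — `x = y = 15`, `t = 20` gives 4500 features — so trials
of any duration map into one feature space: long trials give large counts,
short trials sparse vectors.

The package contains:

- `gaze_model` — fixation/trial/dataset types, CSV readers/writers with
  column dialects, validation, artifact filtering;
- `encoder` — the encoding above, with time-based (default) or
  count-based temporal splitting;
- `traditional_features` — the five-attribute classical baseline
  (total scan time, fixation count, regressive fixation count, total
  saccade length, coverage of the salient image area);
- `synthetic` — a two-archetype scanpath simulator (broad systematic
  "faculty" search vs focal revisiting "trainee" search) with a
  continuous class-separation dial and device-like presets;
- `benchmark` — stratified cross-validation with per-class hold-outs,
  PCA/kernel-PCA feature extraction fitted per training fold, classifiers
  (Gaussian process, logistic regression, k-NN, XGBoost) tuned by inner
  grid search on balanced accuracy, and hierarchical aggregation of AUC,
  F1, accuracy, sensitivity and specificity;
- a `scanpathml` command-line interface tying these into a workflow.

## Worked example

```python
import scanpathml as s
from scanpathml import benchmark as b

ds = s.simulate_dataset(s.preset_config("eyelink_like", seed=1, separation=0.8))
print("trials:", len(ds.trials))

trial = ds.trials[0]
v = s.encode_trial(trial, s.EncodingConfig(grid_x=3, t=3))
print("first trial:", len(trial), "fixations ->", v.counts.tolist())

sweep = b.SweepConfig(grid_sizes=(5, 10), temporal_groups=(3, 10),
                      classifiers=(b.ClassifierSpec("gp"), b.ClassifierSpec("lr")),
                      seeds=(0,))
records = b.run_sweep(ds, sweep)
print(b.aggregate(records, ["classifier", "data_type"])[
    ["classifier", "data_type", "auc_mean", "auc_var"]].to_string(index=False))
```

prints

```
trials: 110
first trial: 37 fixations -> [3, 2, 2, 1, 0, 1, 1, 1, 1, 3, 0, 1, 5, 1, 1, 2, 0, 0, 1, 0, 1, 0, 0, 0, 3, 3, 4]
classifier   data_type  auc_mean  auc_var
        gp     encoded       1.0      0.0
        gp traditional       1.0      0.0
        lr     encoded       1.0      0.0
        lr traditional       1.0      0.0
```

The simulated acquisition has 110 trials (1 faculty + 1 trainee reader,
55 trials each). The 27-entry vector is the first trial's 37 fixations
counted over a 3×3 grid in each of 3 temporal thirds — its first nine
entries are the early-scan spatial histogram, the last nine the late-scan
one. The aggregation table reports fold-averaged AUC per classifier and
feature type: at this class separation both the encoded vectors and the
five classical attributes separate the two readers essentially perfectly
(AUC 1.0); the encoded features retain that performance while also
exposing *where and when* the two readers differ.

The same flow from a shell:

```
scanpathml simulate --preset eyelink_like --seed 1 --out sim
scanpathml encode   --data sim/fixations.csv --grid 5 --t 3 --out encoded.csv
scanpathml features --data sim/fixations.csv --out traditional.csv
scanpathml benchmark --data sim/fixations.csv --config run.yaml --out bench
scanpathml render   --data sim/fixations.csv --grid 3 --out scanpath.png
```

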