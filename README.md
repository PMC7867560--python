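# calcnet

Stone or phlebolith?  On non-contrast CT (NECT) of patients with renal
colic, a calcification in the lower pelvis can be a distal ureteral stone
(needs treatment) or a harmless phlebolith — a calcified vein wall that
sits millimetres from the ureter and looks almost identical.  `calcnet`
implements a complete, reproducible pipeline for studying how well this
distinction can be made from *local* image features alone:

* a **2.5D convolutional classifier**: the calcification is segmented at
  250 HU (with morphological hole filling); every voxel of the mask
  becomes a training/inference example made of the three orthogonal
  (axial, coronal, sagittal) patches through it; the per-voxel softmax
  stone probabilities are averaged into one score per calcification and
  thresholded at 0.5;
* a **semi-quantitative comparator**: 5-mm multiplanar reformats, caliper
  lengths of the three principal axes, ellipsoid volume W·L·H·π/6, mean
  attenuation in a central circular ROI, and the published cutoff rule
  (phlebolith iff HU ≤ 643 and volume ≤ 171 mm³);
* **reader-study statistics**: sensitivity/specificity/accuracy with exact
  binomial CIs, ROC/AUC (trapezoidal = Mann–Whitney concordance), majority
  vote of an odd reader panel (≥ 4 of 7), median reader, one-sample
  t-test, Mann–Whitney U;
* a **synthetic phantom generator** producing labelled 5×5×5 cm NECT
  cubes with the canonical signs (soft-tissue rim for stones; central
  lucency and comet tail for phleboliths), so everything above runs and is
  benchmarked without any patient data.

See `docs/methods.md` for the underlying model, all defaults and the known
limitations, and `examples/` for one short script per capability.

## Worked example

```python
from calcnet import RunConfig, run_experiment

report = run_experiment(RunConfig(n_train_stones=30, n_train_phleboliths=30,
                                  n_test_stones=20, n_test_phleboliths=20,
                                  epochs=6, seed=42))
print("CNN accuracy:", report.cnn_metrics["accuracy"])
print("CNN AUC:     ", report.cnn_metrics["auc"])
print("cutoff-rule accuracy:", report.semiquant_metrics["accuracy"])
```

prints (exactly, given the seed):

```
CNN accuracy: 0.8
CNN AUC:      0.8025
cutoff-rule accuracy: 0.525
```

Even at this miniature scale the voxel-averaged network separates the two
kinds of calcification reasonably well (32 of 40 test cases correct),
while the attenuation/volume cutoff rule stays near chance — by design the
phantom classes share their size and attenuation distributions, so all
class signal is morphological.  At the package's default scale
(150 training calcifications per class, 50+50 test, 30 epochs) the same
experiment reaches accuracy 0.94 and AUC 0.95 at the packaged seed 42
(other master seeds give accuracy ~0.81-0.82 and AUC ~0.88-0.91 — a
100-case synthetic cohort is small, see `docs/methods.md`); run
`python examples/05_full_experiment.py` to reproduce it (several minutes
on one CPU).

The same pipeline is available as a thin CLI:

```bash
calcnet simulate --n-stones 50 --n-phleboliths 50 --out cohort/ --seed 7
calcnet segment  --in cohort/ --out masks/
calcnet train    --candidate C --train cohort/ --out model/ --seed 7
calcnet predict  --model model/ --in cohort/ --out scores.csv
calcnet semiquant --in cohort/ --out semiquant.csv
calcnet evaluate --scores scores.csv --truth cohort/manifest.csv --out metrics.json
calcnet run      --out results/ --seed 42     # the whole experiment
```

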