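# hsicalib

Chemometric calibration of hyperspectral plate images for the simultaneous,
non-destructive quantitation of several quality attributes of bulk plant
material — the motivating case is *Salvia miltiorrhiza* (danshen), where the
attributes are four marker metabolites (salvianolic acid B, dihydrotanshinone
I, cryptotanshinone, tanshinone IIA) and moisture content, all as mass
fractions.

The package is aimed at process-analytical and chemometrics practitioners who
want a tested, pure-Python reference implementation of the full workflow:

* **Radiometric calibration** — raw detector counts to relative reflectance
  via white/dark reference frames, `R = (I − D)/(W − D)`, and the
  Beer–Lambert linearizing transform `A = log10(1/R)`.
* **Plate segmentation** — Otsu thresholding of a NIR band, morphological
  cleanup, connected-component labeling of the sample segments, and
  per-sample mean spectra.
* **Sample-set partitioning** — the Kennard–Stone max–min algorithm at the
  conventional 4:1 calibration:test ratio.
* **Wavelength selection** — CARS (competitive adaptive reweighted sampling),
  SPA (successive projections) and UVE (uninformative variable elimination).
* **Calibration models** — PLSR, ε-SVR and an RBF network as classical
  baselines, and the package's centerpiece: a **squeeze-and-excitation
  residual network** (SE-ResNet) regressor that maps a hyperspectral image
  patch (spectral bands as channels) to the five concentrations.
* **Evaluation** — RMSEC/RMSECV/RMSEP, Rc²/Rcv²/Rp², residual prediction
  deviation `RPD = SD_cal / RMSEP` with its qualitative interpretation
  bands, and relative error range `RER = (Y_max − Y_min)/RMSEP`.

The deep model follows the bottleneck residual family: a 7×7/stride-2 stem
convolution, batch normalization, a 3×3/stride-2 max pool, four stages of
SE-augmented bottleneck blocks with counts (3, 4, 23, 3), global average
pooling, and a 2048 → 256 → 5 fully connected head. Each block ends in a
squeeze-and-excitation unit: per-channel global averaging feeding a two-layer
sigmoid bottleneck whose output rescales the channels. The network, its
backward passes and the Adam optimizer are implemented in numpy and run on
one CPU; a reduced profile (`ArchitectureSpec.reduced()`) trains in minutes.

Because no public image set accompanies this problem, the package ships a
seeded synthetic generator (`hsicalib.synthetic`) producing raw-count cubes
(128 bands, 380–1064 nm at 5.38 nm sampling), white/dark frames, 6×5 segment
grids on a bright plate, and concentration tables with the published content
ranges and the 0.64 cryptotanshinone–tanshinone IIA correlation embedded.

## Worked example

```python
import numpy as np
from hsicalib import CalibrationModel, SyntheticConfig, generate_dataset

records, truth = generate_dataset(SyntheticConfig(n_samples=60, seed=5))
model = CalibrationModel(records=records, estimator="plsr",
                         estimator_kwargs={"n_components": 8}, cv_folds=5)
results = model.fit()
print(results.summary())
```

prints (abridged to the first columns):

```
Calibration results (plsr, 48 calibration / 12 test samples)
==============================================================================
                       Rc2  RMSEC    Rp2  RMSEP      RER     RPD    RPD_category
salvianolic_acid_B  0.9897 0.0347 0.9876 0.0193  77.4946 17.8862  excellent (>3)
dihydrotanshinone_I 0.9976 0.0001 0.9978 0.0001 145.6757 37.8663  excellent (>3)
cryptotanshinone    0.9944 0.0006 0.9954 0.0003 121.4465 26.0168  excellent (>3)
tanshinone_IIA      0.9903 0.0013 0.9973 0.0006 103.9531 22.7842  excellent (>3)
moisture            0.9982 0.0002 0.9966 0.0002 133.0196 31.9373  excellent (>3)
```

Per analyte: `Rc2`/`RMSEC` describe calibration-set fit, `Rp2`/`RMSEP` the
independent Kennard–Stone test set, `RER` the calibration range in RMSEP
units, and `RPD` the ratio of the calibration reference spread to RMSEP —
values above 3 indicate excellent predictive ability, below 1.5 limited
utility. The deep model runs the same way with `estimator="se_resnet"` and
`estimator_kwargs={"n_members": 4}` (a small seed/mixup ensemble).

A CLI mirrors the workflow for shell use:

```bash
hsicalib simulate --n-samples 60 --seed 5 --out data/
hsicalib fit data/ --model plsr --band-method cars --out run/
hsicalib run-all --seed 5 --out run_all/
```

## Layout

```
src/hsicalib/
  hsi_core.py          cube container, ENVI/HDF5 I/O, calibration
  segmentation.py      plate masking, mean spectra
  preprocessing.py     Savitzky–Golay, standardization
  band_selection.py    CARS / SPA / UVE
  baseline_models.py   PLSR / SVMR / RBFNN
  nn.py                numpy layer framework (conv, BN, SE, Adam)
  se_resnet.py         the SE-ResNet regressor
  evaluation.py        Kennard–Stone, metric suite
  synthetic.py         seeded data generator
  calibration.py       CalibrationModel / CalibrationResults
  pipeline.py, cli.py  orchestration and command line
docs/methods.md        model, assumptions, parameter choices, limitations
```
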