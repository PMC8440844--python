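# voxphys

Simulation-trained estimation of **subglottal pressure (Ps)**, **vocal fold
collision pressure (Pc)** and **cricothyroid / thyroarytenoid activation
(a_CT, a_TA)** from aerodynamic and acoustic voice features — together with
the muscle-controlled voice synthesizer that generates the training data and
the subglottal impedance-based inverse filter (IBIF) that recovers glottal
airflow from a neck-surface accelerometer.

These four measures characterize the effort and tissue stress of phonation
and are central to studying vocal hyperfunction, but none of them can be
measured directly outside invasive laboratory setups.  The package is aimed
at voice scientists and biomedical-signal researchers who want a fully
synthetic, reproducible pipeline from physiological controls to estimated
vocal function.

## What is inside

- **Voice production model** — a symmetric *triangular body-cover model* of
  the vocal folds (three masses per side, zipper-like gradual collision)
  whose geometry and stiffness are set by the activation `a ∈ [0,1]` of the
  five intrinsic laryngeal muscles (LCA, IA, PCA, CT, TA) through Kelvin-type
  muscle models and empirical body-cover rules; glottal flow solved with
  full flow–sound–tissue interaction; subglottal and supraglottal tracts as
  wave-reflection (Kelly–Lochbaum) lines with lip radiation.
  (`posture`, `tbcm`, `flow`, `tract`, `synth`)
- **Feature chain** — laboratory-grade conditioning (Chebyshev-II 1,100 Hz
  low-pass, decimation to 8,192 Hz, Butterworth 60 Hz high-pass, zero-phase)
  and the seven features ACFL, MFDR, OQ, SQ, H1−H2, fo, SPL, plus the
  intraoral-pressure plateau method for reference Ps. (`features`)
- **Dataset assembly** — Monte Carlo sampling of the control lattice
  (a_CT, a_TA ∈ [0,1]; a_LCA, a_IA ∈ [0.2,0.8]; a_PCA ∈ {0,0.1};
  P_L ∈ [500,2000] Pa), physiological filtering (ACFL ≥ 30 mL/s,
  fo ∈ [120,400] Hz), fixed SPL (−28.5 dB) and Ps (−3.37 cm H2O) scale
  corrections, min-max normalization, 80/20 split. (`dataset`)
- **Regressor** — ReLU multilayer perceptrons (10% dropout, Adam, lr 0.001,
  100 epochs) mapping six (Case I) or seven (Case II, + SPL) features to the
  four outputs, with per-target MAE/RMSE/R² evaluation and an architecture
  sweep. (`regressor`)
- **IBIF** — tracheal transmission-line + neck-skin model mapping glottal
  flow to accelerometer output, regularized inversion, PSO calibration of
  subject-specific parameters, and the single-notch oral-airflow inverse
  filter used as calibration reference. (`ibif`)

See `docs/methods.md` for the model equations, parameter provenance and
numerical choices.

## Worked example

```bash
python examples/01_simulate_vowel.py
```

```
oscillating: True
prephonatory strain: 0.296  half-width at processes: 0.00 mm
mean Ps (last 50 ms): 10.45 cm H2O (lung pressure 11.22 cm H2O)
peak collision pressure: 14.33 cm H2O

feature vector (last 50 ms):
  acfl  =   489.92
  mfdr  =   606.15
  oq    =    84.12
  sq    =     1.55
  h1h2  =    14.61
  fo    =   312.57
  spl   =   125.01
```

Mid-range activation of all five muscles at 1,100 Pa lung pressure produces
a sustained vowel: the folds are stretched 30% beyond rest (CT dominating),
the membranous glottis is fully adducted, and the mean subglottal pressure
sits just below the lung pressure (the difference is the mean transglottal
drop driving ~490 mL/s of AC flow at 313 Hz).  The collision-pressure peak
of ~14 cm H2O is the kind of tissue-stress number that is inaccessible to
direct measurement, which is what the regression stage is trained to
recover from the feature vector alone.

The other examples cover dataset assembly (`02`), training/evaluation
(`03`), the accelerometer round trip and PSO calibration (`04`) and the
intraoral-pressure reference (`05`).  A thin CLI mirrors the library
(`voxphys simulate | make-dataset | features | train | estimate |
ibif-calibrate | run-all | make-fixtures`).

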