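# faceutil

Latent-utility estimation over a geometric-morphometric face space. The
package builds a PCA "face space" from 2-D landmark configurations
(generalized Procrustes alignment, bilateral symmetrization, thin-plate
spline warps), models ordinal Likert ratings of stimuli in that space with
Gaussian-process ordinal regression (Laplace inference, evidence-based
hyperparameter selection), drives random-then-UCB sequential experimental
sessions, benchmarks prediction with leave-one-out cross-validation against
proportional-odds ordinal logistic regression (MZE / MAE), and pools
per-rater utilities into an averaged utility surface with extrema and
exceedance probabilities. A synthetic-data subpackage generates shape
populations with planted principal-component structure and simulated raters
that respond through the same latent-utility + Gaussian-noise + ordered-
thresholds generative model, enabling end-to-end recovery tests.

## Layout

| subpackage | contents |
| --- | --- |
| `faceutil.morphometrics` | landmarks, symmetry maps, GPA, PCA face space, TPS warps, landmark I/O |
| `faceutil.gpor` | ARD kernel, ordinal likelihood, MAP/Laplace, evidence, hyperparameter fitting, prediction |
| `faceutil.design` | UCB acquisition, session driver (practice / random / adaptive phases) |
| `faceutil.evaluation` | MZE/MAE, ordinal logistic baseline, LOOCV, paired model comparison |
| `faceutil.aggregation` | standard ±2 SD / 0.4-step grid, mixture pooling, extrema, tail probabilities |
| `faceutil.synthetic_data` | planted-covariance shape populations, ground-truth utilities, simulated raters and whole studies |

## CLI

Two console scripts are installed:

```bash
# build a 3-PC face space from landmarks (TPS record file or long CSV)
facespace build --landmarks faces.csv --symmetry sym.json --n-pcs 3 --out space.json
# reconstruct the shape at PC-SD coordinates
facespace render --space space.json --scores "-0.8,-0.4,0.8" --out shape.csv

# simulate a whole rating study (ratings CSV + ground-truth sidecar JSON)
gpor simulate-study --config study.yaml --m 40 --seed 42 --out ratings.csv
# fit one participant's model (hyperparameters by evidence maximization)
gpor fit --data ratings.csv --participant s01 --out model.json --restarts 5 --seed 7
# run a single random+UCB session against a simulated responder
gpor design-session --config session.yaml --responder 'simulated:{}' --seed 11 --out session.csv
# LOOCV error table (model x {MZE, MAE} x {Test, Train})
gpor evaluate --data ratings.csv --models gpor,ologit --out table.csv
# pool per-participant grids, report extrema
gpor aggregate --models model_s01.json --models model_s02.json --out avg.csv --report extrema.json
```

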