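# ivuscal

**The IVUS calcium score (ICS), end to end**: simulation of polar-domain
intravascular ultrasound (IVUS) pullbacks with exact calcium ground truth,
per-A-line calcium detection, scoring, synthetic clinical cohorts, and the
competing-risks prognostic analysis that links the score to outcomes.

## The problem

Coronary calcification predicts adverse cardiovascular events, but
angiography cannot quantify it and manual IVUS reading is slow.  On IVUS,
calcium has an unmistakable per-A-line signature: a **sharp hyperechoic
(white) border** at the calcium interface followed by a **dark acoustic
shadow**, because the interface reflects nearly all acoustic energy.  The
IVUS calcium score exploits this:

```
ICS = (# calcium-positive A-lines) / (total # A-lines) × 1000
```

computed over every A-line of every frame of a motorized pullback
(40 MHz catheter, 0.5 mm/s).  Pullbacks are analyzable when they cover
≥ 40 mm of a native coronary artery without stent struts, poor image
quality, or a false-lumen catheter position; per patient the longest
analyzable pullback is scored.  Clinically the score is studied both
dichotomized at its cohort median of 85 (ICS ≥ 85 = "high") and as a
continuous covariate per 100 units, with √ICS used for linear regression
because the raw score is strongly right-skewed.

Because no patient imaging or outcome data are publicly deposited, this
package pairs the method with two calibrated synthetic generators:

* **`ivuscal.phantom`** — a polar-domain pullback phantom (Rayleigh
  speckle, wall echo band, calcium rendered as a sharp interface with
  multiplicative distal shadowing) that yields pixel-perfect per-A-line
  labels, used to train and validate the detector;
* **`ivuscal.cohort`** — a 408-patient cohort generator with realistic
  baseline covariates, a √ICS linear structure (age +0.07/yr, previous
  stroke +2.46), and cause-specific exponential hazards for the
  patient-oriented composite endpoint (POCE: all-cause death, stroke,
  myocardial infarction, revascularization; first event counts) over a
  6-year / 2191-day horizon.

The analysis stack (`ivuscal.survival`) provides Kaplan–Meier curves,
the log-rank test, Aalen–Johansen cumulative incidence under competing
risks, cause-specific Cox regression (Efron ties, optional strata,
Breslow available), Schoenfeld proportional-hazards checks, and the
univariate *p* < 0.1 screening that builds the multivariate √ICS model.

## Worked example

Train the per-A-line SVM detector on three simulated pullbacks and score a
held-out one:

```python
import numpy as np, pandas as pd
from ivuscal import (PhantomConfig, BurdenModel, simulate_pullback,
                     extract_features, train_detector, predict_mask,
                     evaluate_detection, compute_ics)

geom, burden = PhantomConfig(), BurdenModel()
feats, labels = [], []
for seed in (1, 2, 3):
    pb, mask, _ = simulate_pullback(geom, burden, seed)
    feats.append(extract_features(pb))
    labels.append(mask.mask.ravel())
model = train_detector(pd.concat(feats, ignore_index=True),
                       np.concatenate(labels), seed=0)

pb, truth, _ = simulate_pullback(geom, burden, 99)
pred = predict_mask(model, pb)
print(evaluate_detection(pred, truth).to_dict())
print(compute_ics(pred))
```

```
{'tp': 2726, 'fp': 0, 'tn': 22874, 'fn': 0, 'accuracy': 1.0, 'precision': 1.0, 'recall': 1.0}
ICS 106.5 (sqrt 10.3; 2726/25600 A-lines)
```

2726 of the 25 600 A-lines (100 frames × 256 A-lines) are calcium-positive,
giving ICS 106.5; on the default phantom the detector recovers the ground
truth essentially perfectly.

Generate a cohort and run the prognostic analysis:

```python
from ivuscal import CohortConfig, generate_cohort, analyze_cohort

cohort, events = generate_cohort(CohortConfig(seed=1))
report = analyze_cohort(cohort, events)
poce = report["endpoints"]["poce"]
print(poce["model_group"])
print(report["logrank_poce"])
```

```
{'hr': 1.949271304739204, 'ci_low': 1.3834098322221484, 'ci_high': 2.746589283217938, 'p': 0.00013616817285973335, 'adjusted': True, 'note': None}
{'chi2': 22.440714315072483, 'p': 2.167307261385882e-06}
```

In this single replicate 154 of 408 patients reach POCE within 6 years
(cumulative incidence 0.41 overall; 0.29 in ICS < 85 vs 0.52 in ICS ≥ 85),
and the diabetes-stratified, covariate-adjusted cause-specific Cox model
estimates HR 1.95 (95% CI 1.38–2.75) for the high-ICS group — one draw
around the generating effect of 1.51; averaging over many replicates
recovers the effect (see below).

A `ivuscal` console command wires the same steps as subcommands
(`simulate`, `train`, `detect`, `eval`, `score`, `cohort`, `analyze`),
each writing a reproducibility manifest next to its outputs.

## Layout

```
src/ivuscal/io.py         pullback/mask containers, TIFF+JSON and CSV formats,
                          eligibility and pullback-selection rules
src/ivuscal/phantom.py    polar pullback phantom with calcium ground truth
src/ivuscal/detect.py     A-line features, SVM + rule-based detectors, metrics
src/ivuscal/score.py      ICS, sqrt transform, dichotomization
src/ivuscal/cohort.py     synthetic cohort and event generator
src/ivuscal/survival.py   KM / log-rank / CIF / Cox / Schoenfeld / OLS stack
src/ivuscal/benchmarks.py replication experiments on the default generators
src/ivuscal/cli.py        console entry point
docs/methods.md           models, calibration, and design notes
```
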