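# gpalpha

Pallidal alpha-band LFP biomarker analysis for deep brain stimulation (DBS)
in obsessive–compulsive disorder (OCD).

Sensing-enabled DBS implants record short bipolar local field potential (LFP)
snippets from the ventral capsule/ventral striatum region during routine
clinic visits.  `gpalpha` turns those recordings into candidate biomarkers of
symptom severity and programming decisions, for researchers working on
electrophysiology-informed DBS:

- **Spectral parameterization.**  Welch spectra (1-s Hann windows, 50%
  overlap, 0.5 Hz bins) are decomposed into an aperiodic
  Lorentzian-with-knee background and Gaussian peaks in log power,

      log₁₀ P(f) = log₁₀ L(f) + Σₙ aₙ exp(−(f − f_{c,n})² / 2wₙ²),
      L(f) = A (f_k^χ + f_min^χ) / (f_k^χ + f^χ),

  with a λ = 100 penalty on Gaussian mass below 0 Hz; knee-free spectra are
  handled by convergence to f_k < f_min.  The *periodic spectrum* is the
  log-power residual above L(f).
- **Alpha biomarkers.**  Canonical (7–14 Hz) and individual-peak (±2.5 Hz)
  alpha power per bipolar pair, summarized per hemisphere (max pair or mean).
- **Pseudo-monopolar mapping.**  Per-contact power estimates from the six
  bipolar pairs (including-mean / spanning-max rule) feed optimal-contact
  prediction: ranking, cumulative selection curves, AUC (chance = 0.5,
  perfect = 1) with permutation tests, and rank-distance agreement.
- **Spatial mapping.**  Hemisphere pooling in MNI space, top-percentile power
  centroid, moment-of-inertia focality I = Σwᵢ‖rᵢ − r_avg‖²/Σwᵢ with a
  geometry-preserving permutation null, structure border distances, 2D
  heatmaps.
- **Cohort statistics.**  Severity median split, cluster-based permutation
  correction for frequency-wise contrasts and Spearman correlations,
  session-delta correlations, REML mixed-effects models with Satterthwaite
  F tests (validated against lme4/lmerTest), responder classification.
- **Synthetic cohort generator.**  A fully seeded cohort — lead geometry
  around a planted alpha hotspot, spectrally shaped LFP, severity-coupled
  clinical trajectories, active-contact labels — so the entire pipeline is
  testable against known ground truth without any patient data.

## Worked example

```python
import numpy as np
from gpalpha import (GeneratorConfig, generate_cohort, PipelineConfig,
                     analyze_cohort)

cohort, truth = generate_cohort(GeneratorConfig(), seed=0)
config = PipelineConfig(seed=1, n_perm=2000, n_boot=2000, make_figures=False)
state = analyze_cohort(cohort, config)

cell = state["stats"]["cells"]["pooled|max_pair|periodic"]["alpha_peak"]
pred = state["prediction"]["periodic"]
spa = state["spatial"]["periodic"]
dc = state["stats"]["delta_correlation"]
```

With the default 13-patient cohort this prints:

```
588 recordings, 49 visits, 104 contacts
S1 peak periodic alpha vs Y-BOCS: R = 0.62 [0.26, 0.85], p = 0.0015
optimal-contact AUC = 0.69 (chance 0.5), p = 0.003
alpha hotspot centroid: (-9.6, 4.7, -4.0) mm; planted truth (-10.12, 4.07, -4.0)
focality: I = 9.3 mm^2, sqrt(I) = 3.05 mm, p = 0.0005
session deltas: R = -0.28 [-0.49, -0.07], p = 0.02
LME: beta_alpha = 19.7 +/- 9.2, F = 4.64, p = 0.034
```

Reading the numbers: patients with higher peak periodic alpha power at the
first recording session have more severe symptoms (positive cross-sectional
Spearman R); ranking contacts by pseudo-monopolar alpha finds the clinically
chosen stimulation contact far better than blind testing (AUC 0.69 vs 0.5);
the spatial centroid of the top-5% alpha contacts lands within ~1 mm of the
planted hotspot and the distribution is significantly more focal than the
permutation null; within patients, sessions with suppressed alpha coincide
with symptom improvement (negative delta correlation), and the mixed model
confirms the alpha–severity association while adjusting for stimulation
amplitude and time since DBS onset.

## Command line

```sh
gpalpha simulate --seed 0 --out cohort/          # write a synthetic fixture
gpalpha run-all --config pipeline.toml           # full analysis bundle
gpalpha metrics --input cohort/ --out run/ --seed 1   # run up to one stage
gpalpha validate --config pipeline.toml
```

`run-all` writes `metrics.csv`, `monopolar.csv`, selection curves, a JSON
report, figures, the serialized config and a MANIFEST of completed stages
into the output directory; reports are a pure function of (inputs, config).

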