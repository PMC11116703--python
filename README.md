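# wfgica

Group ICA analysis of wide-field calcium imaging across brain states.

`wfgica` is for researchers who record mesoscale cortical fluorescence
movies (e.g. a genetically encoded calcium indicator imaged over the
dorsal cortex) while stepping the brain state — here, graded isoflurane
anesthesia from 2% down to wakefulness — and who want to ask *which
cortical regions carry the activity in each state*. It implements, as a
tested and reusable Python pipeline:

- **Preprocessing**: spatial block-mean downsampling, landmark-based
  similarity registration (bregma/lambda), a common field-of-view mask
  across sessions, per-pixel ΔF/F₀ against the session mean F₀, and a
  zero-phase 0.1 Hz Butterworth high-pass.
- **Group spatial ICA**: temporal-concatenation group ICA — per-session
  temporal PCA to L₁ components, a second PCA to K group components, and
  FastICA over pixels — with session maps and time courses recovered by
  the standard back-reconstruction matrix chain.
- **ICASSO stability analysis**: repeated ICA under bootstrap resampling
  and random initialization, agglomerative clustering of the estimates by
  |r|, centrotype components, a per-cluster stability index, and model
  order selection by minimizing the cluster R-index.
- **Annotation**: atlas macro-area tagging of each IC by its peak-|weight|
  pixel, automatic flagging of midline-confined and vessel-like (elongated)
  artifact components, and rectangular-assignment matching between
  component sets (Hungarian algorithm on |R|).
- **Brain-state statistics**: per-IC binary activation vectors from
  ±3σ thresholds referenced to the deepest-anesthesia segment; the
  per-state activation counts N_IC,ST and relative occurrences
  N_IC,ST / Σ_IC N_IC,ST; a 10,000-draw bootstrap null for the expected
  occurrence (5,000 crossings resampled from the deepest state and 5,000
  from the awake state); the across-subject 95% CI prominence rule;
  per-state phi (binary Pearson) co-occurrence matrices; Fisher-z within-
  area averaging; one-factor repeated-measures ANOVA over the six states
  and Holm-corrected paired post hoc t-tests.
- **A synthetic study generator** that emulates the study design — 3
  subjects × 2 sessions, six concatenated states per session, bistable
  near-global up/down dynamics in deep anesthesia, oscillatory dynamics at
  intermediate levels, fragmented independent transients awake, a
  calibrated state-dependent coupling between two retrosplenial-like
  sources, sensor noise, slow drift and a vessel-like artifact — so that
  every pipeline stage has a ground-truth recovery test.

## Worked example

Simulate the default synthetic study at a 10 Hz analysis rate, run the
whole pipeline at K = 8, and look at the retrosplenial statistics:

```python
import numpy as np
from wfgica import RunConfig, run_study
from wfgica.annotate import match_components

cfg = RunConfig(seed=1, k=8,
                simulate=dict(fps=10.0, dur_per_state=150.0, height=48, width=48))
result, truth = run_study(cfg)

m = match_components(truth.maps[:, result.mask], result.fit.components.maps)
print("mean matched spatial |r|:", round(float(m.abs_r.mean()), 3))

retro = result.occurrence[result.occurrence.group == "Retrosplenial"]
curve = retro.pivot_table(index="subject", columns="state", values="rel",
                          sort=False).mean(axis=0)
print("retrosplenial occurrence:", np.round(curve.values, 3))

z = result.group_tables["Retrosplenial"].mean(axis=0)
print("retrosplenial phi (deep, awake):",
      round(np.tanh(z['iso2.0']), 3), round(np.tanh(z['awake']), 3))
a = result.occurrence_anova["Retrosplenial"]
print(f"RM ANOVA: F({a.df1}, {a.df2}) = {a.f:.2f}, p = {a.p:.2g}")
```

prints (seed 1):

```
mean matched spatial |r|: 0.995
retrosplenial occurrence: [0.155 0.109 0.079 0.059 0.043 0.023]
retrosplenial phi (deep, awake): 0.795 0.359
RM ANOVA: F(5, 10) = 110.49, p = 2e-08
```

The eight planted sources are recovered almost perfectly; the
retrosplenial share of all threshold crossings falls monotonically from
deep anesthesia (0.16) to wakefulness (0.02); the binarized co-activation
of the retrosplenial pair drops from ≈0.8 under 2% isoflurane to ≈0.36
awake (the generator's designed values are 0.80 and 0.35); and the
repeated-measures ANOVA over the six states flags the occurrence trend
with the (5, 10) degrees of freedom of a 6-state × 3-subject design.

There is also a CLI for file-based runs:

```bash
wfgica all --seed 1 --out runs/demo          # simulate + full pipeline
wfgica simulate --seed 1 --out data/         # raw TIFFs + atlas only
```

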