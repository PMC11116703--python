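# Methods

This note documents the models and procedures implemented in `wfgica`,
the design choices made where several reasonable options existed, and
what the synthetic-data tests do and do not establish.

## Preprocessing

Raw session stacks are (optionally) block-mean downsampled (default
factor 4 for 512×512 acquisition; factor 1 for the synthetic movies that
are generated at analysis resolution), then registered to a reference by
the 4-degree-of-freedom similarity transform fixed exactly by the two
landmark pairs (bregma, lambda). Interpolation is bilinear; a pure
integer translation is applied as an exact pixel copy. Registration of
non-divisible dimensions crops the bottom/right remainder. The analysis
mask is the logical AND of every session's usable field of view with the
atlas cortex mask.

ΔF/F₀ is computed per pixel against the temporal mean of the whole
concatenated session (states recorded in one session share F₀), in
percent. The high-pass is a 4th-order Butterworth at 0.1 Hz applied
forward-backward (zero phase); no explicit low-pass is applied because
the acquisition Nyquist frequency bounds the band from above. Filtered
traces are re-centered to exactly zero temporal mean. The filter family
and order are a declared choice — only the 0.1 Hz corner is part of the
analysis definition. Frame ranges are half-open `[start, end)`; pixel
coordinates are 0-based `(row, col)`.

## Group ICA

The decomposition follows the two-stage temporal-concatenation scheme
used for multi-subject fMRI. Stage 1 reduces each session's T×P matrix
in the temporal domain by PCA to L₁ components (default L₁ = ⌈1.5 K⌉,
capped by the session rank); the whitened rows (identity covariance over
pixels) are exposed as the per-session contract. Stage 2 concatenates
the **variance-preserving** PCA projections (uᵀX, not the unit-variance
whitened rows) and reduces to K whitened group rows. Concatenating at
natural scale keeps the pooled eigenvalue ordering meaningful: weak but
structured signals (e.g. a vessel artifact) rank below every true source
instead of being equalized with them, and bootstrap re-estimation of the
reduction remains well conditioned. This choice matters in practice —
with unit-variance concatenation a low-energy artifact can randomly
displace a true source from the K-dimensional group subspace.

Spatial FastICA (logcosh contrast, symmetric decorrelation) unmixes the
group rows with pixels as samples. Maps are z-scored over masked pixels
and oriented so the peak-|weight| pixel is positive; the mixing matrix
carries the complementary scale. Session maps and time courses follow
the standard back-reconstruction chain
`maps_s = A⁻¹ W[:,s] G_s`, `tc_s = u_s D[s,:] A`,
which collapses exactly to the group maps for a single full-rank
session. Time courses are in arbitrary ICA scale; all downstream
thresholds are σ-based and therefore scale-free.

### ICASSO and order selection

Stability analysis reruns FastICA `n_runs` times (default 10) under
bootstrap resampling of pixels and/or fresh random initialization. Each
bootstrap run **re-estimates the K-dimensional reduction from the
resampled pixels**, so the perturbation reaches the retained subspace
itself; this is what makes wrong model orders visibly unstable.
Estimates (expressed on the full pixel set) are clustered by
average-linkage agglomeration on 1 − |r|; each cluster's centrotype (the
estimate with maximal total within-cluster similarity) becomes the
reliable component, with a quality index
`Iq = mean within-cluster similarity − mean similarity to all outside
estimates`, clipped to [0, 1].

Model order is chosen by minimizing the cluster R-index

    I_R(K) = (1/K) Σ_k d_in(k) / min_{l≠k} d_ext(k, l)

with d_in the mean within-cluster dissimilarity (0 for singletons) and
d_ext the mean between-cluster dissimilarity. On the synthetic study the
curve has a clear minimum at the true source count (typical values:
≈0.07 at K = 8 versus ≈0.2–0.37 at 4, 12, 16).

## Annotation and artifact exclusion

Each component is tagged with the macro area (somatomotor,
somatosensory, posterior parietal, visual, retrosplenial, or the midline
band) under the pixel with the largest |weight|, sign-independent, ties
broken row-major. Artifact flagging operates on the largest connected
blob of the component's top-decile |weight| support:

- **midline**: more than half (default) of the blob's pixels fall on the
  midline column band;
- **vessel**: the |weight|-weighted major/minor axis ratio of the blob
  exceeds 4 (default). The weighted ratio is used because a binary
  support ratio mislabels compact sources clipped by the mask edge,
  while the planted vessel scores ≥ 5 and true sources ≤ ~2.

Both thresholds are configurable, and a manual exclusion list overrides
the automatic rules — the flags automate what is ultimately a visual
quality call.

Component sets are matched by rectangular assignment: the Pearson
correlation matrix over masked pixels is computed, and the injective
assignment maximizing total |r| is solved with the Hungarian algorithm;
signed r is reported per pair.

## Activation occurrence and co-occurrence

For each session and IC, thresholds are the mean ± 3 SD of the IC's time
course during the deepest-anesthesia segment (iso 2%), the state of
global inactivation that serves as the reference. The binary activation
vector is 1 wherever the time course strictly exceeds either threshold;
both polarities count. N_IC,ST is the number of suprathreshold *frames*
in state ST (not runs of frames), and the relative occurrence is
N_IC,ST / Σ_IC N_IC,ST over retained ICs; a state with no crossings is
reported missing rather than zero.

The expected-occurrence null pools every crossing event (a frame with
its IC identity) from the deepest and the awake segments across
sessions, draws 5,000 events with replacement from each pool (10,000
total), and takes each IC's share of the draws. As the number of draws
grows this converges to the analytic mixture (p_deep + p_awake)/2 of the
IC's pool shares. A component is *prominent* in a state when the lower
bound of the across-subject 95% t-interval (df = N−1) of its relative
occurrence exceeds its expected proportion.

Co-occurrence in a state is the Pearson correlation of the binary
vectors restricted to that state's frames (the phi coefficient);
matrices are per session and state, symmetric with unit diagonal, and
entries involving a constant vector are missing. Within-area coupling
averages the Fisher z = atanh(r) of within-area pairs (|r| clipped at
1 − 10⁻⁶ so coincident vectors stay finite), then sessions within
subject; tanh of the average is reported on the correlation scale.

State dependence is tested with a one-factor repeated-measures ANOVA
(F = MS_state/MS_error, df = (s−1, (s−1)(n−1)); no sphericity
correction, matching the uncorrected-df convention), followed by paired
t-tests on all state pairs with Holm step-down correction. Subjects with
missing cells are dropped listwise from the affected test. A zero
residual variance is reported as a degenerate result rather than raised.

## The synthetic study generator

The generator emulates the study design the pipeline targets, and its
defaults *are* the tested conditions: 3 subjects × 2 sessions, six
states concatenated deepest→awake, eight Gaussian sources (σ ≈ 0.055 of
the grid) over five bilateral macro areas, peak amplitude 8% ΔF/F₀,
calcium transients as single-exponential kernels (τ = 0.5 s,
slow red-shifted-indicator-like), ±20% per-event amplitude jitter,
baseline 1000 counts, Gaussian sensor noise 0.5% of baseline,
multiplicative drift (1% sinusoid at 0.02 Hz plus 1% linear), one
vessel-like elongated static map with band-limited 0.5–1.5 Hz temporal
noise at 0.8% ΔF/F₀, and integer landmark offsets up to ±2 px per
session that the registration stage must undo.

Per-state event mechanics:

| state   | mechanism            | clock (min⁻¹) | coherence | retro / other participation |
|---------|----------------------|---------------|-----------|------------------------------|
| iso2.0  | global Poisson clock | 9  (0.15 Hz)  | 1.00      | calibrated (≈1.0) / 0.415    |
| iso1.75 | global Poisson clock | 11 (0.18 Hz)  | 0.90      | 0.75 / 0.48                  |
| iso1.5  | quasi-periodic clock | 15 (0.25 Hz)  | 0.75      | 0.60 / 0.57                  |
| iso1.0  | quasi-periodic clock | 18 (0.30 Hz)  | 0.60      | 0.50 / 0.71                  |
| iso0.5  | quasi-periodic clock | 21 (0.35 Hz)  | 0.45      | 0.42 / 0.93                  |
| awake   | independent Poisson  | —             | 0         | 6 / 23 events·min⁻¹          |

"Coherence" is the fraction of a source's events drawn from the shared
clock (the rest are independent Poisson events at the same total rate).
Deep states therefore show near-global bistable up-states, intermediate
states coherent oscillations at 0.2–0.4 Hz, and the awake state
fragmented independent transients — with total threshold crossings
rising monotonically toward wakefulness while the retrosplenial *share*
of crossings falls monotonically (≈0.15 → 0.03 of the total under the
default geometry). Sources joining a shared clock event receive a
per-event onset latency, uniform on [0, 0.1 s], modelling slow-wave
propagation; the two retrosplenial-like sources share their latency draw
(homotopic posterior-medial regions receive the wave nearly
synchronously). Every source additionally expresses independent local
sub-threshold transients (12 min⁻¹ at 30% of the source amplitude) in
every state. These two features keep each source's raw trace
individually identifiable to ICA even when its binarized co-activation
with a partner is high; without them the retrosplenial pair's raw traces
are ≈0.99 correlated and cannot be separated at K = n_sources.

The awake regime is a modeling choice: published descriptions of awake
mesoscale dynamics are qualitative ("fragmented and distributed"), so
independent Poisson transients with one coupled pair are used as the
simplest process with the right marginal statistics.

### Coupling calibration

The design's co-activation targets are stated on the analysis scale: the
phi correlation of the pair's *binarized, 0.1 Hz high-passed* time
courses should be ≈0.80 in the deepest state and ≈0.35 awake. Two knobs
— the deep-state participation probability of the retrosplenial pair and
the awake shared-event fraction — are calibrated at design construction
by deterministic bisection (fixed internal seed, six 1200 s replicates
per step) against exactly the thresholding rule the pipeline applies.
Binarization on high-passed traces is essential here: filtering alone
changes the achievable phi ceiling by ~0.1.

The vessel amplitude (0.8% ΔF/F₀) is set so the artifact's pooled energy
sits below the weakest source-specific variance direction (the
retrosplenial pair difference) but far above the PCA noise floor: at the
true order K = 8 all eight sources are recovered and the vessel is
excluded by the reduction, while at K ≥ 9 the vessel emerges as a
component and must be caught by the elongation flag.

## What the tests show — and what they do not

The recovery tests establish that the implementation is internally
correct: the forward model is inverted by ΔF/F₀ to numerical precision,
the decomposition recovers planted sources (mean matched spatial
|r| ≥ 0.99 at study scale), back-reconstruction agrees with
single-session ICA (median |r| ≈ 0.999), the R-index selects the true
order, and the designed occurrence trend and coupling values are
recovered within the stated tolerances. They do *not* establish
performance on real wide-field data: the generator uses compact Gaussian
sources with linear mixing, stationary within-state statistics, Gaussian
sensor noise and no hemodynamic contamination, residual motion,
photobleaching beyond a smooth drift, or behavior-locked activity. The
headline statistics also depend on the chosen analysis order K; the
robustness sweep (K ∈ {7, 8, 10, 12}) shows the retrosplenial contrasts
survive moderate over- and under-specification, with the caveat that at
K one below the truth the bilateral pair merges into a single
retrosplenial component.

## Problem sizes and runtimes

Simulations run at a 10 Hz analysis rate (event rates are defined per
unit time, so this is equivalent to decimating a 40 Hz acquisition;
40 Hz remains the generator default for study-scale realism). The test
suite uses: one study-scale run (64×64 px, six 300 s states, 6 sessions,
K = 8) for source recovery and session reproducibility; twenty seeded
replicates at 40×40 px with 120 s states for the occurrence and coupling
recovery statistics; ten seeded 3-session datasets at 40×40 px with 90 s
states for order selection; these sizes keep the full suite within a
desk-scale run while leaving the acceptance margins wide.
`scripts/acceptance.py` recomputes the same quantities from scratch with
twelve replicates and eight order-selection repeats.

## Known limitations

- FastICA with logcosh replaces the Infomax variant used by the
  historical MATLAB tooling for this analysis family; on the synthetic
  sources the two families agree up to sign/permutation, but real-data
  components may differ in detail.
- ICASSO bootstrap resamples pixels (the ICA samples); temporal block
  bootstrap is not implemented.
- The artifact flags are heuristics with tunable thresholds, not a
  trained classifier; borderline vascular components on real data still
  warrant visual review (the manual exclusion list exists for this).
- The R-index criterion can be flat between adjacent orders on very
  clean data; the full curve is always reported so the choice can be
  inspected.
- Greenhouse–Geisser sphericity correction is available via
  ``rm_anova(..., sphericity_correction="gg")`` but off by default,
  matching the uncorrected-df reporting convention.
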