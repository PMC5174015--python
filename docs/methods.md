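# Methods

## Signal model and preprocessing

The package operates on single-channel EMG amplitude series (μV) at a known
sampling rate. A recording is modeled as muscle-response bursts separated by
near-flat non-signal stretches. Epoch detection works on the full-wave
rectified trace:

- a candidate epoch is opened at every local maximum whose rectified
  amplitude reaches `amp_threshold_frac` (default 0.3) of the global
  rectified maximum;
- its borders are found by scanning outward from the peak until the local
  slope magnitude stays below `slope_eps_frac × global max` (default 0.01
  per sample) for `min_gap_ms` (default 5 ms) of consecutive samples — the
  zero-slope region between bursts; windows closer than the same gap merge.

Slopes are measured on a short moving-average envelope (`smooth_ms`,
default 2 ms) of the rectified signal rather than on raw sample
differences. On any realistic noisy baseline the raw sample-to-sample slope
exceeds a 1%-of-peak tolerance almost surely, so a literal per-sample rule
never observes a quiet run; averaging over ~20 samples reduces the noise
slope by roughly the window length while leaving burst edges sharp at the
millisecond scale. `smooth_ms = 0` restores the literal rule for clean
signals.

Each detected window is rectified and divided by its peak, so epoch
amplitudes satisfy x ∈ [0, 1] with max(x) = 1 exactly; a `rectify=False`
switch preserves signed amplitudes for experimentation. Normalization makes
the analysis scale-invariant — recordings from subjects with different
overall signal strengths produce identical epochs up to noise. An epoch can
optionally be decimated by an integer factor on a grid aligned with its
peak (the peak sample is always retained, the first sample is kept as an
anchor, and the result is renormalized); the default factor is 1.

## Visibility network

A normalized epoch of N samples maps to an undirected weighted graph on N
nodes. Nodes i < j are linked iff j = i + 1 or every intermediate sample
lies strictly below the chord from (i, xᵢ) to (j, xⱼ); the weight of a link
is |xᵢ − xⱼ| + 1, so all weights lie in [1, 2]. Consequences used
throughout:

- the chain 1–2–…–N is always present, so every graph is connected and
  all shortest-path quantities are finite;
- strict inequality means an equal-amplitude intermediate blocks the line
  of sight, but the adjacency clause prevents plateaus from isolating
  nodes;
- the link structure is invariant under affine rescaling x → a·x + b
  (a > 0) and equivariant under time reversal.

The production construction is an O(N²) sweep per node maintaining the
running maximum chord slope, with early termination once no remaining
sample can beat it; the literal O(N³) inequality check is kept in the test
suite as an independent oracle, never on the production path.

## Network measurements

Thirteen scalars summarize each graph (L = link count, kᵢ = degree):

| measure | definition | notes |
|---|---|---|
| AD | 2L/N | |
| ACC | mean of Cᵢ = 2Lᵢ/(kᵢ(kᵢ−1)) | Lᵢ is the **weight sum** over linked neighbor pairs by default, so Cᵢ may exceed 1; an unweighted (count) mode is provided. Cᵢ = 0 when kᵢ < 2. |
| T | 3·triangles/triples | binarized graph; triples = Σkᵢ(kᵢ−1)/2; NaN when no triples |
| As | (S₁Sₑ − S₂²)/(S₁S₃ − S₂²) | Sₘ = Σkᵢᵐ, Sₑ = ΣᵢⱼWᵢⱼkᵢkⱼ over ordered pairs; NaN for regular graphs |
| Den | 2L/(N(N−1)) | |
| CPD | Σᵢ(B_max − Bᵢ)/(N−1) | Bᵢ = betweenness, all minimum-weight paths counted |
| CC | mean of N/Σⱼdᵢⱼ | |
| ASP | Σᵢ≠ⱼ dᵢⱼ/(N(N−1)) | |
| E | Σᵢ≠ⱼ dᵢⱼ⁻¹/(N(N−1)) | positive entries only |
| D | max dᵢⱼ | |
| AW | ΣᵢⱼWᵢⱼ/N | |
| skewness, kurtosis | standardized 3rd/4th central moments of all N² matrix elements | population sd; kurtosis not excess-corrected; NaN when variance is zero |

Numerical choices:

- **Distances.** dᵢⱼ is the minimum total edge weight (edge length = Wᵢⱼ,
  the full weight including the +1), computed by Dijkstra
  (`scipy.sparse.csgraph`). A `direct` mode (dᵢⱼ = Wᵢⱼ, 0 where unlinked)
  exists because the reference worked example tabulates direct distances;
  the pipeline default is true shortest paths.
- **Betweenness.** Brandes' algorithm with a tolerance-aware Dijkstra:
  tentative path lengths within a relative 1e−9 are treated as tied, so all
  minimum-weight paths are counted even when floating-point accumulation
  makes equal sums differ in the last bits. Library implementations that
  compare by exact float equality can split tied-path credit differently
  on weighted graphs; the test suite therefore checks the weighted case
  against exhaustive path enumeration and the binary case against networkx.
- **Moments.** Mean and sd are taken over all N² matrix elements, zeros and
  diagonal included, with the population (not sample) standard deviation —
  the only convention under which the reference network's element mean
  equals its total weight divided by N².
- **Undefined values** (regular-graph assortativity, triangle-free
  transitivity, zero-variance moments) are returned as NaN with an explicit
  `UndefinedMeasureWarning`, never silently zeroed; feature assembly drops
  affected epochs and logs the count.

## Feature selection and classification

Per-epoch measures are assembled into an M×N feature matrix. A one-way
fixed-effects ANOVA across the three diagnostic groups scores each
candidate; features with p < α (default 0.001) are kept. No
multiple-testing correction is applied by default, matching per-feature
reporting; Bonferroni across the candidates is available. The canonical
effective set is {AD, ACC, Den, AW, skewness, kurtosis}; in practice all
thirteen candidates clear p < 0.001 on default synthetic data, so the
selector simply keeps what it finds.

Evaluation uses repeated stratified hold-out at test fractions 0.20–0.80
with 10 repeats by default. In every repeat, features are standardized
using training-portion statistics only (no leakage); any tuned
hyperparameter would be chosen by stratified 5-fold CV on the training
portion (the defaults fix all hyperparameters, so the grid machinery is
idle unless a grid is supplied). Metrics — specificity, sensitivity for
neuropathy and for myopathy, total accuracy — come from one 3×3 confusion
matrix per repeat and are reported in percent as mean ± sd across repeats
(not across folds).

Classifier defaults:

- **k-NN**: k = 3, Euclidean distance on standardized features.
- **MLP**: one hidden layer of 10 logistic units, L-BFGS solver, ≤ 500
  iterations. Full-batch quasi-Newton is the appropriate optimizer at
  study sample sizes (a few hundred epochs): stochastic solvers paired
  with early stopping on a ~10-sample validation split terminate at chance
  level before the loss moves, which we observed directly (37% vs 100%
  accuracy on identical, perfectly separable features).
- **SVM**: RBF kernel, one-vs-rest, C = 1, kernel width by the median
  heuristic (γ = 1/(2m²), m the median pairwise training distance).

Class codes are fixed as {0: normal, 1: neuropathy/ALS, 2: myopathy}. One
protocol seed derives every split and initialization via
`numpy.random.SeedSequence`, making reports bitwise-reproducible.

## Synthetic data generator

The generator emulates the class-specific time-domain morphology: per
burst, **normal** = 1 pulse of 400 μV peak / 15 ms, **neuropathy (ALS)** =
2 pulses of 1400 μV / 20 ms, **myopathy** = 3 pulses of 300 μV / 10 ms.
Each pulse is biphasic — a positive raised-cosine lobe followed by a
negative lobe at 0.45 of its amplitude (kept under one half so rectified
secondary maxima stay below half-peak and the per-class peak count is
exact at zero noise). Pulses sit back to back, giving evenly spaced peaks;
amplitude and duration each jitter by a uniform ±10% by default. Bursts are
embedded in 25 ms of baseline padding with zero-mean Gaussian noise of
20 μV sd (5% of the healthy peak — the generator's free choice, as real
recordings' noise statistics vary by instrument). The default sampling rate
of 10 kHz puts 100 samples across a 10 ms pulse.

What the generator does *not* model: motor-unit recruitment and firing
statistics, pulse-shape variability beyond the raised-cosine template,
inter-subject variability, electrode artifacts, power-line interference.
Passing end-to-end tests therefore demonstrate that the pipeline recovers
the stated burst-morphology differences under additive Gaussian noise —
not clinical performance on real recordings, which depends on segmentation
quality and noise structure the generator idealizes. The pulse template is
configurable so recorded motor-unit waveforms can be substituted.

## Problem sizes and runtime

Default study conditions are 60 epochs per class (180 total). Study runs
configure `decimation_factor = 4` (10 kHz → 2.5 kHz, epochs of roughly
40–110 nodes): the method itself prescribes subsampling normalized epochs
before graph construction, and at these node counts all thirteen measures,
including all-pairs shortest paths and betweenness, complete for a full
study in well under a minute. The configuration default remains factor 1
(no decimation) so users opt into subsampling explicitly; undecimated
epochs at 10 kHz make the path-based measures substantially slower.

## Known limitations

- Segmentation parameters (threshold fraction, slope tolerance, minimum
  gap) are heuristics chosen for burst-like signals with quiet baselines;
  continuously active interference-pattern EMG would need different
  windowing.
- The assortativity variant with weighted Sₑ is not bounded to [−1, 1]
  (weights ≥ 1 inflate the numerator); it is kept as defined for
  comparability, not as a correlation coefficient.
- The reference worked example's central-point-dominance, closeness,
  efficiency and diameter figures are internally inconsistent and cannot be
  regenerated from its printed intermediates; they are treated as reference
  values only, not fixtures.
- ANOVA selection is per-epoch; epochs from the same recording are treated
  as independent, which overstates effective sample size when many epochs
  share a subject.
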