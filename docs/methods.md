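# Methods

This note documents the models, estimators and numerical choices behind
`avaconn`, and what the synthetic-data tests do and do not establish about
real recordings.

## The analysis in one paragraph

Resting-state source-level activity (e.g. beamformed MEG, regions ×
samples at ~1024 Hz) is z-scored per region, thresholded at |z| > 3, and
OR-pooled into time bins of a few samples. A *neuronal avalanche* is a
maximal run of contiguous bins in which at least one region is active,
bounded by fully quiescent bins. Each avalanche yields a *transition
matrix* (TM): entry (i, j) is the conditional frequency with which region
j is active one bin after region i, within that avalanche. TMs are
averaged over avalanches per participant, then over participants, and
symmetrized. The structure–function question is whether these transition
probabilities track white-matter connection strength: the edge-wise
Spearman correlation r between the group TM and a structural connectome,
judged against a null built by uniformly permuting the temporal order of
bins inside every avalanche (which preserves each bin's active-region set
and therefore all purely spatial statistics) and rebuilding the TM; p is
the plain proportion of null correlations ≥ the observed one.

## Branching parameter and bin selection

For an avalanche with per-bin event counts n(1)…n(N):

    sigma_i = [ prod_{j=1}^{N-1} n(j+1)/n(j) ] ^ (1/(N-1)),
    sigma   = geometric mean of sigma_i over avalanches,

with duration-1 avalanches excluded (no descendant bin exists). The time
bin is chosen from candidates 1–5 samples as the one whose sigma is
closest to 1 (ties to the smaller bin), the operating point of a critical
branching process.

Two properties of this estimator are worth knowing. First, the product
telescopes: sigma_i = (n_last/n_first)^(1/(N-1)). On cascades that start
from a single event, sigma_i ≥ 1 always, and the final bin is conditioned
on imminent extinction, which biases short avalanches upward. On critical
Galton–Watson ensembles the estimate is ≈1.07 with all avalanches but
≈1.016 once avalanches of ≤10 bins are excluded — which is precisely the
default duration filter of the pipeline (short detected avalanches are
also the ones most likely to be noise). Second, and for the same reason,
the estimator cannot separate subcritical from critical dynamics on
single-ancestor cascades (both read ≈1); supercritical dynamics are
clearly separated because surviving cascades grow geometrically and the
telescoped ratio recovers the growth rate. The estimator is used here the
way the avalanche literature uses it — as a criticality check and a
bin-selection criterion — not as a general branching-ratio measurement.

## Transition matrices

- Denominator of row i: bins t (over the first N−1 bins) with i active;
  numerator of (i, j): those bins with j active at t+1. Rows whose region
  is never an ancestor are *undefined* (NaN), not zero: treating them as
  zero would conflate "never active" with "active but never followed".
  Undefined entries are excluded from all averages; the entrywise count of
  contributing inputs is carried alongside.
- Aggregation is the unweighted arithmetic mean (avalanche → participant →
  group). Symmetrization averages (i, j) with (j, i), copying one-sided
  values.
- The *long-delay* variant is binary per avalanche: (i, j) = 1 iff i is
  active in the first bin and j at any later bin. It admits delays as long
  as the avalanche itself and is therefore insensitive to zero-lag
  (volume-conduction-like) co-activation.
- Frequency-specific analyses band-pass the continuous series (fourth-order
  Butterworth, canonical bands delta 0.5–4 … gamma 30–48 Hz) before the
  standard chain. The filter is applied forward–backward: zero net phase,
  so excursion timing — which the thresholding measures — is not shifted.
  The band must satisfy high < fs/2.

## Coupling statistic and null

All off-diagonal region pairs enter the correlation, including zero-weight
structural edges (an option restricts to nonzero edges); pairs undefined in
the TM are dropped from both vectors. Ties get average ranks. Each of the
`n_perm` permutations (default 1000) re-randomizes every avalanche with an
independent child of one master seed stream, so runs are reproducible. The
p-value is the plain proportion with no continuity correction; its
resolution is 1/n_perm, and a zero proportion is reported as "< 1/n_perm".
The temporal randomization preserves each avalanche's duration, size, and
per-bin event counts, so the null ensemble is matched to the data in every
scalar avalanche statistic — including sigma — and differs only in
transition structure. Because each bin's active-region *set* is kept
intact, spatial co-activation survives randomization; with genuinely
structure-coupled cascades the null correlations therefore have a positive
mean, and the test asks whether the observed r exceeds even that.

## Avalanche-size distribution

Critical branching predicts P(S = s) ∝ s^(−3/2). The fit is a discrete
maximum-likelihood power law: alpha maximizes the zeta-normalized
likelihood over s ≥ xmin, optionally upper-truncated (normalizer
ζ(α, xmin) − ζ(α, xmax+1)) when the generator caps avalanche size; capped
avalanches are censored observations and are excluded from the sample.
xmin defaults to 1, with a Kolmogorov–Smirnov tail-selection option that
picks the xmin minimizing the distance between the empirical tail CDF and
the fitted law. The exponent is returned on the −α convention.

## Synthetic-data generators

The generators define the study conditions for every test; none of them is
fitted to data.

**Connectome** (`gen_connectome`): edges exist independently with
probability `density` (default 0.3, a typical deterministic-tractography
density); weights are log-normal (log-SD `weight_dispersion`, default 1),
mimicking the heavy tail of streamline counts. Symmetric, zero diagonal,
at least one positive edge.

**Connectome-coupled cascades** (`simulate_cascades`): one uniformly chosen
seed region; each active region i independently activates j ≠ i with
probability sigma_target · u_ij, where u mixes the row-normalized
structural weights with a uniform kernel by `coupling` ∈ [0, 1]. Rows of u
sum to 1, so the expected offspring per active region is exactly
`sigma_target`; duplicate activations collapse within a bin; cascades end
at quiescence or `max_duration`. `coupling` is the ground truth that
recovery tests estimate against: at 0 the spread ignores the connectome,
at 1 it follows it fully.

**Continuous embedding** (`embed_continuous`): cascades become constant
pulses of `event_amplitude` (default 5, in baseline-SD units) spanning
their bins, on the binning grid, separated by quiet gaps of ≥ 2 bins. Two
deliberate design choices make the detection round trip exact at amplitude
≥ 10: (1) the background is smoothed Gaussian noise that is
amplitude-limited (clipped at 2.8 SD, then re-standardized to unit
variance), so the noise itself never crosses the default |z| > 3
threshold; (2) gaps are widened until no region is active in more than 1%
of the recording, because z-scoring over the whole recording divides pulse
amplitudes by √(1 + amplitude²·duty-cycle). Real MEG noise is neither
bounded nor stationary; what the round-trip tests establish is that the
detection chain itself is lossless under conditions where detection is
unambiguous, not that real excursions are always recovered.

**Branching process** (`simulate_branching_process`): Galton–Watson with
Poisson(sigma) offspring per event, one ancestor, events placed in
uniformly random regions. Boolean rasters collapse duplicate (region, bin)
events, but the pre-collapse counts are retained in `events_per_bin`, so
sigma estimation sees the true event sequence. Avalanches reaching
`max_events` finish their last generation and are flagged `truncated`
(censored) rather than clipped mid-generation, which would bias offspring
statistics.

**Field-spread surrogate** (`gen_leadfield_surrogate`): 66 white Gaussian
sources smoothed with a zero-phase polynomial (Savitzky–Golay) filter
(window 21, order 3); 100 non-overlapping boxcar perturbations, one region
at a time, lengths drawn from {5, 10, 100} samples, amplitudes uniform in
[50, 400], onsets ≥ 200 samples apart (placement is exact: lengths first,
the remaining slack split into random gaps). Sources sit on a jittered
quasi-uniform shell (radius 0.85) inside a random hemispheric sensor cap
(radius 1); the leadfield is gain/distance with random gains, so mixing is
dense and distance-dependent. Sensor noise with spatial correlation
falling off as 1/distance (eigen-clipped to the nearest positive
semidefinite correlation) is added at SNR 4 (variance ratio per sensor),
and sources are re-extracted with a Tikhonov-regularized linear inverse
(λ = 10⁻⁶·tr(LᵀL)/n) of the same leadfield. A linear inverse rather than a
beamformer is used deliberately: only linear mixing and its leakage
structure matter for the control, and any linear inverse preserves them.
Reconstructed leakage makes neighbouring sources co-activate — exactly the
confound the surrogate exists to emulate — while carrying no connectome
structure at all, so any TM–connectome correlation it produces is the
field-spread floor.

## Problem sizes and numerical choices

- Default analysis parameters: threshold 3 (sweep 2.5/3/3.5), bin 3
  samples (candidates 1–5, or automatic sigma≈1 selection), minimum
  duration 10 bins (presets 1/10/30), broadband, 1000 permutations.
- z-scores use the population (1/N) SD over the full recording.
  Thresholding is strict (|z| > threshold). Bin pooling is OR; a trailing
  partial bin is dropped. Runs touching the recording edges are kept.
- End-to-end checks run at desk scale: criticality recovery uses ≥5000
  filtered avalanches (≈40k simulated), the size-exponent fit 10⁵
  avalanches capped at 3·10⁴ events, the positive control 66 regions with
  ≥2000 coupled cascades at 200 permutations, the negative control 200
  independent runs at 100 permutations, and the field-spread control 100
  surrogate datasets of 30 000 samples. These sizes give Monte-Carlo error
  comfortably inside each test's tolerance band.
- All randomness flows from `numpy.random.SeedSequence`; every generator
  and the permutation test are bit-reproducible under a fixed seed, and
  `run_pipeline` writes a manifest from which a run can be replayed
  exactly.

## Known limitations

- The branching estimator's inability to flag subcritical dynamics on
  single-seed cascades (see above) is inherent to the telescoping
  geometric mean, not an implementation artifact.
- The surrogate's sensor geometry and leadfield are generated, not
  measured; they reproduce the 1/distance correlation structure and dense
  linear mixing but no realistic head conductivity.
- Synthetic cascades have no refractoriness, no region-specific
  excitability, and no oscillatory carrier; passing recovery tests shows
  the estimators are correct under the stated model, not that the model
  captures cortical dynamics.
- The participant-level average excludes undefined TM entries; zeroing
  them instead is available as a sensitivity option and changes the edge
  ranking when avalanches are few.
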