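# Methods

This note documents the statistical procedures the package implements, the
synthetic data model behind its tests, and the numerical and design choices
that were genuinely open.

## Units of observation

The analysis unit is the *point count*: a timed survey during which every
bird species detected is recorded. Only occurrence (presence/absence) is
used; richness is the cardinality of a point count's species set, and
community composition is the binary row of the occurrence matrix whose
columns are the lexicographically sorted union of observed species.
Citizen-science collections are reduced to pseudo point counts by filtering
checklists (complete, travelling or stationary protocol, within 200 m of
the recorder inclusive, strictly under 30 minutes) and unioning the species
of every checklist that started during a recording. Membership uses the
half-open interval `[recording start, start + duration)`: a checklist
starting exactly at the recording's end is not "during" it. Recordings with
no qualifying checklist are dropped with a warning rather than kept as
richness-0 rows; an audio file with no paired observation carries no
community information and a zero would be an artefact of survey coverage,
not of the community.

## Audio front end

Audio is averaged to mono (stereo sources carry no channel semantics
relevant here) and polyphase-resampled to 16 kHz. The log-mel spectrogram
uses 25 ms periodic-Hann windows hopped by 10 ms with no padding, so
`frames = 1 + floor((n_samples − 400)/160)`; magnitudes from a 512-point
FFT pass through a 64-filter triangular mel bank on the HTK mel scale
(`mel = 2595·log10(1 + f/700)`) spanning 125–7,500 Hz, and are compressed
as `log(energy + offset)`. The offset defaults to 0.01 and is configurable;
it sets the dynamic-range floor and is recorded in the extraction metadata.
Frames are cut into non-overlapping 96-frame (0.96 s) patches — the fixed
input size of general-purpose audio embedding CNNs — and trailing
remainders are discarded, since a fixed-input-size embedder forces a
boundary choice and padding would fabricate signal.

The embedder is pluggable behind a one-method contract (deterministic
96×64 → 128 finite reals). The default is a seeded random linear projection
of the flattened patch followed by a tanh squash: it satisfies the
contract, is sensitive to any cell of the patch, and carries no learned
acoustic semantics — tests that need meaningful features use the synthetic
feature map instead. Pretrained network weights, training, and GPU paths
are out of scope.

Four soundscape indices are computed analytically per recording (not per
patch; averaging scalar indices over sub-second patches would change their
meaning): temporal entropy (Shannon entropy of the normalized Hilbert
envelope over `log n`), spectral entropy (entropy of the normalized
time-averaged magnitude spectrum over `log n_bins`), acoustic complexity
(per-frequency sum of absolute frame-to-frame magnitude differences over
that frequency's total magnitude, summed across bins), and spectrogram
cover (fraction of cells more than 3 dB above their frequency bin's
median). Silence returns 0 for every index with a warning; bins holding
less than 1e−10 of the peak bin's total energy are excluded from the
acoustic-complexity ratio, which would otherwise amplify rounding noise in
empty bins. Richer external index suites plug in through the same
extractor interface; re-implementing a full 60-index catalogue is
deliberately not attempted.

Features are averaged per point count. Where audio and surveys are not
paired 1:1, recordings are matched to a point count if they start within a
closed window centred on the point-count start time (default 60 minutes;
40/20-minute reruns are a single flag). Point counts matching no recording
are excluded from feature-based analyses with a warning.

## Univariate screening against a pooled permutation null

Every feature column is Pearson-correlated with the richness vector;
constant columns are flagged undefined, never silently zeroed. The null is
built by repeating, `S` times: independently permute each feature column
against the fixed richness vector and record |r|. The `N = S·F` pooled
values are sorted ascending; with significance level α and Bonferroni
divisor `m` the cut removes `⌈N·α/m⌉` top values and the threshold is the
value at 1-based position `N − ⌈N·α/m⌉`. A feature is significant iff |r|
*strictly* exceeds the threshold value. Threshold position is
non-decreasing in `m` and non-increasing in α.

The divisor defaults to the number of features scanned (standard
Bonferroni over the tests actually performed). A `paper_mode` preset uses
divisor 60: for the canonical pool of 100 shuffles × 188 features
(N = 18,800) that puts the cut at position 18,784
(`⌈18,800 · 0.05/60⌉ = 16`), whereas divisor 188 would give 18,795. Both
semantics of the published rank ("position" vs "value stored there") are
returned in `ThresholdResult`. Per-feature first-order polynomial fits
(richness as predictor) report slope, intercept and r² = (Pearson r)².

## Cross-dataset generalization

Each dataset is partitioned once, uniformly at random, into train/test with
`|train| = round-half-up(0.7·n)` (the rounding rule is a free choice and is
fixed here). The regressor sits behind a fit/predict contract; the default
is scikit-learn's random-forest regression with a fixed seed and library
defaults otherwise. Bit-level reproduction across library versions is not
promised — determinism per environment per seed is. Every cell of the
train × test R² matrix, including the diagonal, is evaluated on the target
dataset's held-out test split; train/test disjointness is asserted before
each fit. R² = 1 − SS_res/SS_tot is unbounded below. One split per dataset
is reused across LF-only / SSI-only / all-feature variants, so variant
comparisons are not confounded by partition noise. The sample-size check
correlates dataset n with the matrix diagonal and with row means excluding
the diagonal; constant inputs yield a flagged NaN rather than a number.

## Turnover (Mantel) analysis

Community change is Jaccard distance `1 − |A∩B|/|A∪B|` (empty vs empty
defined as 0, empty vs non-empty as 1 — a degenerate case field data never
produce but the generator can); soundscape change is Euclidean distance on
raw (unstandardized) mean feature vectors of the selected family, with an
opt-in z-score flag. Richness change |Δrichness| serves as a control
matrix.

The Mantel statistic is the Spearman correlation (average ranks for ties)
of the upper-triangle entries; the null jointly permutes rows and columns
of one matrix; the one-tailed alternative is fixed to "greater" (positive
association). The estimator `p = (1 + #{ρ_perm ≥ ρ_obs})/(1 + B)` includes
the observed statistic, so `p ≥ 1/(B+1)` and the test is never
anti-conservative; B defaults to 999. Implementation note: a symmetric
matrix's multiset of off-diagonal values is invariant under joint row/column
permutation, so pair ranks are computed once and re-indexed per draw,
making each permutation O(pairs). Per-site analyses restrict both matrices
to one site's point counts (sites with fewer than 4 skipped with a
warning) and draw seeds from a site-keyed stream so results are independent
of processing order.

The asymmetry diagnostic min-max normalizes both condensed matrices and
compares the spread of community distances among bottom-decile soundscape
pairs with the spread of soundscape distances among bottom-decile community
pairs; normalization is required because the two axes have incomparable
units (Jaccard in [0,1], Euclidean unbounded).

## Synthetic data model

The generator emulates the statistical structure the analyses assume, not
birdsong. Sites lie on a habitat axis; by default 20 sites are evenly
spaced on [0,1] ("gradient-block"; a "uniform" option draws them randomly).
Species `j` of 50 has a Gaussian niche centred at `c_j` (evenly spaced on
[0,1]) with width w = 0.15, giving occupancy
`p_js = 0.9·exp(−(h_s−c_j)²/(2w²))`; a point count at site `s` records
species `j` independently with probability `p_js · 0.8` (detection). 200
point counts per dataset visit sites round-robin, with survey times spread
over a 4-hour morning window on successive days. Expected richness is the
closed form `Σ_j p_js·d`, used as the calibration oracle; composition turns
over along the gradient, which is what gives Jaccard distances their
structure.

Features are `f_i = β·W·x_i + η·u_i·v + ε_i`: `x_i` the binary occurrence
row, `W` a (188 × n_species) standard-normal mixing map drawn from a
dataset-specific `map_seed`, `u_i` a smooth nuisance process (sinusoid in
time-of-day plus a site offset — a stand-in for non-biotic sound such as
motors or wind), `v` a fixed unit direction and `ε` iid Gaussian noise.
Defaults β = 1, σ = 0.5, η = 1. Sharing `W` across datasets makes feature
semantics transferable (cross-dataset R² comparable to within-dataset);
independent maps make cross-dataset regression fail by construction while
within-dataset regression still works — the mechanism hypothesized to
underlie non-generalizing feature–biodiversity relationships. Collections
cycle survey-effort multipliers (1.0, 0.6, 1.5, 0.8) across datasets so
sample sizes are heterogeneous, as in real multi-study campaigns; equal
sizes would also make the sample-size correlation degenerate. All
randomness flows from named seeds; observation noise draws from the
landscape seed so shared-map datasets still get independent noise.

Rendered audio assigns each present species an intermittent (25 % duty
cycle) tone train at a species-specific frequency between 500 and 7,000 Hz
plus white noise, so richer communities occupy more spectrogram bands; the
duty cycle is kept below 50 % so each frequency bin's median stays at the
noise floor and spectrogram cover grows monotonically with richness. No
attempt is made to imitate real spectro-temporal call structure.

What passing tests on this generator do show: the screening, regression and
Mantel machinery detect coupling when it exists, stay at nominal error
rates when it does not, and reproduce the qualitative
within-vs-cross-dataset contrast. What they do not show: robustness to the
things the generator omits — non-linear feature maps, abundance effects,
detection covariance between species, weather/equipment drift, or real
vocalization structure.

## Problem sizes and tolerances

The test suite runs the heavy distributional checks at reduced but
statistically adequate sizes chosen once: 500 replicates for the Mantel
type-I rate (binomial SE ≈ 0.01 against a ±0.02 band), 200 replicates for
null-uniformity (KS at 5 %) and Bonferroni-conservativeness checks, 1,000
Monte-Carlo draws against exhaustive enumeration at n = 4, 5 (within 3
binomial SE), and 25-replicate medians for the power ordering. Exact
algebraic identities (distance matrices vs double-loop oracles, the Pearson
scan vs the two-pass covariance formula) are asserted to 1e−12. The
acceptance script runs the full default-size study (4 datasets, 188
features, pooled null of 18,800) in well under a minute of CPU.

## Known limitations

* The default embedder is a contract stand-in; learned-feature analyses on
  real audio require plugging in a trained embedding model.
* Only four soundscape indices ship in-package; external suites must be
  supplied through the extractor interface.
* Occurrence-only throughout: no abundance-based dissimilarities (e.g.
  Bray–Curtis), no partial Mantel, no FDR-style alternatives to the
  Bonferroni rank cut beyond the configurable divisor.
* Timestamps are timezone-naive local times; datasets are analysed
  independently, so no cross-timezone arithmetic is attempted.
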