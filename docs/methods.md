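# Methods

`neurosound` implements, at desk scale, a complete framework for
reconstructing sounds from fMRI responses: hierarchical auditory feature
extraction, linear brain decoding of those features, a vector-quantized
spectrogram generator with autoregressive index prediction, and a
quantitative evaluation battery (identification, temporal perturbation,
selective attention, prospective power). Because no scanner data or
pretrained network weights are involved, every stage is driven by a
synthetic auditory-encoding simulator, and the package's claims are about
the *machinery* — its contracts, recoverability limits and statistical
calibration — not about any particular brain.

## Stimuli and simulated responses

Stimuli are 8-s, 22,050 Hz waveforms from four procedural recipes
(speech-like gated harmonic stacks with a wandering pitch contour and
formant emphasis; animal-like chirp trains; music-like pentatonic note
sequences; environment-like multi-peak shaped noise). Recipes only need to
produce category-distinct, mutually identifiable spectra, not realism.
Test exemplars within a category stratify the recipe's primary parameter
(register, chirp band, root note, dominant spectral peak) so that no two
exemplars collapse onto each other after spectrogram compression — the
synthetic analogue of curating recognizable test stimuli. All generators
are pure functions of their seed.

Voxel responses are noisy linear encodings of stimulus features. Two
routes exist:

- **Volume-level** (`synth.simulate_fmri`): the volume at time `t`
  (TR = 2 s) encodes the window-averaged features of the stimulus content
  in `[t − lag − 4, t − lag)` s, zero-padded outside the stimulus, plus
  i.i.d. Gaussian noise. The hemodynamic model is a pure lag with boxcar
  averaging — no HRF kernel — because samples are only ever built from
  2–8 s post-onset averages. Default lag 0 centers the three averaged
  volumes' content on the data-sample window.
- **Sample-level** (`benchmark.sample_encoded_dataset`): the voxel vector
  of each data sample directly encodes that window's feature vector.

The volume-level route is the general simulator, but it is *non-invertible
in principle*: the three overlapping 4-s windows of one stimulus share
averaged volumes, so per-window features cannot be exactly recovered from
sample averages no matter the noise level. Parameter-recovery benchmarks
that presuppose an invertible encoding therefore use the sample-level
route; the volume route's own exact-recoverability contract (features from
single volumes by least squares) is tested at the volume level.

Attention trials superimpose two RMS-equalized cross-category stimuli
(24 pairs from two exemplars per category, each pair under both attention
conditions = 48 trials); simulated responses encode the attended
component's features plus a leak (default 0.3) of the unattended one.

## Data samples

Each 8-s stimulus is cut into three overlapping 4-s windows (onsets 0, 2,
4 s, half-open). A window's fMRI sample is the mean of the three volumes
acquired 2–8 s after *window* onset (+2, +4, +6 s at TR = 2). Training
presentations stay single-trial; test and attention responses average
their eight repetitions. The full-scale bookkeeping follows: 1,200
stimuli × 4 repetitions × 3 windows = 14,400 training samples, 50 × 3 =
150 test samples, 24 × 2 × 3 = 144 attention samples, all exposed without
simulation through `sampling.design_manifest`.

## Feature hierarchy

The large pretrained sound-recognition CNN is replaced by a small 1-D
convolutional hierarchy over log-mel spectrograms (80 bands, 125–7,600 Hz,
hop 256; a 4-s window gives 345 frames center-cropped to 336). Mel bands
enter as channels; five conv levels (default channels 16/32/64/64/64,
kernel 3, ReLU, stride-2 mean pooling between levels) yield the temporal
geometry 336 → 168 → 84 → 42 → 21, and a fully connected category readout
has no temporal axis. Feature maps flatten to the `units × temporal`
layout used everywhere. The net can be left at its seeded random weights
(the untrained-network control) or fitted to category classification by
its built-in Adam trainer. Conditioning inputs to the generator are
segment-mean pooled to 21 temporal columns; fully connected features
broadcast to 21 identical columns.

Other stimulus-side representations: a spectrotemporal modulation
filterbank (128 log-spaced channels 180–7,040 Hz, half-wave rectification,
compression 0.3, directional 2-D filters at 6 spectral rates 0.5–4
cyc/oct × 10 temporal rates 1–30 Hz × 2 directions, integrated to 40
frames → 128×40×6×20; the 100-ms integration window is the only value
consistent with 40 frames over 4 s); scalar acoustic descriptors (mean F0
from a YIN-style tracker, frame 2,048, hop 256, range 65–2,093 Hz,
threshold 0.15 with ≥ 5 voiced frames required; median spectral centroid;
mean autocorrelation HNR — undefined estimates carry `None`, never 0);
moment-matched texture surrogates (colored Gaussian frames with the
original's band means, variances and inter-band correlations imposed
exactly, all temporal autocorrelation destroyed — a stand-in for full
summary-statistics texture synthesis); and segment-shuffled spectrograms
(frame-domain, equal segments, remainder frames kept in place, permutation
redrawn if it reproduces the original).

## Decoding

Voxels are selected by the maximum absolute Pearson correlation with any
target unit over training samples (500 for the pooled auditory cortex, 200
per ROI in the full-scale configuration; a mean-|r| variant is a config
switch), then voxels and targets are z-scored by training statistics and a
per-unit ridge regression is solved in closed form with λ = 100.
Predictions are denormalized and, for n-trial-averaged inputs, then
rescaled by the literal factor n (a √n variant is selectable). Applied
after denormalization the rescale is a single global scalar, so no
correlation-based evaluation can depend on it — a property the tests
verify. Inside the reconstruction pipeline the same factor serves its
stated purpose — aligning the decoded-feature distribution with the
true-feature distribution the generator was trained on — so the translator
is conditioned on decoded features whose deviations about the training
mean are restored by the factor (mean + n·(ŷ − mean)); the noiseless
benchmark (where averaging changes nothing) marks its test samples as
single-trial. Leave-category-out fits simply filter the
training samples and record the exclusion.

## Generator

- **Codebook**: k-means (k = 256, fixed seed) over all 16×16 patches of
  the training spectrograms; an 80×336 spectrogram encodes to a 5×21 grid
  of nearest-code indices (ties to the lowest index) and decodes by
  pasting code patches. Duplicate centers are re-seeded from the farthest
  patches. The adversarial/perceptual training of the original
  spectrogram codec is out of scope; the downstream contract (256 codes,
  5×21 grid, decodable patches) is preserved.
- **Translator**: the transformer is replaced by one 256-way softmax
  classifier per raster position (spectral-major within each temporal
  step) over the conditioning feature columns t and t−1 plus one-hot codes
  of the previous five indices. Each position's L2-regularized multinomial
  logistic model is solved exactly in the span of its training rows
  (representer parameterization, L-BFGS, λ = 1e-5 primary / 1e-6 in the
  benchmark, maxiter 200–300); conditioning features are z-scored with
  corpus statistics stored in the artifact — without this the kernel is
  too badly scaled to optimize. Generation is raster-order autoregressive,
  argmax (deterministic) or seeded sampling.
- **Vocoder**: mel inversion by projected-gradient non-negative least
  squares, Griffin-Lim phase recovery (60 iterations), re-centering of the
  336-frame segment in the 4-s span, and scale-down-only peak limiting
  (so silence stays silent).
- **Alternative pipelines**: brain-to-codebook decodes the continuous
  5×21 patch-space representation from voxels and quantizes each decoded
  patch to its nearest code (the continuous-latent reading of an ambiguous
  target; decoding one-hot indices directly is the noted alternative).
  Pixel optimization matches hierarchy features at every layer by Adam on
  the spectrogram pixels from seeded noise, with step-size annealing and a
  leaky surrogate slope (0.1) on inactive ReLUs in the input-gradient pass
  only — exact-ReLU backprop stalls on dead-unit plateaus at ~96% loss
  reduction; with the surrogate the loss (always measured on the exact
  forward pass) falls ≥ 99%.

## Evaluation

Profile correlation is the per-unit Pearson (or Spearman) correlation
between true and decoded values across test samples; constant units are
excluded and counted. Pairwise identification uses each other test item
once as a lure (49 pairs for a 50-item pool); a pair is correct when the
probe is more similar to the true candidate than to the lure (Pearson for
high-dimensional features, negative Euclidean distance for scalar
descriptors); exact ties score 0.5 (unbiased under exchangeability);
undefined scalar descriptors exclude the sample. Window accuracies average
into one point per 8-s block (50 points in the full-scale design).
Confidence intervals are t-based (a bootstrap variant is provided).
Attention trials pool their three window-level scores by majority vote
(sum > 1.5) into 48 binaries tested against 0.5 with an exact one-sided
binomial test; window scores compare distribution-matched decoded features
(the same calibration as the generator conditioning) with the attended and
unattended stimulus features, since in a two-candidate margin the common
mean pattern would otherwise swamp the attended-stream signal. Hierarchy-based identification uses an *independent*
evaluator net (its own seed; optionally untrained) at six stages; stage 0
denotes raw spectrogram pixels.

Power analytics: the smallest n for a one-sample one-sided t-test
(noncentral-t) at d = 0.5, α = 0.05, power 0.80 is 27; the smallest n for
an exact one-sided binomial test of 0.7 vs 0.5 at the same level and power
is 37 (exact tail sums, no normal approximation). One-sided tests at power
0.80 are the only conventions consistent with both numbers. Both are
cross-checked by Monte-Carlo power simulation in `scripts/acceptance.py`.

## Benchmarks and problem sizes

Two frozen configurations in `neurosound.benchmark`:

- **recovery** — narrow hierarchy (channels 4/6/8/8/8 → 168 feature
  units), 800 voxels with 500 selected, 1,000 training stimuli × 4
  repetitions × 3 windows, noiseless sample-level encoding. Invertible
  ridge recovery at λ = 100 needs units ≪ selected voxels and ample
  samples (shrinkage scales like λ/n along each principal component);
  in this regime decoded profile correlation exceeds 0.95 and block
  identification saturates at 100%, while a zero-weight (pure noise)
  control stays inside the exact binomial 95% band around chance.
- **generator** — the mini-benchmark shape (120 training stimuli, 20 test
  stimuli: 8 speech + 4 per other category, 400 voxels with 200 selected)
  with the default 64-channel hierarchy and the full codebook + translator
  stack. The translator corpus is 240 training windows plus the test
  windows' audio: generator training uses sound alone, never voxel data,
  and held-in audio is what the best-case recovery check presupposes.
  Default noise is calibrated once so decoded block identification lands
  mid-way in the 70–90% band (measured 84% at noise 12).

Evaluation-level choices grounded in measurements on these benchmarks:
the recovery check is scored at evaluator stage 4 (the stage most aligned
with perceptual judgments), because codec quantization alone caps
*pixel-level* held-out identification just below 100% — two broadband
noise exemplars lose their distinguishing fine structure; and the
shuffled-candidate battery is scored at stage 6 (the position-invariant
category stage), because with near-stationary synthetic stimuli and
reconstructions that preserve global temporal placement, position-locked
pixel correlation reverses the expected coarse-vs-fine direction, whereas
the position-invariant stage isolates exactly the short-term-structure
effect the battery is meant to probe.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline's contracts hold: features
recoverable in principle are recovered, identification calibrates to
chance under pure noise, the generator reproduces what its inputs
determine, temporal-perturbation directions follow from what the
reconstructions carry, and the statistics match their closed forms. They
do *not* show that real cortical responses encode these features, how
strong real fMRI noise correlations are (noise here is i.i.d.), or how the
method behaves under realistic hemodynamics, attention lapses, or
category structure richer than four procedural recipes.

## Known limitations

- The volume-level simulator's window mixing bounds sample-level decoding
  below perfection even noiselessly; this is a property of the overlapping
  window design itself.
- The per-position translator has no cross-position weight sharing, so it
  needs a few hundred corpus windows to generalize and its artifacts are
  large relative to a shared-weight model.
- Griffin-Lim phase and NNLS mel inversion limit audio round-trip fidelity
  to roughly r ≈ 0.95–0.98 in log-mel terms.
- The texture surrogate matches second-order time-averaged statistics
  only, not the full auditory-texture statistic set (envelope modulation
  power, cross-band envelope correlations).
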