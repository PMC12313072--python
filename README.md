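# neurosound

Sound reconstruction from (simulated) fMRI responses: hierarchical
auditory feature decoding, a vector-quantized spectrogram generator, and
the full identification / temporal-perturbation / selective-attention
evaluation battery — all runnable on one CPU with no scanner data and no
pretrained weights, driven by a built-in synthetic auditory-encoding
simulator.

## Who this is for

Researchers building or stress-testing fMRI-to-sound decoding pipelines
who need every stage — stimulus design, data-sample construction, linear
feature decoding, discrete audio generation, and the statistics — as
testable, seedable components with known recovery limits.

## The method

An 8-s stimulus is cut into three overlapping 4-s windows; each window's
fMRI sample is the mean of the three volumes acquired 2–8 s after window
onset (TR = 2 s). A hierarchy of convolutional features `f_l(x)` is
extracted from the window's 80×336 log-mel spectrogram, and per-unit
L2-regularized linear decoders predict those features from multi-voxel
patterns:

    ŷ = argmin_w ||Z w − y||² + λ ||w||²,   λ = 100,

on z-scored voxels (correlation-selected: 500 for the whole auditory
cortex) and z-scored targets. Decoded feature maps (units × 21 temporal
columns) condition an autoregressive translator that predicts a 5×21 grid
of indices into a 256-entry codebook of 16×16 spectrogram patches
(256-way softmax per raster position); the codebook decoder tiles the
grid back into a spectrogram and Griffin-Lim inverts it to audio.
Evaluation is pairwise identification — a reconstruction identifies its
stimulus when it is more similar (Pearson; Euclidean for scalar acoustic
descriptors) to the true candidate than to a lure, every other test item
serving as a lure once; window accuracies average into one point per 8-s
block, and attention trials pool three windows by majority vote into 48
binaries tested against chance with an exact binomial test.

## Worked example

```bash
python examples/02_decode_features.py
```

prints (seed 1, the packaged mini-benchmark: 120 training stimuli, 20
test stimuli, 400 voxels, calibrated noise):

```
mean profile correlation: 0.644
block identification: 0.788 (95% CI 0.685-0.891, n=20)
```

Profile correlation is the per-feature-unit correlation between decoded
and true values across the 60 test samples; block identification is the
fraction of pairwise comparisons won by the decoded features, averaged
over the three windows of each of the 20 test stimuli (chance 0.5). The
other examples build reconstructions (`03`), probe which temporal scales
they preserve (`04`), and run the attention battery and power analytics
(`05`).

A thin CLI drives the same stages artifact-by-artifact:

```bash
neurosound simulate --config run.yaml
neurosound train-decoder --config run.yaml
neurosound train-generator --config run.yaml
neurosound reconstruct --config run.yaml
neurosound evaluate --config run.yaml
neurosound power
```

## Layout

- `src/neurosound/` — `synth` (stimuli + encoding simulator), `sampling`
  (windows, volume/trial averaging, design bookkeeping), `features`
  (mel / hierarchy / modulation / acoustic / perturbations), `decoding`
  (ridge decoders), `generator` (codebook, translator, vocoder,
  pipelines), `evaluation` (identification + statistics + power),
  `benchmark` (frozen end-to-end configurations), `workflow`/`cli`/`io`.
- `docs/methods.md` — the model, its assumptions, parameter choices and
  limits.
- `examples/` — one short narrative script per capability.
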