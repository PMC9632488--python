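# Methods

## Pipeline

A labeled cohort of multichannel EEG records is processed in four stages:

1. **Clipping / augmentation (MSC).** Each record is cut into fixed-length
   windows of `X` samples on a non-overlapping grid; the tail shorter than
   `X` is discarded. Augmentation factor `C` repeats the grid at `C` origins:
   part `k` (1-based) is shifted by `(k−1) · round_half_up(X/C)` samples.
   Windows never straddle record boundaries (segmentation is per record),
   and within one part consecutive windows are disjoint with stride exactly
   `X`. All segment indices are 1-based inclusive.
2. **Rendering (MCF).** Each segment becomes one `H×W×3` uint8 image:
   channels are drawn as polylines in stacked horizontal bands
   (`⌊H/n_channels⌋` rows each, remainder to the bottom band), top-to-bottom
   in channel order, dark lines on a light background replicated over the
   three RGB planes.
3. **Split.** Subject-level by default (whole subjects assigned to train or
   test, stratified by class) or "sample-level": a seeded stratified shuffle
   of individual images. Sample-level splitting mirrors the protocol used
   with overlapping-window augmentation in the source study, but lets
   near-duplicate windows of one subject appear on both sides; accuracy
   under it should be read as within-subject, not generalization,
   performance. Default train fraction 0.9.
4. **Train / evaluate.** Minibatch gradient descent on softmax
   cross-entropy; evaluation reports accuracy, a k×k confusion matrix
   (rows = true class) and optionally a 2-D t-SNE embedding of
   penultimate-layer features.

## Classifier

`vgg16-paper` is the classic VGG-16 stack: thirteen 3×3 stride-1
same-padded convolutions in five blocks (64,64 | 128,128 | 256,256,256 |
512,512,512 | 512,512,512), a 2×2 max-pool after each block, then fully
connected layers 2048 → 2048 → k and a softmax. The 2048-wide FC layers
(rather than the canonical 4096) match the published variant this package
implements. `tiny` keeps the same family at desk scale: three
conv+ReLU+pool blocks of 8/16/32 channels on 64×64 inputs, then FC(64) and
FC(k); 137k parameters, a few ms per image on one CPU core.

The layers, softmax cross-entropy and optimizers are implemented directly
in NumPy (im2col convolutions; the input gradient of a stride-1 same conv
is computed as a same conv of the output gradient with the flipped,
channel-transposed kernel). Gradients are verified against central
differences in the test suite, and the conv/pool forward passes against
`scipy.signal.correlate2d` and direct enumeration.

Training defaults follow the published protocol: 20 epochs, learning rate
1e-4, Adam (the source names only the learning rate; Adam is the community
default for VGG-scale fine-tuning, SGD is available via config), batch size
32, He-normal initialization from a fixed seed, no pretrained weights. The
tiny network in the synthetic experiments uses learning rate 1e-3: a 350×
smaller from-scratch model tolerates and needs the larger step to converge
within the same 20 epochs. Cross-entropy clamps probabilities at 1e-12
inside the log; the loss carries the conventional negative sign (a
positive-sign "loss" would be maximized, not minimized, by correct
predictions).

## Numerical conventions

- `round_half_up(x) = ⌊x + 0.5⌋`; with X=2100, C=8 the per-part shift is
  round_half_up(262.5) = 263 and part offsets are exact multiples of it
  (0, 263, 526, 789, …). The offset is `(k−1) · round_half_up(X/C)`, not
  `round_half_up((k−1)·X/C)` — the two differ at C=8, k=4 (789 vs 788), and
  the worked reference constructions fix the former.
- Rasterization: row 0 is the top of the image; larger signal values map to
  smaller row indices. Sample `i` of `X` maps to column
  `round_half_up(i·(W−1)/(X−1))`; values are min-max scaled per channel per
  segment (amplitude-invariant; a "global" per-segment mode preserves
  relative channel amplitudes), a constant channel draws at the band
  midline, and consecutive points are joined by integer Bresenham lines —
  no anti-aliasing, fonts or axes, so output is bit-identical across
  platforms. A plotting toolkit was deliberately not used for this step:
  its output depends on DPI and library version.
- CSV records are written with `%.17g` floats and read with the round-trip
  parser, so write→read is bit-exact. EDF is read-only (an acquisition
  format); 16-bit quantization bounds the representation error by
  `(phys_max − phys_min)/65535`.

## Synthetic data

Each channel of a synthetic record is
`alpha + pink + white`: a sum of 5 sinusoids with frequencies uniform in
the alpha band (default 8–12 Hz) and random phases, scaled so the total
alpha RMS equals the per-class `alpha_amplitude`; 1/f^β colored noise
(default β = 1.0, RMS 1 µV); and white noise (default SD 1 µV). Defaults:
250 Hz sampling, 3 channels named Fp1/Fpz/Fp2, and a strong monotone
alpha contrast across classes (RMS 3.0 µV down to 0.5 µV), mimicking an
alpha-power difference between healthy controls and depressed subjects
(2-class) or a severity gradient (4-class). Per-record seeds derive from
`SeedSequence(master_seed, class, index)`, so a cohort is a pure function
of its config.

The generator produces class-separable, EEG-plausible waveforms — no more.
It has no artifacts (eye blinks, muscle), no cross-channel correlation, no
non-stationarity, and no physiological forward model; the source study also
gives no quantitative healthy-vs-depressed spectral contrast to match, so
the effect size here is a free parameter set deliberately high. Passing
tests therefore demonstrate that the pipeline machinery works and can
recover a known spectral contrast, not that real depression EEG is
classifiable at any particular accuracy.

## Desk-scale experiment design

The published experiments used full-length clinical records, 2100-sample
windows and 224×224 images on GPU hardware; their headline accuracies are
not reproducible here and are not targeted. The synthetic experiments keep
every pipeline stage but shrink the problem so the full suite runs on one
CPU in minutes:

- **Window vs image resolution.** At 64 px width a 2100-sample window puts
  ~33 samples in each pixel column and a 10 Hz rhythm completes ~84 cycles
  across the image, so both classes rasterize to near-solid bands
  (verified: chance accuracy). Synthetic runs therefore use X = 256
  (~1 s at 250 Hz, ~4 samples per column), which the 64×64 rendering
  resolves; X = 2100 remains the default `ClipConfig` and is exercised by
  the reference worked examples.
- **Separable-cohort run:** 8 records per class × 12 s, AU-N, subject-level
  split at 0.8 (leaving 2 test subjects per class), tiny net, 20 epochs,
  lr 1e-3, five seeds.
- **Data-starved augmentation run:** 6 records per class × 3 s — two AU-N
  windows per record — AU-N vs AU-8, same net and split, five seeds;
  the comparison is directional (seed-averaged AU-8 accuracy ≥ AU-N), the
  regime where translation augmentation is expected to matter.

## Known limitations

- The NumPy network trains small models only; there is no GPU path, no
  batch-norm/dropout, and `vgg16-paper` is practical to *construct* and
  inspect (70.3M parameters) but not to train at full scale here.
- t-SNE uses perplexity min(30, n/4) with PCA init and a fixed seed;
  embeddings are reproducible per scikit-learn version, not across versions.
- Sample-level splitting inflates accuracy in the presence of overlapping
  augmented windows (by design, for protocol comparison); subject-level
  results are the ones to report.
- The EDF reader trusts header scaling and applies no filtering,
  re-referencing or artifact handling (none is applied upstream either).
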