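# Methods

This note documents the models and procedures implemented in
`splinesound`, the choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Signal model and feature extraction

Records are mono waveforms in [-1, 1]. Long recordings are cut into
contiguous, non-overlapping fixed-length records (default 5 s; long
records, e.g. 200 s, can be configured per class for propeller-like
sources). Overlapped segmentation is deliberately not used: it inflates
apparent dataset size with correlated records.

Three time-frequency views are computed per record:

* **STFT** — Hanning window, `n_fft = 256`, 75 % overlap (hop 64).
  Frames start at multiples of the hop with no padding, so the frame
  count is `1 + floor((N - n_fft)/hop)`. The grid holds magnitudes
  (not power): image intensity is meant to represent signal strength.
* **Mel** — 1024-sample window, 64 triangular, area-normalized bands
  on mel(f) = 2595·log10(1 + f/700) between 0 Hz and Nyquist, applied
  to the power spectrum. The hop convention follows the STFT stage
  (75 % overlap) since no separate value is specified anywhere.
  The base-10 logarithm is used; 2595 is the standard base-10 constant.
* **Haar CWT scalogram** — the continuous transform is discretized as
  a finite sum with unit sample spacing and 1/sqrt(scale)
  normalization; the stored quantity is the squared coefficient
  magnitude. Scales are logarithmically spaced even integers in
  [2, window_len] (even, so the discrete Haar kernel has exactly zero
  mean and constant signals map to an identically zero scalogram);
  the default window is 512 samples with 128 scale steps, and columns
  are evaluated every window_len/4 samples.

### Cubic-spline spectrogram interpolation (STFT-CSI)

The 1-D natural cubic spline through uniformly spaced knots is computed
from the closed-form per-interval coefficients, with knot second
derivatives solving the tridiagonal C2-continuity system and natural
end conditions M0 = Mn = 0 (the standard closure; only interior
conditions are implied by the derivation). Non-uniform knot spacing is
rejected rather than silently generalized, because the closed forms
assume a single spacing q.

2-D spectrogram upsampling applies the 1-D spline separably: frequency
axis first, then time (the order is fixed for bit-reproducibility;
exact spline surfaces on uniform grids make the passes commute).
Default upsampling factor is 2 per axis, configurable. Negative spline
overshoot is clipped to zero after interpolation, preserving the
non-negativity of magnitude grids. Piecewise-constant and linear
interpolation are available under the same grid interface as baselines.

On a spectrum whose structure is resolved by the knot grid (e.g. the
two-sine worked example, Hann-windowed so mainlobes span several
knots), the L2 reconstruction error orders CSI <= LI <= PCI; the test
suite pins this ordering. When knots undersample the spectral peaks
no interpolant can recover them and the ordering is not guaranteed —
spline overshoot can then exceed the linear interpolant's error.

### RGB stacking

Each grid is mapped to decibels relative to its own maximum
(20·log10, floored at -80 dB), min-max normalized per image to [0, 1],
bilinearly resized to a square (default 128 px, matching the encoder's
128×128×3 input; 224 px is available for the plain-CNN configuration),
and oriented with low frequencies at the bottom row. Per-image
normalization deliberately discards absolute recording gain — class
identity must come from spectro-temporal structure, not level. The
channel assignment is fixed: R = mel, G = STFT-CSI, B = scalogram.

## The SNN-VAE

The encoder is a stack of re-parameterizable convolution stages
(default widths 16/32/64/128, one block per stage, stride 2 on the
first block of each stage, ReLU, no pooling). During training each
block sums three parallel branches — 3×3 conv, 1×1 conv and (where
shapes permit) identity — each followed by batch normalization. For
inference the branches are algebraically fused into a single 3×3
convolution with bias (1×1 kernels zero-padded to 3×3, identity as a
Dirac kernel, batch-norm statistics folded into weights); the fused
output equals the multi-branch output for every input up to float
rounding, and the test suite checks this to 1e-4.

A dense head yields the latent mean and log-variance (log-variance
clamped to [-10, 10] for numerical stability; variance is its
exponential, hence always positive). The decoder mirrors the encoder
with nearest-neighbour upsampling + 3×3 convolutions and a sigmoid
output; the architecture of the decoder is the package's own choice —
only the encoder side is constrained by the model description.

Losses (all terms non-negative):

* triplet: hinge on squared Euclidean embedding distances with margin
  alpha, summed over mined triples;
* reconstruction: mean squared error over pixels, each batch image
  being its own reconstruction target (the weighting of branch
  reconstructions is not specified anywhere; per-image MSE averaged
  over the batch covers all three Siamese branches symmetrically);
* KL: closed-form divergence to the standard normal, averaged per
  batch, weighted by beta.

Semi-hard mining: for each anchor a random same-class positive is
drawn; the negative is the closest other-class sample inside the
window d(A,P) < d(A,N) < d(A,P) + alpha, falling back to the hardest
negative when the window is empty. A batch without any anchor/positive
pair raises a mining error before training starts.

The embedding used for distances and classification is the latent mean
(deterministic at inference; whether embeddings are taken pre- or
post-sampling is unspecified, and the mean is the standard choice).
Classification is nearest class centroid (per-class mean of training
embeddings) by Euclidean distance with a softmin similarity score;
ties break by class-name order. A centroid rule is a gap-filling
choice: the decision rule over embeddings is not otherwise specified.

Training uses Adam (lr 1e-3 by default; no optimizer is named in the
source description). Library defaults are alpha = 0.2, beta = 1.0.

## Synthetic data

The generator emulates the class structure of passive-sonar corpora:

* `fm_whistle` — repeated up-down frequency sweeps inside a band
  (dolphin-whistle-like), ~0.35 s per call;
* `pulse_train` — Gaussian-windowed clicks at the band centre repeated
  at the call rate (odontocete-click-like);
* `moan` — a long narrowband tone with slow vibrato (baleen-moan-like);
* `broadband_am` — band-limited noise amplitude-modulated at a
  blade-rate frequency (propeller-like).

Calls are band-pass filtered (zero-phase brickwall) so out-of-band
power is negligible, scaled to the requested peak amplitude, and
embedded in 1/f-shaped Gaussian noise at the requested SNR (10 dB by
default). Everything is a pure function of its arguments and a seed.

What this does **not** emulate: multipath propagation, Doppler,
overlapping simultaneous sources, recording-chain variation, realistic
species vocal production, or the spectral statistics of any real
corpus. Passing tests therefore demonstrate that the pipeline
recovers class structure it is mathematically able to represent — not
field performance on real recordings.

## Desk-scale experiment sizes

The recovery experiments in the test suite use 4 classes × 10 records
of 2 s at 16 kHz/4 kHz, 32×32 feature images, a 3-stage encoder
(widths 8/16/32), latent dimension 32, and 30 epochs — sizes chosen so
a full run takes seconds on one CPU. At this scale the library-default
margin and KL weight leave the latent clusters only marginally
separated, so the `TrainConfig.desk_scale()` preset uses alpha = 1.0,
beta = 0.1, lr = 3e-3 and full-batch updates (stable batch-norm
statistics); with it, held-out accuracy is >= 0.92 across seeds on
separable classes while an identical-class negative control stays near
the 25 % chance level. The full-scale preset (`TrainConfig.paper_scale()`,
batch 256, 200 epochs, 128 px, latent 128) mirrors the printed
configuration but needs a real corpus and far more compute to be
meaningful.

Recovery checks evaluate on the combined validation + test split
(30 % of the data) and the negative control on a separate 60-record
manifest, purely to reduce the granularity of small-sample accuracy
estimates; thresholds are unchanged by this choice.

## Numerical notes and limitations

* All array math is float64; WAV output is PCM-16 (round-trip error
  bounded by one quantization step).
* Out-of-range interpolation queries raise (no extrapolation).
* An all-zero spectrogram maps to an all-zero image channel (the
  min = max degenerate case is defined, not an error).
* Undefined per-class precision (class never predicted) is reported
  as 0 with a flag rather than NaN, keeping reports aggregable.
* The stratified splitter uses largest-remainder allocation per class,
  so realized proportions are within one record of 70/20/10.
* K-fold CV and the 70/20/10 split are independent utilities; how they
  would be combined on a real corpus is a protocol choice left to the
  user.
* MFCC cepstral features, DEMON/LOFAR transforms and Lofargram
  pipelines for propellers are out of scope; propeller-like audio goes
  through the same three-transform pipeline as biotic classes.
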