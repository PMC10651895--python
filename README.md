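# splinesound

Passive-sonar classification of marine-mammal (and propeller) acoustic
signals from spline-interpolated, multi-transform spectrogram images,
using a Siamese triplet-loss variational auto-encoder (SNN-VAE).

The package is aimed at bioacousticians and underwater-signal-processing
researchers who want a small, fully inspectable, CPU-only implementation
of this two-stage pipeline, testable end to end on synthetic data —
no external corpus required.

## The method

**Stage 1 — features.** Each fixed-length mono record (e.g. 5 s of a
dolphin whistle) is transformed three ways:

* **STFT-CSI** — a short-time Fourier magnitude spectrogram (Hanning
  window, 256-point FFT, 75 % overlap) upsampled by separable natural
  **cubic-spline interpolation** along the frequency and time axes.
  For uniform knots $(x_i, y_i)$ with spacing $q$ and knot second
  derivatives $M_i$ solving
  $M_{i-1} + 4M_i + M_{i+1} = 6(y_{i-1} - 2y_i + y_{i+1})/q^2$
  (natural ends $M_0 = M_n = 0$), each interval carries the cubic
  $f_i(x) = A_i(x-x_i)^3 + B_i(x-x_i)^2 + C_i(x-x_i) + D_i$ with
  $A_i = (M_{i+1}-M_i)/6q$, $B_i = M_i/2$,
  $C_i = (y_{i+1}-y_i)/q - (M_{i+1}+2M_i)\,q/6$, $D_i = y_i$.
  Piecewise-constant (PCI) and linear (LI) interpolation are provided
  as baselines and are measurably worse on resolved spectra.
* **Mel spectrogram** — 1024-sample window, 64 bands on the scale
  $\mathrm{mel}(f) = 2595\log_{10}(1 + f/700)$.
* **Haar CWT scalogram** — squared continuous-wavelet coefficients
  $\mathrm{CWT}(\lambda,\tau) = \sum_n x[n]\,\Psi((n-\tau)/\lambda)/\sqrt{\lambda}$
  with the Haar mother wavelet ($+1$ on $[0,\tfrac12)$, $-1$ on
  $[\tfrac12,1)$, $0$ elsewhere) over log-spaced scales.

The three grids are converted to per-image-normalized dB images and
stacked as (R, G, B) = (mel, STFT-CSI, scalogram).

**Stage 2 — model.** A weight-shared convolutional encoder built from
re-parameterizable blocks (parallel 3×3 + 1×1 + identity branches with
batch normalization during training, fused into a single 3×3
convolution for inference) maps each RGB image to a diagonal Gaussian
$(\mathbb{E}(z), \mathbb{V}(z))$ over a 128-dimensional latent space.
Training draws $z = \mathbb{E}(z) + \varepsilon \odot \sqrt{\mathbb{V}(z)}$
(re-parameterization trick), decodes it back to an image, and minimizes

$$\mathcal{L} = \mathcal{L}(A,P,N) + \mathcal{L}_\text{reconstruct}
  + \beta\,\mathrm{KL}(z, N(0, I_d))$$

where $\mathcal{L}(A,P,N) = \sum_i \max(\lVert f(A_i)-f(P_i)\rVert^2 -
\lVert f(A_i)-f(N_i)\rVert^2 + \alpha,\ 0)$ is the hinge triplet loss
over semi-hard mined anchor/positive/negative triples, and
$\mathrm{KL} = \tfrac12\sum_i (\mathbb{V}(z_i) - \log\mathbb{V}(z_i) - 1
+ \mathbb{E}(z_i)^2)$. The embedding $f(\cdot)$ is the latent mean;
records are classified by nearest class centroid in embedding space.

A seeded synthetic-data module generates class-separable datasets
(narrowband FM whistles, click trains, low-frequency moans, and
propeller-like amplitude-modulated broadband noise in coloured ocean
noise), so every stage is testable offline.

## Worked example

```python
from splinesound import SiameseVAEClassifier, DatasetManifest, EncoderConfig
from splinesound.pipeline import demo_config
from splinesound.synthetic import default_class_specs, generate_dataset
from splinesound.train_eval import SplitConfig, TrainConfig

specs = default_class_specs(sample_rate=4000, snr_db=10.0, n_classes=4)
manifest = generate_dataset(specs, n_per_class=10, duration_s=2.0,
                            sample_rate=4000, out_dir="runs/data", seed=0)
clf = SiameseVAEClassifier(
    manifest=manifest,
    features=demo_config().featurize_config(),
    encoder=EncoderConfig(image_size=32, latent_dim=32, stage_widths=(8, 16, 32)),
    split=SplitConfig(seed=0),
    training=TrainConfig.desk_scale(seed=0),
)
print(clf.fit().summary())
```

prints (about 5 s on one CPU):

```
Siamese triplet-loss VAE classification results
=======================================================
classes:            clicks, moan, whistle_hi, whistle_lo
records (tr/va/te): 28/8/4
latent dim:         32
image size:         32
epochs:             30
final loss total:   0.8358 (triplet 0.0000, recon 0.0227, kl 8.1314)
final val accuracy: 0.875
test accuracy:      1.000
-------------------------------------------------------
per-class precision / recall:
  clicks           1.000 / 1.000
  moan             1.000 / 1.000
  whistle_hi       1.000 / 1.000
  whistle_lo       1.000 / 1.000
```

The loss breakdown is the three objective terms; `total = triplet +
reconstruction + beta*kl` with the desk-scale preset's `beta = 0.1`.
Test accuracy 1.000 means all four held-out test records were assigned
to the correct synthetic class by nearest-centroid classification.

The same run is available from the shell:

```sh
splinesound demo --out-dir runs/demo --seed 0
```

and the individual stages as `splinesound generate | segment |
transform | interp | featurize | split | fuse`.

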