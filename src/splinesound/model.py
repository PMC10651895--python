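"""The Siamese triplet-loss variational auto-encoder (SNN-VAE).

A weight-shared convolutional encoder built from re-parameterizable
blocks maps a stacked RGB spectrogram to a diagonal Gaussian over a
latent space: mean E(z) and variance V(z).  A latent sample
z = E(z) + eps * sqrt(V(z)) (re-parameterization trick) is decoded back
to an image.  Training minimizes

    L = L(A, P, N) + L_reconstruct + beta * KL(z, N(0, I_d))

where L(A, P, N) is the hinge triplet loss
sum_i max(||f(A_i)-f(P_i)||^2 - ||f(A_i)-f(N_i)||^2 + alpha, 0) over
semi-hard mined triplets, L_reconstruct is the pixel MSE and KL is the
closed-form divergence to the standard normal

    KL = 1/2 sum_i (V(z_i) - log V(z_i) - 1 + E(z_i)^2).

The embedding f(.) used for distances and classification is the latent
mean, which is deterministic at inference.  Classification is nearest
class centroid in embedding space with a softmin similarity score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import RGBSpectrogram
from .nn import Adam, BatchNorm2d, Conv2d, Dense, Flatten, NearestUpsample, RepVGGBlock, ReLU, Sequential, Sigmoid

__all__ = [
    "EncoderConfig",
    "LatentDistribution",
    "TripletBatch",
    "LossBreakdown",
    "MiningError",
    "SNNVAE",
    "sample_latent",
    "kl_divergence",
    "reconstruction_loss",
    "triplet_loss",
    "total_loss",
    "mine_semi_hard",
    "fuse_branches",
    "classify",
]

_LOGVAR_CLAMP = 10.0


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the shared encoder.

    ``stage_widths`` gives the channel count of each stride-2 stage
    (one re-parameterizable block per stage by default); ``latent_dim``
    is the embedding length, 128 by default.
    """

    image_size: int = 128
    latent_dim: int = 128
    stage_widths: tuple[int, ...] = (16, 32, 64, 128)
    blocks_per_stage: int = 1
    in_channels: int = 3
    mode: str = "train_multibranch"

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if self.image_size % (2 ** len(self.stage_widths)) != 0:
            raise ValueError("image_size must be divisible by 2^n_stages")
        if self.mode not in ("train_multibranch", "inference_fused"):
            raise ValueError("unknown mode")

    @property
    def bottleneck_hw(self) -> int:
        return self.image_size // (2 ** len(self.stage_widths))


@dataclass(frozen=True)
class LatentDistribution:
    """Encoder output: diagonal Gaussian with mean E(z), variance V(z)."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=np.float64)
        var = np.asarray(self.variance, dtype=np.float64)
        if mean.shape != var.shape:
            raise ValueError("mean and variance shapes differ")
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(var))):
            raise ValueError("latent parameters must be finite")
        if np.any(var <= 0):
            raise ValueError("variance must be strictly positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance", var)


@dataclass(frozen=True)
class TripletBatch:
    """Mined (anchor, positive, negative) index triples over a batch."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    labels: np.ndarray  # anchor labels

    def __len__(self) -> int:
        return self.anchors.size


@dataclass(frozen=True)
class LossBreakdown:
    triplet: float
    reconstruction: float
    kl: float
    beta: float = 1.0
    alpha: float = 0.2

    @property
    def total(self) -> float:
        return self.triplet + self.reconstruction + self.beta * self.kl


class MiningError(RuntimeError):
    """Raised when a batch has no valid anchor/positive pair."""


def sample_latent(
    dist: LatentDistribution,
    eps: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Re-parameterization trick: z = E(z) + eps * sqrt(V(z))."""
    if eps is None:
        eps = np.random.default_rng(seed).standard_normal(dist.mean.shape)
    eps = np.asarray(eps, dtype=np.float64)
    if eps.shape != dist.mean.shape:
        raise ValueError("eps shape must match the latent mean")
    return dist.mean + eps * np.sqrt(dist.variance)


def kl_divergence(dist: LatentDistribution) -> float:
    """Closed-form KL(N(E, V) || N(0, I)), summed over latent dims.

    For batched distributions the per-sample KLs are averaged.
    """
    per_dim = dist.variance - np.log(dist.variance) - 1.0 + dist.mean**2
    if per_dim.ndim == 1:
        return float(0.5 * per_dim.sum())
    return float(0.5 * per_dim.sum(axis=-1).mean())


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over all pixels and channels."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((x - x_hat) ** 2))


def triplet_loss(
    fA: np.ndarray, fP: np.ndarray, fN: np.ndarray, alpha: float = 0.2
) -> float:
    """Hinge triplet loss summed over the batch.

    max(||f(A)-f(P)||^2 - ||f(A)-f(N)||^2 + alpha, 0) per triplet.
    """
    fA, fP, fN = (np.atleast_2d(np.asarray(v, dtype=np.float64)) for v in (fA, fP, fN))
    if not (fA.shape == fP.shape == fN.shape):
        raise ValueError("embedding shapes differ")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    d_ap = np.sum((fA - fP) ** 2, axis=1)
    d_an = np.sum((fA - fN) ** 2, axis=1)
    return float(np.maximum(d_ap - d_an + alpha, 0.0).sum())


def total_loss(
    triplet: float, reconstruction: float, kl: float, beta: float = 1.0, alpha: float = 0.2
) -> LossBreakdown:
    """Combine the three terms: total = triplet + reconstruction + beta*KL."""
    return LossBreakdown(
        triplet=float(triplet), reconstruction=float(reconstruction), kl=float(kl),
        beta=beta, alpha=alpha,
    )


def mine_semi_hard(
    embeddings: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.2,
    seed: int | None = None,
) -> TripletBatch:
    """Mine one (A, P, N) triple per eligible anchor.

    The positive is a random same-class sample; the negative is
    semi-hard — the closest other-class sample with
    d(A, P) < d(A, N) < d(A, P) + alpha — falling back to the hardest
    (closest) negative when the window is empty.  Distances are squared
    Euclidean on the embeddings.  Deterministic given the seed.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    n = embeddings.shape[0]
    sq = np.sum(embeddings**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * embeddings @ embeddings.T, 0.0)
    rng = np.random.default_rng(seed)
    anchors, positives, negatives, tri_labels = [], [], [], []
    for i in range(n):
        same = np.where((labels == labels[i]) & (np.arange(n) != i))[0]
        diff = np.where(labels != labels[i])[0]
        if same.size == 0 or diff.size == 0:
            continue
        p = int(rng.choice(same))
        d_ap = d2[i, p]
        d_an = d2[i, diff]
        window = diff[(d_an > d_ap) & (d_an < d_ap + alpha)]
        if window.size:
            neg = int(window[np.argmin(d2[i, window])])
        else:
            neg = int(diff[np.argmin(d_an)])
        anchors.append(i)
        positives.append(p)
        negatives.append(neg)
        tri_labels.append(labels[i])
    if not anchors:
        raise MiningError("no valid anchor/positive pair in this batch")
    return TripletBatch(
        anchors=np.array(anchors),
        positives=np.array(positives),
        negatives=np.array(negatives),
        labels=np.array(tri_labels),
    )


def fuse_branches(block: RepVGGBlock) -> RepVGGBlock:
    """Fold a multi-branch block into one 3x3 convolution (idempotent)."""
    return block.fuse()


def classify(
    embedding: np.ndarray, class_centroids: dict[str, np.ndarray]
) -> tuple[str, float]:
    """Nearest-centroid label with a softmin similarity score in [0, 1].

    Ties break deterministically by class-name order.
    """
    if not class_centroids:
        raise RuntimeError("no fitted class centroids")
    names = sorted(class_centroids)
    cents = np.stack([class_centroids[name] for name in names])
    d = np.linalg.norm(cents - np.asarray(embedding, dtype=np.float64)[None, :], axis=1)
    scores = np.exp(-(d - d.min()))
    scores = scores / scores.sum()
    idx = int(np.argmin(d))
    return names[idx], float(scores[idx])


def _as_batch(image: RGBSpectrogram | np.ndarray) -> np.ndarray:
    """Accept an RGBSpectrogram, HxWx3 array or NCHW batch; return NCHW."""
    if isinstance(image, RGBSpectrogram):
        arr = image.array
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:  # HWC -> 1CHW
        arr = arr.transpose(2, 0, 1)[None]
    elif arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError("expected an image or an NCHW batch")
    return arr


class SNNVAE:
    """Shared encoder + variational heads + decoder.

    One instance is the shared sub-network of every Siamese branch
    (weights are literally shared, not copied).
    """

    def __init__(self, cfg: EncoderConfig = EncoderConfig(), seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        blocks: list = []
        prev = cfg.in_channels
        for w in cfg.stage_widths:
            blocks.append(RepVGGBlock(prev, w, stride=2, rng=rng))
            for _ in range(cfg.blocks_per_stage - 1):
                blocks.append(RepVGGBlock(w, w, stride=1, rng=rng))
            prev = w
        hw = cfg.bottleneck_hw
        feat = cfg.stage_widths[-1] * hw * hw
        self.backbone = Sequential(*blocks, Flatten())
        self.head = Dense(feat, 2 * cfg.latent_dim, rng=rng)
        wlast = cfg.stage_widths[-1]
        self.dec_head = Dense(cfg.latent_dim, feat, rng=rng)
        dec_layers: list = []
        widths = list(cfg.stage_widths[::-1])  # e.g. 128, 64, 32, 16
        prev = wlast
        for w in widths[1:]:
            dec_layers += [NearestUpsample(2), Conv2d(prev, w, 3, 1, 1, rng=rng),
                           BatchNorm2d(w), ReLU()]
            prev = w
        dec_layers += [NearestUpsample(2), Conv2d(prev, cfg.in_channels, 3, 1, 1, rng=rng), Sigmoid()]
        self.dec_body = Sequential(*dec_layers)
        if cfg.mode == "inference_fused":
            self.fuse()

    # ------------------------------------------------------------ encoder
    def encode(
        self, image: RGBSpectrogram | np.ndarray, train: bool = False
    ) -> LatentDistribution:
        """Map an image (or batch) to its latent Gaussian."""
        x = _as_batch(image)
        if x.shape[2] != self.cfg.image_size or x.shape[3] != self.cfg.image_size:
            raise ValueError(
                f"expected {self.cfg.image_size}x{self.cfg.image_size} input, got {x.shape[2]}x{x.shape[3]}"
            )
        h = self.head.forward(self.backbone.forward(x, train), train)
        d = self.cfg.latent_dim
        mean = h[:, :d]
        logvar = np.clip(h[:, d:], -_LOGVAR_CLAMP, _LOGVAR_CLAMP)
        self._logvar_mask = (h[:, d:] > -_LOGVAR_CLAMP) & (h[:, d:] < _LOGVAR_CLAMP)
        if mean.shape[0] == 1 and (
            isinstance(image, RGBSpectrogram) or np.asarray(image).ndim == 3
        ):
            return LatentDistribution(mean=mean[0], variance=np.exp(logvar[0]))
        return LatentDistribution(mean=mean, variance=np.exp(logvar))

    def encode_backward(self, dmean: np.ndarray, dlogvar: np.ndarray) -> None:
        """Backpropagate gradients w.r.t. mean and log-variance."""
        dh = np.concatenate([dmean, dlogvar * self._logvar_mask], axis=1)
        self.backbone.backward(self.head.backward(dh))

    def embed(self, image: RGBSpectrogram | np.ndarray) -> np.ndarray:
        """Embedding f(.) = latent mean E(z); deterministic at inference."""
        return self.encode(image, train=False).mean

    # ------------------------------------------------------------ decoder
    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Decode latent vector(s) to image(s) in [0, 1], NCHW."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError("latent length mismatch")
        hw = self.cfg.bottleneck_hw
        h = self.dec_head.forward(z, train)
        h = h.reshape(z.shape[0], self.cfg.stage_widths[-1], hw, hw)
        self._dec_shape = h.shape
        return self.dec_body.forward(h, train)

    def decode_backward(self, dxhat: np.ndarray) -> np.ndarray:
        """Backpropagate through the decoder; returns gradient w.r.t. z."""
        dh = self.dec_body.backward(dxhat)
        return self.dec_head.backward(dh.reshape(dh.shape[0], -1))

    # ------------------------------------------------------------- misc
    def modules(self) -> list:
        return [self.backbone, self.head, self.dec_head, self.dec_body]

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.modules(), lr=lr)

    def fuse(self) -> "SNNVAE":
        """Fuse every re-parameterizable block for single-branch inference."""
        for layer in self.backbone.layers:
            if isinstance(layer, RepVGGBlock):
                layer.fuse()
        return self

    # -------------------------------------------------------- checkpoints
    def save(self, path: str | Path) -> None:
        """Portable checkpoint: named parameter arrays + config snapshot."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for mi, mod in enumerate(self.modules()):
            for name, leaf in mod.named_layers():
                for pname, p in leaf.params.items():
                    arrays[f"m{mi}.{name}.{pname}"] = p
                if isinstance(leaf, BatchNorm2d):
                    arrays[f"m{mi}.{name}.running_mean"] = leaf.running_mean
                    arrays[f"m{mi}.{name}.running_var"] = leaf.running_var
        cfg = {
            "image_size": self.cfg.image_size,
            "latent_dim": self.cfg.latent_dim,
            "stage_widths": list(self.cfg.stage_widths),
            "blocks_per_stage": self.cfg.blocks_per_stage,
            "in_channels": self.cfg.in_channels,
            "mode": self.cfg.mode,
        }
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SNNVAE":
        data = np.load(Path(path), allow_pickle=False)
        cfg_dict = json.loads(str(data["__config__"]))
        cfg = EncoderConfig(
            image_size=cfg_dict["image_size"],
            latent_dim=cfg_dict["latent_dim"],
            stage_widths=tuple(cfg_dict["stage_widths"]),
            blocks_per_stage=cfg_dict["blocks_per_stage"],
            in_channels=cfg_dict["in_channels"],
            mode=cfg_dict["mode"],
        )
        model = cls(cfg)
        for mi, mod in enumerate(model.modules()):
            for name, leaf in mod.named_layers():
                for pname in leaf.params:
                    leaf.params[pname][...] = data[f"m{mi}.{name}.{pname}"]
                if isinstance(leaf, BatchNorm2d):
                    leaf.running_mean[...] = data[f"m{mi}.{name}.running_mean"]
                    leaf.running_var[...] = data[f"m{mi}.{name}.running_var"]
        return model
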