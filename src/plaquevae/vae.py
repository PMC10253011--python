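"""Two-dimensional-latent convolutional variational autoencoder.

The model compresses 64x64 pseudo-color vessel cross-sections into a 2-D
latent space.  The encoder is five strided convolutional layers of strictly
increasing depth followed by a flat fully connected layer feeding two heads
of the latent dimension — the posterior mean and log-variance of a diagonal
Gaussian.  The decoder mirrors the encoder with transposed convolutions and
a sigmoid output on the [0, 1] intensity scale.  The objective is the usual
evidence lower bound: per-pixel mean squared reconstruction error plus a
weighted Kullback-Leibler divergence of the posterior from the standard
normal prior,

    L = MSE(x, x_hat) + kl_weight * 0.5 * sum(exp(lv) + mu^2 - 1 - lv).

Usage follows the model/results idiom::

    model = TissueVAE(images, VaeConfig.desk_scale(seed=0))
    results = model.fit()
    z = results.encode(images)        # (n, 2) posterior means
    print(results.summary())

Deterministic embedding: :meth:`VAEResults.encode` returns the posterior
mean (no sampling), so downstream classification is reproducible.  All
randomness — weight initialization, epoch shuffling, reparameterization
noise — derives from ``config.seed``; identical seed and data give an
identical loss trace up to platform floating-point differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .nn import Adam, Conv2D, ConvTranspose2D, Dense, Layer, ReLU, Sigmoid

__all__ = [
    "VaeConfig",
    "LatentDistribution",
    "LatentPoint",
    "TissueVAE",
    "VAEResults",
    "build_vae",
    "reparameterize",
    "vae_loss",
    "train",
    "encode",
]


@dataclass(frozen=True)
class VaeConfig:
    """Hyperparameters of the convolutional VAE.

    Defaults reproduce the reference training recipe (500 epochs, batch
    128, Adam at 0.0005, 2-D latent, five convolutional stages of
    increasing depth).  :meth:`desk_scale` returns a preset sized for
    CPU-only runs on synthetic phantoms.
    """

    image_side: int = 64
    channels: int = 3
    encoder_depths: tuple[int, ...] = (32, 64, 128, 256, 512)
    kernel_size: int = 3
    stride: int = 2
    latent_dim: int = 2
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 5e-4
    kl_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "encoder_depths", tuple(self.encoder_depths))
        if len(self.encoder_depths) != 5:
            raise ValueError("exactly 5 encoder convolutional stages are required")
        if any(b >= a for a, b in zip(self.encoder_depths[1:], self.encoder_depths)):
            raise ValueError("encoder_depths must be strictly increasing")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kl_weight <= 0:
            raise ValueError("kl_weight must be positive")
        self.spatial_chain()  # validates side/stride compatibility

    def spatial_chain(self) -> list[int]:
        """Spatial sizes after each encoder stage, e.g. 64 -> [32,16,8,4,2]."""
        side = self.image_side
        chain = []
        for _ in self.encoder_depths:
            if side % self.stride != 0:
                raise ValueError(
                    f"stride {self.stride} does not evenly reduce image_side "
                    f"{self.image_side} across 5 stages (chain so far: "
                    f"{[self.image_side] + chain}, next size {side} not divisible)"
                )
            side //= self.stride
            if side < 1:
                raise ValueError(
                    f"image_side {self.image_side} collapses below 1 pixel: "
                    f"chain {[self.image_side] + chain + [side]}"
                )
            chain.append(side)
        return chain

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 80, **kw) -> "VaeConfig":
        """CPU-sized preset for phantom experiments.

        Narrower depths and far fewer epochs than the full recipe; the
        Adam learning rate is unchanged.  The batch size drops to 32 so a
        few-hundred-image cohort still yields enough optimizer steps per
        epoch.  ``kl_weight`` is set to 1/(side^2 * channels), which makes
        the per-pixel MSE term equivalent to the sum-form Gaussian ELBO at
        unit beta.
        """
        side = kw.pop("image_side", 64)
        channels = kw.pop("channels", 3)
        return cls(
            image_side=side,
            channels=channels,
            encoder_depths=kw.pop("encoder_depths", (12, 24, 36, 48, 64)),
            epochs=epochs,
            batch_size=kw.pop("batch_size", 32),
            kl_weight=kw.pop("kl_weight", 1.0 / (side * side * channels)),
            seed=seed,
            **kw,
        )


@dataclass
class LatentDistribution:
    """Diagonal Gaussian posterior: mean and log-variance, one row per image."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.log_variance = np.atleast_2d(
            np.asarray(self.log_variance, dtype=np.float64)
        )
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance must have equal shape")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.log_variance).all()):
            raise ValueError("latent distribution parameters must be finite")


@dataclass(frozen=True)
class LatentPoint:
    """The 2-D latent representation (x, y) of one image."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("latent coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


def reparameterize(dist: LatentDistribution, noise: np.ndarray) -> np.ndarray:
    """Sample z = mean + exp(0.5 * log_variance) * noise.

    ``noise`` holds standard-normal draws of the same shape as the mean;
    zero noise returns the mean exactly.
    """
    noise = np.asarray(noise, dtype=np.float64)
    return dist.mean + np.exp(0.5 * dist.log_variance) * noise


def kl_divergence(dist: LatentDistribution) -> np.ndarray:
    """Per-image KL(q || N(0, I)) = 0.5 * sum(exp(lv) + mu^2 - 1 - lv)."""
    return 0.5 * np.sum(
        np.exp(dist.log_variance) + dist.mean**2 - 1.0 - dist.log_variance,
        axis=-1,
    )


def vae_loss(
    original: np.ndarray,
    reconstruction: np.ndarray,
    dist: LatentDistribution,
    kl_weight: float = 1.0,
) -> tuple[float, float, float]:
    """Total, reconstruction and KL terms for one image or batch.

    Images may be uint8 on [0, 255] or float on [0, 1]; the reconstruction
    term is the mean squared error on the [0, 1] scale.  For batches the
    terms are averaged over images.  Returns ``(total, recon, kl)``.
    """
    x = np.asarray(original, dtype=np.float64)
    xhat = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {xhat.shape}")
    if np.issubdtype(np.asarray(original).dtype, np.integer) or x.max() > 1.0:
        x = x / 255.0
    if np.issubdtype(np.asarray(reconstruction).dtype, np.integer) or xhat.max() > 1.0:
        xhat = xhat / 255.0
    recon = float(np.mean((x - xhat) ** 2))
    kl = float(np.mean(kl_divergence(dist)))
    return recon + kl_weight * kl, recon, kl


class _Network:
    """Encoder/decoder layer stacks with shared parameter bookkeeping."""

    def __init__(self, config: VaeConfig, rng: np.random.Generator) -> None:
        cfg = config
        chain = cfg.spatial_chain()
        k, s = cfg.kernel_size, cfg.stride
        self.config = cfg
        self.flat_hw = chain[-1]
        self.flat_size = chain[-1] * chain[-1] * cfg.encoder_depths[-1]

        self.enc_layers: list[Layer] = []
        c_prev = cfg.channels
        for depth in cfg.encoder_depths:
            self.enc_layers += [Conv2D(c_prev, depth, k, s, rng), ReLU()]
            c_prev = depth
        self.enc_dense = Dense(self.flat_size, self.flat_size, rng)
        self.enc_act = ReLU()
        # mean head at Xavier scale (carries the encoder's gradient path);
        # small log-variance head keeps the initial posterior near unit width
        self.mu_head = Dense(
            self.flat_size, cfg.latent_dim, rng, w_scale=np.sqrt(1.0 / self.flat_size)
        )
        self.lv_head = Dense(self.flat_size, cfg.latent_dim, rng, w_scale=0.01)

        self.dec_dense = Dense(cfg.latent_dim, self.flat_size, rng)
        self.dec_act = ReLU()
        self.dec_layers: list[Layer] = []
        sizes_up = [self.flat_hw * s**i for i in range(1, 6)]  # e.g. 4..64
        depths_rev = list(cfg.encoder_depths[::-1][1:]) + [cfg.channels]
        c_prev = cfg.encoder_depths[-1]
        for depth, size in zip(depths_rev, sizes_up):
            self.dec_layers.append(
                ConvTranspose2D(c_prev, depth, k, s, (size, size), rng)
            )
            self.dec_layers.append(
                Sigmoid() if depth == cfg.channels else ReLU()
            )
            c_prev = depth

    @property
    def layers(self) -> list[Layer]:
        return (
            self.enc_layers
            + [self.enc_dense, self.enc_act, self.mu_head, self.lv_head]
            + [self.dec_dense, self.dec_act]
            + self.dec_layers
        )

    # --- forward/backward -------------------------------------------------
    def encode_dist(self, x01: np.ndarray) -> LatentDistribution:
        h = x01
        for layer in self.enc_layers:
            h = layer.forward(h)
        h = h.reshape(h.shape[0], -1)
        h = self.enc_act.forward(self.enc_dense.forward(h))
        mu = self.mu_head.forward(h)
        lv = np.clip(self.lv_head.forward(h), -15.0, 15.0)
        return LatentDistribution(mu, lv)

    def decode01(self, z: np.ndarray) -> np.ndarray:
        h = self.dec_act.forward(self.dec_dense.forward(z))
        h = h.reshape(
            z.shape[0], self.flat_hw, self.flat_hw, self.config.encoder_depths[-1]
        )
        for layer in self.dec_layers:
            h = layer.forward(h)
        return h

    def backward(
        self,
        dxhat: np.ndarray,
        dmu_extra: np.ndarray,
        dlv_extra: np.ndarray,
        eps: np.ndarray,
        dist: LatentDistribution,
    ) -> None:
        """Backpropagate loss gradients through decoder, sampling and encoder."""
        g = dxhat
        for layer in reversed(self.dec_layers):
            g = layer.backward(g)
        g = g.reshape(g.shape[0], -1)
        dz = self.dec_dense.backward(self.dec_act.backward(g))
        # z = mu + exp(lv/2) * eps
        dmu = dz + dmu_extra
        dlv = dz * eps * 0.5 * np.exp(0.5 * dist.log_variance) + dlv_extra
        gh = self.mu_head.backward(dmu) + self.lv_head.backward(dlv)
        gh = self.enc_dense.backward(self.enc_act.backward(gh))
        g = gh.reshape(
            gh.shape[0], self.flat_hw, self.flat_hw, self.config.encoder_depths[-1]
        )
        for layer in reversed(self.enc_layers):
            g = layer.backward(g)

    # --- serialization ----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


def _as_image_array(images, config: VaeConfig) -> np.ndarray:
    arr = np.stack([np.asarray(im) for im in images]) if isinstance(
        images, (list, tuple)
    ) else np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    want = (config.image_side, config.image_side, config.channels)
    if arr.ndim != 4 or arr.shape[1:] != want:
        raise ValueError(
            f"expected images of shape (n,) + {want}, got {arr.shape}"
        )
    if arr.dtype == np.uint8 or arr.max() > 1.0:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


class TissueVAE:
    """Convolutional VAE model over a stack of pseudo-color slices.

    Parameters
    ----------
    images
        (n, side, side, 3) array or list of (side, side, 3) slices; uint8
        on [0, 255] or float on [0, 1].
    config
        :class:`VaeConfig`; defaults to the full-scale recipe.
    """

    def __init__(self, images, config: VaeConfig | None = None) -> None:
        self.config = config or VaeConfig()
        self.images01 = _as_image_array(images, self.config)
        if self.images01.shape[0] == 0:
            raise ValueError("cannot train on an empty image stack")

    @classmethod
    def from_stacks(cls, stacks, config: VaeConfig | None = None) -> "TissueVAE":
        """Build from one or more labelled/lesion stacks (``.slices`` lists)."""
        if hasattr(stacks, "slices"):
            stacks = [stacks]
        slices = [sl for st in stacks for sl in st.slices]
        return cls(slices, config)

    def fit(
        self, callback: Callable[[int, float, float], None] | None = None
    ) -> "VAEResults":
        """Train with Adam for ``config.epochs`` epochs; returns results.

        Per-epoch mean reconstruction and KL terms are recorded in the loss
        trace.  ``callback(epoch, recon, kl)`` is invoked after each epoch
        when given.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _Network(cfg, rng)
        opt = Adam(net.layers, cfg.learning_rate)
        n = self.images01.shape[0]
        trace = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            recon_sum = kl_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = self.images01[idx]
                B = x.shape[0]
                dist = net.encode_dist(x)
                eps = rng.standard_normal(dist.mean.shape)
                z = reparameterize(dist, eps)
                xhat = net.decode01(z)

                recon = float(np.mean((xhat - x) ** 2))
                kl = float(np.mean(kl_divergence(dist)))
                recon_sum += recon * B
                kl_sum += kl * B

                dxhat = 2.0 * (xhat - x) / (x.size)
                dmu = cfg.kl_weight * dist.mean / B
                dlv = cfg.kl_weight * 0.5 * (np.exp(dist.log_variance) - 1.0) / B
                net.backward(dxhat, dmu, dlv, eps, dist)
                opt.step()
            recon_ep, kl_ep = recon_sum / n, kl_sum / n
            trace.append(
                {
                    "epoch": epoch + 1,
                    "recon": recon_ep,
                    "kl": kl_ep,
                    "total": recon_ep + cfg.kl_weight * kl_ep,
                }
            )
            if callback is not None:
                callback(epoch + 1, recon_ep, kl_ep)
        return VAEResults(
            config=cfg,
            weights=net.get_weights(),
            loss_trace=pd.DataFrame(trace).set_index("epoch"),
            n_images=n,
        )


@dataclass
class VAEResults:
    """Fitted VAE: parameters, loss trace and encode/decode machinery."""

    config: VaeConfig
    weights: list[np.ndarray]
    loss_trace: pd.DataFrame
    n_images: int

    def __post_init__(self) -> None:
        self._net = _Network(self.config, np.random.default_rng(0))
        self._net.set_weights(self.weights)

    # --- embedding --------------------------------------------------------
    def encode(self, images) -> np.ndarray:
        """Posterior-mean embedding, (n, latent_dim); deterministic."""
        x01 = _as_image_array(images, self.config)
        out = []
        for start in range(0, x01.shape[0], 256):
            out.append(self._net.encode_dist(x01[start : start + 256]).mean)
        return np.vstack(out)

    def encode_point(self, image) -> LatentPoint:
        """Embed one image as a :class:`LatentPoint` (2-D latent only)."""
        if self.config.latent_dim != 2:
            raise ValueError("encode_point requires latent_dim == 2")
        z = self.encode(image)[0]
        return LatentPoint(float(z[0]), float(z[1]))

    def encode_dist(self, images) -> LatentDistribution:
        """Full posterior (mean, log-variance) for each image."""
        x01 = _as_image_array(images, self.config)
        return self._net.encode_dist(x01)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent codes to uint8 images on [0, 255]."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent codes must have {self.config.latent_dim} components"
            )
        x01 = self._net.decode01(z)
        return np.clip(np.rint(x01 * 255.0), 0, 255).astype(np.uint8)

    def reconstruct(self, images) -> np.ndarray:
        """Encode (posterior mean) then decode; uint8 output."""
        return self.decode(self.encode(images))

    def reconstruction_mse(self, images) -> float:
        """Mean squared reconstruction error on the [0, 1] scale."""
        x01 = _as_image_array(images, self.config)
        xhat01 = self._net.decode01(self._net.encode_dist(x01).mean)
        return float(np.mean((x01 - xhat01) ** 2))

    # --- reporting --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        first, last = self.loss_trace.iloc[0], self.loss_trace.iloc[-1]
        lines = [
            "Convolutional VAE results",
            "=" * 54,
            f"{'images':<28}{self.n_images}",
            f"{'image size':<28}{cfg.image_side}x{cfg.image_side}x{cfg.channels}",
            f"{'encoder depths':<28}{cfg.encoder_depths}",
            f"{'latent dimension':<28}{cfg.latent_dim}",
            f"{'epochs':<28}{len(self.loss_trace)}",
            f"{'batch size':<28}{cfg.batch_size}",
            f"{'learning rate (Adam)':<28}{cfg.learning_rate}",
            f"{'KL weight':<28}{cfg.kl_weight:.6g}",
            f"{'seed':<28}{cfg.seed}",
            "-" * 54,
            f"{'first-epoch recon MSE':<28}{first['recon']:.6f}",
            f"{'final-epoch recon MSE':<28}{last['recon']:.6f}",
            f"{'final-epoch KL':<28}{last['kl']:.6f}",
            f"{'final-epoch total loss':<28}{last['total']:.6f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    # --- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Save weights (.npz) plus a JSON config/trace echo alongside."""
        path = Path(path)
        np.savez(
            path,
            **{f"w{i}": w for i, w in enumerate(self.weights)},
        )
        echo = {
            "config": {**asdict(self.config)},
            "n_images": self.n_images,
            "loss_trace": self.loss_trace.reset_index().to_dict(orient="list"),
        }
        path.with_suffix(".json").write_text(json.dumps(echo, indent=2))
        return path if path.suffix == ".npz" else path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "VAEResults":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        data = np.load(path)
        weights = [data[f"w{i}"] for i in range(len(data.files))]
        echo = json.loads(path.with_suffix(".json").read_text())
        cfg = VaeConfig(**echo["config"])
        trace = pd.DataFrame(echo["loss_trace"]).set_index("epoch")
        return cls(cfg, weights, trace, echo["n_images"])


# --- thin functional surface ---------------------------------------------

def build_vae(config: VaeConfig) -> _Network:
    """Build an untrained encoder/decoder network from ``config``."""
    return _Network(config, np.random.default_rng(config.seed))


def train(stack, config: VaeConfig) -> VAEResults:
    """Train a VAE on a list/array of pseudo-color images."""
    return TissueVAE(stack, config).fit()


def encode(results: VAEResults, image) -> np.ndarray:
    """Deterministic latent embedding(s) of ``image`` under a fitted model."""
    return results.encode(image)
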