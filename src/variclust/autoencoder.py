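"""Dense symmetric autoencoder for compressing gene-set vectors.

The network has six dense encoding layers funnelling the G-dimensional input
down to a 64-component latent code, mirrored by six decoding layers, and is
trained to reconstruct its input under mean-squared error.  It is trained on
the phenotype rows of the phenotype x gene matrix only; the frozen encoder is
then applied to per-individual gene-set vectors.  Hidden units are rectified
linear, the latent and output layers are linear, and optimisation is Adam on
shuffled mini-batches.  All randomness (initialisation, shuffling) flows from
a single mandatory seed, so training is bit-reproducible on one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import GeneEmbedding, PhenotypeMatrix, build_individual_matrix
from .variant_io import IndividualGeneSet

__all__ = [
    "AutoencoderConfig",
    "EncoderModel",
    "LatentMatrix",
    "geometric_layer_widths",
    "train_autoencoder",
    "encode_individuals",
]


def geometric_layer_widths(input_dim: int, latent_dim: int, n_layers: int) -> list[int]:
    """Strictly decreasing encoder widths on a geometric ramp, ending at latent_dim."""
    if latent_dim >= input_dim:
        raise ValueError("latent_dim must be smaller than input_dim")
    ratio = (latent_dim / input_dim) ** (1.0 / n_layers)
    widths = [int(round(input_dim * ratio**k)) for k in range(1, n_layers + 1)]
    widths[-1] = latent_dim
    # enforce strict decrease; geometric rounding can collide at small dims
    for i in range(len(widths) - 2, -1, -1):
        if widths[i] <= widths[i + 1]:
            widths[i] = widths[i + 1] + 1
    if widths[0] >= input_dim:
        raise ValueError(
            f"cannot fit {n_layers} strictly decreasing layers between "
            f"{input_dim} and {latent_dim}"
        )
    return widths


@dataclass
class AutoencoderConfig:
    """Architecture and training hyperparameters.

    ``layer_widths`` are the encoder widths (decoder is mirrored); when absent
    they are derived by geometric interpolation from ``input_dim`` to
    ``latent_dim`` over ``n_layers_each_side`` layers.
    """

    input_dim: int
    seed: int
    latent_dim: int = 64
    n_layers_each_side: int = 6
    layer_widths: list[int] | None = None
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    scale_inputs: bool = False  # optional min-max scaling to [0, 1]

    def resolved_widths(self) -> list[int]:
        if self.layer_widths is not None:
            w = list(self.layer_widths)
            if len(w) != self.n_layers_each_side:
                raise ValueError("layer_widths length must equal n_layers_each_side")
            if w[-1] != self.latent_dim:
                raise ValueError("last layer width must equal latent_dim")
            if any(a <= b for a, b in zip(w, w[1:])) or self.input_dim <= w[0]:
                raise ValueError("layer widths must be strictly decreasing from input_dim")
            return w
        return geometric_layer_widths(self.input_dim, self.latent_dim, self.n_layers_each_side)

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "seed": self.seed,
            "latent_dim": self.latent_dim,
            "n_layers_each_side": self.n_layers_each_side,
            "layer_widths": self.layer_widths,
            "activation": self.activation,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "scale_inputs": self.scale_inputs,
        }


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass
class EncoderModel:
    """A trained autoencoder with its frozen encoder half.

    ``weights``/``biases`` cover the full network (encoder then decoder);
    ``n_encoder_layers`` marks where the latent code is read off.  Hidden
    layers are ReLU; the latent layer and the reconstruction output are
    linear.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_encoder_layers: int
    config: AutoencoderConfig
    history: list[float] = field(default_factory=list)
    input_offset: np.ndarray | None = None  # min-max scaling, when enabled
    input_scale: np.ndarray | None = None

    @property
    def latent_dim(self) -> int:
        return self.weights[self.n_encoder_layers - 1].shape[1]

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {x.shape[1]} does not match model input {self.input_dim}"
            )
        if self.input_offset is not None:
            x = (x - self.input_offset) * self.input_scale
        return x

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Map row vectors to latent codes (linear latent layer)."""
        h = self._prepare(x)
        for layer in range(self.n_encoder_layers):
            h = h @ self.weights[layer] + self.biases[layer]
            if layer < self.n_encoder_layers - 1:
                h = _relu(h)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        h = self._prepare(x)
        last = len(self.weights) - 1
        for layer in range(len(self.weights)):
            h = h @ self.weights[layer] + self.biases[layer]
            if layer not in (self.n_encoder_layers - 1, last):
                h = _relu(h)
        if self.input_offset is not None:
            h = h / self.input_scale + self.input_offset
        return h

    def save(self, path: str | Path) -> None:
        """Persist weights + config + seed in one self-describing .npz archive."""
        arrays: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        if self.input_offset is not None:
            arrays["input_offset"] = self.input_offset
            arrays["input_scale"] = self.input_scale
        meta = {
            "config": self.config.to_dict(),
            "n_encoder_layers": self.n_encoder_layers,
            "n_layers": len(self.weights),
            "history": self.history,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        # np.savez stamps current time into the zip entries; write the archive
        # with a fixed date so identical models are byte-identical on disk
        import io
        import zipfile

        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            for name in sorted(arrays):
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
                info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta_json"]).decode("utf-8"))
            n = meta["n_layers"]
            weights = [npz[f"W{i}"] for i in range(n)]
            biases = [npz[f"b{i}"] for i in range(n)]
            offset = npz["input_offset"] if "input_offset" in npz else None
            scale = npz["input_scale"] if "input_scale" in npz else None
        return cls(
            weights=weights,
            biases=biases,
            n_encoder_layers=meta["n_encoder_layers"],
            config=AutoencoderConfig(**meta["config"]),
            history=list(meta["history"]),
            input_offset=offset,
            input_scale=scale,
        )


@dataclass
class LatentMatrix:
    """Latent codes for an ordered list of individuals."""

    individual_ids: list[str]
    values: np.ndarray  # n x latent_dim

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _init_network(
    dims: list[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """He-style initialisation scaled for rectifier units."""
    weights, biases = [], []
    for fan_in, fan_out in zip(dims, dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_autoencoder(
    matrix: PhenotypeMatrix | np.ndarray, cfg: AutoencoderConfig
) -> EncoderModel:
    """Train the autoencoder on phenotype rows (non-flagged only).

    Raises on fewer than two usable rows and on a non-finite loss (with the
    epoch index).  The returned model records the per-epoch training MSE; the
    final epoch's loss never exceeds the initial one for a converged run, and
    identical (data, config, seed) reproduce the model bit-for-bit.
    """
    if isinstance(matrix, PhenotypeMatrix):
        data = matrix.dense_rows(include_flagged=False)
    else:
        data = np.asarray(matrix, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("autoencoder training needs at least 2 usable rows")
    if data.shape[1] != cfg.input_dim:
        raise ValueError(
            f"data has {data.shape[1]} columns but cfg.input_dim is {cfg.input_dim}"
        )

    offset = scale = None
    if cfg.scale_inputs:
        lo, hi = data.min(axis=0), data.max(axis=0)
        offset = lo
        scale = np.where(hi > lo, 1.0 / np.where(hi > lo, hi - lo, 1.0), 1.0)
        data = (data - offset) * scale

    enc_widths = cfg.resolved_widths()
    dims = [cfg.input_dim] + enc_widths + enc_widths[-2::-1] + [cfg.input_dim]
    n_encoder_layers = len(enc_widths)
    linear_layers = {n_encoder_layers - 1, len(dims) - 2}  # latent + output

    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_network(dims, rng)

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate
    t = 0

    n = data.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_sse = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            x = data[idx]
            # forward
            acts = [x]
            pre: list[np.ndarray] = []
            h = x
            for layer in range(len(weights)):
                z = h @ weights[layer] + biases[layer]
                pre.append(z)
                h = z if layer in linear_layers else _relu(z)
                acts.append(h)
            err = h - x
            epoch_sse += float(np.sum(err * err))
            # backward
            delta = (2.0 / (x.shape[0] * x.shape[1])) * err
            for layer in range(len(weights) - 1, -1, -1):
                if layer not in linear_layers:
                    delta = delta * (pre[layer] > 0)
                g_w = acts[layer].T @ delta
                g_b = delta.sum(axis=0)
                delta = delta @ weights[layer].T
                t_layer = t + 1
                m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * g_w
                v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * g_w * g_w
                m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * g_b
                v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * g_b * g_b
                mhat_w = m_w[layer] / (1 - beta1**t_layer)
                vhat_w = v_w[layer] / (1 - beta2**t_layer)
                mhat_b = m_b[layer] / (1 - beta1**t_layer)
                vhat_b = v_b[layer] / (1 - beta2**t_layer)
                weights[layer] -= lr * mhat_w / (np.sqrt(vhat_w) + eps)
                biases[layer] -= lr * mhat_b / (np.sqrt(vhat_b) + eps)
            t += 1
        epoch_mse = epoch_sse / (n * data.shape[1])
        if not np.isfinite(epoch_mse):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        history.append(epoch_mse)

    return EncoderModel(
        weights=weights,
        biases=biases,
        n_encoder_layers=n_encoder_layers,
        config=cfg,
        history=history,
        input_offset=offset,
        input_scale=scale,
    )


def encode_individuals(
    sets: Sequence[IndividualGeneSet], emb: GeneEmbedding, model: EncoderModel
) -> LatentMatrix:
    """Encode each individual's gene-set vector into the latent space.

    Row order follows ``sets``; identical gene sets yield identical rows and
    an empty set encodes the image of the zero vector.
    """
    if model.input_dim != emb.n_genes:
        raise ValueError(
            f"model input dim {model.input_dim} != embedding vocabulary {emb.n_genes}"
        )
    vectors, _ = build_individual_matrix([s.genes for s in sets], emb)
    codes = model.encode(vectors) if len(sets) else np.zeros((0, model.latent_dim))
    return LatentMatrix(individual_ids=[s.individual_id for s in sets], values=codes)
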