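"""Drug-pair features, the MLP interaction predictor, and the training objective.

A drug pair (x, y) is represented by concatenating the two drug embeddings,
h(x, y) = [Z_x || Z_y] (640-dim at defaults).  The predictor is a five-layer
perceptron — input, three hidden layers of 128/64/32 units, and a 2-unit
output — with ReLU on the hidden activations and a softmax over the two
output units; the positive-class component is the interaction probability.
(A ReLU on the output layer itself would zero both logits for many inputs
and freeze them at p = 0.5 with no gradient, so the output affine feeds the
softmax directly.)
Training minimizes the mean binary cross-entropy over labeled pairs.

Because concatenation is order-sensitive while interaction is symmetric,
inference averages the probabilities of both orientations (configurable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, softmax_rows
from .encoder import (
    DrugEmbedding,
    EncoderConfig,
    EncoderParams,
    GATHeadParams,
    UnionGraph,
    encode_drug,
    encode_union_tape,
    init_encoder_params,
)
from .molgraph import MolecularGraph

CHECKPOINT_VERSION = 1
DEFAULT_HIDDEN = (128, 64, 32)
PROB_EPS = 1e-7


@dataclass
class MLPParams:
    """Weights/biases of the pair classifier; ``sizes`` chains input to output."""

    sizes: tuple
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    def parameters(self):
        yield from self.weights
        yield from self.biases


def init_mlp_params(input_dim: int, hidden: tuple = DEFAULT_HIDDEN,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> MLPParams:
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = (input_dim, *hidden, 2)
    params = MLPParams(sizes=sizes)
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params.weights.append(
            Tensor(rng.uniform(-limit, limit, (fan_in, fan_out)),
                   requires_grad=True))
        params.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))
    return params


def pair_features(Zx: np.ndarray, Zy: np.ndarray) -> np.ndarray:
    """Ordered pair feature [Z_x || Z_y]."""
    Zx, Zy = np.asarray(Zx), np.asarray(Zy)
    if Zx.shape != Zy.shape:
        raise ValueError(f"drug vectors differ in length: {Zx.shape} vs {Zy.shape}")
    return np.concatenate([Zx, Zy])


def mlp_forward_tape(features: Tensor, params: MLPParams) -> Tensor:
    """Forward pass on the tape; returns (n, 2) class probabilities."""
    if features.shape[-1] != params.sizes[0]:
        raise ValueError(
            f"pair feature length {features.shape[-1]} != input layer "
            f"{params.sizes[0]}")
    h = features
    for W, b in zip(params.weights[:-1], params.biases[:-1]):
        h = ((h @ W) + b).relu()
    logits = (h @ params.weights[-1]) + params.biases[-1]
    return softmax_rows(logits)


def mlp_forward(feature: np.ndarray, params: MLPParams) -> float | np.ndarray:
    """Interaction probability (positive-class softmax component) for features."""
    arr = np.atleast_2d(np.asarray(feature, dtype=float))
    probs = mlp_forward_tape(Tensor(arr), params).value[:, 1]
    return float(probs[0]) if np.asarray(feature).ndim == 1 else probs


def bce_loss(predictions, labels) -> float:
    """Mean binary cross-entropy with epsilon clamping."""
    p = np.clip(np.asarray(predictions, dtype=float), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in shape")
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def bce_loss_tape(probabilities: Tensor, labels: np.ndarray) -> Tensor:
    """Tape version of :func:`bce_loss` for training."""
    y = np.asarray(labels, dtype=float)
    p = probabilities.clip(PROB_EPS, 1 - PROB_EPS)
    return -((p.log() * y + (1 - p).log() * (1 - y)).mean())


@dataclass
class DDIModel:
    """Encoder + pair classifier with their configuration.

    ``symmetrize`` averages both pair orientations at inference;
    ``augment_swapped`` additionally trains on the swapped orientation of
    every training pair.
    """

    encoder_config: EncoderConfig
    encoder_params: EncoderParams
    mlp_params: MLPParams
    symmetrize: bool = True
    augment_swapped: bool = False

    @classmethod
    def initialize(cls, encoder_config: EncoderConfig | None = None,
                   hidden: tuple = DEFAULT_HIDDEN, seed: int = 0,
                   symmetrize: bool = True,
                   augment_swapped: bool = False) -> "DDIModel":
        config = encoder_config or EncoderConfig(seed=seed)
        rng = np.random.default_rng(seed)
        enc = init_encoder_params(config, rng)
        mlp = init_mlp_params(2 * config.embedding_dim, hidden, rng)
        return cls(config, enc, mlp, symmetrize, augment_swapped)

    def parameters(self) -> list:
        return list(self.encoder_params.parameters()) + \
            list(self.mlp_params.parameters())

    def embed(self, graph: MolecularGraph) -> DrugEmbedding:
        return encode_drug(graph, self.encoder_params, self.encoder_config)

    def predict_from_embeddings(self, ex: DrugEmbedding,
                                ey: DrugEmbedding) -> float:
        p_xy = mlp_forward(pair_features(ex.Z, ey.Z), self.mlp_params)
        if not self.symmetrize:
            return p_xy
        p_yx = mlp_forward(pair_features(ey.Z, ex.Z), self.mlp_params)
        return 0.5 * (p_xy + p_yx)

    def predict_pair(self, graph_x: MolecularGraph,
                     graph_y: MolecularGraph) -> float:
        """Interaction probability, averaged over both pair orientations."""
        return self.predict_from_embeddings(self.embed(graph_x),
                                            self.embed(graph_y))

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Serialize all parameters and config to a versioned JSON checkpoint."""
        enc = self.encoder_params
        payload = {
            "format_version": CHECKPOINT_VERSION,
            "encoder_config": {
                "num_layers": self.encoder_config.num_layers,
                "heads": self.encoder_config.heads,
                "head_dim": self.encoder_config.head_dim,
                "leaky_relu_slope": self.encoder_config.leaky_relu_slope,
                "seed": self.encoder_config.seed,
            },
            "symmetrize": self.symmetrize,
            "augment_swapped": self.augment_swapped,
            "encoder": {
                "layers": [
                    [{"W": h.W.value.tolist(), "a": h.a.value.tolist()}
                     for h in heads]
                    for heads in enc.layers
                ],
                "scores": [{"w": w.value.tolist(), "b": b.value.tolist()}
                           for w, b in enc.scores],
            },
            "mlp": {
                "sizes": list(self.mlp_params.sizes),
                "weights": [w.value.tolist() for w in self.mlp_params.weights],
                "biases": [b.value.tolist() for b in self.mlp_params.biases],
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DDIModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        config = EncoderConfig(**payload["encoder_config"])
        enc = EncoderParams()
        for heads in payload["encoder"]["layers"]:
            enc.layers.append([
                GATHeadParams(W=Tensor(np.array(h["W"]), requires_grad=True),
                              a=Tensor(np.array(h["a"]), requires_grad=True))
                for h in heads
            ])
        for s in payload["encoder"]["scores"]:
            enc.scores.append((Tensor(np.array(s["w"]), requires_grad=True),
                               Tensor(np.array(s["b"]), requires_grad=True)))
        mlp = MLPParams(sizes=tuple(payload["mlp"]["sizes"]))
        mlp.weights = [Tensor(np.array(w), requires_grad=True)
                       for w in payload["mlp"]["weights"]]
        mlp.biases = [Tensor(np.array(b), requires_grad=True)
                      for b in payload["mlp"]["biases"]]
        return cls(config, enc, mlp,
                   symmetrize=payload.get("symmetrize", True),
                   augment_swapped=payload.get("augment_swapped", False))

    def state_copy(self) -> list:
        return [p.value.copy() for p in self.parameters()]

    def load_state(self, state: list) -> None:
        for p, v in zip(self.parameters(), state):
            p.value = v.copy()


def batch_forward(model: DDIModel, graphs: dict, pairs: list) -> Tensor:
    """Tape forward pass for a batch of (drug_x, drug_y) id pairs.

    Encodes each distinct drug in the batch once, concatenates the pair
    features in stored orientation, and returns the (n,) tensor of
    positive-class probabilities.
    """
    ids = sorted({d for pair in pairs for d in pair})
    union = UnionGraph([graphs[i] for i in ids])
    Z, _ = encode_union_tape(union, model.encoder_params, model.encoder_config)
    index = {d: i for i, d in enumerate(ids)}
    za = gather_rows(Z, [index[a] for a, b in pairs])
    zb = gather_rows(Z, [index[b] for a, b in pairs])
    features = concat([za, zb], axis=1)
    probs = mlp_forward_tape(features, model.mlp_params)
    selector = np.zeros((2, 1))
    selector[1, 0] = 1.0
    return (probs @ Tensor(selector)).reshape(-1)
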