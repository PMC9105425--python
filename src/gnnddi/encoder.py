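"""Multi-layer graph-attention encoder with per-layer attention-pooled readouts.

Each of the K (default 5) layers runs L (default 2) independent attention
heads.  A head projects atom features with a weight matrix W, scores each
bonded neighbor pair with a shared attention vector a through a LeakyReLU,
softmax-normalizes the scores over the neighborhood, aggregates the
projected neighbors with those weights and adds the projected self term
before a ReLU:

    h_i' = ReLU( sum_{j in N(i)} alpha_ij W h_j  +  W h_i )
    alpha_ij = softmax_j( LeakyReLU( a^T [W h_i || W h_j] ) )

Head outputs are concatenated, giving per-atom rows of width L*F' (64 at
defaults).  After every layer a soft self-attention readout scores each
atom with a one-channel graph convolution, softmax-normalizes the scores
into weights gamma, and pools the layer's atom rows into a single graph
vector HG(k) = sum_i gamma_i h_i.  The K pooled vectors are concatenated
into the drug embedding Z (320-dim at defaults); the per-layer gamma
weights are retained for substructure attribution.

Because each layer widens an atom's receptive field by one bond, HG(k) is
a k-hop summary: small functional groups are visible in early layers,
larger ones in later layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_sum, softmax_rows
from .molgraph import ATOM_FEATURE_DIM, MolecularGraph

MASK_BIAS = -1e30  # additive bias that removes non-neighbors from the softmax


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the graph-attention feature extractor.

    ``num_layers`` is the number of attention layers K (the receptive-field
    depth in bonds), ``heads`` the number of attention heads L per layer and
    ``head_dim`` the per-head output width F'.  Per-layer atom rows have
    width ``heads * head_dim`` and the drug embedding has width
    ``num_layers * heads * head_dim``.
    """

    num_layers: int = 5
    heads: int = 2
    head_dim: int = 32
    leaky_relu_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1 or self.heads < 1 or self.head_dim < 1:
            raise ValueError("num_layers, heads and head_dim must be >= 1")

    @property
    def layer_dim(self) -> int:
        return self.heads * self.head_dim

    @property
    def embedding_dim(self) -> int:
        return self.num_layers * self.layer_dim


@dataclass
class GATHeadParams:
    """One attention head: projection W (in_dim x F') and attention vector a (2F')."""

    W: Tensor
    a: Tensor


@dataclass
class EncoderParams:
    """All trainable encoder parameters: K layers of L heads + K scoring layers."""

    layers: list = field(default_factory=list)   # list[list[GATHeadParams]]
    scores: list = field(default_factory=list)   # list[(w: Tensor, b: Tensor)]

    def parameters(self):
        for heads in self.layers:
            for head in heads:
                yield head.W
                yield head.a
        for w, b in self.scores:
            yield w
            yield b


@dataclass(frozen=True)
class DrugEmbedding:
    """Per-layer pooled vectors, their concatenation Z, and per-layer atom weights."""

    drug_id: str
    layer_vectors: tuple   # K arrays of length L*F'
    Z: np.ndarray          # length K*L*F'
    gammas: tuple          # K arrays of length p, each summing to 1


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_encoder_params(config: EncoderConfig,
                        rng: np.random.Generator | None = None,
                        in_dim: int = ATOM_FEATURE_DIM) -> EncoderParams:
    """Uniform Glorot initialization of every layer, seeded via ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = EncoderParams()
    dim = in_dim
    for _ in range(config.num_layers):
        heads = [
            GATHeadParams(
                W=_glorot(rng, dim, config.head_dim, (dim, config.head_dim)),
                a=_glorot(rng, 2 * config.head_dim, 1, (2 * config.head_dim,)),
            )
            for _ in range(config.heads)
        ]
        params.layers.append(heads)
        out_dim = config.layer_dim
        params.scores.append((
            _glorot(rng, out_dim, 1, (out_dim, 1)),
            Tensor(np.zeros(1), requires_grad=True),
        ))
        dim = out_dim
    return params


# -- single-edge primitives (contract-level, used directly in tests) ---------


def attention_logit(h_i: np.ndarray, h_j: np.ndarray, W: np.ndarray,
                    a: np.ndarray, slope: float = 0.2) -> float:
    """Unnormalized attention score e_ij = LeakyReLU(a^T [W h_i || W h_j])."""
    W = np.asarray(W)
    z = np.concatenate([W.T @ np.asarray(h_i), W.T @ np.asarray(h_j)])
    a = np.asarray(a)
    if a.shape != z.shape:
        raise ValueError(f"attention vector shape {a.shape} != {z.shape}")
    e = float(a @ z)
    return e if e > 0 else slope * e


def attention_coefficients(logits) -> np.ndarray:
    """Softmax over a neighborhood's logits, stabilized by max subtraction."""
    logits = np.asarray(logits, dtype=float)
    if logits.size == 0:
        raise ValueError("empty neighborhood has no attention coefficients")
    e = np.exp(logits - logits.max())
    return e / e.sum()


# -- layer-level forward passes ----------------------------------------------


def _directed_edges(graph) -> tuple[np.ndarray, np.ndarray]:
    """Both directions of every bond as (updating node i, neighbor j) arrays."""
    return np.nonzero(graph.adjacency())


def layer_forward(H: Tensor | np.ndarray, graph: MolecularGraph,
                  heads: list, config: EncoderConfig) -> Tensor:
    """One attention layer: per-head aggregate + self term, heads concatenated.

    Attention runs over the bond list (sparse), so the cost scales with the
    number of bonds rather than atoms squared.  Atoms without neighbors
    receive an empty aggregation (zero), keeping only their projected self
    term.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    p = graph.num_atoms
    if H.shape[0] != p:
        raise ValueError(f"feature rows {H.shape[0]} != atom count {p}")
    i_arr, j_arr = _directed_edges(graph)
    outputs = []
    for head in heads:
        if head.W.shape[0] != H.shape[1]:
            raise ValueError(
                f"head input dim {head.W.shape[0]} != feature width {H.shape[1]}")
        if head.a.shape[0] != 2 * config.head_dim:
            raise ValueError(
                f"attention vector length {head.a.shape[0]} != {2 * config.head_dim}")
        HW = H @ head.W                                    # (p, F')
        # e_ij = a[:F'].Wh_i + a[F':].Wh_j on every directed edge (i, j)
        fa = head.a.reshape(2, config.head_dim)
        atom_scores = HW @ fa.T                            # (p, 2)
        self_part = gather_col(atom_scores, 0)
        nbr_part = gather_col(atom_scores, 1)
        e = (gather_rows(self_part, i_arr)
             + gather_rows(nbr_part, j_arr)).leaky_relu(config.leaky_relu_slope)
        # softmax over each atom's neighborhood, max-shifted for stability
        shift = np.zeros(p)
        np.maximum.at(shift, i_arr, e.value)
        exp_e = (e - shift[i_arr]).exp()
        denom = segment_sum(exp_e, i_arr, p)
        alpha = exp_e / gather_rows(denom, i_arr)
        messages = alpha.reshape(-1, 1) * gather_rows(HW, j_arr)
        aggregated = segment_sum(messages, i_arr, p)
        outputs.append((aggregated + HW).relu())
    return concat(outputs, axis=1)


def gather_col(t: Tensor, col: int) -> Tensor:
    """Select one column of a 2-D tensor (gradient-aware)."""
    p = t.shape[0]
    selector = np.zeros((t.shape[1], 1))
    selector[col, 0] = 1.0
    return (t @ Tensor(selector)).reshape(p)


def _gcn_norm(graph: MolecularGraph) -> np.ndarray:
    """Symmetric GCN normalization D^{-1/2}(A + I)D^{-1/2} (constant per graph)."""
    a_hat = graph.adjacency() + np.eye(graph.num_atoms)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def sag_readout(H: Tensor | np.ndarray, graph: MolecularGraph,
                score_params) -> tuple[Tensor, Tensor]:
    """Soft attention readout over all atoms.

    A one-channel graph convolution scores each atom from its own and its
    neighbors' features; the scores are softmax-normalized into weights
    gamma and the pooled vector is the gamma-weighted sum of atom rows.
    Returns ``(HG, gamma)``; no atoms are dropped.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    w, b = score_params
    scores = (Tensor(_gcn_norm(graph)) @ H @ w) + b        # (p, 1)
    gamma = softmax_rows(scores.reshape(1, -1)).reshape(-1)  # (p,)
    pooled = (gamma.reshape(1, -1) @ H).reshape(-1)          # (L*F',)
    return pooled, gamma


def encode_drug_tape(graph: MolecularGraph, params: EncoderParams,
                     config: EncoderConfig) -> tuple[Tensor, list, list]:
    """Full encoder forward pass on the autodiff tape.

    Returns ``(Z, pooled_per_layer, gamma_per_layer)`` as tensors so the
    training loop can backpropagate through them.
    """
    if graph.atom_features is None:
        raise ValueError(f"drug {graph.drug_id!r}: graph has no atom features")
    H: Tensor | np.ndarray = Tensor(graph.atom_features)
    pooled_all, gamma_all = [], []
    for heads, score_params in zip(params.layers, params.scores):
        H = layer_forward(H, graph, heads, config)
        pooled, gamma = sag_readout(H, graph, score_params)
        pooled_all.append(pooled)
        gamma_all.append(gamma)
    Z = concat(pooled_all, axis=0)
    return Z, pooled_all, gamma_all


class UnionGraph:
    """Disjoint union of several molecular graphs (block-diagonal adjacency).

    Encoding many molecules at once as one union graph turns the per-layer
    work into a few dense matrix operations; the attention mask keeps
    molecules independent, so the result equals encoding each molecule
    separately.
    """

    def __init__(self, graphs: list):
        self.graphs = list(graphs)
        sizes = [g.num_atoms for g in self.graphs]
        self.offsets = np.cumsum([0] + sizes)
        self.num_atoms = int(self.offsets[-1])
        adj = np.zeros((self.num_atoms, self.num_atoms))
        for g, off in zip(self.graphs, self.offsets[:-1]):
            adj[off:off + g.num_atoms, off:off + g.num_atoms] = g.adjacency()
        self._adj = adj
        # segment bias: row m admits only atoms of molecule m in a softmax
        seg = np.full((len(self.graphs), self.num_atoms), MASK_BIAS)
        for m, (g, off) in enumerate(zip(self.graphs, self.offsets[:-1])):
            seg[m, off:off + g.num_atoms] = 0.0
        self.segment_bias = seg

    def adjacency(self) -> np.ndarray:
        return self._adj

    def features(self) -> np.ndarray:
        return np.concatenate([g.atom_features for g in self.graphs])


def sag_readout_union(H: Tensor, union: UnionGraph,
                      score_params) -> tuple[Tensor, Tensor]:
    """Per-molecule soft attention readout over a union graph.

    Returns ``(pooled, gamma)`` where ``pooled`` is (n_mols, width) and
    ``gamma`` is (n_mols, total_atoms) with each row summing to 1 over its
    own molecule's atoms and zero elsewhere.
    """
    w, b = score_params
    scores = (Tensor(_gcn_norm(union)) @ H @ w) + b          # (N, 1)
    logits = scores.reshape(1, -1) + union.segment_bias       # (n_mols, N)
    gamma = softmax_rows(logits)
    pooled = gamma @ H
    return pooled, gamma


def encode_union_tape(union: UnionGraph, params: EncoderParams,
                      config: EncoderConfig) -> tuple[Tensor, list]:
    """Encoder forward pass over a union graph on the tape.

    Returns ``(Z, gammas)``: Z is (n_mols, K*L*F'); gammas holds one
    (n_mols, total_atoms) tensor per layer.
    """
    H: Tensor = Tensor(union.features())
    pooled_all, gamma_all = [], []
    for heads, score_params in zip(params.layers, params.scores):
        H = layer_forward(H, union, heads, config)
        pooled, gamma = sag_readout_union(H, union, score_params)
        pooled_all.append(pooled)
        gamma_all.append(gamma)
    return concat(pooled_all, axis=1), gamma_all


def encode_drug(graph: MolecularGraph, params: EncoderParams,
                config: EncoderConfig) -> DrugEmbedding:
    """Encode one drug into its k-hop embedding (plain arrays, no tape)."""
    Z, pooled_all, gamma_all = encode_drug_tape(graph, params, config)
    return DrugEmbedding(
        drug_id=graph.drug_id,
        layer_vectors=tuple(p.value.copy() for p in pooled_all),
        Z=Z.value.copy(),
        gammas=tuple(g.value.copy() for g in gamma_all),
    )
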