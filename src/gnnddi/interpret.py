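"""Substructure attribution for a predicted drug-drug interaction.

Each drug embedding keeps its K per-layer pooled vectors HG(k), where layer
k summarizes k-hop substructures, together with the readout weights gamma
that say how much each atom contributed to that layer's pooled vector.  To
explain a predicted interaction between drugs x and y, every layer pair
(s, t) is scored by the inner product HG_x(s) . HG_y(t); the largest score
names the pair of receptive-field depths whose substructure features drive
the prediction, and the corresponding gamma weights highlight the atoms —
in practice the functional groups — responsible on each side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import DrugEmbedding
from .molgraph import MolecularGraph
from .pairmodel import DDIModel


@dataclass(frozen=True)
class AttributionResult:
    """Layer-pair score matrix and per-atom weights at the selected layers."""

    drug_x: str
    drug_y: str
    score_matrix: np.ndarray        # (K, K) inner products
    best_pair: tuple                # (s, t), 1-based layer indices
    best_score: float
    atoms_x: list                   # [(atom_index, element, gamma), ...]
    atoms_y: list


def contribution_scores(embedding_x: DrugEmbedding,
                        embedding_y: DrugEmbedding) -> np.ndarray:
    """K x K matrix of inner products between per-layer pooled vectors."""
    if len(embedding_x.layer_vectors) != len(embedding_y.layer_vectors):
        raise ValueError("embeddings have different layer counts")
    for hx, hy in zip(embedding_x.layer_vectors, embedding_y.layer_vectors):
        if hx.shape != hy.shape:
            raise ValueError("per-layer dimensions differ between embeddings")
    return np.array([
        [float(np.dot(hx, hy)) for hy in embedding_y.layer_vectors]
        for hx in embedding_x.layer_vectors
    ])


def best_layer_pair(scores: np.ndarray) -> tuple[int, int, float]:
    """Argmax layer pair (1-based); ties break to smallest s, then smallest t."""
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    flat = int(np.argmax(scores))  # argmax scans row-major: smallest s then t
    s, t = np.unravel_index(flat, scores.shape)
    return int(s) + 1, int(t) + 1, float(scores[s, t])


def atom_attribution(graph: MolecularGraph, embedding: DrugEmbedding,
                     layer: int) -> list:
    """Per-atom weights ``(atom_index, element, gamma)`` at a 1-based layer."""
    if not 1 <= layer <= len(embedding.gammas):
        raise ValueError(
            f"layer {layer} out of range 1..{len(embedding.gammas)}")
    gamma = embedding.gammas[layer - 1]
    return [(i, graph.elements[i], float(gamma[i]))
            for i in range(graph.num_atoms)]


def explain_pair(model: DDIModel, graph_x: MolecularGraph,
                 graph_y: MolecularGraph) -> AttributionResult:
    """Full attribution: encode both drugs, score layer pairs, export weights."""
    ex = model.embed(graph_x)
    ey = model.embed(graph_y)
    scores = contribution_scores(ex, ey)
    s, t, best = best_layer_pair(scores)
    return AttributionResult(
        drug_x=graph_x.drug_id,
        drug_y=graph_y.drug_id,
        score_matrix=scores,
        best_pair=(s, t),
        best_score=best,
        atoms_x=atom_attribution(graph_x, ex, s),
        atoms_y=atom_attribution(graph_y, ey, t),
    )


def write_attribution_tsv(path, result: AttributionResult) -> None:
    """TSV export: one row per atom of each drug at its selected layer."""
    rows = [(result.drug_x, result.best_pair[0], i, el, w)
            for i, el, w in result.atoms_x]
    rows += [(result.drug_y, result.best_pair[1], i, el, w)
             for i, el, w in result.atoms_y]
    pd.DataFrame(rows, columns=["drug_id", "layer", "atom_index", "element",
                                "weight"]).to_csv(path, sep="\t", index=False)


def read_attribution_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_attribution_json(path, result: AttributionResult) -> None:
    """Summary JSON: score matrix, selected layer pair and its score."""
    payload = {
        "drug_x": result.drug_x,
        "drug_y": result.drug_y,
        "score_matrix": result.score_matrix.tolist(),
        "best_pair": list(result.best_pair),
        "best_score": result.best_score,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
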