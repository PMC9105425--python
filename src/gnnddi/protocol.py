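"""Evaluation protocols: splits, negative sampling, training and metrics.

Two cross-validation strategies are supported.  The *edge partition*
(warm start) randomly partitions the known interaction edges into 75%
training / 5% validation / 20% test, so every drug may appear in training.
The *drug partition* (cold start) randomly partitions the drugs 80/20:
pairs between two training drugs are training samples, pairs joining a
training drug to a held-out drug are test samples, and pairs between two
held-out drugs are discarded — the held-out drugs are completely unseen
during training, emulating newly developed drugs.

Unlabeled pairs are sampled uniformly without replacement as negatives
(balanced 1:1 by default), respecting each strategy's eligibility rule so
cold-start negatives also join a training drug to a held-out drug.

Performance is reported as accuracy, precision, recall and F1 at a 0.5
threshold plus threshold-free AUC (tie-averaged rank statistic) and AUPR
(precision-recall step integration).  Experiments repeat over independent
splits and report per-metric mean and standard deviation; all randomness
derives from ``(seed, repeat_index)``.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .autodiff import Adam
from .molgraph import build_graph_table
from .pairmodel import DDIModel, batch_forward, bce_loss, bce_loss_tape

logger = logging.getLogger("gnnddi")

EDGE_PARTITION = "edge_partition"
DRUG_PARTITION = "drug_partition"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered drug pair in canonical (sorted) orientation."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid drug pair")
    return (a, b) if a < b else (b, a)


@dataclass
class DDIDataset:
    """A drug table plus the positive (and optionally negative) pair sets."""

    drugs: pd.DataFrame
    positives: set
    negatives: set = field(default_factory=set)

    def __post_init__(self):
        known = set(self.drugs["drug_id"])
        self.positives = {canonical_pair(*p) for p in self.positives}
        self.negatives = {canonical_pair(*p) for p in self.negatives}
        for pair in itertools.chain(self.positives, self.negatives):
            unknown = set(pair) - known
            if unknown:
                raise ValueError(f"pair {pair} references unknown drugs {unknown}")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labeled both + and -")

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drugs["drug_id"])


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a dataset into train/validation/test."""

    strategy: str = EDGE_PARTITION
    fractions: tuple = (0.75, 0.05, 0.20)
    seed: int = 0
    repeat_index: int = 1

    def __post_init__(self):
        if self.strategy not in (EDGE_PARTITION, DRUG_PARTITION):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def rng(self, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, self.repeat_index, *extra])


@dataclass
class Split:
    """Positive pairs per split, plus the drug partition when applicable."""

    strategy: str
    train: tuple
    val: tuple
    test: tuple
    train_drugs: tuple | None = None
    test_drugs: tuple | None = None


def edge_partition_split(dataset: DDIDataset, spec: SplitSpec) -> Split:
    """Warm-start split: shuffle positive edges into 75/5/20 train/val/test."""
    if spec.strategy != EDGE_PARTITION:
        raise ValueError("spec.strategy must be edge_partition")
    positives = sorted(dataset.positives)
    if len(positives) < 5:
        raise ValueError("need at least 5 positive edges to split")
    order = spec.rng(0).permutation(len(positives))
    shuffled = [positives[i] for i in order]
    n = len(shuffled)
    n_test = round(spec.fractions[2] * n)
    n_val = round(spec.fractions[1] * n)
    test = tuple(shuffled[:n_test])
    val = tuple(shuffled[n_test:n_test + n_val])
    train = tuple(shuffled[n_test + n_val:])
    return Split(EDGE_PARTITION, train, val, test)


def drug_partition_split(dataset: DDIDataset, spec: SplitSpec) -> Split:
    """Cold-start split: hold out 20% of drugs entirely.

    Training pairs join two training drugs; test pairs join a training drug
    to a held-out drug; pairs between two held-out drugs are discarded.
    Validation is a holdout of the training pairs (5% of them).
    """
    if spec.strategy != DRUG_PARTITION:
        raise ValueError("spec.strategy must be drug_partition")
    drugs = dataset.drug_ids
    order = spec.rng(0).permutation(len(drugs))
    n_test_drugs = round(0.2 * len(drugs))
    test_drugs = {drugs[i] for i in order[:n_test_drugs]}
    train_drugs = {drugs[i] for i in order[n_test_drugs:]}
    train_pool, test = [], []
    for pair in sorted(dataset.positives):
        in_test = sum(d in test_drugs for d in pair)
        if in_test == 0:
            train_pool.append(pair)
        elif in_test == 1:
            test.append(pair)
        # both endpoints held out: discarded (no usable supervision signal)
    if not test:
        raise ValueError("drug partition produced no test pairs; try another seed")
    if not train_pool:
        raise ValueError("drug partition produced no training pairs; try another seed")
    n_val = round(0.05 * len(train_pool))
    val_order = spec.rng(1).permutation(len(train_pool))
    val = tuple(train_pool[i] for i in val_order[:n_val])
    train = tuple(train_pool[i] for i in val_order[n_val:])
    return Split(DRUG_PARTITION, train, val, tuple(test),
                 train_drugs=tuple(sorted(train_drugs)),
                 test_drugs=tuple(sorted(test_drugs)))


def make_split(dataset: DDIDataset, spec: SplitSpec) -> Split:
    if spec.strategy == EDGE_PARTITION:
        return edge_partition_split(dataset, spec)
    return drug_partition_split(dataset, spec)


def _eligible_negatives(dataset: DDIDataset, split: Split) -> dict:
    """Candidate unlabeled pairs per split, respecting the strategy's rule."""
    positives = dataset.positives
    if split.strategy == EDGE_PARTITION:
        ids = dataset.drug_ids
        pool = [p for p in (canonical_pair(a, b)
                            for a, b in itertools.combinations(ids, 2))
                if p not in positives]
        return {"train": pool, "val": pool, "test": pool, "_shared": True}
    train_ids = sorted(split.train_drugs)
    test_ids = sorted(split.test_drugs)
    train_pool = [p for p in (canonical_pair(a, b)
                              for a, b in itertools.combinations(train_ids, 2))
                  if p not in positives]
    test_pool = [p for p in (canonical_pair(a, b)
                             for a in train_ids for b in test_ids)
                 if p not in positives]
    return {"train": train_pool, "val": train_pool, "test": test_pool,
            "_shared": False}


def sample_negatives(dataset: DDIDataset, split: Split, ratio: float = 1.0,
                     rng: np.random.Generator | None = None,
                     seed: int = 0) -> dict:
    """Uniform, collision-free negative pairs for each split.

    Negatives never coincide with any positive, never repeat across splits,
    and are sampled ``ratio`` times the split's positive count.
    """
    if ratio <= 0:
        raise ValueError("negative sampling ratio must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    pools = _eligible_negatives(dataset, split)
    wanted = {name: round(ratio * len(getattr(split, name)))
              for name in ("train", "val", "test")}
    out: dict = {}
    if pools["_shared"]:
        pool = pools["train"]
        total = sum(wanted.values())
        if total > len(pool):
            raise ValueError(
                f"requested {total} negatives but only {len(pool)} unlabeled "
                f"pairs are available")
        chosen = rng.choice(len(pool), size=total, replace=False)
        cursor = 0
        for name in ("train", "val", "test"):
            out[name] = tuple(pool[i]
                              for i in chosen[cursor:cursor + wanted[name]])
            cursor += wanted[name]
    else:
        train_total = wanted["train"] + wanted["val"]
        if train_total > len(pools["train"]):
            raise ValueError(
                f"requested {train_total} train/val negatives but only "
                f"{len(pools['train'])} candidate pairs exist")
        if wanted["test"] > len(pools["test"]):
            raise ValueError(
                f"requested {wanted['test']} test negatives but only "
                f"{len(pools['test'])} candidate pairs exist")
        chosen = rng.choice(len(pools["train"]), size=train_total, replace=False)
        out["train"] = tuple(pools["train"][i] for i in chosen[:wanted["train"]])
        out["val"] = tuple(pools["train"][i] for i in chosen[wanted["train"]:])
        test_chosen = rng.choice(len(pools["test"]), size=wanted["test"],
                                 replace=False)
        out["test"] = tuple(pools["test"][i] for i in test_chosen)
    return out


# -- metrics -----------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts at a threshold plus the derived and rank metrics."""

    ACC: float
    precision: float
    recall: float
    F1: float
    AUC: float
    AUPR: float
    TP: int
    FP: int
    TN: int
    FN: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ACC", "precision", "recall", "F1", "AUC", "AUPR",
                 "TP", "FP", "TN", "FN")}


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the tie-averaged Mann-Whitney rank statistic."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """Full metric suite from labels and predicted probabilities."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    for cls in (0, 1):
        if not np.any(y == cls):
            raise ValueError(f"no samples of class {cls}; metrics undefined")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / (tp + fp + tn + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MetricsReport(
        ACC=acc, precision=precision, recall=recall, F1=f1,
        AUC=auc_rank(y, p), AUPR=float(average_precision_score(y, p)),
        TP=tp, FP=fp, TN=tn, FN=fn,
    )


# -- training ----------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (Adam)."""

    epochs: int = 400
    learning_rate: float = 1e-3
    batch_size: int = 1024
    negative_ratio: float = 1.0
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Reduced profile for small synthetic benchmarks."""
        base = {"epochs": 50, "batch_size": 128}
        base.update(overrides)
        return cls(**base)


def _labeled_pairs(split: Split, negatives: dict, part: str):
    pos = list(getattr(split, part))
    neg = list(negatives[part])
    pairs = pos + neg
    labels = np.array([1] * len(pos) + [0] * len(neg))
    return pairs, labels


def predict_pairs(model: DDIModel, graphs: dict, pairs: list) -> np.ndarray:
    """Probabilities for many pairs, encoding each distinct drug once."""
    from .encoder import UnionGraph, encode_union_tape
    from .pairmodel import mlp_forward

    ids = sorted({d for pair in pairs for d in pair})
    union = UnionGraph([graphs[i] for i in ids])
    Z, _ = encode_union_tape(union, model.encoder_params, model.encoder_config)
    zv = Z.value
    index = {d: i for i, d in enumerate(ids)}
    ia = np.array([index[a] for a, b in pairs])
    ib = np.array([index[b] for a, b in pairs])
    p_xy = mlp_forward(np.hstack([zv[ia], zv[ib]]), model.mlp_params)
    if not model.symmetrize:
        return p_xy
    p_yx = mlp_forward(np.hstack([zv[ib], zv[ia]]), model.mlp_params)
    return 0.5 * (p_xy + p_yx)


def train_model(model: DDIModel, graphs: dict, split: Split, negatives: dict,
                config: TrainConfig) -> dict:
    """Mini-batch Adam training with validation-loss checkpoint selection.

    Returns a history dict; the model is left holding the parameters of the
    best validation epoch (or the last epoch when there is no validation set).
    """
    rng = np.random.default_rng(config.seed)
    pairs, labels = _labeled_pairs(split, negatives, "train")
    if model.augment_swapped:
        pairs = pairs + [(b, a) for a, b in pairs]
        labels = np.concatenate([labels, labels])
    val_pairs, val_labels = _labeled_pairs(split, negatives, "val")
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val, best_state = np.inf, None
    n = len(pairs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_pairs = [pairs[i] for i in idx]
            batch_labels = labels[idx]
            optimizer.zero_grad()
            probs = batch_forward(model, graphs, batch_pairs)
            loss = bce_loss_tape(probs, batch_labels)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.value) * len(idx)
        history["train_loss"].append(epoch_loss / n)
        if val_pairs:
            val_loss = bce_loss(predict_pairs(model, graphs, val_pairs),
                                val_labels)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val, best_state = val_loss, model.state_copy()
        logger.debug("epoch %d train_loss=%.4f", epoch + 1,
                     history["train_loss"][-1])
    if best_state is not None:
        model.load_state(best_state)
    history["best_val_loss"] = best_val if val_pairs else None
    return history


@dataclass
class ExperimentReport:
    """Per-repeat metric reports plus their mean and standard deviation."""

    per_repeat: list
    mean: dict
    sd: dict

    def to_dict(self) -> dict:
        return {metric: {"mean": self.mean[metric], "sd": self.sd[metric],
                         "per_repeat": [r.to_dict()[metric]
                                        for r in self.per_repeat]}
                for metric in self.mean}


def run_experiment(dataset: DDIDataset, spec: SplitSpec,
                   train_config: TrainConfig,
                   encoder_config=None, repeats: int = 1,
                   hidden: tuple = (128, 64, 32)) -> ExperimentReport:
    """Train and evaluate over ``repeats`` independent splits.

    Every source of randomness (split shuffle, negative sampling, parameter
    initialization, batch order) derives from ``(spec.seed, repeat_index)``.
    """
    logger.info("experiment: strategy=%s seed=%d repeats=%d epochs=%d "
                "batch=%d", spec.strategy, spec.seed, repeats,
                train_config.epochs, train_config.batch_size)
    reports = []
    graphs = build_graph_table(dataset.drugs)
    for repeat in range(1, repeats + 1):
        rspec = SplitSpec(strategy=spec.strategy, fractions=spec.fractions,
                          seed=spec.seed, repeat_index=repeat)
        split = make_split(dataset, rspec)
        negatives = sample_negatives(dataset, split,
                                     ratio=train_config.negative_ratio,
                                     rng=rspec.rng(2))
        init_seed = int(rspec.rng(3).integers(2**31))
        model = DDIModel.initialize(encoder_config=encoder_config,
                                    hidden=hidden, seed=init_seed)
        run_config = TrainConfig(epochs=train_config.epochs,
                                 learning_rate=train_config.learning_rate,
                                 batch_size=train_config.batch_size,
                                 negative_ratio=train_config.negative_ratio,
                                 seed=init_seed)
        train_model(model, graphs, split, negatives, run_config)
        test_pairs, test_labels = _labeled_pairs(split, negatives, "test")
        probs = predict_pairs(model, graphs, test_pairs)
        reports.append(compute_metrics(test_labels, probs))
        logger.info("repeat %d/%d (%s): AUC=%.3f AUPR=%.3f", repeat, repeats,
                    spec.strategy, reports[-1].AUC, reports[-1].AUPR)
    keys = ("ACC", "precision", "recall", "F1", "AUC", "AUPR")
    values = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    return ExperimentReport(
        per_repeat=reports,
        mean={k: float(v.mean()) for k, v in values.items()},
        sd={k: float(v.std(ddof=1)) if len(reports) > 1 else 0.0
            for k, v in values.items()},
    )


# -- pair-list I/O ------------------------------------------------------------


def read_edge_list(path) -> tuple[set, set]:
    """Read ``drug_a``/``drug_b`` (+ optional ``label``) TSV/CSV.

    Returns ``(positives, negatives)``; without a label column every edge
    is positive.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = {"drug_a", "drug_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list {path}: missing columns {sorted(missing)}")
    positives, negatives = set(), set()
    for row in df.itertuples(index=False):
        pair = canonical_pair(str(row.drug_a), str(row.drug_b))
        if "label" in df.columns and int(getattr(row, "label")) == 0:
            negatives.add(pair)
        else:
            positives.add(pair)
    return positives, negatives


def write_split_manifest(path, split: Split, negatives: dict) -> None:
    """Write a TSV with ``drug_a``, ``drug_b``, ``label``, ``split`` columns."""
    rows = []
    for part in ("train", "val", "test"):
        for a, b in getattr(split, part):
            rows.append((a, b, 1, part))
        for a, b in negatives.get(part, ()):
            rows.append((a, b, 0, part))
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "label", "split"]).to_csv(
        path, sep="\t", index=False)


def write_metrics_json(path, report: ExperimentReport) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
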