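"""Optimization, evaluation protocols, metrics and ablation variants.

Training is plain mini-batch SGD with weight decay on a categorical
cross-entropy loss; all stochasticity (initialization, batch order, dropout,
Monte Carlo edge masks) flows from one seeded generator, so a run is fully
reproducible from its seed.

Two evaluation protocols are provided: a session-level holdout (train on
every subject's first session pooled, test on the pooled second sessions —
one model for all subjects, with per-subject test metrics) and
leave-one-subject-out cross-validation.

The ablation variants mirror the usual component-knockout design: removing
the edge-evolution machinery, swapping attention for plain graph
convolution, and replacing the PLV adjacency with a random graph with and
without the evolution mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph_construction import GraphDataset
from .model import ModelConfig, SFEGAT
from .nn.autodiff import Tensor

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalMetrics",
    "AblationVariant",
    "VARIANTS",
    "train_model",
    "recalibrate_batchnorm",
    "evaluate_model",
    "confusion_matrix",
    "compute_metrics",
    "evaluate_metrics",
    "run_holdout",
    "run_loso",
    "run_protocol",
    "build_variant",
    "random_adjacency",
    "apply_random_adjacency",
]


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters (defaults follow the reference protocol)."""

    lr: float = 0.01
    batch_size: int = 64
    weight_decay: float = 0.001
    epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class TrainResult:
    model: SFEGAT
    loss_history: list[float]


@dataclass(frozen=True)
class EvalMetrics:
    """Accuracy, macro precision, macro F1 and Cohen's kappa."""

    accuracy: float
    precision: float
    f1: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "kappa": self.kappa,
        }


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, k = logits.shape
    onehot = np.eye(k)[labels]
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = (logits - shift).exp()
    logp = logits - shift - z.sum(axis=-1, keepdims=True).log()
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def _batchnorm_modules(module) -> list:
    from .nn.layers import BatchNorm

    found = []
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, BatchNorm):
            found.append(m)
        stack.extend(child for _, child in m._children())
    return found


def recalibrate_batchnorm(
    model: SFEGAT,
    graphs: GraphDataset,
    batch_size: int = 64,
    rng: np.random.Generator | None = None,
) -> None:
    """Replace batch-norm running statistics with exact dataset statistics.

    Under SGD with weight decay the pre-normalization activations shrink
    steadily (batch norm is scale-invariant to its input, so the scale is a
    free direction that weight decay contracts); the exponential-moving
    running estimates then lag the current activation scale by a roughly
    constant factor and eval-mode outputs drift away from train-mode ones.
    A "precise" recalibration pass — one train-mode sweep over the data that
    averages the per-batch moments equally — removes the lag.
    """
    rng = rng or np.random.default_rng(0)
    bns = _batchnorm_modules(model)
    momenta = [bn.momentum for bn in bns]
    was_training = model.training
    model.train()
    try:
        for k, start in enumerate(range(0, len(graphs), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (k + 1)  # cumulative moving average
            sl = slice(start, start + batch_size)
            model.logits(graphs.features[sl], graphs.adjacency[sl], rng=rng)
    finally:
        for bn, m in zip(bns, momenta):
            bn.momentum = m
        model.train(was_training)


def train_model(
    graphs: GraphDataset,
    model: SFEGAT,
    cfg: TrainConfig = TrainConfig(),
    callback=None,
) -> TrainResult:
    """Mini-batch SGD with weight decay on cross-entropy.

    ``callback(epoch, mean_loss)``, if given, is invoked after every epoch.
    After the final epoch, batch-norm running statistics are recalibrated
    with one pass over the training data (see
    :func:`recalibrate_batchnorm`).  Raises on an empty dataset and aborts
    with a diagnostic on NaN loss.
    """
    n = len(graphs)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    history: list[float] = []
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.logits(graphs.features[idx], graphs.adjacency[idx], rng=rng)
            loss = _cross_entropy(logits, graphs.labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"{float(loss.data)}"
                )
            model.zero_grad()
            loss.backward()
            for p in params:
                if p.grad is None:  # e.g. a GAE kept structurally but unused
                    continue
                p.data -= cfg.lr * (p.grad + cfg.weight_decay * p.data)
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        history.append(mean_loss)
        if callback is not None:
            callback(epoch, mean_loss)
    if cfg.epochs > 0:
        recalibrate_batchnorm(model, graphs, cfg.batch_size, rng)
    return TrainResult(model=model, loss_history=history)


def evaluate_model(
    model: SFEGAT, graphs: GraphDataset, batch_size: int = 64
) -> np.ndarray:
    """Deterministic eval-mode class predictions for every graph."""
    was_training = model.training
    model.eval()
    preds = []
    try:
        for start in range(0, len(graphs), batch_size):
            sl = slice(start, start + batch_size)
            probs = model.forward(graphs.features[sl], graphs.adjacency[sl])
            preds.append(probs.data.argmax(axis=1))
    finally:
        model.train(was_training)
    return np.concatenate(preds)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """n x n count matrix, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def compute_metrics(cm: np.ndarray) -> EvalMetrics:
    """Accuracy, macro precision, macro F1 and Cohen's kappa from counts.

    Per-class precision (or recall) with an empty denominator is defined as
    0, and a class F1 with both components 0 is 0, so the metrics stay
    defined for degenerate predictors.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no observations")
    tp = np.diag(cm)
    pred_counts = cm.sum(axis=0)
    true_counts = cm.sum(axis=1)
    accuracy = tp.sum() / total
    with np.errstate(invalid="ignore", divide="ignore"):
        precision_i = np.where(pred_counts > 0, tp / pred_counts, 0.0)
        recall_i = np.where(true_counts > 0, tp / true_counts, 0.0)
        denom = precision_i + recall_i
        f1_i = np.where(denom > 0, 2 * precision_i * recall_i / denom, 0.0)
    po = accuracy
    pe = float((pred_counts * true_counts).sum()) / (total**2)
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return EvalMetrics(
        accuracy=float(accuracy),
        precision=float(precision_i.mean()),
        f1=float(f1_i.mean()),
        kappa=float(kappa),
    )


def evaluate_metrics(model: SFEGAT, graphs: GraphDataset, n_classes: int) -> EvalMetrics:
    preds = evaluate_model(model, graphs)
    return compute_metrics(confusion_matrix(graphs.labels, preds, n_classes))


# ---------------------------------------------------------------------------
# Ablation variants


@dataclass(frozen=True)
class AblationVariant:
    """Structural switches distinguishing one ablation from the full model."""

    name: str
    use_evolution: bool = True  # GAE + Monte Carlo masking active
    conv: str = "attention"  # "attention" | "gcn"
    keep_gae_params: bool = True  # instantiate GAE even when masking is off
    random_adjacency: bool = False  # replace the PLV graph with a random one


VARIANTS: dict[str, AblationVariant] = {
    "SFE-GAT": AblationVariant("SFE-GAT"),
    "PLV-GAT": AblationVariant("PLV-GAT", use_evolution=False, keep_gae_params=False),
    "SFE-GCN": AblationVariant("SFE-GCN", conv="gcn"),
    "FE-GAT": AblationVariant("FE-GAT", use_evolution=False),
    "R-GAT": AblationVariant(
        "R-GAT", use_evolution=False, keep_gae_params=False, random_adjacency=True
    ),
    "R-SFE-GAT": AblationVariant("R-SFE-GAT", random_adjacency=True),
}


def build_variant(
    variant: str | AblationVariant,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> SFEGAT:
    """Instantiate the model for an ablation variant.

    Random-adjacency variants change the data, not the model; apply
    :func:`apply_random_adjacency` to the graph dataset separately.
    """
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
            ) from None
    cfg = replace(
        config,
        conv=variant.conv,
        masking=variant.use_evolution,
        use_gae=variant.use_evolution or variant.keep_gae_params,
    )
    return SFEGAT(cfg, seed=seed)


def random_adjacency(
    n_channels: int, density: float = 0.3, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Symmetric Bernoulli(density) support, zero diagonal, unit weights."""
    rng = rng or np.random.default_rng(0)
    upper = rng.random((n_channels, n_channels)) < density
    adj = np.triu(upper, 1)
    adj = (adj | adj.T).astype(np.float64)
    return adj


def apply_random_adjacency(
    graphs: GraphDataset, density: float = 0.3, seed: int = 0
) -> GraphDataset:
    """Replace every trial's adjacency with one shared random graph."""
    adj = random_adjacency(graphs.n_channels, density, np.random.default_rng(seed))
    return GraphDataset(
        adjacency=np.broadcast_to(adj, graphs.adjacency.shape).copy(),
        features=graphs.features,
        labels=graphs.labels,
        channel_labels=graphs.channel_labels,
    )


# ---------------------------------------------------------------------------
# Protocols


@dataclass
class ProtocolResult:
    per_subject: dict[str, EvalMetrics]
    mean: EvalMetrics
    pooled: EvalMetrics
    loss_histories: list[list[float]] = field(default_factory=list)


def _metrics_mean(per_subject: dict[str, EvalMetrics]) -> EvalMetrics:
    vals = list(per_subject.values())
    return EvalMetrics(
        accuracy=float(np.mean([v.accuracy for v in vals])),
        precision=float(np.mean([v.precision for v in vals])),
        f1=float(np.mean([v.f1 for v in vals])),
        kappa=float(np.mean([v.kappa for v in vals])),
    )


def _prepare(graphs: GraphDataset, variant: AblationVariant, seed: int) -> GraphDataset:
    if variant.random_adjacency:
        return apply_random_adjacency(graphs, seed=seed)
    return graphs


def run_holdout(
    train_sets: dict[str, GraphDataset],
    test_sets: dict[str, GraphDataset],
    variant: str | AblationVariant = "SFE-GAT",
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> ProtocolResult:
    """Session-level holdout: pool all subjects' training sessions, train one
    model, report per-subject metrics on their test sessions."""
    if set(train_sets) != set(test_sets):
        raise ValueError("train and test subject sets differ")
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    pooled_train = GraphDataset.concatenate([train_sets[s] for s in sorted(train_sets)])
    pooled_train = _prepare(pooled_train, variant, train_config.seed)
    model = build_variant(variant, model_config, seed=train_config.seed)
    result = train_model(pooled_train, model, train_config)
    n_classes = model_config.n_classes
    per_subject = {}
    all_true, all_pred = [], []
    for subject in sorted(test_sets):
        test = _prepare(test_sets[subject], variant, train_config.seed)
        preds = evaluate_model(model, test)
        per_subject[subject] = compute_metrics(
            confusion_matrix(test.labels, preds, n_classes)
        )
        all_true.append(test.labels)
        all_pred.append(preds)
    pooled = compute_metrics(
        confusion_matrix(np.concatenate(all_true), np.concatenate(all_pred), n_classes)
    )
    return ProtocolResult(
        per_subject=per_subject,
        mean=_metrics_mean(per_subject),
        pooled=pooled,
        loss_histories=[result.loss_history],
    )


def run_loso(
    subject_sets: dict[str, GraphDataset],
    variant: str | AblationVariant = "SFE-GAT",
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> ProtocolResult:
    """Leave-one-subject-out cross-validation over ``subject_sets``."""
    if len(subject_sets) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    n_classes = model_config.n_classes
    per_subject = {}
    histories = []
    all_true, all_pred = [], []
    for held_out in sorted(subject_sets):
        train_pool = GraphDataset.concatenate(
            [subject_sets[s] for s in sorted(subject_sets) if s != held_out]
        )
        train_pool = _prepare(train_pool, variant, train_config.seed)
        test = _prepare(subject_sets[held_out], variant, train_config.seed)
        model = build_variant(variant, model_config, seed=train_config.seed)
        result = train_model(train_pool, model, train_config)
        preds = evaluate_model(model, test)
        per_subject[held_out] = compute_metrics(
            confusion_matrix(test.labels, preds, n_classes)
        )
        histories.append(result.loss_history)
        all_true.append(test.labels)
        all_pred.append(preds)
    pooled = compute_metrics(
        confusion_matrix(np.concatenate(all_true), np.concatenate(all_pred), n_classes)
    )
    return ProtocolResult(
        per_subject=per_subject,
        mean=_metrics_mean(per_subject),
        pooled=pooled,
        loss_histories=histories,
    )


def run_protocol(
    mode: str,
    variant: str | AblationVariant = "SFE-GAT",
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    train_sets: dict[str, GraphDataset] | None = None,
    test_sets: dict[str, GraphDataset] | None = None,
    subject_sets: dict[str, GraphDataset] | None = None,
) -> ProtocolResult:
    """Dispatch to :func:`run_holdout` or :func:`run_loso` by name."""
    if mode == "holdout":
        if train_sets is None or test_sets is None:
            raise ValueError("holdout needs train_sets and test_sets")
        return run_holdout(train_sets, test_sets, variant, model_config, train_config)
    if mode == "loso":
        if subject_sets is None:
            raise ValueError("loso needs subject_sets")
        return run_loso(subject_sets, variant, model_config, train_config)
    raise ValueError(f"unknown protocol {mode!r}; expected 'holdout' or 'loso'")
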