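"""The structure-feature evolution graph attention network.

The network consumes one graph per trial (C electrode nodes, PLV-derived
adjacency, B filter-bank band powers per node) and lets topology and node
features co-evolve through a stack of evolution blocks:

* an input GATv2 layer lifts the B-dimensional band-power features to the
  block width (heads x per-head channels, 128 by default);
* each of L = 3 evolution blocks applies GATv2 aggregation, ReLU, batch
  normalization, then a graph autoencoder (GCN encoder to a 32-d latent
  space, inner-product + sigmoid decoder) that assigns every electrode pair
  an edge probability; a binary mask — Monte Carlo-sampled against the
  probabilities during training, thresholded at ``tau_eval`` during
  evaluation — sparsifies the adjacency via the Hadamard product before the
  next block;
* a classifier head (GATv2 + batch norm + global mean pooling + dropout +
  linear + softmax) maps the evolved node features to class probabilities.

Masks are sampled on the upper triangle and mirrored so the functional graph
stays undirected.  Self-loops are always added for attention and GCN
propagation (and are never masked), so fully pruned nodes remain defined.
The discrete mask has no gradient of its own; by default retained edges
carry the weight ``A_ij * P_ij`` during train-mode message passing so the
classification loss reaches the autoencoder ("prob-scale"), with
straight-through and no-gradient estimators available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn.autodiff import Tensor
from .nn.layers import (
    BatchNorm,
    DenseGATv1,
    DenseGATv2,
    DenseGCN,
    Dropout,
    Linear,
    Module,
    add_self_loops,
    gcn_normalize,
)

__all__ = [
    "ModelConfig",
    "EvolutionState",
    "EvolutionBlock",
    "SFEGAT",
    "sample_edge_mask_train",
    "threshold_edge_mask_eval",
    "apply_mask",
    "count_parameters",
    "format_parameter_table",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network.

    ``block_dim`` is derived as ``heads * hidden_per_head`` (4 x 32 = 128).
    ``attention`` switches between the dynamic (GATv2, default) and original
    (GAT) energy orderings; ``conv`` replaces attention layers with plain
    graph convolutions (the SFE-GCN ablation).  ``use_gae`` / ``masking``
    disable the edge-evolution machinery for ablations.  ``edge_gradient``
    selects how gradients pass the discrete mask during training.
    """

    in_dim: int = 8
    hidden_per_head: int = 32
    heads: int = 4
    gae_latent: int = 32
    n_blocks: int = 3
    n_classes: int = 4
    dropout_p: float = 0.5
    tau_eval: float = 0.5
    negative_slope: float = 0.2
    bn_momentum: float = 0.1
    attention: str = "gatv2"  # "gatv2" | "gat"
    conv: str = "attention"  # "attention" | "gcn"
    use_gae: bool = True
    masking: bool = True
    edge_gradient: str = "prob-scale"  # "prob-scale" | "ste" | "none"
    edge_weight_mode: str = "weighted"  # attention: "weighted" | "topology"

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("need at least one evolution block")
        if not 0.0 <= self.tau_eval <= 1.0:
            raise ValueError(f"tau_eval must be in [0, 1], got {self.tau_eval}")
        if self.edge_gradient not in ("prob-scale", "ste", "none"):
            raise ValueError(f"unknown edge_gradient {self.edge_gradient!r}")
        if self.attention not in ("gatv2", "gat"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.conv not in ("attention", "gcn"):
            raise ValueError(f"unknown conv {self.conv!r}")

    @property
    def block_dim(self) -> int:
        return self.heads * self.hidden_per_head


@dataclass
class EvolutionState:
    """Per-stage (H, A) trajectory of one forward pass.

    Stage 0 is the constructed graph (raw band-power features and PLV
    adjacency); stage k is the output of evolution block k.  ``supports``
    are the binary edge supports (self-loops excluded), ``edge_probs`` the
    GAE edge-probability matrices of each block.
    """

    features: list[np.ndarray] = field(default_factory=list)
    adjacency: list[np.ndarray] = field(default_factory=list)
    supports: list[np.ndarray] = field(default_factory=list)
    edge_probs: list[np.ndarray] = field(default_factory=list)

    def edge_counts(self) -> list[int]:
        """Total retained (off-diagonal) edge count per stage."""
        return [int(s.sum()) for s in self.supports]


def sample_edge_mask_train(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo edge mask: M = I(P > R), R ~ U(0,1) i.i.d.

    The uniform matrix is drawn on the upper triangle (diagonal included)
    and mirrored, so a symmetric probability matrix yields a symmetric mask.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.min() < 0 or P.max() > 1:
        raise ValueError("edge probabilities must lie in [0, 1]")
    r = rng.random(P.shape)
    upper = np.triu(r)
    r_sym = upper + np.swapaxes(np.triu(r, 1), -1, -2)
    return (P > r_sym).astype(np.float64)


def threshold_edge_mask_eval(P: np.ndarray, tau: float) -> np.ndarray:
    """Deterministic eval-time mask M = I(P > tau)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    P = np.asarray(P, dtype=np.float64)
    return (P > tau).astype(np.float64)


def apply_mask(A: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Hadamard sparsification A' = A . M (support shrinks or stays)."""
    A = np.asarray(A, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if A.shape != M.shape:
        raise ValueError(f"shape mismatch: A {A.shape} vs M {M.shape}")
    return A * M


class GraphAutoencoder(Module):
    """GCN encoder to a latent space + inner-product sigmoid edge decoder."""

    def __init__(self, in_dim: int, latent_dim: int, rng, bn_momentum: float = 0.1):
        super().__init__()
        self.encoder = DenseGCN(in_dim, latent_dim, rng)
        self.latent_bn = BatchNorm(latent_dim, momentum=bn_momentum)

    def edge_probabilities(self, h: Tensor, adjacency) -> Tensor:
        """(N, C, C) symmetric edge-probability matrix in [0, 1]."""
        a_hat = gcn_normalize(adjacency)
        z = self.encoder(h, a_hat).relu()
        z = self.latent_bn(z)
        logits = z @ z.swapaxes(1, 2)
        return logits.sigmoid()


class EvolutionBlock(Module):
    """One co-evolution cycle: attention -> BN -> GAE edge resampling."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.conv = _make_conv(config, config.block_dim, rng)
        self.bn = BatchNorm(config.block_dim, momentum=config.bn_momentum)
        self.gae = (
            GraphAutoencoder(
                config.block_dim, config.gae_latent, rng, config.bn_momentum
            )
            if config.use_gae
            else None
        )

    def __call__(self, h: Tensor, a: Tensor, rng: np.random.Generator | None = None):
        """Returns (h', a', edge_probabilities-or-None)."""
        cfg = self.config
        h2 = self.bn(_apply_conv(self.conv, h, a, cfg).relu())
        if self.gae is None:
            return h2, a, None
        p = self.gae.edge_probabilities(h2, a)
        if not cfg.masking:
            return h2, a, p
        if self.training:
            if rng is None:
                raise ValueError("train-mode mask sampling needs an rng")
            m = sample_edge_mask_train(p.data, rng)
            m_t = Tensor(m)
            if cfg.edge_gradient == "prob-scale":
                a_next = a * m_t * p
            elif cfg.edge_gradient == "ste":
                a_next = a * m_t + a.detach() * (p - p.detach())
            else:  # "none"
                a_next = Tensor(apply_mask(a.data, m))
        else:
            m = threshold_edge_mask_eval(p.data, cfg.tau_eval)
            a_next = Tensor(apply_mask(a.data, m))
        return h2, a_next, p


def _make_conv(config: ModelConfig, in_dim: int, rng):
    if config.conv == "gcn":
        return DenseGCN(in_dim, config.block_dim, rng)
    cls = DenseGATv2 if config.attention == "gatv2" else DenseGATv1
    return cls(
        in_dim,
        config.heads,
        config.hidden_per_head,
        rng,
        negative_slope=config.negative_slope,
    )


def _apply_conv(conv, h: Tensor, a: Tensor, config: ModelConfig) -> Tensor:
    if isinstance(conv, DenseGCN):
        return conv(h, gcn_normalize(a))
    support = add_self_loops(a.data != 0)
    weight = None
    if config.edge_weight_mode == "weighted":
        # self-loops carry unit weight so they survive the |w| prior
        eye = np.broadcast_to(np.eye(a.shape[-1]), a.shape)
        weight = a + Tensor(eye.copy())
    return conv(h, support, edge_weight=weight)


class SFEGAT(Module):
    """Full network: input layer, L evolution blocks, classifier head."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.input_conv = _make_conv(config, config.in_dim, rng)
        self.blocks = [EvolutionBlock(config, rng) for _ in range(config.n_blocks)]
        self.cls_conv = _make_conv(config, config.block_dim, rng)
        self.cls_bn = BatchNorm(config.block_dim, momentum=config.bn_momentum)
        self.dropout = Dropout(config.dropout_p)
        self.cls_linear = Linear(config.block_dim, config.n_classes, rng)

    def logits(
        self,
        features: np.ndarray,
        adjacency: np.ndarray,
        rng: np.random.Generator | None = None,
        return_state: bool = False,
    ):
        """Pre-softmax class scores for a batch of graphs.

        ``features``: (N, C, B); ``adjacency``: (N, C, C) weighted, zero
        diagonal.  ``rng`` drives mask sampling and dropout (train mode
        only).  With ``return_state`` the per-stage (H, A) trajectory is
        returned alongside.
        """
        features = np.asarray(features, dtype=np.float64)
        adjacency = np.asarray(adjacency, dtype=np.float64)
        if features.ndim != 3 or adjacency.ndim != 3:
            raise ValueError("expected batched (N, C, .) inputs")
        h = Tensor(features)
        a = Tensor(adjacency)
        state = EvolutionState() if return_state else None
        if state is not None:
            state.features.append(features.copy())
            state.adjacency.append(adjacency.copy())
            state.supports.append(adjacency != 0)
        h = _apply_conv(self.input_conv, h, a, self.config).relu()
        for block in self.blocks:
            h, a, p = block(h, a, rng)
            if state is not None:
                state.features.append(h.data.copy())
                state.adjacency.append(a.data.copy())
                state.supports.append(a.data != 0)
                if p is not None:
                    state.edge_probs.append(p.data.copy())
        hc = _apply_conv(self.cls_conv, h, a, self.config)
        hc = self.cls_bn(hc)
        pooled = hc.mean(axis=1)  # global mean pool over the C nodes
        pooled = self.dropout(pooled, rng)
        out = self.cls_linear(pooled)
        return (out, state) if return_state else out

    def forward(
        self,
        features: np.ndarray,
        adjacency: np.ndarray,
        rng: np.random.Generator | None = None,
        return_state: bool = False,
    ):
        """Class probability vectors (rows sum to 1) for a batch of graphs."""
        result = self.logits(features, adjacency, rng=rng, return_state=return_state)
        out, state = result if return_state else (result, None)
        shift = out.data.max(axis=-1, keepdims=True)
        z = (out - Tensor(shift)).exp()
        probs = z / z.sum(axis=-1, keepdims=True)
        return (probs, state) if return_state else probs

    __call__ = forward

    def predict_proba(self, features, adjacency) -> np.ndarray:
        """Eval-mode class probabilities as a plain array."""
        was_training = self.training
        self.eval()
        try:
            return self.forward(features, adjacency).data
        finally:
            self.train(was_training)


def count_parameters(config: ModelConfig = ModelConfig()) -> dict[str, int]:
    """Trainable-scalar counts per architecture component, plus the total.

    A GATv2 layer counts its two input projections (each with bias), the
    per-head attention vectors, and the output bias on the concatenated
    heads; a batch norm counts gamma and beta; the GAE counts its GCN
    encoder (weights + bias) and latent batch norm — the inner-product
    decoder is parameter-free.
    """
    model = SFEGAT(config, seed=0)
    conv_name = {"attention": config.attention, "gcn": "gcn"}[config.conv]
    counts: dict[str, int] = {f"input_{conv_name}": model.input_conv.n_parameters()}
    for k, block in enumerate(model.blocks, start=1):
        counts[f"block{k}_{conv_name}"] = block.conv.n_parameters()
        counts[f"block{k}_batchnorm"] = block.bn.n_parameters()
        if block.gae is not None:
            counts[f"block{k}_gae"] = block.gae.n_parameters()
    counts[f"classifier_{conv_name}"] = model.cls_conv.n_parameters()
    counts["classifier_batchnorm"] = model.cls_bn.n_parameters()
    counts["classifier_linear"] = model.cls_linear.n_parameters()
    counts["total"] = model.n_parameters()
    return counts


def format_parameter_table(config: ModelConfig = ModelConfig()) -> str:
    """Human-readable component/parameter table for the configured model."""
    counts = count_parameters(config)
    width = max(len(k) for k in counts)
    lines = [f"{'component':<{width}}  parameters", "-" * (width + 12)]
    for name, n in counts.items():
        if name == "total":
            lines.append("-" * (width + 12))
        lines.append(f"{name:<{width}}  {n:>10,}")
    return "\n".join(lines)


def save_checkpoint(model: SFEGAT, path: str | Path) -> None:
    """Weights, batch-norm running statistics and config in one npz file."""
    import json

    state = model.state_dict()
    payload = {f"state::{k}": v for k, v in state.items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.config)))
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> SFEGAT:
    import json

    with np.load(path, allow_pickle=False) as archive:
        config = ModelConfig(**json.loads(str(archive["config_json"])))
        state = {
            k.removeprefix("state::"): archive[k]
            for k in archive.files
            if k.startswith("state::")
        }
    model = SFEGAT(config)
    model.load_state_dict(state)
    return model
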