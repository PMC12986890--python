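"""Post-hoc analyses of the evolution trajectory.

Two views of what the stacked evolution blocks do to a trial set:

* *embedding snapshots*: the graph-level (mean-pooled) feature vector of
  every trial at each evolution stage (stage 0 = the constructed band-power
  features), projected to 2-D with t-SNE and scored with the silhouette
  coefficient and the Davies-Bouldin index — higher silhouette / lower DBI
  means tighter, better-separated class clusters;
* *edge-retention counts*: for each electrode pair, how many trials of a set
  still carry that edge at stage k — the evolution mechanism's
  sparsification profile.

Clustering operates on one point per trial (mean-pooled node features);
per-trial node-level matrices are also exposed for scatter exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .graph_construction import GraphDataset
from .model import SFEGAT

__all__ = [
    "EmbeddingSnapshot",
    "ClusterQuality",
    "capture_snapshots",
    "cluster_scores",
    "count_edge_retention",
    "export_stage_scores_csv",
    "export_edge_counts_csv",
]


@dataclass
class EmbeddingSnapshot:
    """Per-trial graph-level vectors at one evolution stage."""

    stage: int
    vectors: np.ndarray  # (n_trials, d) mean-pooled node features
    labels: np.ndarray  # (n_trials,)
    node_features: np.ndarray | None = None  # (n_trials, C, d), optional


@dataclass(frozen=True)
class ClusterQuality:
    """Cluster-separation scores for one snapshot.

    ``silhouette`` / ``davies_bouldin`` are computed on the seeded 2-D t-SNE
    projection; the ``raw_*`` pair on the unprojected vectors.
    """

    silhouette: float
    davies_bouldin: float
    raw_silhouette: float
    raw_davies_bouldin: float


def capture_snapshots(
    model: SFEGAT,
    graphs: GraphDataset,
    batch_size: int = 64,
    keep_node_features: bool = False,
) -> list[EmbeddingSnapshot]:
    """Mean-pooled per-trial features at stages 0..L (eval mode, deterministic)."""
    was_training = model.training
    model.eval()
    n_stages = model.config.n_blocks + 1
    pooled: list[list[np.ndarray]] = [[] for _ in range(n_stages)]
    nodes: list[list[np.ndarray]] = [[] for _ in range(n_stages)]
    try:
        for start in range(0, len(graphs), batch_size):
            sl = slice(start, start + batch_size)
            _, state = model.logits(
                graphs.features[sl], graphs.adjacency[sl], return_state=True
            )
            for k in range(n_stages):
                pooled[k].append(state.features[k].mean(axis=1))
                if keep_node_features:
                    nodes[k].append(state.features[k])
    finally:
        model.train(was_training)
    return [
        EmbeddingSnapshot(
            stage=k,
            vectors=np.concatenate(pooled[k]),
            labels=graphs.labels.copy(),
            node_features=np.concatenate(nodes[k]) if keep_node_features else None,
        )
        for k in range(n_stages)
    ]


def cluster_scores(
    snapshot: EmbeddingSnapshot,
    project: bool = True,
    seed: int = 42,
    perplexity: float = 30.0,
) -> ClusterQuality:
    """Silhouette and Davies-Bouldin scores for one snapshot.

    With ``project`` (default) the scores are computed on a seeded 2-D t-SNE
    embedding, with raw-space scores reported alongside; ``project=False``
    reuses the raw scores for both.  Perplexity is clamped below the sample
    count as t-SNE requires.
    """
    x = np.asarray(snapshot.vectors, dtype=np.float64)
    y = np.asarray(snapshot.labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cluster scores need at least 2 classes")
    lonely = classes[counts < 2]
    if lonely.size:
        raise ValueError(
            f"silhouette undefined: class {lonely[0]} has a single member"
        )
    raw_sil = float(silhouette_score(x, y, metric="euclidean"))
    raw_dbi = float(davies_bouldin_score(x, y))
    if not project:
        return ClusterQuality(raw_sil, raw_dbi, raw_sil, raw_dbi)
    eff_perplexity = min(perplexity, (len(y) - 1) / 3.0)
    embedding = TSNE(
        n_components=2,
        perplexity=eff_perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(x)
    return ClusterQuality(
        silhouette=float(silhouette_score(embedding, y, metric="euclidean")),
        davies_bouldin=float(davies_bouldin_score(embedding, y)),
        raw_silhouette=raw_sil,
        raw_davies_bouldin=raw_dbi,
    )


def export_stage_scores_csv(
    path,
    model: SFEGAT,
    graphs: GraphDataset,
    seed: int = 42,
    perplexity: float = 30.0,
) -> list[ClusterQuality]:
    """Per-stage cluster-score table (one row per evolution stage) to CSV."""
    snaps = capture_snapshots(model, graphs)
    scores = [cluster_scores(s, seed=seed, perplexity=perplexity) for s in snaps]
    with open(path, "w") as fh:
        fh.write("stage,silhouette,davies_bouldin,raw_silhouette,raw_davies_bouldin\n")
        for snap, q in zip(snaps, scores):
            fh.write(
                f"evo{snap.stage},{q.silhouette:.6f},{q.davies_bouldin:.6f},"
                f"{q.raw_silhouette:.6f},{q.raw_davies_bouldin:.6f}\n"
            )
    return scores


def export_edge_counts_csv(path, counts: np.ndarray, channel_labels=None) -> None:
    """Edge-retention count matrix to CSV with channel-label headers."""
    c = counts.shape[0]
    labels = list(channel_labels) if channel_labels else [f"ch{i}" for i in range(c)]
    with open(path, "w") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for i in range(c):
            fh.write(labels[i] + "," + ",".join(str(int(v)) for v in counts[i]) + "\n")


def count_edge_retention(
    model: SFEGAT, graphs: GraphDataset, stage: int, batch_size: int = 64
) -> np.ndarray:
    """C x C counts of how many trials retain each edge at ``stage``.

    Stage 0 counts edges of the constructed graphs; stage k the support
    after evolution block k (eval mode, deterministic masks).
    """
    n_blocks = model.config.n_blocks
    if not 0 <= stage <= n_blocks:
        raise ValueError(f"stage must be in [0, {n_blocks}], got {stage}")
    if stage == 0:
        return (graphs.adjacency != 0).sum(axis=0).astype(np.int64)
    was_training = model.training
    model.eval()
    counts = np.zeros((graphs.n_channels, graphs.n_channels), dtype=np.int64)
    try:
        for start in range(0, len(graphs), batch_size):
            sl = slice(start, start + batch_size)
            _, state = model.logits(
                graphs.features[sl], graphs.adjacency[sl], return_state=True
            )
            counts += state.supports[stage].sum(axis=0)
    finally:
        model.train(was_training)
    return counts
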