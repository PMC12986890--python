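"""Watch the graph evolve: cluster quality and edge retention per stage.

Trains a small model, then reports (a) silhouette / Davies-Bouldin scores of
the trial embeddings at each evolution stage and (b) how many edges survive
each stage's resampling, with the planted coupled pairs highlighted.
"""

import numpy as np

from sfegat.analysis import capture_snapshots, cluster_scores, count_edge_retention
from sfegat.graph_construction import build_graph_dataset
from sfegat.model import ModelConfig
from sfegat.synthetic_data import (
    SyntheticDatasetConfig,
    default_class_specs,
    generate_dataset,
)
from sfegat.training import TrainConfig, build_variant, evaluate_metrics, train_model

specs = default_class_specs(n_channels=12, coupling=0.9, noise_sd=0.3)
cfg = SyntheticDatasetConfig(
    class_specs=specs, n_subjects=1, n_sessions=2, trials_per_class=24,
    amp_jitter=0.15, seed=3
)
data, truth = generate_dataset(cfg)
train = build_graph_dataset(data["S01"]["0"])
test = build_graph_dataset(data["S01"]["1"])

model = build_variant("SFE-GAT", ModelConfig(), seed=0)
train_model(train, model, TrainConfig(epochs=60, batch_size=32, seed=0))
print(f"held-out accuracy: {evaluate_metrics(model, test, 4).accuracy:.3f}\n")

print("cluster quality per evolution stage (t-SNE projection):")
for snap in capture_snapshots(model, test):
    q = cluster_scores(snap, seed=42)
    print(f"  evo{snap.stage}: silhouette {q.silhouette:+.3f}  "
          f"Davies-Bouldin {q.davies_bouldin:.3f}")
print("-> rising silhouette / falling DBI means the evolved features")
print("   separate the classes better than the raw band powers.\n")

planted = {
    (min(i, j), max(i, j))
    for spec in truth["S01"]
    for i, j, _, _ in spec.coupled_pairs
}
for stage in (0, model.config.n_blocks):
    counts = count_edge_retention(model, test, stage)
    print(f"stage {stage}: {counts.sum() // 2} edge retentions across "
          f"{len(test)} trials")
iu = np.triu_indices(test.n_channels, 1)
final = count_edge_retention(model, test, model.config.n_blocks)
order = np.argsort(final[iu])[::-1]
top = [(int(iu[0][k]), int(iu[1][k])) for k in order[:8]]
print("most-retained edges at the final stage:", top)
print("planted coupled pairs:", sorted(planted))
print("-> evolution sparsifies the graph while keeping the planted structure.")
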