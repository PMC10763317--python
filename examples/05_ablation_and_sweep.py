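"""Ablation tables and the GCN hyperparameter grid.

Evaluates the contribution of the interclass association blocks (Z),
the intraclass similarity blocks (S) and the transformer's Add / Norm /
feed-forward modules, then sweeps GCN depth against embedding size.
A reduced model keeps this quick; relative ordering, not absolute
numbers, is the point.
"""

from gcnlda import ModelConfig
from gcnlda.evaluation import run_ablation, run_parameter_sweep
from gcnlda.pipeline import graph_from_dataset, labeled_pairs
from gcnlda.synthetic import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_lnc=40, n_dis=24, n_mir=20, n_terms=36,
                     p_in=0.5, p_out=0.02, seed=5)
data = generate_dataset(spec)
graph = graph_from_dataset(data)
pairs, labels = labeled_pairs(data.Z_ld, seed=5)

config = ModelConfig(embedding=32, heads=2, encoder_layers=1,
                     ffn_multiplier=2, epochs=120)

tables = run_ablation(graph, pairs, labels, config, seed=5)
print("graph-block ablation (interclass Z / intraclass S):")
for row in tables["graph"]:
    z = "yes" if row["interclass_Z"] else " no"
    s = "yes" if row["intraclass_S"] else " no"
    print(f"  Z={z}  S={s}  AUC={row['auc']:.3f}  AUPR={row['aupr']:.3f}")

print("\ntransformer-module ablation (Add / Norm / FFN):")
for row in tables["transformer"]:
    flags = "  ".join(f"{k}={'yes' if row[k] else ' no'}" for k in ("add", "norm", "ffn"))
    print(f"  {flags}  AUC={row['auc']:.3f}  AUPR={row['aupr']:.3f}")

rows = run_parameter_sweep(graph, pairs, labels, config,
                           layer_counts=[1, 2], embedding_sizes=[16, 32],
                           seed=5)
print("\nGCN layers x embedding sweep:")
for row in rows:
    print(f"  layers={row['gcn_layers']}  embedding={row['embedding']:3d}  "
          f"AUC={row['auc']:.3f}")
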