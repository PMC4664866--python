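"""The accuracy / betweenness trade-off controlled by beta.

On a GN benchmark with clear communities, trace AUC and the mean edge
betweenness <B> of the predicted links as beta moves from 0 (inter-community
candidates first) to 1 (intra first).
"""

import numpy as np

from netmend import beta_curve, generate_gn, mean_predicted_betweenness, split_edges
from netmend.ranking import RankedList

planted = generate_gn(k_in=14, seed=1)
split = split_edges(planted.graph, (0.9, 0.0, 0.1), seed=1)
g_train = split.train_graph()

curve = beta_curve(
    g_train, split.probe, "CBCN",
    grid=np.linspace(0, 1, 6), reps=5, seed=1,
)
true_B = mean_predicted_betweenness(g_train, RankedList(list(split.probe)))

print("beta   AUC    <B> of predictions")
for b, a, bb in zip(curve.grid, curve.auc_values, curve.meanB_values):
    print(f"{b:4.1f}  {a:.3f}  {bb:7.1f}")
print(f"\n<B> of the true missing links: {true_B:.1f}")
print(
    "\nRaising beta ranks intra-community pairs first: accuracy (AUC) goes\n"
    "up, but the predictions' mean betweenness <B> falls below that of the\n"
    "true missing links — the inter-community shortcuts get ignored."
)
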