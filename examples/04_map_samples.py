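"""Build a fixed 2-D map of samples with parametric t-SNE.

The network learns a t-SNE-like layout of topic mixtures; because the map
is a feed-forward function, new samples can be placed without moving
existing points.  One-hot inputs give each topic a fixed anchor position.
"""

import numpy as np

from ecotopics.embed import (
    EmbedConfig, embed_points, topic_coordinates, train_embedder,
)

rng = np.random.default_rng(0)
centers = np.array([
    [0.80, 0.10, 0.05, 0.03, 0.02],
    [0.05, 0.80, 0.10, 0.03, 0.02],
    [0.05, 0.10, 0.03, 0.02, 0.80],
])
labels = np.repeat([0, 1, 2], 50)
theta = np.vstack([rng.dirichlet(centers[c] * 80) for c in labels])

net = train_embedder(theta, EmbedConfig(epochs=120, seed=1))
losses = net.metadata["epoch_losses"]
print(f"t-SNE loss: {losses[0]:.3f} (first epoch) -> {losses[-1]:.3f} (last)")

coords = embed_points(net, theta)
anchors = topic_coordinates(net)
for c in range(3):
    xy = coords[labels == c].mean(axis=0)
    print(f"cluster {c}: mean map position ({xy[0]:7.2f}, {xy[1]:7.2f})")
print("topic anchors:")
for k, (x, y) in enumerate(anchors):
    print(f"  topic {k}: ({x:7.2f}, {y:7.2f})")

again = embed_points(net, theta)
print("re-embedding the samples reproduces their coordinates exactly:",
      bool(np.array_equal(again, coords)))
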