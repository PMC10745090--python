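"""Training co-occurrence embeddings on a two-topic toy corpus.

Words that co-occur within a topic should end up closer in cosine
similarity than words from different topics.
"""

import numpy as np

from semsyn.corpus import FeatureStream
from semsyn.embeddings import build_cooccurrence, train_glove

rng = np.random.default_rng(0)
topics = [[f"animal{i}" for i in range(6)], [f"tool{i}" for i in range(6)]]
corpus = []
for _ in range(400):
    topic = topics[int(rng.integers(2))]
    corpus.extend(rng.choice(topic, size=8).tolist())

stream = FeatureStream(mode="integral", symbols=corpus,
                       alignment=list(range(len(corpus))))
cooc = build_cooccurrence(stream, window=4, weighting="inverse-distance")
model = train_glove(cooc, d=8, epochs=400, lr=0.1, x_max=20.0, seed=0)

V = model.vectors / np.linalg.norm(model.vectors, axis=1, keepdims=True)
sims = V @ V.T
idx = {s: i for i, s in enumerate(model.symbols)}
within, between = [], []
for i, s1 in enumerate(model.symbols):
    for s2 in model.symbols[i + 1:]:
        (within if s1[0] == s2[0] else between).append(sims[idx[s1], idx[s2]])

print(f"training loss: {model.losses[0]:.3f} -> {model.losses[-1]:.3f} "
      "(mean weighted squared error on log counts)")
print(f"mean cosine within topic:  {np.mean(within):.3f}")
print(f"mean cosine between topics: {np.mean(between):.3f}")
print("within > between means the embeddings recovered the topic structure")
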