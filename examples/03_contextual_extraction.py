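"""Bounded-context extraction through a causal toy provider.

Shows that a fixed-context extraction with bound k is blind to tokens more
than k+4 positions in the past, while longer bounds see them.
"""

import numpy as np

from semsyn.corpus import FeatureStream
from semsyn.embeddings import ToyContextualProvider, fixed_context_extract

rng = np.random.default_rng(1)
base = {f"w{i}": rng.standard_normal(6) for i in range(40)}
base["SURPRISE"] = 10.0 * rng.standard_normal(6)
provider = ToyContextualProvider(base, decay=0.9)

symbols = [f"w{i}" for i in range(40)]
stream = FeatureStream(mode="integral", symbols=symbols,
                       alignment=list(range(40)))
perturbed = list(symbols)
t = 30
perturbed[t - 12] = "SURPRISE"   # 12 positions back
stream_p = FeatureStream(mode="integral", symbols=perturbed,
                         alignment=list(range(40)))

for k in (5, 15):
    a = fixed_context_extract(provider, stream, k).X[t]
    b = fixed_context_extract(provider, stream_p, k).X[t]
    print(f"k={k:2d}: |embedding change at token {t}| = {np.linalg.norm(a - b):.4f}"
          f"  (usable context = {k + 4} tokens)")
print("k=5 cannot see 12 tokens back (change 0); k=15 can (change > 0)")
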