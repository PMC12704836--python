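"""Map a fingerprint set into 2-D chemical space via Tanimoto + MDS.

Tanimoto similarity T = c/(|a|+|b|-c) between binary fingerprints gives
the distance 1 - T, which classical multidimensional scaling embeds in
the plane; nearby points are structurally similar compounds.
"""

import numpy as np

from freundlich_qsar import FingerprintSet, classical_mds, tanimoto_matrix

rng = np.random.default_rng(0)
# two structural "families" sharing different bit blocks + one outlier
family_a = [np.concatenate([np.ones(8), rng.integers(0, 2, 8)]) for _ in range(5)]
family_b = [np.concatenate([np.zeros(8), np.ones(4), rng.integers(0, 2, 4)]) for _ in range(5)]
outlier = [np.concatenate([np.zeros(12), np.ones(4)])]
names = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)] + ["outlier"]
fps = FingerprintSet(tuple(names), np.array(family_a + family_b + outlier))

t = tanimoto_matrix(fps)
print(f"mean within-family-A similarity: {t[:5, :5][np.triu_indices(5, 1)].mean():.3f}")
print(f"mean A-vs-B similarity:          {t[:5, 5:10].mean():.3f}")

emb = classical_mds(t, dims=2, names=fps.compound_names)
print("\n2-D embedding (first axes of classical MDS):")
print(emb.to_frame().round(3).to_string(index=False))
lam = emb.eigenvalues
print(f"\nvariance captured by 2 axes: "
      f"{lam[:2].sum() / lam[lam > 0].sum():.1%}")

# The two families form separate clusters and the outlier sits apart:
# exactly the kind of coverage check used to judge whether a test set
# lies inside the training set's chemical space.
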