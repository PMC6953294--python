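"""Sequence weighting: features, the weighting MLP, and gradients.

Every alignment row gets 7 features (depth, identity with the target,
identity with the consensus, gap ratio, and the alignment means of the
last three); a 7->7->7->1 sigmoid MLP turns them into weights in (0, 1).
Because the weights feed the covariance computation differentiably, the
contact loss can push noise-sequence weights down during training.
"""

import numpy as np

from coevonet import SyntheticSpec, WeightMLP, build_weight_features, generate_protein
from coevonet import features as F
from coevonet.weighting import FEATURE_NAMES

protein = generate_protein(SyntheticSpec(n_proteins=1, seed=5), seed=7)
enc = protein.enc
feats = build_weight_features(enc)
print("per-sequence features (7 columns):", ", ".join(FEATURE_NAMES))
for row in (0, 1, enc.depth - 1):  # query, a homolog, a noise sequence
    kind = "noise" if protein.noise_mask[row] else "evolved"
    print(f"  row {row:2d} ({kind:7s}): " + " ".join(f"{v:.3f}" for v in feats[row]))

mlp = WeightMLP(seed=0)
w = mlp(feats)
print(f"\nuntrained MLP weights: evolved mean {w.data[~protein.noise_mask].mean():.3f}, "
      f"noise mean {w.data[protein.noise_mask].mean():.3f} (no separation yet)")

# gradients flow from a covariance-based scalar back into the MLP parameters
single, pair = F.weighted_frequencies(enc, w)
S = F.covariance(single, pair)
(S * S).sum().backward()
gnorm = max(np.abs(p.grad).max() for p in mlp.parameters())
print(f"max |gradient| on MLP parameters through the covariance: {gnorm:.2e}")
print("non-zero gradients are what make the weighting trainable end-to-end.")
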