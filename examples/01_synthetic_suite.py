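"""Generate a small synthetic protein suite and inspect the planted signal.

Builds 8 desk-scale proteins (L=30, 50 evolved homologs + 25 pure-noise
sequences each), then compares mutual information at the planted
(co-evolving) contact pairs against the background pairs: the gap is the
statistical footprint that covariance-based contact prediction relies on.
"""

import numpy as np

from coevonet import SyntheticSpec, make_suite
from coevonet import features as F

spec = SyntheticSpec(n_proteins=8, seed=42)
suite = make_suite(spec)
print(f"generated {len(suite.proteins)} proteins, folds of sizes "
      f"{[len(f) for f in suite.folds]}")

protein = suite.proteins[0]
enc = protein.enc
print(f"\n{protein.identifier}: alignment {enc.depth} x {enc.length} "
      f"({int(protein.noise_mask.sum())} noise rows), "
      f"{len(protein.planted_pairs)} planted contact pairs")

single, pair = F.weighted_frequencies(enc, np.ones(enc.depth))
mi = F.mutual_information(pair, single)
ii, jj = np.triu_indices(enc.length, k=6)
planted = set(protein.planted_pairs)
bg = np.array([mi[i, j] for i, j in zip(ii, jj) if (i, j) not in planted])
pl = np.array([mi[i, j] for i, j in planted])
print(f"mean MI at planted pairs : {pl.mean():.3f} nats")
print(f"mean MI at background    : {bg.mean():.3f} +- {bg.std():.3f} nats")
print(f"separation               : {(pl.mean() - bg.mean()) / bg.std():.1f} "
      "background standard deviations")
print("\nA large separation means the planted co-evolution is detectable "
      "from pair frequencies, i.e. the contact-prediction task is solvable.")
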