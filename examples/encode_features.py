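"""Windowed PSSM feature encoding on a tiny hand-made profile.

Builds a 9-residue profile, encodes it with the default 13-residue
sliding window, and shows where the central residue's own profile sits
inside the 260-dimensional feature vector.
"""

import numpy as np

from psrsm import encode_windows
from psrsm.io import central_block, scale_pssm

rng = np.random.default_rng(0)
pssm = rng.integers(-8, 9, size=(9, 20)).astype(float)

features = encode_windows(pssm, w=13, scaling="sigmoid")
lo, hi = central_block(13)

print(f"profile shape       : {pssm.shape}  (L residues x 20 amino-acid columns)")
print(f"feature matrix shape: {features.shape}  (one 260-dim row per residue)")
print(f"central block       : columns {lo}..{hi} (1-based)")
ok = np.allclose(features[:, lo - 1:hi], scale_pssm(pssm, "sigmoid"))
print(f"central block equals the scaled profile row: {ok}")

# residue 1 sits at the N-terminus: six of its thirteen window positions
# fall outside the chain and are zero-padded
blocks = features[0].reshape(13, 20)
n_zero = sum(bool(np.all(b == 0)) for b in blocks)
print(f"zero-padded 20-blocks for residue 1: {n_zero} (window runs off the terminus)")
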