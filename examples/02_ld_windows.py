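"""Anatomy of a seed-anchored LD window.

Builds a small block-LD panel, picks a seed SNP, and shows the correlation of
each neighbour with the seed next to the resulting window membership: the
walk admits |r| >= 0.1 neighbours, rescues a single failing SNP when a
passing one lies beyond it, and stops after two consecutive failures.
"""

import numpy as np

from pleiocov import SimConfig, define_window, make_segments, simulate_genotypes

cfg = SimConfig(n_individuals=800, n_snps=60, block_lengths=(6, 12),
                within_block_rho=0.8, rng_seed=7)
panel = simulate_genotypes(cfg)
X = panel.dosages.astype(float)
X -= X.mean(0)
seg = make_segments(panel)[0]

seed = 30
w = define_window(X, seg, seed, threshold=0.1)
print(f"seed SNP index {seed} (block {panel.snp_map['block'].iat[seed]})")
print(f"window members: {w.member_indices[0]}..{w.member_indices[-1]} "
      f"({w.n_snps} SNPs)")
print(" idx  |r(seed,.)|  member")
for j in range(max(0, seed - 8), min(60, seed + 9)):
    r = np.corrcoef(X[:, seed], X[:, j])[0, 1]
    mark = "*" if j in w.member_indices else " "
    print(f"  {j:3d}   {abs(r):9.3f}     {mark}")
# SNPs marked * form one contiguous run around the seed; every member either
# passes the 0.1 threshold itself or is a rescued single gap between passes.
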