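"""Pool per-sample full-length ASV sets and measure coverage.

Builds a small synthetic community, pools growing numbers of samples and
prints the accumulation curve, plus the closed-form expected richness at
reduced read depth for one abundance vector.
"""

import numpy as np

import refforge as rf

world = rf.make_world(n_taxa=30, n_samples=6, taxa_per_sample=12, root_length=900, seed=7)
per_sample = world.per_sample_asvs()

curve = rf.sample_accumulation(per_sample, ks=[1, 2, 4, 6], replicates=20, seed=1)
print("samples pooled -> mean distinct ASVs (sd):")
for k, mean, sd in zip(curve.x, curve.mean_richness, curve.sd):
    print(f"  k={k}: {mean:6.1f} ({sd:.1f})")
print("Richness grows with the number of pooled samples: single samples miss")
print("taxa that a pooled reference recovers.")

counts = np.array([40, 20, 10, 8, 5, 3, 2, 1, 1])
for depth in (10, 30, 60, int(counts.sum())):
    print(f"expected richness at depth {depth}: "
          f"{rf.rarefaction_expected(counts, depth):.2f}")
print("The rarefaction expectation shows how much richness a shallower")
print("sequencing run would have observed.")
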