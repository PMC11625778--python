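"""Shrink a redundant reference DB by pendant-branch trimming.

Plants 3 near-duplicate ASVs per taxon, builds a neighbor-joining tree
from pairwise Jukes-Cantor distances, runs the trim-sweep optimization
and prints the size/identity trade-off at each threshold.
"""

import refforge as rf
from refforge.pipeline import RunConfig

world = rf.make_world(n_taxa=10, n_samples=4, root_length=900, seed=2)
records, truth = rf.plant_redundancy(world, 3, 0.0012, seed=3)
db = rf.ReferenceDB(
    records=records,
    taxonomy={r.id: world.taxonomy[truth[r.id]] for r in records},
)
reads, _ = rf.simulate_reads(world, "S1", "v3v4", depth=30, error_rate=0.005, seed=5)

result = rf.optimize_db(db, reads, RunConfig())
print(f"input DB: {len(db)} ASVs ({len(world.taxa)} true taxa x 4 near-duplicates)")
for row in result.sweep:
    print(f"  threshold {row['threshold']:g}: {row['n_asvs']} ASVs, "
          f">=97% fraction {row['high_identity_fraction']:.2f} "
          f"(drop {row['drop_points']:.1f} pts)")
print(f"chosen threshold {result.chosen_threshold:g}: "
      f"{len(result.db)}/{len(db)} ASVs retained")
print("The sweep keeps the largest threshold whose search performance stays")
print("within 2 points of the untrimmed DB — here redundancy collapses to one")
print("representative per taxon with no loss of species-level identity.")
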