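"""TSS metagene profiles and promoter occupancy graded by gene expression.

Builds a panel of promoters whose planted nucleosome-binding strength grows
with expression decile, simulates ChIP fragments, and shows that per-decile
promoter occupancy (midpoints in the -500..+250 window around each TSS)
increases monotonically with expression.
"""

import numpy as np
import pandas as pd

from nucmeth import fragments, profiles, synth
from nucmeth.intervals import IntervalSet

rng = np.random.default_rng(3)
genome = synth.make_genome(1, 400_000, gc_content=0.45, seed=3)

genes, dyad_rows, expr_rows = [], [], []
for d in range(1, 11):
    for k in range(20):
        pos = 4_000 + (d - 1) * 39_000 + k * 1_800
        name = f"g{d}_{k}"
        genes.append(("chr1", pos, pos + 1, "+", 0.0, name))
        dyad_rows.append(("chr1", pos, float(d) ** 2))
        expr_rows.append((name, float(d) + rng.random()))

tss = IntervalSet(pd.DataFrame(
    genes, columns=["chrom", "start", "end", "strand", "score", "name"]))
dyads = pd.DataFrame(dyad_rows, columns=["chrom", "pos", "weight"])
expr = pd.DataFrame(expr_rows, columns=["gene_id", "expression"])

cfg = synth.SimulationConfig(seed=4, n_fragments=150_000, background_fraction=0.1)
pairs = synth.simulate_nucleosome_fragments(genome, dyads, cfg)
track, _ = fragments.midpoints_paired(pairs)

classes = profiles.expression_classes(expr)
occ = profiles.promoter_occupancy(track, tss)
profile = profiles.tss_profile(track, tss, flank=1000, step=5)

print("mean promoter occupancy (midpoints in -500..+250) by expression decile:")
for d in range(1, 11):
    names = classes.loc[classes["decile"] == d, "gene_id"]
    print(f"  decile {d:2d}: {occ[names].mean():8.1f}")
peak = profile.offsets[np.argmax(profile.density)]
print(f"metagene profile peak at offset {peak} bp relative to the TSS")
# Occupancy rising with decile mirrors the expression-graded promoter binding
# the profile aggregates; the peak near 0 reflects dyads planted at the TSS.
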