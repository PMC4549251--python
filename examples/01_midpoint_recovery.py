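"""Estimate nucleosome fragment length and midpoints from simulated reads.

Plants 1,000 nucleosome dyads on a 2 Mb chromosome, simulates 50,000
mononucleosomal fragment pairs around them, then recovers the mean fragment
length from forward/reverse strand cross-covariance and checks how close the
paired midpoints land to the true dyads.
"""

import numpy as np
import pandas as pd

from nucmeth import fragments, synth

rng = np.random.default_rng(0)
genome = synth.GenomeModel(["chr1"], {"chr1": 2_000_000})
dyad_pos = np.sort(rng.choice(np.arange(1_000, 1_999_000), 1_000, replace=False))
dyads = pd.DataFrame({"chrom": "chr1", "pos": dyad_pos, "weight": 1.0})

cfg = synth.SimulationConfig(
    seed=1, n_fragments=50_000, fragment_length_mean=150.0,
    fragment_length_sd=20.0, background_fraction=0.0,
)
pairs = synth.simulate_nucleosome_fragments(genome, dyads, cfg)

reads = fragments.reads_from_pairs(pairs)
reads, n_dup = fragments.deduplicate(reads)
offset = fragments.estimate_strand_offset(reads)
kept, (lo, hi) = fragments.fragment_size_filter(pairs)
track, _ = fragments.midpoints_paired(kept)

mids = track.for_chrom("chr1")
idx = np.searchsorted(dyad_pos, mids)
left = dyad_pos[np.clip(idx - 1, 0, None)]
right = dyad_pos[np.clip(idx, None, len(dyad_pos) - 1)]
dist = np.minimum(np.abs(mids - left), np.abs(mids - right))

print(f"duplicate reads removed:        {n_dup}")
print(f"strand cross-covariance offset: {offset} bp (planted mean length 150)")
print(f"size filter bounds:             ({lo:.1f}, {hi:.1f}) bp, "
      f"{100 * len(kept) / len(pairs):.1f}% retained")
print(f"midpoints within 20 bp of dyad: {100 * (dist <= 20).mean():.1f}%")
# The offset approximates the mean fragment length (the peak sits at the
# distance between mate 5' ends, length - 1); near-100% recovery shows the
# pair-midpoint estimator localizes nucleosome dyads to well under a turn of
# the nucleosomal wrap.
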