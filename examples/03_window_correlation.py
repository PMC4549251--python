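"""Windowed correlation between nucleosome-ChIP density and an external track.

Tiles a 10 Mb genome into 2 kb windows, computes the log2 ratio of ChIP
midpoints over a total-nucleosome background per window, and correlates it
with a signal track generated to correlate at r = 0.35 with the planted
per-window binding intensity — the analysis used to relate factor binding to
histone-modification landscapes.
"""

import numpy as np
import pandas as pd

from nucmeth import fragments, synth, windows

rng = np.random.default_rng(9)
n_win, width = 5_000, 2_000
genome = synth.GenomeModel(["chr1"], {"chr1": n_win * width})

intensity = rng.lognormal(0.0, 0.8, size=n_win)
dyads = pd.DataFrame(
    {"chrom": "chr1", "pos": np.arange(n_win) * width + width // 2,
     "weight": intensity}
)
cfg = synth.SimulationConfig(
    seed=10, n_fragments=400_000, background_fraction=0.0, dyad_jitter=900
)
pairs = synth.simulate_nucleosome_fragments(genome, dyads, cfg)
track, _ = fragments.midpoints_paired(pairs)
bg_pairs = synth.simulate_nucleosome_fragments(
    genome, dyads.iloc[:0],
    synth.SimulationConfig(seed=11, n_fragments=400_000, background_fraction=1.0),
)
bg_track, _ = fragments.midpoints_paired(bg_pairs)

wins = windows.tile_genome(genome, width)
density = windows.normalized_density(track, bg_track, wins, drop_empty=False)
signal = synth.simulate_signal_track(wins, 0.35, np.log2(intensity), seed=12)
r, p = windows.pearson_corr(density["log2_density"].to_numpy(), signal)

print(f"windows: {len(wins)} x {width} bp")
print(f"Pearson r between log2 midpoint density and external track: {r:.4f}")
print(f"two-sided p: {p:.3g} (planted correlation 0.35)")
# r close to the planted 0.35 shows the tiling + log-ratio normalization
# preserves genuine window-level covariation rather than inventing it.
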