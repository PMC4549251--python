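import numpy as np
import pandas as pd
import pytest

from nucmeth import synth
from nucmeth.intervals import IntervalSet


@pytest.fixture(scope="session")
def small_genome():
    return synth.make_genome(1, 50_000, gc_content=0.45, seed=42)


@pytest.fixture(scope="session")
def site_genome():
    """Genome with 400 isolated CpG/CWG sites every 2 kb on an A/T background."""
    return synth.make_site_genome(400, spacing=2000, seed=7)


@pytest.fixture(scope="session")
def planted_fragments(small_genome):
    """Fragment pairs around three weighted dyads plus 20% uniform background."""
    cfg = synth.SimulationConfig(
        seed=3, n_fragments=20_000, fragment_length_mean=150.0,
        fragment_length_sd=15.0, background_fraction=0.2,
    )
    dyads = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [10_000, 25_000, 40_000], "weight": [2.0, 1.0, 1.0]}
    )
    pairs = synth.simulate_nucleosome_fragments(small_genome, dyads, cfg)
    return pairs, dyads, cfg


def make_intervals(records):
    """records: iterable of (chrom, start, end[, strand[, score[, name]]])."""
    rows = []
    for rec in records:
        rec = list(rec) + [".", 0.0, ""][len(rec) - 3 :]
        rows.append(tuple(rec[:6]))
    return IntervalSet(
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "score", "name"]
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
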