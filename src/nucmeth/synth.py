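"""Synthetic-data generators for the whole pipeline.

Every input the analysis consumes can be generated here with known ground
truth: a random genome, nucleosomal fragment pairs drawn around planted dyads
with class-graded enrichment, a strand-resolved methylome obeying a planted
homo/hemi x CpG/CWG x coverage hierarchy, correlated per-window signal tracks,
and paired treated/untreated Infinium-style probe tables with spiked
differential sites.  Truth tables accompany every dataset so downstream
recovery tests never peek at the data itself.

All randomness flows through a single numpy Generator seeded explicitly; the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet

# Fig-4-style methylation classes, ordered from most to least expected PARP1
# binding: hemimethylated beats homomethylated, CWG beats CpG, moderate ("1",
# <=10 methylated reads) beats high ("10", >10).
METH_CLASS_ORDER = [
    "hemi-CWG1",
    "hemi-CpG1",
    "hemi-CWG10",
    "hemi-CpG10",
    "homo-CWG1",
    "homo-CWG10",
    "homo-CpG1",
    "homo-CpG10",
]

#: Default PARP1 enrichment multiplier per methylation class (relative fragment
#: rate at the site versus background).  Monotone in METH_CLASS_ORDER.
DEFAULT_METHYLATION_EFFECT = {
    "hemi-CWG1": 3.2,
    "hemi-CpG1": 2.8,
    "hemi-CWG10": 2.4,
    "hemi-CpG10": 2.0,
    "homo-CWG1": 1.7,
    "homo-CWG10": 1.45,
    "homo-CpG1": 1.25,
    "homo-CpG10": 1.1,
}


@dataclass
class GenomeModel:
    """A toy genome: chromosome names, lengths, optional sequence."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.sequence is not None:
            for name, seq in self.sequence.items():
                if len(seq) != self.chrom_lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared {self.chrom_lengths[name]} "
                        f"for {name}"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class SimulationConfig:
    """Knobs for the fragment / methylome / array simulators.

    seed fully determines every output.  Rates are relative: a dyad of weight w
    in a class with multiplier m receives fragments at rate proportional to
    w * m; `background_fraction` of fragments fall uniformly on the genome.
    """

    seed: int = 0
    n_fragments: int = 50_000
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 20.0
    background_fraction: float = 0.1
    dyad_jitter: int = 10  # fragment centers jitter uniformly within +/- this
    enrichment_by_class: dict[str, float] = field(default_factory=dict)
    methylation_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_EFFECT)
    )
    dm_effect_size: float = 1.5  # |log2 fold change| of spiked probes

    def __post_init__(self) -> None:
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        for name, rate in {**self.enrichment_by_class, **self.methylation_effect}.items():
            if rate < 0:
                raise ValueError(f"negative rate for class {name}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_genome(
    n_chroms: int, length: int, gc_content: float = 0.41, seed: int = 0
) -> GenomeModel:
    """Generate a genome of i.i.d. nucleotides at the requested GC fraction.

    Parameters
    ----------
    n_chroms, length
        Number of chromosomes and length (bp) of each.
    gc_content
        Stationary G+C fraction, strictly between 0 and 1 exclusive is not
        required: 1.0 yields all-G/C, 0.0 all-A/T.
    """
    if n_chroms <= 0 or length < 10_000:
        raise ValueError("need n_chroms >= 1 and length >= 10,000")
    if not 0 <= gc_content <= 1:
        raise ValueError("gc_content must be within [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {}
    for name in names:
        draws = rng.choice(alphabet, size=length, p=[at, gc, gc, at])
        seqs[name] = draws.tobytes().decode("ascii")
    return GenomeModel(names, {n: length for n in names}, seqs)


def make_site_genome(
    n_sites: int,
    spacing: int = 2000,
    cwg_fraction: float = 0.5,
    seed: int = 0,
) -> GenomeModel:
    """Genome with isolated CpG/CWG sites planted at a regular spacing.

    The background sequence is random A/T only, so the planted motifs (CG, or
    CAG/CTG for CWG) are the genome's only methylation-context sites.  Useful
    for enrichment experiments where neighboring sites must not share their
    profile windows.
    """
    if n_sites < 1 or spacing < 10:
        raise ValueError("need n_sites >= 1 and spacing >= 10")
    rng = np.random.default_rng(seed)
    length = max((n_sites + 1) * spacing, 10_000)
    at = np.frombuffer(b"AT", dtype=np.uint8)
    seq = rng.choice(at, size=length)
    positions = (np.arange(n_sites) + 1) * spacing
    is_cwg = rng.random(n_sites) < cwg_fraction
    for pos, cwg in zip(positions, is_cwg):
        if cwg:
            w = b"A" if rng.random() < 0.5 else b"T"
            seq[pos : pos + 3] = np.frombuffer(b"C" + w + b"G", dtype=np.uint8)
        else:
            seq[pos : pos + 2] = np.frombuffer(b"CG", dtype=np.uint8)
    text = seq.tobytes().decode("ascii")
    return GenomeModel(["chr1"], {"chr1": length}, {"chr1": text})


def simulate_nucleosome_fragments(
    genome: GenomeModel,
    dyads: pd.DataFrame,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Draw fragment pairs centered on weighted dyads plus uniform background.

    `dyads` needs columns (chrom, pos, weight).  Each planted fragment's center
    is its dyad plus uniform jitter in [-dyad_jitter, +dyad_jitter]; lengths are
    normal(fragment_length_mean, fragment_length_sd) clipped at 20 bp.  Returns
    a pair table with columns (chrom, start, end, name, length, strand) in
    0-based half-open coordinates; `strand` is the strand of the first-sequenced
    mate (uniform random, carried for BED compatibility).
    """
    if len(dyads) == 0 and cfg.background_fraction == 0:
        raise ValueError("no dyads and zero background: nothing to simulate")
    if len(dyads):
        for _, row in dyads.drop_duplicates("chrom").iterrows():
            if row["chrom"] not in genome.chrom_lengths:
                raise ValueError(f"dyad chromosome {row['chrom']} not in genome")
        lengths = np.array([genome.chrom_lengths[c] for c in dyads["chrom"]])
        if ((dyads["pos"] < 0) | (dyads["pos"] >= lengths)).any():
            raise ValueError("dyad position outside chromosome bounds")

    rng = cfg.rng()
    n = cfg.n_fragments
    n_bg = int(round(n * cfg.background_fraction)) if len(dyads) else n
    n_planted = n - n_bg

    chroms: list[np.ndarray] = []
    centers: list[np.ndarray] = []

    if n_planted > 0 and len(dyads):
        w = dyads["weight"].to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("negative dyad weight")
        idx = rng.choice(len(dyads), size=n_planted, p=w / w.sum())
        jitter = (
            rng.integers(-cfg.dyad_jitter, cfg.dyad_jitter + 1, size=n_planted)
            if cfg.dyad_jitter > 0
            else np.zeros(n_planted, dtype=np.int64)
        )
        chroms.append(dyads["chrom"].to_numpy()[idx])
        centers.append(dyads["pos"].to_numpy()[idx] + jitter)

    if n_bg > 0:
        lens = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
        which = rng.choice(len(genome.chrom_names), size=n_bg, p=lens / lens.sum())
        pos = rng.integers(0, lens[which].astype(np.int64))
        chroms.append(np.array(genome.chrom_names, dtype=object)[which])
        centers.append(pos)

    chrom = np.concatenate(chroms)
    center = np.concatenate(centers).astype(np.int64)
    frag_len = np.maximum(
        20, np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n))
    ).astype(np.int64)
    start = center - frag_len // 2
    end = start + frag_len
    # clip to chromosome bounds, preserving length where possible
    bounds = np.array([genome.chrom_lengths[c] for c in chrom])
    shift = np.where(start < 0, -start, 0) - np.where(end > bounds, end - bounds, 0)
    start = start + shift
    end = end + shift
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "name": [f"frag{i}" for i in range(n)],
            "length": frag_len,
            "strand": strand,
        }
    )


def _complement_matches_cwg(seq: str, p: int) -> bool:
    return seq[p] == "C" and seq[p + 1] in "AT" and seq[p + 2] == "G"


def find_methylation_sites(genome: GenomeModel) -> pd.DataFrame:
    """Scan the genome sequence for CpG and CWG sites.

    Returns one row per site with the plus-strand cytosine position.  A CpG at
    p pairs its minus-strand cytosine at p+1; a CWG (W = A/T) at p pairs at
    p+2 (the minus strand of CWG is again CWG).
    """
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    rows = []
    for chrom in genome.chrom_names:
        seq = genome.sequence[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        c = arr == ord("C")
        g = arr == ord("G")
        w = (arr == ord("A")) | (arr == ord("T"))
        cpg = np.flatnonzero(c[:-1] & g[1:])
        cwg = np.flatnonzero(c[:-2] & w[1:-1] & g[2:]) if len(arr) >= 3 else np.array([], int)
        for pos in cpg:
            rows.append((chrom, int(pos), "CpG"))
        for pos in cwg:
            rows.append((chrom, int(pos), "CWG"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_methylome(
    genome: GenomeModel,
    cfg: SimulationConfig,
    hemi_fraction: float = 0.5,
    high_fraction: float = 0.5,
    mean_coverage: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit strand-resolved methylation calls at every CpG/CWG site.

    Each site is randomly assigned a symmetry (hemi with probability
    `hemi_fraction`, else homo) and a coverage level (high with probability
    `high_fraction`).  High sites receive enough methylated reads to exceed the
    >10-read rule, moderate sites stay below it.  Methylated strands report
    ~90% methylation, unmethylated strands ~5%.

    Returns (calls, truth): `calls` has one row per strand-cytosine with
    columns (chrom, pos, strand, context, coverage, pct_meth); `truth` has one
    row per site with its planted class label (e.g. "hemi-CWG1").
    """
    sites = find_methylation_sites(genome)
    rng = cfg.rng()
    n = len(sites)
    hemi = rng.random(n) < hemi_fraction
    high = rng.random(n) < high_fraction
    # methylated-read budget: high sites must sum > 10 across strands, moderate <= 10
    call_rows = []
    truth_rows = []
    for i, row in enumerate(sites.itertuples(index=False)):
        ctx = row.context
        partner_off = 1 if ctx == "CpG" else 2
        is_hemi = bool(hemi[i])
        is_high = bool(high[i])
        if is_high:
            cov = int(rng.poisson(max(mean_coverage, 14.0))) + 14
        else:
            # capped so the methylated-read mass stays at or below the
            # >10-read boundary, keeping truth and derived level consistent
            cov = min(int(rng.poisson(4.0)) + 2, 10)
        cov_plus = max(1, cov // 2)
        cov_minus = max(1, cov - cov_plus)
        pm_meth = float(np.clip(rng.normal(90.0, 4.0), 60.0, 100.0))
        pm_unmeth = float(np.clip(rng.normal(5.0, 2.0), 0.0, 30.0))
        if is_hemi:
            meth_plus = bool(rng.random() < 0.5)
            pct_plus = pm_meth if meth_plus else pm_unmeth
            pct_minus = pm_unmeth if meth_plus else pm_meth
        else:
            pct_plus = pct_minus = pm_meth
        call_rows.append((row.chrom, row.pos, "+", ctx, cov_plus, round(pct_plus, 2)))
        call_rows.append(
            (row.chrom, row.pos + partner_off, "-", ctx, cov_minus, round(pct_minus, 2))
        )
        sym = "hemi" if is_hemi else "homo"
        ctx_label = "CpG" if ctx == "CpG" else "CWG"
        level = "10" if is_high else "1"
        truth_rows.append(
            (row.chrom, row.pos, ctx, sym, "high" if is_high else "moderate",
             f"{sym}-{ctx_label}{level}")
        )
    calls = pd.DataFrame(
        call_rows, columns=["chrom", "pos", "strand", "context", "coverage", "pct_meth"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "context", "symmetry", "level", "class"]
    )
    return calls, truth


def dyads_from_methylation_truth(
    truth: pd.DataFrame, cfg: SimulationConfig
) -> pd.DataFrame:
    """Turn a methylome truth table into weighted dyads for the fragment simulator.

    Each site becomes a dyad at its cytosine position, weighted by the PARP1
    enrichment multiplier of its planted class (cfg.methylation_effect).
    """
    weights = truth["class"].map(cfg.methylation_effect)
    if weights.isna().any():
        missing = truth["class"][weights.isna()].unique()
        raise ValueError(f"no methylation_effect for classes: {list(missing)}")
    return pd.DataFrame(
        {"chrom": truth["chrom"], "pos": truth["pos"], "weight": weights.to_numpy(float)}
    )


def simulate_signal_track(
    windows: IntervalSet,
    target_corr: float,
    reference: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Per-window values with Pearson correlation ~= target_corr to `reference`.

    Constructed as rho * z + sqrt(1 - rho^2) * noise on the standardized
    reference; at >= 2,000 windows the sample r lands within +/-0.05 of the
    target.  |target_corr| = 1 returns an exact affine transform.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) != len(windows):
        raise ValueError("reference length must match window count")
    if np.ptp(reference) == 0:
        raise ValueError("reference signal is constant")
    if not -1 <= target_corr <= 1:
        raise ValueError("|target_corr| must be <= 1")
    z = (reference - reference.mean()) / reference.std()
    if abs(target_corr) == 1.0:
        return np.sign(target_corr) * z
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(z))
    # project noise orthogonal to z so the sample correlation concentrates tightly
    noise = noise - noise.mean()
    noise = noise - (noise @ z) / (z @ z) * z
    noise = noise / noise.std()
    return target_corr * z + np.sqrt(1.0 - target_corr**2) * noise


def simulate_450k(
    n_probes: int,
    annotations: pd.DataFrame | None = None,
    cfg: SimulationConfig | None = None,
    n_spiked_hyper: int = 0,
    n_spiked_hypo: int = 0,
    n_replicates: int = 2,
    noise_precision: float = 2000.0,
    n_failing: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired untreated/treated Infinium-style probe tables with spiked effects.

    Baseline beta per probe comes from an equal mixture of Beta(2, 12) and
    Beta(12, 2) (modes near 0.1 and 0.9, matching the bimodal shape of array
    methylation).  Spiked hyper probes multiply treated beta by
    2**dm_effect_size, spiked hypo probes divide; candidates are restricted so
    the shift stays inside (0, 1) without clipping, and any residual clip is
    recorded in the truth table.  Replicate betas are drawn from
    Beta(base * noise_precision, (1 - base) * noise_precision) — intensity-like
    noise whose standard deviation shrinks toward the 0/1 extremes, as on
    arrays.  `n_failing` probes get detection p = 0.5 in one treated
    replicate.

    Returns (table, truth).  `table` is long-form with columns (probe_id,
    chrom, pos, gene, region, island_relation, sample, condition, beta,
    detection_p); `truth` lists each probe's spiked direction ("hyper",
    "hypo" or "none").
    """
    if n_probes < 1:
        raise ValueError("need at least one probe")
    if n_spiked_hyper + n_spiked_hypo > n_probes:
        raise ValueError("spiked fraction exceeds 1")
    cfg = cfg or SimulationConfig()
    rng = cfg.rng()
    comp = rng.random(n_probes) < 0.5
    beta0 = np.where(
        comp, rng.beta(2.0, 12.0, size=n_probes), rng.beta(12.0, 2.0, size=n_probes)
    )
    effect = 2.0**cfg.dm_effect_size
    # spike candidates whose shifted value stays comfortably inside (0, 1)
    ok_hyper = np.flatnonzero((beta0 * effect < 0.95) & (beta0 > 0.01))
    ok_hypo = np.flatnonzero(beta0 / effect > 0.005)
    if len(ok_hyper) < n_spiked_hyper or len(ok_hypo) < n_spiked_hypo:
        raise ValueError("not enough probes admit the requested spike without clipping")
    hyper_idx = rng.choice(ok_hyper, size=n_spiked_hyper, replace=False)
    remaining = np.setdiff1d(ok_hypo, hyper_idx)
    hypo_idx = rng.choice(remaining, size=n_spiked_hypo, replace=False)

    beta_treated = beta0.copy()
    beta_treated[hyper_idx] = beta0[hyper_idx] * effect
    beta_treated[hypo_idx] = beta0[hypo_idx] / effect
    clipped = (beta_treated <= 0) | (beta_treated >= 1)
    beta_treated = np.clip(beta_treated, 1e-4, 1 - 1e-4)

    direction = np.full(n_probes, "none", dtype=object)
    direction[hyper_idx] = "hyper"
    direction[hypo_idx] = "hypo"

    if annotations is None:
        annotations = pd.DataFrame(
            {
                "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
                "chrom": "chr1",
                "pos": np.arange(n_probes) * 1000 + 500,
                "gene": [f"GENE{i // 4}" for i in range(n_probes)],
                "region": "gene body",
                "island_relation": "open sea",
            }
        )
    if len(annotations) != n_probes:
        raise ValueError("annotation table length must equal n_probes")

    fail_idx = rng.choice(n_probes, size=n_failing, replace=False) if n_failing else []

    frames = []
    for cond, base in (("untreated", beta0), ("treated", beta_treated)):
        for rep in range(1, n_replicates + 1):
            a = np.clip(base, 1e-4, 1 - 1e-4) * noise_precision
            b = noise_precision - a
            noisy = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
            detp = np.full(n_probes, 0.001)
            if cond == "treated" and rep == 1 and len(fail_idx):
                detp[fail_idx] = 0.5
            sub = annotations.copy()
            sub["sample"] = f"{cond}_{rep}"
            sub["condition"] = cond
            sub["beta"] = noisy
            sub["detection_p"] = detp
            frames.append(sub)
    table = pd.concat(frames, ignore_index=True)
    truth = annotations[["probe_id"]].copy()
    truth["direction"] = direction
    truth["clipped"] = clipped
    return table, truth
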