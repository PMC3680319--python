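"""Seedable generators for genomes, probe tilings, and two-channel arrays.

The simulator is the test bed for the whole pipeline: it emits a
CpG-heterogeneous genome, a CHARM-style probe tiling concentrated on
CpG-containing windows, and two-channel intensity tables for two tissue
groups with planted differentially methylated regions (DMRs) of known
location, direction, and effect size.

The generative model, per genomic probe i with CpG count c_i and planted
methylation level m (a fraction in [0, 1]):

* input channel: a per-probe log-normal baseline, shared across samples
  (probe affinity), times per-sample multiplicative noise;
* enriched channel: input times a saturating capture ratio
  ``g(x) = r_bg + (r_max - r_bg) * x / (x + k)`` with ``x = m * c_i`` —
  methyl-CpG-binding capture grows with the amount of methylated CpG in
  the fragment and saturates;
* a smooth intensity-dependent dye bias ("banana" in the M-A plane) is
  added to the log-ratio so the dye-correction stage has real work to do;
* low-input arrays get a larger multiplicative noise SD and a small
  per-probe probability that the enriched channel collapses to background
  (capture dropout).

Control probes hybridize in both channels identically (expected M = 0);
anti-genomic probes receive background-only intensities in both channels.
Every function is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import (
    NON_GENOMIC_CHROM,
    ArraySample,
    ExperimentBundle,
    GenomeSequence,
    ProbeSet,
    SimulationTruth,
)

_BASES = "ACGT"

# per-channel log2 intensity distributions
_GENOMIC_LOG2_MEAN = 10.0
_GENOMIC_LOG2_SD = 1.0
_BACKGROUND_LOG2_MEAN = 7.0
_BACKGROUND_LOG2_SD = 0.7

# anchors of the intensity-dependent dye-bias curve in A = mean log2 intensity
_BIAS_A_LO = 6.0
_BIAS_A_HI = 14.0


def generate_genome(
    length: int,
    island_fraction: float,
    seed: int,
    island_length: int = 2000,
    name: str = "chrSim",
    p_cg_island: float = 0.20,
    p_cg_background: float = 0.003,
) -> GenomeSequence:
    """Generate a CpG-heterogeneous chromosome.

    The sequence is a two-state first-order nucleotide process: after a C,
    the next base is G with probability ``p_cg_island`` inside designated
    island segments and ``p_cg_background`` elsewhere (remaining mass
    spread evenly over A/C/T); after any other base the four bases are
    equiprobable. The defaults put the CpG observed/expected ratio around
    0.85 in islands and near 0.01 in background — a CpG-desert background
    against which the CpG-driven probe tiling stays sparse, so probe
    clusters concentrate on the islands.

    Islands of ``island_length`` bases are placed one per equal-width
    block at a random offset, covering ``island_fraction`` of the genome.
    """
    if length < 1000:
        raise ValueError("genome length < 1000: too short to tile probes")
    if not 0.0 <= island_fraction <= 1.0:
        raise ValueError("island_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_islands = int(round(length * island_fraction / island_length))
    islands: list[tuple[int, int]] = []
    if n_islands > 0:
        block = length // n_islands
        eff = min(island_length, block)
        for i in range(n_islands):
            lo = i * block
            s = int(rng.integers(lo, lo + block - eff + 1))
            islands.append((s, s + eff))

    in_island = np.zeros(length, dtype=bool)
    for s, e in islands:
        in_island[s:e] = True

    u = rng.random(length)
    p_cg = np.where(in_island, p_cg_island, p_cg_background)
    seq = bytearray(length)
    a, c, g, t = (ord(b) for b in "ACGT")
    prev_is_c = False
    for i in range(length):
        ui = u[i]
        if prev_is_c:
            p = p_cg[i]
            if ui < p:
                b = g
            else:
                # residual mass split evenly over A, C, T
                r = (ui - p) / (1.0 - p)
                b = a if r < 1 / 3 else (c if r < 2 / 3 else t)
        else:
            b = (a, c, g, t)[int(ui * 4.0)]
        seq[i] = b
        prev_is_c = b == c
    return GenomeSequence(name=name, sequence=seq.decode(), islands=tuple(islands))


def cpg_site_positions(sequence: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits)


def tile_probes(
    genome: GenomeSequence,
    spacing: int = 35,
    probe_length: int = 50,
    n_control: int = 500,
    n_antigenomic: int = 500,
    seed: int = 0,
) -> ProbeSet:
    """Tile CpG-containing windows of the genome with probes.

    Candidate starts sit every ``spacing`` bases; a probe is kept only if
    its footprint fully contains at least one CG dinucleotide (CpG-driven
    tiling). ``cpg_count`` is the number of CG dinucleotides fully inside
    the footprint. ``n_control`` normalization controls and
    ``n_antigenomic`` background probes, which carry no genomic
    coordinates, are appended after the genomic block.

    ``seed`` is accepted for interface uniformity; the tiling itself is a
    deterministic function of the genome.
    """
    del seed
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if probe_length < 10:
        raise ValueError("probe_length must be >= 10")
    if probe_length > genome.length:
        raise ValueError("probe longer than genome")

    cg = cpg_site_positions(genome.sequence)
    rows = []
    idx = 0
    for s in range(0, genome.length - probe_length + 1, spacing):
        # a CG at position p is fully inside [s, s+L) iff s <= p <= s+L-2
        lo = np.searchsorted(cg, s, side="left")
        hi = np.searchsorted(cg, s + probe_length - 2, side="right")
        count = int(hi - lo)
        if count >= 1:
            rows.append(
                (f"P{idx:07d}", genome.name, s, probe_length, False, False, count)
            )
            idx += 1
    for j in range(n_control):
        rows.append(
            (f"CTRL{j:05d}", NON_GENOMIC_CHROM, -1, probe_length, True, False, 0)
        )
    for j in range(n_antigenomic):
        rows.append(
            (f"ANTI{j:05d}", NON_GENOMIC_CHROM, -1, probe_length, False, True, 0)
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "chrom",
            "start",
            "length",
            "is_control",
            "is_antigenomic",
            "cpg_count",
        ],
    )
    return ProbeSet(table)


def plant_dmrs(
    genome: GenomeSequence,
    n_dmrs: int,
    seed: int,
    tissues: tuple[str, str] = ("retina", "brain"),
    meth_high: float = 0.9,
    meth_low: float = 0.1,
    baseline: float = 0.3,
    noise_sd_by_input_ng: dict[float, float] | None = None,
    dropout_by_input_ng: dict[float, float] | None = None,
) -> SimulationTruth:
    """Plant ``n_dmrs`` differential intervals on the genome's CpG islands.

    Each chosen island becomes a DMR hypermethylated (``meth_high``) in
    one tissue and hypomethylated (``meth_low``) in the other; everywhere
    else both tissues sit at ``baseline``. Directions are assigned as a
    random but balanced split (half up in each tissue), so the two
    groups' M-value distributions stay comparable — the situation
    between-sample quantile normalization assumes, and roughly what real
    tissue pairs show.
    """
    if n_dmrs > len(genome.islands):
        raise ValueError(
            f"cannot plant {n_dmrs} DMRs: genome has {len(genome.islands)} islands"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(genome.islands), size=n_dmrs, replace=False))
    intervals = tuple(
        (genome.name, genome.islands[i][0], genome.islands[i][1]) for i in chosen
    )
    up_in_first = rng.permutation(
        np.arange(n_dmrs) < (n_dmrs + 1) // 2
    )
    lv1 = tuple(meth_high if u else meth_low for u in up_in_first)
    lv2 = tuple(meth_low if u else meth_high for u in up_in_first)
    kwargs = {}
    if noise_sd_by_input_ng is not None:
        kwargs["noise_sd_by_input_ng"] = noise_sd_by_input_ng
    if dropout_by_input_ng is not None:
        kwargs["dropout_by_input_ng"] = dropout_by_input_ng
    return SimulationTruth(
        dmr_intervals=intervals,
        methylation_per_tissue={tissues[0]: lv1, tissues[1]: lv2},
        baseline_methylation=baseline,
        seed=seed,
        **kwargs,
    )


def probe_methylation(
    probes: ProbeSet, truth: SimulationTruth
) -> dict[str, np.ndarray]:
    """Planted methylation level per probe per tissue (probe midpoint rule).

    A probe belongs to a DMR interval when its footprint midpoint falls
    inside the half-open interval; all other probes take the baseline.
    """
    t = probes.table
    mid = (t["start"] + t["length"] // 2).to_numpy()
    chroms = t["chrom"].to_numpy()
    out = {
        tissue: np.full(len(t), truth.baseline_methylation)
        for tissue in truth.tissues
    }
    for k, (chrom, start, end) in enumerate(truth.dmr_intervals):
        inside = (chroms == chrom) & (mid >= start) & (mid < end)
        for tissue in truth.tissues:
            out[tissue][inside] = truth.methylation_per_tissue[tissue][k]
    return out


def capture_ratio(
    x: np.ndarray, r_background: float = 0.2, r_max: float = 4.0, k_half: float = 2.0
) -> np.ndarray:
    """Saturating enriched/input ratio ``r_bg + (r_max-r_bg) * x/(x+k)``.

    ``x`` is the methylated-CpG content of the probe footprint
    (methylation fraction times CpG count); the ratio rises monotonically
    from ``r_background`` at x = 0 toward ``r_max``.
    """
    x = np.asarray(x, dtype=float)
    return r_background + (r_max - r_background) * x / (x + k_half)


def dye_bias(a_values: np.ndarray, strength: float) -> np.ndarray:
    """Smooth additive M-bias as a function of mean log intensity A.

    Half-sine bump between fixed A anchors: zero at the extremes of the
    intensity range and ``strength`` log2 units at its middle — the
    classic banana shape a loess-style correction must remove.
    """
    frac = np.clip(
        (np.asarray(a_values, float) - _BIAS_A_LO) / (_BIAS_A_HI - _BIAS_A_LO), 0, 1
    )
    return strength * np.sin(math.pi * frac)


def simulate_experiment(
    genome: GenomeSequence | None,
    probes: ProbeSet,
    truth: SimulationTruth,
    n_replicates_per_tissue: int,
    input_ng: float,
    seed: int,
    dye_bias_strength: float = 0.4,
    r_background: float = 0.2,
    r_max: float = 4.0,
    k_half: float = 2.0,
) -> list[ArraySample]:
    """Simulate one array group: all tissues x replicates at one input mass.

    The per-probe input baseline is drawn once and shared by every sample
    (probe affinity is a property of the probe); per-sample noise, dye
    bias, and dropout are layered on top. The enriched-channel expectation
    depends on the genome only through each probe's CpG count, so
    ``genome`` may be None.
    """
    del genome
    if n_replicates_per_tissue < 1:
        raise ValueError("need at least one replicate per tissue")
    if input_ng not in truth.noise_sd_by_input_ng:
        raise ValueError(
            f"unknown input mass {input_ng} ng; known: "
            f"{sorted(truth.noise_sd_by_input_ng)}"
        )
    rng = np.random.default_rng(seed)
    t = probes.table
    n = len(t)
    is_anti = t["is_antigenomic"].to_numpy()
    is_ctrl = t["is_control"].to_numpy()
    is_gen = ~is_anti & ~is_ctrl
    cpg = t["cpg_count"].to_numpy().astype(float)

    log2_input_base = np.where(
        is_anti,
        rng.normal(_BACKGROUND_LOG2_MEAN, _BACKGROUND_LOG2_SD, n),
        rng.normal(_GENOMIC_LOG2_MEAN, _GENOMIC_LOG2_SD, n),
    )
    meth = probe_methylation(probes, truth)
    sd = float(truth.noise_sd_by_input_ng[input_ng])
    p_drop = float(truth.dropout_by_input_ng.get(input_ng, 0.0))

    samples: list[ArraySample] = []
    for tissue in truth.tissues:
        ratio = capture_ratio(meth[tissue] * cpg, r_background, r_max, k_half)
        ratio[is_ctrl] = 1.0
        for rep in range(1, n_replicates_per_tissue + 1):
            log2_inp = log2_input_base.copy()
            log2_enr = log2_input_base + np.log2(ratio)
            log2_enr[is_anti] = rng.normal(
                _BACKGROUND_LOG2_MEAN, _BACKGROUND_LOG2_SD, int(is_anti.sum())
            )
            if dye_bias_strength != 0.0:
                a = 0.5 * (log2_inp + log2_enr)
                log2_enr = log2_enr + dye_bias(a, dye_bias_strength)
            if sd > 0.0:
                log2_inp = log2_inp + rng.normal(0.0, sd, n)
                log2_enr = log2_enr + rng.normal(0.0, sd, n)
            if p_drop > 0.0:
                drop = (rng.random(n) < p_drop) & is_gen
                if drop.any():
                    log2_enr[drop] = rng.normal(
                        _BACKGROUND_LOG2_MEAN, _BACKGROUND_LOG2_SD, int(drop.sum())
                    )
            samples.append(
                ArraySample(
                    sample_id=f"{tissue}_{input_ng:g}ng_rep{rep}",
                    tissue=tissue,
                    input_ng=input_ng,
                    replicate=rep,
                    input_intensity=np.exp2(log2_inp),
                    enriched_intensity=np.exp2(log2_enr),
                )
            )
    return samples


def recovery_summary(regions, truth: SimulationTruth) -> dict[str, float]:
    """Score called regions against the planted truth.

    A planted interval counts as recovered when at least one called
    region overlaps it (any overlap, half-open) with the planted
    direction (sign of tissue1 - tissue2 methylation, tissues in
    declaration order); a call is spurious when it overlaps no planted
    interval at all.
    """
    t1, t2 = truth.tissues[0], truth.tissues[1]
    lv1 = truth.methylation_per_tissue[t1]
    lv2 = truth.methylation_per_tissue[t2]

    def overlaps(r, chrom, start, end):
        return r.chrom == chrom and r.start < end and start < r.end

    n_rec = 0
    for k, (chrom, start, end) in enumerate(truth.dmr_intervals):
        want = 1 if lv1[k] > lv2[k] else -1
        if any(
            overlaps(r, chrom, start, end) and r.direction == want for r in regions
        ):
            n_rec += 1
    n_spur = sum(
        1
        for r in regions
        if not any(overlaps(r, *iv) for iv in truth.dmr_intervals)
    )
    n_called = len(regions)
    n_planted = len(truth.dmr_intervals)
    return {
        "n_planted": n_planted,
        "n_called": n_called,
        "n_recovered": n_rec,
        "n_spurious": n_spur,
        "recovered_fraction": n_rec / n_planted if n_planted else float("nan"),
        "spurious_fraction": n_spur / n_called if n_called else 0.0,
    }


def simulate_bundle(
    genome: GenomeSequence,
    probes: ProbeSet,
    truth: SimulationTruth,
    n_replicates_per_tissue: int,
    input_ng: float,
    seed: int,
    **kwargs,
) -> ExperimentBundle:
    """Convenience wrapper returning an :class:`ExperimentBundle`."""
    samples = simulate_experiment(
        genome, probes, truth, n_replicates_per_tissue, input_ng, seed, **kwargs
    )
    return ExperimentBundle(probes=probes, samples=samples, genome=genome)
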