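"""CpG-landscape annotation: observed/expected CpG ratio and local density.

Two sequence statistics characterize where a called region sits in the
CpG landscape:

* ``CpG O/E = N_CpG / (N_C * N_G) * L`` — the observed-to-expected CpG
  ratio of the region's own sequence (values above ~0.6 are
  CpG-island-like);
* local CpG density — for one nucleotide, the triangularly weighted count
  of CpG sites within +/- ``half_window`` bases (weight 1 at the
  nucleotide, falling linearly to 0 at the window boundary); for a
  region, the mean of that quantity over every nucleotide in the region.

CpG sites are anchored at the C of the CG dinucleotide; CpG is
palindromic so no strand handling is needed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import cpg_site_positions
from .types import CpGStats, GenomeSequence, TDMR


def cpg_counts(sequence: str) -> tuple[int, int, int, int]:
    """(N_CpG, N_C, N_G, L) for a sequence; N bases excluded from all counts.

    An N breaks a potential CG dinucleotide and does not contribute to L.
    """
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    length = len(seq) - seq.count("N")
    n_cpg = seq.count("CG")
    return n_cpg, n_c, n_g, length


def cpg_oe(sequence: str) -> float:
    """Observed/expected CpG ratio ``N_CpG / (N_C * N_G) * L``.

    Degenerate sequences (no C or no G) have an undefined ratio and
    return 0.0; use :func:`cpg_stats` to see the degeneracy flag.
    """
    return cpg_stats(sequence).cpg_oe


def cpg_stats(sequence: str) -> CpGStats:
    """Full composition statistics for one sequence."""
    if len(sequence) < 2:
        raise ValueError("sequence shorter than 2 bases")
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    n_cpg, n_c, n_g, length = cpg_counts(sequence)
    if n_c == 0 or n_g == 0:
        return CpGStats(
            n_cpg=n_cpg, n_c=n_c, n_g=n_g, length=length, cpg_oe=0.0, degenerate=True
        )
    oe = n_cpg / (n_c * n_g) * length
    return CpGStats(n_cpg=n_cpg, n_c=n_c, n_g=n_g, length=length, cpg_oe=oe)


def local_cpg_density(
    genome: GenomeSequence,
    position: int,
    half_window: int = 300,
    _cpg_positions: np.ndarray | None = None,
) -> float:
    """Triangular-weighted CpG count around one nucleotide.

    Every CpG site (anchored at its C) at offset d with |d| <= half_window
    contributes weight ``1 - |d| / half_window``. Windows truncated at
    chromosome ends simply use the in-bounds sites. ``_cpg_positions``
    lets batch callers reuse a precomputed site index.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if not 0 <= position < genome.length:
        raise ValueError(f"position {position} outside genome of {genome.length} bp")
    cg = (
        cpg_site_positions(genome.sequence)
        if _cpg_positions is None
        else _cpg_positions
    )
    lo = np.searchsorted(cg, position - half_window, side="left")
    hi = np.searchsorted(cg, position + half_window, side="right")
    offsets = np.abs(cg[lo:hi] - position)
    return float(np.sum(1.0 - offsets / half_window))


def region_local_density(
    genome: GenomeSequence,
    start: int,
    end: int,
    half_window: int = 300,
    _cpg_positions: np.ndarray | None = None,
) -> float:
    """Mean local CpG density over every nucleotide in [start, end)."""
    if not (0 <= start < end <= genome.length):
        raise ValueError(f"region {start}-{end} outside genome of {genome.length} bp")
    cg = (
        cpg_site_positions(genome.sequence)
        if _cpg_positions is None
        else _cpg_positions
    )
    positions = np.arange(start, end)
    lo = np.searchsorted(cg, start - half_window, side="left")
    hi = np.searchsorted(cg, end - 1 + half_window, side="right")
    sites = cg[lo:hi]
    if len(sites) == 0:
        return 0.0
    # outer |site - position| table; regions and windows are short
    d = np.abs(sites[None, :] - positions[:, None])
    w = np.clip(1.0 - d / half_window, 0.0, None)
    return float(w.sum(axis=1).mean())


def annotate_region(
    genome: GenomeSequence,
    region: TDMR,
    half_window: int = 300,
    island_oe: float = 0.6,
    _cpg_positions: np.ndarray | None = None,
) -> TDMR:
    """Attach CpG O/E, local density, and the island-like flag to a region."""
    if region.chrom != genome.name:
        raise ValueError(
            f"region on {region.chrom} but genome is {genome.name}"
        )
    if not (0 <= region.start < region.end <= genome.length):
        raise ValueError(f"region {region.region_id} outside genome bounds")
    if region.end - region.start >= 2:
        stats = cpg_stats(genome.sequence[region.start : region.end])
    else:
        # single-base region: O/E undefined, reported as degenerate 0
        base = genome.sequence[region.start]
        stats = CpGStats(
            n_cpg=0, n_c=int(base == "C"), n_g=int(base == "G"),
            length=1, cpg_oe=0.0, degenerate=True,
        )
    density = region_local_density(
        genome, region.start, region.end, half_window, _cpg_positions
    )
    return region.with_annotation(
        local_density=density,
        cpg_oe=stats.cpg_oe,
        n_cpg=stats.n_cpg,
        is_island_like=bool(stats.cpg_oe > island_oe),
    )


def annotate_regions(
    genome: GenomeSequence,
    regions: Iterable[TDMR],
    half_window: int = 300,
    island_oe: float = 0.6,
) -> list[TDMR]:
    """Annotate a batch of regions, sharing one CpG site index."""
    cg = cpg_site_positions(genome.sequence)
    return [
        annotate_region(genome, r, half_window, island_oe, _cpg_positions=cg)
        for r in regions
    ]


def summarize_landscape(
    regions: Sequence[TDMR],
    island_oe: float = 0.6,
    density_bins: Sequence[float] | None = None,
    oe_bins: Sequence[float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary statistics and histograms of the CpG landscape of regions.

    Returns a dict with ``summary`` (min/max/mean of local density and
    O/E, counts of island-like regions) and histogram tables
    ``density_hist`` and ``oe_hist``.
    """
    if len(regions) == 0:
        empty = pd.DataFrame()
        return {"summary": empty, "density_hist": empty, "oe_hist": empty}
    dens = np.array([r.local_density for r in regions], dtype=float)
    oe = np.array([r.cpg_oe for r in regions], dtype=float)
    if np.isnan(dens).any() or np.isnan(oe).any():
        raise ValueError("regions must be annotated before summarizing")
    summary = pd.DataFrame(
        {
            "statistic": ["min", "max", "mean"],
            "local_density": [dens.min(), dens.max(), dens.mean()],
            "cpg_oe": [oe.min(), oe.max(), oe.mean()],
        }
    )
    summary.attrs["n_regions"] = len(regions)
    summary.attrs["n_island_like"] = int(np.sum(oe > island_oe))

    if density_bins is None:
        density_bins = np.arange(0.0, max(50.0, dens.max() + 5.0), 5.0)
    if oe_bins is None:
        oe_bins = np.arange(0.0, max(1.2, oe.max() + 0.1), 0.1)
    d_counts, d_edges = np.histogram(dens, bins=np.asarray(density_bins, float))
    o_counts, o_edges = np.histogram(oe, bins=np.asarray(oe_bins, float))
    density_hist = pd.DataFrame(
        {"bin_low": d_edges[:-1], "bin_high": d_edges[1:], "count": d_counts}
    )
    oe_hist = pd.DataFrame(
        {"bin_low": o_edges[:-1], "bin_high": o_edges[1:], "count": o_counts}
    )
    return {"summary": summary, "density_hist": density_hist, "oe_hist": oe_hist}
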