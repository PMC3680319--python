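"""Core in-memory containers shared across the pipeline.

The array experiment is represented by four objects:

* :class:`GenomeSequence` — one chromosome of plain A/C/G/T sequence.
* :class:`ProbeSet` — the array layout: genomic tiling probes plus
  non-genomic normalization controls and anti-genomic background probes.
* :class:`ArraySample` — per-probe two-channel intensities (input and
  methyl-enriched) for one hybridization, with tissue / input-mass metadata.
* :class:`MethylationMatrix` — the normalized relative-methylation values
  (log2 enriched/input), genomic probes x samples, that all downstream
  statistics operate on.

Called regions are :class:`TDMR` records; simulation ground truth is a
:class:`SimulationTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_COLUMNS = [
    "probe_id",
    "chrom",
    "start",
    "length",
    "is_control",
    "is_antigenomic",
    "cpg_count",
]

#: chromosome label used for probes that have no genomic coordinate
#: (normalization controls and anti-genomic background probes)
NON_GENOMIC_CHROM = "*"


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome over the alphabet {A, C, G, T}.

    ``islands`` optionally records the half-open intervals that the
    synthetic-genome generator designated as CpG-rich segments; it is
    metadata only and never consulted by the analysis modules.
    """

    name: str
    sequence: str
    islands: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(f"genome contains non-ACGT characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimulationTruth:
    """Planted methylation landscape and noise model for one simulation.

    ``dmr_intervals`` are half-open 0-based ``(chrom, start, end)`` tuples,
    sorted and non-overlapping. ``methylation_per_tissue`` maps each tissue
    label to one methylation fraction per interval (aligned by index).
    Probes outside every interval sit at ``baseline_methylation`` in every
    tissue, so only the planted intervals are differential.

    ``noise_sd_by_input_ng`` gives the per-channel multiplicative
    (log2-scale) noise SD for each supported DNA input mass;
    ``dropout_by_input_ng`` the per-probe probability that the enriched
    channel collapses to background, emulating capture failure at low input.
    """

    dmr_intervals: tuple[tuple[str, int, int], ...]
    methylation_per_tissue: Mapping[str, tuple[float, ...]]
    baseline_methylation: float = 0.3
    noise_sd_by_input_ng: Mapping[float, float] = field(
        default_factory=lambda: {250: 0.20, 50: 0.35, 25: 0.45, 10: 0.60}
    )
    dropout_by_input_ng: Mapping[float, float] = field(
        default_factory=lambda: {250: 0.0, 50: 0.02, 25: 0.05, 10: 0.08}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        prev_chrom, prev_end = None, -1
        for chrom, start, end in self.dmr_intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if chrom == prev_chrom and start < prev_end:
                raise ValueError("dmr intervals must be sorted and non-overlapping")
            prev_chrom, prev_end = chrom, end
        n = len(self.dmr_intervals)
        for tissue, levels in self.methylation_per_tissue.items():
            if len(levels) != n:
                raise ValueError(f"tissue {tissue!r}: need one level per interval")
            if any(not (0.0 <= x <= 1.0) for x in levels):
                raise ValueError(f"tissue {tissue!r}: methylation outside [0, 1]")
        if not 0.0 <= self.baseline_methylation <= 1.0:
            raise ValueError("baseline methylation outside [0, 1]")
        # noise must not shrink as input mass drops
        by_ng = sorted(self.noise_sd_by_input_ng.items())
        for (_, sd_lo), (_, sd_hi) in zip(by_ng, by_ng[1:]):
            if sd_lo < sd_hi:
                raise ValueError("noise SD must be non-increasing in input ng")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.methylation_per_tissue)


@dataclass
class ProbeSet:
    """Array layout held as a DataFrame with the ``PROBE_COLUMNS`` schema.

    Genomic probes are sorted by ``(chrom, start)``; control and
    anti-genomic probes carry the placeholder chromosome ``*`` and start
    ``-1`` and are kept after the genomic block. Intensity vectors in
    :class:`ArraySample` are aligned to ``table`` row order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        self.table = self.table[PROBE_COLUMNS].reset_index(drop=True)
        if self.table["probe_id"].duplicated().any():
            dups = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe ids: {sorted(set(dups))[:5]}")
        if (self.table["cpg_count"] < 0).any():
            raise ValueError("cpg_count must be non-negative")
        gen = self.table[self.genomic_mask]
        if not gen.sort_values(["chrom", "start"], kind="mergesort").index.equals(
            gen.index
        ):
            raise ValueError("genomic probes must be sorted by (chrom, start)")

    @property
    def genomic_mask(self) -> np.ndarray:
        return (~self.table["is_control"] & ~self.table["is_antigenomic"]).to_numpy()

    @property
    def genomic(self) -> pd.DataFrame:
        return self.table[self.genomic_mask]

    @property
    def control(self) -> pd.DataFrame:
        return self.table[self.table["is_control"].to_numpy()]

    @property
    def antigenomic(self) -> pd.DataFrame:
        return self.table[self.table["is_antigenomic"].to_numpy()]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ArraySample:
    """One two-channel hybridization: input and methyl-enriched intensities.

    Intensities are linear-scale positive reals aligned to the ProbeSet
    row order. ``signal_score`` and ``qc_flag`` are filled in by
    preprocessing (None until then).
    """

    sample_id: str
    tissue: str
    input_ng: float
    replicate: int
    input_intensity: np.ndarray
    enriched_intensity: np.ndarray
    signal_score: float | None = None
    qc_flag: bool | None = None

    def __post_init__(self) -> None:
        self.input_intensity = np.asarray(self.input_intensity, dtype=float)
        self.enriched_intensity = np.asarray(self.enriched_intensity, dtype=float)
        if self.input_intensity.shape != self.enriched_intensity.shape:
            raise ValueError("channel vectors differ in length")


@dataclass
class ExperimentBundle:
    """A ProbeSet, its aligned samples, and (optionally) the genome."""

    probes: ProbeSet
    samples: list[ArraySample]
    genome: GenomeSequence | None = None

    def __post_init__(self) -> None:
        n = len(self.probes)
        for s in self.samples:
            if len(s.input_intensity) != n:
                raise ValueError(
                    f"sample {s.sample_id}: {len(s.input_intensity)} intensities "
                    f"for {n} probes"
                )

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "input_ng": [s.input_ng for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "signal_score": [s.signal_score for s in self.samples],
                "qc_flag": [s.qc_flag for s in self.samples],
            }
        )


@dataclass
class MethylationMatrix:
    """Normalized relative methylation: genomic probes x samples.

    ``values`` is indexed by probe_id with one column per sample_id;
    ``probes`` is the matching genomic slice of the probe table (same row
    order); ``samples`` carries sample_id / tissue / input_ng / replicate.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.values.index == self.probes["probe_id"].to_numpy()).all():
            raise ValueError("matrix rows not aligned to probe table")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns not aligned to sample table")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values")

    def group_columns(self, tissue: str) -> list[str]:
        sel = self.samples.loc[self.samples["tissue"] == tissue, "sample_id"]
        return list(sel)


@dataclass
class TDMR:
    """A called tissue-specific differentially methylated region.

    Coordinates are half-open 0-based, spanning the first member probe's
    start to the last member probe's end. ``direction`` is the common sign
    of the member t statistics (+1: group1 hypermethylated). ``area`` is
    the sum of |t| over member probes; ``region_p`` a two-sided p from a
    pooled-variance t test on per-sample region-mean smoothed M.
    CpG-landscape fields are attached by annotation and None before it.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    direction: int
    delta_m: float
    area: float
    region_p: float
    cluster_id: int
    rank: int | None = None
    local_density: float | None = None
    cpg_oe: float | None = None
    n_cpg: int | None = None
    is_island_like: bool | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def with_annotation(self, **kwargs) -> "TDMR":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CpGStats:
    """Sequence-composition summary of a region.

    ``cpg_oe`` is the observed/expected CpG ratio N_CpG / (N_C * N_G) * L;
    ``local_density`` the mean triangular-weighted CpG count over the
    region's nucleotides (None when computed for a bare sequence).
    ``degenerate`` marks sequences with no C or no G, where the O/E ratio
    is undefined and reported as 0.
    """

    n_cpg: int
    n_c: int
    n_g: int
    length: int
    cpg_oe: float
    local_density: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class QpcrMeasurement:
    """Fold enrichment for methylation from QPCR threshold cycles.

    ``delta_ct`` is mean Ct(tissue1) - mean Ct(tissue2) and
    ``fold_enrichment`` is exactly ``2 ** delta_ct``: a lower Ct in
    tissue2 (earlier amplification, more captured DNA) yields fold > 1.
    """

    gene: str
    tissue1: str
    tissue2: str
    ct_tissue1: tuple[float, ...]
    ct_tissue2: tuple[float, ...]
    mean_ct1: float
    mean_ct2: float
    delta_ct: float
    fold_enrichment: float
    fold_sem: float | None = None


@dataclass(frozen=True)
class CorrelationReport:
    """Observed pairing correlation versus a shuffled-pairing null."""

    observed: float
    null_mean: float
    null_sd: float
    null_q025: float
    null_q975: float
    p_value: float
    n_regions: int
    n_perm: int
    null_values: tuple[float, ...] = ()


def regions_to_frame(regions: Sequence[TDMR]) -> pd.DataFrame:
    """Flatten TDMR records to a DataFrame (one row per region)."""
    cols = [
        "region_id",
        "chrom",
        "start",
        "end",
        "n_probes",
        "direction",
        "delta_m",
        "area",
        "region_p",
        "rank",
        "cluster_id",
        "local_density",
        "cpg_oe",
        "n_cpg",
        "is_island_like",
        "probe_ids",
    ]
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "direction": r.direction,
                "delta_m": r.delta_m,
                "area": r.area,
                "region_p": r.region_p,
                "rank": r.rank,
                "cluster_id": r.cluster_id,
                "local_density": r.local_density,
                "cpg_oe": r.cpg_oe,
                "n_cpg": r.n_cpg,
                "is_island_like": r.is_island_like,
                "probe_ids": ",".join(r.probe_ids),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def frame_to_regions(frame: pd.DataFrame) -> list[TDMR]:
    """Inverse of :func:`regions_to_frame`."""

    def _opt(v, cast):
        return None if pd.isna(v) else cast(v)

    out = []
    for _, row in frame.iterrows():
        out.append(
            TDMR(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                probe_ids=tuple(str(row["probe_ids"]).split(",")),
                direction=int(row["direction"]),
                delta_m=float(row["delta_m"]),
                area=float(row["area"]),
                region_p=float(row["region_p"]),
                cluster_id=int(row["cluster_id"]),
                rank=_opt(row.get("rank"), int),
                local_density=_opt(row.get("local_density"), float),
                cpg_oe=_opt(row.get("cpg_oe"), float),
                n_cpg=_opt(row.get("n_cpg"), int),
                is_island_like=_opt(row.get("is_island_like"), bool),
            )
        )
    return out
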