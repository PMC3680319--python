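"""Readers and writers for every on-disk format the pipeline touches.

Plain-text formats only: FASTA for the genome (via Biopython), TSV for
probe tables / intensity tables / sample manifests / region tables /
methylation matrices, and BED6 for probe and region coordinates. All
genomic coordinates are half-open 0-based, both internally and on disk.

Floats are written with ``%.10g`` so writer/reader round trips are exact
to well below 1e-9 and repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ArraySample,
    ExperimentBundle,
    GenomeSequence,
    MethylationMatrix,
    ProbeSet,
    SimulationTruth,
    TDMR,
    frame_to_regions,
    regions_to_frame,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"
#: BED score cap for -log10(p) when p underflows to 0
BED_SCORE_CAP = 320.0


def convert_vendor_export(path) -> None:
    """Stub: proprietary NimbleGen array exports are not parsed.

    Convert vendor files externally into the plain TSV schema this
    package reads: one intensity table per sample with columns
    ``probe_id``, ``input_intensity``, ``enriched_intensity`` (tab
    separated, one header row), a probe table with the columns of
    ``types.PROBE_COLUMNS``, and a sample manifest with columns
    ``sample_id``, ``tissue``, ``input_ng``, ``replicate``, ``path``.
    """
    raise NotImplementedError(
        "vendor binary formats are out of scope; see this docstring for the "
        "TSV schema to convert into"
    )


# ---------------------------------------------------------------- genome

def write_genome(genome: GenomeSequence, path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "fasta")


def read_genome(path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record")
    rec = records[0]
    return GenomeSequence(name=rec.id, sequence=str(rec.seq).upper())


# ---------------------------------------------------------------- probes

def write_probes(probes: ProbeSet, tsv_path, bed_path=None) -> None:
    """Canonical probe TSV; optionally a BED6 of the genomic probes.

    BED columns: chrom, start, end, probe_id, cpg_count, '.'; control and
    anti-genomic probes have no genomic coordinates and appear only in
    the TSV (their flags live there too).
    """
    probes.table.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        gen = probes.genomic
        bed = pd.DataFrame(
            {
                "chrom": gen["chrom"],
                "start": gen["start"],
                "end": gen["start"] + gen["length"],
                "name": gen["probe_id"],
                "score": gen["cpg_count"],
                "strand": ".",
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)


def read_probes(tsv_path) -> ProbeSet:
    table = pd.read_csv(
        tsv_path,
        sep="\t",
        dtype={
            "probe_id": str,
            "chrom": str,
            "start": int,
            "length": int,
            "is_control": bool,
            "is_antigenomic": bool,
            "cpg_count": int,
        },
    )
    return ProbeSet(table)


# --------------------------------------------------------------- samples

def write_sample_intensities(sample: ArraySample, probes: ProbeSet, path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": probes.table["probe_id"],
            "input_intensity": sample.input_intensity,
            "enriched_intensity": sample.enriched_intensity,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_manifest(samples: Sequence[ArraySample], paths: Sequence, path) -> None:
    """Sample manifest TSV: sample_id, tissue, input_ng, replicate, path."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "input_ng": [s.input_ng for s in samples],
            "replicate": [s.replicate for s in samples],
            "path": [str(p) for p in paths],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_experiment(
    bundle: ExperimentBundle, outdir, genome: GenomeSequence | None = None
) -> dict[str, Path]:
    """Write a full experiment directory (genome, probes, samples, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    genome = genome or bundle.genome
    if genome is not None:
        paths["genome"] = outdir / "genome.fa"
        write_genome(genome, paths["genome"])
    paths["probes"] = outdir / "probes.tsv"
    write_probes(bundle.probes, paths["probes"], outdir / "probes.bed")
    rel_paths = []
    for s in bundle.samples:
        p = outdir / "samples" / f"{s.sample_id}.tsv"
        write_sample_intensities(s, bundle.probes, p)
        rel_paths.append(p.relative_to(outdir))
    paths["manifest"] = outdir / "manifest.tsv"
    write_manifest(bundle.samples, rel_paths, paths["manifest"])
    return paths


def read_experiment(
    probe_path,
    sample_manifest_path,
    genome_path=None,
    intensity_floor: float = 1.0,
) -> ExperimentBundle:
    """Assemble an in-memory experiment from a probe table and manifest.

    Every intensity file must cover exactly the probe ids of the probe
    table (rows may be in any order; they are aligned to the probe table).
    Non-positive intensities are clamped to ``intensity_floor`` with a
    warning. Sample order follows the manifest. A missing genome is
    allowed; CpG annotation is then unavailable.
    """
    probes = read_probes(probe_path)
    manifest = pd.read_csv(sample_manifest_path, sep="\t")
    required = {"sample_id", "tissue", "input_ng", "replicate", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(sample_manifest_path).parent
    probe_ids = probes.table["probe_id"]
    samples = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        df = pd.read_csv(p, sep="\t", dtype={"probe_id": str})
        got = set(df["probe_id"])
        want = set(probe_ids)
        if got != want:
            missing_ids = sorted(want - got)[:5]
            extra_ids = sorted(got - want)[:5]
            raise ValueError(
                f"{p}: probe id mismatch (missing {missing_ids}, "
                f"unexpected {extra_ids})"
            )
        df = df.set_index("probe_id").loc[probe_ids]
        inp = df["input_intensity"].to_numpy(dtype=float)
        enr = df["enriched_intensity"].to_numpy(dtype=float)
        n_bad = int((inp <= 0).sum() + (enr <= 0).sum())
        if n_bad:
            logger.warning(
                "%s: clamped %d non-positive intensities to %g", p, n_bad,
                intensity_floor,
            )
            inp = np.maximum(inp, intensity_floor)
            enr = np.maximum(enr, intensity_floor)
        samples.append(
            ArraySample(
                sample_id=str(row["sample_id"]),
                tissue=str(row["tissue"]),
                input_ng=float(row["input_ng"]),
                replicate=int(row["replicate"]),
                input_intensity=inp,
                enriched_intensity=enr,
            )
        )
    genome = read_genome(genome_path) if genome_path is not None else None
    return ExperimentBundle(probes=probes, samples=samples, genome=genome)


# ---------------------------------------------------------------- matrix

def write_matrix(matrix: MethylationMatrix, path, samples_path=None) -> None:
    """M matrix TSV (probe coordinates + one column per sample).

    ``samples_path`` additionally stores the sample metadata table so the
    matrix can be reconstructed without the original manifest.
    """
    out = matrix.probes[["probe_id", "chrom", "start", "length"]].copy()
    for col in matrix.values.columns:
        out[col] = matrix.values[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    if samples_path is not None:
        matrix.samples.to_csv(
            samples_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )


def read_matrix(path, samples_path) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    sample_ids = list(samples["sample_id"])
    probes = df[["probe_id", "chrom", "start", "length"]].copy()
    probes["is_control"] = False
    probes["is_antigenomic"] = False
    probes["cpg_count"] = 0  # not stored in the matrix file
    values = df[sample_ids].copy()
    values.index = df["probe_id"].to_numpy()
    return MethylationMatrix(values=values, probes=probes, samples=samples)


# --------------------------------------------------------------- regions

def write_regions(regions: Sequence[TDMR], tsv_path, bed_path=None) -> None:
    """Region tables: full TSV plus BED6.

    BED score is -log10(region p) capped at 320 (p underflow); strand is
    always '.'. An empty region list yields a header-only TSV and an
    empty BED.
    """
    frame = regions_to_frame(regions)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    if bed_path is None:
        bed_path = Path(tsv_path).with_suffix(".bed")
    with open(bed_path, "w") as fh:
        for r in regions:
            if np.isfinite(r.region_p) and r.region_p > 0:
                score = min(-np.log10(r.region_p), BED_SCORE_CAP)
            else:
                score = BED_SCORE_CAP
            name = f"tdmr_rank{r.rank}" if r.rank is not None else r.region_id
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score:.6g}\t.\n"
            )


def read_regions(tsv_path) -> list[TDMR]:
    frame = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    if frame.empty:
        return []
    return frame_to_regions(frame)


# ----------------------------------------------------------------- truth

def write_truth(truth: SimulationTruth, path) -> None:
    """Planted-DMR table: chrom, start, end, one methylation column per tissue."""
    tissues = list(truth.tissues)
    rows = []
    for k, (chrom, start, end) in enumerate(truth.dmr_intervals):
        row = {"chrom": chrom, "start": start, "end": end}
        for t in tissues:
            row[f"meth_{t}"] = truth.methylation_per_tissue[t][k]
        rows.append(row)
    cols = ["chrom", "start", "end"] + [f"meth_{t}" for t in tissues]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_truth_intervals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
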