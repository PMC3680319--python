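"""End-to-end orchestration: simulate -> normalize -> call -> annotate ->
compare, with resumable plain-file stage outputs and an output manifest.

Every stage writes ordinary TSV/FASTA/BED files into the run directory,
so any stage can be inspected or re-run on its own. A completed stage
(all of its outputs present) is skipped on rerun; the run ends with a
``manifest.json`` listing each artifact with its SHA-256 content hash and
a ``run.log`` with per-stage timings. Two runs from the same config and
seed produce identical region tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_io, concordance, cpg_annotation, preprocessing, synthetic_data
from . import tdmr_calling
from .config import RunConfig

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _outputs_exist(paths) -> bool:
    return all(Path(p).exists() for p in paths)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline described by ``config``; returns the manifest.

    The demo layout: one simulated genome and probe tiling; a high-input
    group (``config.replicates`` per tissue at ``config.input_ng`` ng)
    used to call reference T-DMRs; and one low-input 1-vs-1 run per entry
    of ``config.low_input_ngs`` used for concordance.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    log_path = out / "run.log"
    timings: list[tuple[str, float]] = []

    def _stage(name, output_paths, fn):
        if _outputs_exist(output_paths):
            logger.info("stage %s: outputs present, skipped", name)
            timings.append((name, 0.0))
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # halt with stage name
            raise PipelineError(name, exc) from exc
        timings.append((name, time.perf_counter() - t0))

    low_dirs = {ng: out / f"low_{ng:g}ng" for ng in config.low_input_ngs}

    # ---- stage 1: simulate -------------------------------------------
    sim_outputs = [
        out / "genome.fa",
        out / "probes.tsv",
        out / "manifest.tsv",
        out / "truth.tsv",
    ] + [d / "manifest.tsv" for d in low_dirs.values()]

    def _simulate():
        genome = synthetic_data.generate_genome(
            config.genome_length,
            config.island_fraction,
            seed=config.derive_seed(1),
            island_length=config.island_length,
        )
        probes = synthetic_data.tile_probes(
            genome,
            spacing=config.spacing,
            probe_length=config.probe_length,
            n_control=config.n_control,
            n_antigenomic=config.n_antigenomic,
        )
        truth = synthetic_data.plant_dmrs(
            genome,
            config.n_dmrs,
            seed=config.derive_seed(2),
            tissues=(config.group1, config.group2),
            meth_high=config.meth_high,
            meth_low=config.meth_low,
            baseline=config.baseline_methylation,
        )
        bundle = synthetic_data.simulate_bundle(
            genome,
            probes,
            truth,
            config.replicates,
            config.input_ng,
            seed=config.derive_seed(3),
            dye_bias_strength=config.dye_bias_strength,
        )
        array_io.write_experiment(bundle, out)
        array_io.write_truth(truth, out / "truth.tsv")
        for k, ng in enumerate(config.low_input_ngs):
            low = synthetic_data.simulate_bundle(
                genome,
                probes,
                truth,
                1,
                ng,
                seed=config.derive_seed(10 + k),
                dye_bias_strength=config.dye_bias_strength,
            )
            d = low_dirs[ng]
            d.mkdir(exist_ok=True)
            array_io.write_probes(probes, d / "probes.tsv")
            rel = []
            (d / "samples").mkdir(exist_ok=True)
            for s in low.samples:
                p = d / "samples" / f"{s.sample_id}.tsv"
                array_io.write_sample_intensities(s, probes, p)
                rel.append(p.relative_to(d))
            array_io.write_manifest(low.samples, rel, d / "manifest.tsv")

    _stage("simulate", sim_outputs, _simulate)

    # ---- stage 2: normalize ------------------------------------------
    norm_outputs = [out / "m_matrix.tsv", out / "m_samples.tsv", out / "qc.tsv"] + [
        d / "m_matrix.tsv" for d in low_dirs.values()
    ]

    def _normalize():
        bundle = array_io.read_experiment(
            out / "probes.tsv", out / "manifest.tsv", out / "genome.fa",
            intensity_floor=config.intensity_floor,
        )
        matrix = preprocessing.relative_methylation(
            bundle,
            span=config.span,
            background_quantile=config.background_quantile,
            signal_threshold=config.signal_threshold,
            intensity_floor=config.intensity_floor,
            method=config.dye_method,
        )
        array_io.write_matrix(matrix, out / "m_matrix.tsv", out / "m_samples.tsv")
        preprocessing.qc_table(bundle).to_csv(
            out / "qc.tsv", sep="\t", index=False, float_format="%.6g"
        )
        for ng, d in low_dirs.items():
            low = array_io.read_experiment(
                d / "probes.tsv", d / "manifest.tsv",
                intensity_floor=config.intensity_floor,
            )
            lm = preprocessing.relative_methylation(
                low,
                span=config.span,
                background_quantile=config.background_quantile,
                signal_threshold=config.signal_threshold,
                intensity_floor=config.intensity_floor,
                method=config.dye_method,
            )
            array_io.write_matrix(lm, d / "m_matrix.tsv", d / "m_samples.tsv")

    _stage("normalize", norm_outputs, _normalize)

    # ---- stage 3: call -----------------------------------------------
    call_outputs = [
        out / "regions.tsv",
        out / "regions.bed",
        out / "probe_stats.tsv",
        out / "m_smoothed.tsv",
    ]

    def _call():
        matrix = array_io.read_matrix(out / "m_matrix.tsv", out / "m_samples.tsv")
        probes = array_io.read_probes(out / "probes.tsv")
        clusters = tdmr_calling.cluster_probes(probes, config.max_gap)
        smoothed = tdmr_calling.smooth_m(matrix, clusters, config.window)
        g1 = smoothed.group_columns(config.group1)
        g2 = smoothed.group_columns(config.group2)
        stats = tdmr_calling.probe_ttest(smoothed, g1, g2)
        regions = tdmr_calling.call_regions(
            stats,
            clusters,
            p_cutoff=config.p_cutoff,
            min_probes=config.min_probes,
            matrix=smoothed,
            group1=g1,
            group2=g2,
        )
        array_io.write_regions(regions, out / "regions.tsv", out / "regions.bed")
        stats.to_csv(
            out / "probe_stats.tsv", sep="\t", index=False, float_format="%.10g"
        )
        array_io.write_matrix(
            smoothed, out / "m_smoothed.tsv", out / "m_samples.tsv"
        )

    _stage("call", call_outputs, _call)

    # ---- stage 4: annotate -------------------------------------------
    ann_outputs = [out / "regions_annotated.tsv", out / "landscape_summary.tsv"]

    def _annotate():
        genome = array_io.read_genome(out / "genome.fa")
        regions = array_io.read_regions(out / "regions.tsv")
        annotated = cpg_annotation.annotate_regions(
            genome, regions, config.half_window, config.island_oe
        )
        array_io.write_regions(
            annotated, out / "regions_annotated.tsv", out / "regions_annotated.bed"
        )
        tables = cpg_annotation.summarize_landscape(annotated, config.island_oe)
        tables["summary"].to_csv(
            out / "landscape_summary.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        tables["density_hist"].to_csv(
            out / "landscape_density_hist.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        tables["oe_hist"].to_csv(
            out / "landscape_oe_hist.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    _stage("annotate", ann_outputs, _annotate)

    # ---- stage 5: compare --------------------------------------------
    cmp_outputs = [out / "concordance.tsv", out / "correlation_report.tsv"]

    def _compare():
        regions = array_io.read_regions(out / "regions_annotated.tsv")
        if not regions:
            pd.DataFrame().to_csv(out / "concordance.tsv", sep="\t", index=False)
            pd.DataFrame().to_csv(
                out / "correlation_report.tsv", sep="\t", index=False
            )
            return
        probes = array_io.read_probes(out / "probes.tsv")
        clusters = tdmr_calling.cluster_probes(probes, config.max_gap)
        ref_matrix = array_io.read_matrix(
            out / "m_smoothed.tsv", out / "m_samples.tsv"
        )
        ref_dm = np.array([r.delta_m for r in regions])
        low_dm = {}
        reports = []
        for k, (ng, d) in enumerate(low_dirs.items()):
            lm = array_io.read_matrix(d / "m_matrix.tsv", d / "m_samples.tsv")
            ls = tdmr_calling.smooth_m(lm, clusters, config.window)
            g1 = ls.group_columns(config.group1)
            g2 = ls.group_columns(config.group2)
            run = f"{ng:g}ng"
            low_dm[run] = concordance.regions_delta_m(ls, regions, g1, g2)
            rep = concordance.shuffled_null(
                ref_dm,
                low_dm[run],
                n_perm=config.n_perm,
                seed=config.derive_seed(20 + k),
            )
            reports.append(
                {
                    "run": run,
                    "correlation": rep.observed,
                    "null_mean": rep.null_mean,
                    "null_sd": rep.null_sd,
                    "null_q025": rep.null_q025,
                    "null_q975": rep.null_q975,
                    "p_value": rep.p_value,
                    "n_regions": rep.n_regions,
                }
            )
        classified = concordance.classify_regions(regions, low_dm)
        classified.to_csv(
            out / "concordance.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(reports).to_csv(
            out / "correlation_report.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        summary = concordance.concordance_summary(classified)
        with open(out / "concordance_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)

    _stage("compare", cmp_outputs, _compare)

    # ---- manifest -----------------------------------------------------
    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(log_path, "a") as fh:
        for name, dt in timings:
            fh.write(f"{name}\t{dt:.2f}s\n")
    return manifest
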