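"""QPCR enrichment QC: ΔCt and fold enrichment for methylation.

Methylation capture is checked at control loci by quantitative PCR before
hybridization: for a locus hypermethylated in tissue2, tissue2's enriched
DNA amplifies earlier (lower Ct), so

    ΔCt = mean Ct(tissue1) - mean Ct(tissue2),
    fold enrichment = 2 ** ΔCt

exceeds 1, and a successful enrichment should show fold > 2 (strictly).
For loci methylated equally in both tissues a symmetric band check
|log2 fold| < log2(threshold) is appropriate instead.

The ΔCt orientation (which tissue is subtracted) is explicit in every
call to avoid silent sign errors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import QpcrMeasurement


def fold_enrichment(
    ct_tissue1: Sequence[float],
    ct_tissue2: Sequence[float],
    gene: str = "",
    tissue1: str = "tissue1",
    tissue2: str = "tissue2",
) -> QpcrMeasurement:
    """ΔCt and fold enrichment from replicate threshold cycles.

    ``fold = 2 ** (mean Ct(tissue1) - mean Ct(tissue2))`` exactly. With at
    least two replicates on each side, replicate-wise folds (pairwise when
    the replicate counts match, else each tissue1 replicate against the
    tissue2 mean) give an SEM for the fold.
    """
    ct1 = np.asarray(ct_tissue1, dtype=float)
    ct2 = np.asarray(ct_tissue2, dtype=float)
    if ct1.size < 1 or ct2.size < 1:
        raise ValueError("need at least one Ct replicate per tissue")
    if not (np.all(np.isfinite(ct1)) and np.all(np.isfinite(ct2))):
        raise ValueError("non-finite Ct value")
    if np.any(ct1 <= 0) or np.any(ct2 <= 0):
        raise ValueError("Ct values must be positive")
    mean1, mean2 = float(ct1.mean()), float(ct2.mean())
    delta = mean1 - mean2
    fold = float(2.0**delta)
    sem = None
    if ct1.size >= 2 and ct2.size >= 2:
        if ct1.size == ct2.size:
            folds = 2.0 ** (ct1 - ct2)
        else:
            folds = 2.0 ** (ct1 - mean2)
        sem = float(folds.std(ddof=1) / np.sqrt(folds.size))
    return QpcrMeasurement(
        gene=gene,
        tissue1=tissue1,
        tissue2=tissue2,
        ct_tissue1=tuple(ct1),
        ct_tissue2=tuple(ct2),
        mean_ct1=mean1,
        mean_ct2=mean2,
        delta_ct=delta,
        fold_enrichment=fold,
        fold_sem=sem,
    )


def enrichment_passes(
    measurement: QpcrMeasurement,
    threshold_fold: float = 2.0,
    mode: str = "greater",
) -> bool:
    """Enrichment QC rule.

    ``mode="greater"`` (hypermethylated control loci): pass iff
    fold is strictly greater than ``threshold_fold``.
    ``mode="band"`` (equal-methylation control loci): pass iff
    ``|log2 fold| < log2 threshold_fold`` — no spurious enrichment in
    either direction.
    """
    if threshold_fold <= 0:
        raise ValueError("threshold_fold must be positive")
    if mode == "greater":
        return measurement.fold_enrichment > threshold_fold
    if mode == "band":
        return abs(np.log2(measurement.fold_enrichment)) < np.log2(threshold_fold)
    raise ValueError(f"unknown mode {mode!r}")


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns gene, tissue, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "tissue", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def qpcr_report(
    ct_table: pd.DataFrame,
    tissue1: str,
    tissue2: str,
    threshold_fold: float = 2.0,
    band_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-gene fold enrichment and pass/fail from a long-format Ct table.

    Genes listed in ``band_genes`` (equal-methylation controls) are
    checked with the symmetric band rule instead of the strict
    greater-than rule.
    """
    rows = []
    for gene, sub in ct_table.groupby("gene", sort=True):
        ct1 = sub.loc[sub["tissue"] == tissue1, "ct"].to_numpy()
        ct2 = sub.loc[sub["tissue"] == tissue2, "ct"].to_numpy()
        if ct1.size == 0 or ct2.size == 0:
            raise ValueError(f"gene {gene!r}: missing Ct for one tissue")
        m = fold_enrichment(ct1, ct2, gene=gene, tissue1=tissue1, tissue2=tissue2)
        mode = "band" if gene in band_genes else "greater"
        rows.append(
            {
                "gene": gene,
                "mean_ct_" + tissue1: m.mean_ct1,
                "mean_ct_" + tissue2: m.mean_ct2,
                "delta_ct": m.delta_ct,
                "fold_enrichment": m.fold_enrichment,
                "fold_sem": m.fold_sem,
                "rule": mode,
                "passes": enrichment_passes(m, threshold_fold, mode),
            }
        )
    return pd.DataFrame(rows)
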