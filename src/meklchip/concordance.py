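"""High- versus low-input concordance of regional methylation differences.

Regions called in a high-input reference experiment are re-measured in
each low-input experiment via their regional methylation difference
(ΔM = mean over member probes of mean M(group1) - mean M(group2)). The
module then

* correlates reference ΔM with each low-input run's ΔM (Pearson by
  default, Spearman on request) and compares the observed correlation to
  a null built by randomly re-pairing the two vectors;
* classifies every region as ``verified`` (all low runs reproduce the
  reference ΔM sign), ``dropout_1`` (exactly one run disagrees) or
  ``dropout_2plus`` (two or more disagree). A low-run ΔM of exactly 0
  has no direction and counts as a disagreement.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CorrelationReport, MethylationMatrix, TDMR

LABELS = ("verified", "dropout_1", "dropout_2plus")


def region_delta_m(
    matrix: MethylationMatrix,
    region: TDMR,
    group1: Sequence[str],
    group2: Sequence[str],
) -> float:
    """Regional ΔM: mean over member probes of the group-mean difference.

    Groups may hold a single sample each (the low-input case).
    """
    present = [p for p in region.probe_ids if p in matrix.values.index]
    if not present:
        raise ValueError(f"region {region.region_id}: no member probes in matrix")
    sub = matrix.values.loc[present]
    per_probe = sub[list(group1)].mean(axis=1) - sub[list(group2)].mean(axis=1)
    return float(per_probe.mean())


def regions_delta_m(
    matrix: MethylationMatrix,
    regions: Sequence[TDMR],
    group1: Sequence[str],
    group2: Sequence[str],
) -> np.ndarray:
    """Vector of regional ΔM values for a list of regions."""
    return np.array(
        [region_delta_m(matrix, r, group1, group2) for r in regions], dtype=float
    )


def classify_regions(
    reference: Sequence[TDMR],
    low_dm: Mapping[str, Sequence[float]],
    reference_dm: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Label every reference region by its low-input sign concordance.

    ``low_dm`` maps each low-input run name to a ΔM vector aligned with
    ``reference``. The reference ΔM defaults to the regions' own
    ``delta_m``. Returns one row per region with per-run agreement flags
    and the label; counts over the three labels always partition the
    region list.
    """
    ref_dm = (
        np.array([r.delta_m for r in reference], dtype=float)
        if reference_dm is None
        else np.asarray(reference_dm, dtype=float)
    )
    if len(ref_dm) != len(reference):
        raise ValueError("reference ΔM length mismatch")
    if np.any(ref_dm == 0.0):
        raise ValueError("reference ΔM of 0 has no direction")
    runs = list(low_dm)
    for run in runs:
        v = np.asarray(low_dm[run], dtype=float)
        if len(v) != len(reference):
            raise ValueError(f"run {run!r}: ΔM missing for some regions")
        if not np.all(np.isfinite(v)):
            bad = [reference[i].region_id for i in np.flatnonzero(~np.isfinite(v))]
            raise ValueError(f"run {run!r}: non-finite ΔM for regions {bad}")

    rows = []
    for i, region in enumerate(reference):
        agree = {}
        ties = 0
        for run in runs:
            v = float(low_dm[run][i])
            ok = np.sign(v) == np.sign(ref_dm[i]) and v != 0.0
            agree[run] = ok
            if v == 0.0:
                ties += 1
        n_disagree = sum(not ok for ok in agree.values())
        if n_disagree == 0:
            label = "verified"
        elif n_disagree == 1:
            label = "dropout_1"
        else:
            label = "dropout_2plus"
        row = {
            "region_id": region.region_id,
            "delta_m_reference": ref_dm[i],
            "label": label,
            "n_disagree": n_disagree,
            "n_zero": ties,
        }
        for run in runs:
            row[f"delta_m_{run}"] = float(low_dm[run][i])
            row[f"agree_{run}"] = agree[run]
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_summary(classified: pd.DataFrame) -> dict[str, float]:
    """Verified fraction and the dropout split from a classification table."""
    n = len(classified)
    counts = {lab: int((classified["label"] == lab).sum()) for lab in LABELS}
    dropouts = counts["dropout_1"] + counts["dropout_2plus"]
    return {
        "n_regions": n,
        **{f"n_{lab}": counts[lab] for lab in LABELS},
        "verified_fraction": counts["verified"] / n if n else float("nan"),
        "dropout_1_fraction_of_dropouts": (
            counts["dropout_1"] / dropouts if dropouts else float("nan")
        ),
    }


def delta_m_correlation(
    reference_dm: Sequence[float],
    low_dm: Sequence[float],
    method: str = "pearson",
) -> float:
    """Correlation of paired regional ΔM vectors (Pearson or Spearman)."""
    x = np.asarray(reference_dm, dtype=float)
    y = np.asarray(low_dm, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite ΔM values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def shuffled_null(
    reference_dm: Sequence[float],
    low_dm: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    keep_null: bool = False,
) -> CorrelationReport:
    """Correlation null from random re-pairing of the ΔM vectors.

    The low-input vector is permuted ``n_perm`` times against the fixed
    reference vector; the report carries the null mean/SD, its 2.5 and
    97.5 percentiles, and an add-one empirical p for the observed
    correlation (one-sided, high).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = delta_m_correlation(reference_dm, low_dm, method)
    rng = np.random.default_rng(seed)
    y = np.asarray(low_dm, dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = delta_m_correlation(reference_dm, rng.permutation(y), method)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return CorrelationReport(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        null_q025=float(np.quantile(null, 0.025)),
        null_q975=float(np.quantile(null, 0.975)),
        p_value=p,
        n_regions=len(y),
        n_perm=n_perm,
        null_values=tuple(null) if keep_null else (),
    )
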