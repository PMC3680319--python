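"""Probe smoothing, per-probe statistics, and T-DMR aggregation.

Genomic probes are first grouped into clusters (consecutive probes on one
chromosome closer than ``max_gap`` start-to-start). Within each cluster
every probe's M value is replaced, per sample, by a triangular-kernel
weighted mean over neighboring probes within ``+/- window`` bases
(genome-weighted smoothing; the kernel weight is 1 at the probe and falls
linearly to 0 at the window edge). A pooled-variance two-sample t test is
then computed per probe on the smoothed values, and maximal runs of
consecutive probes that are individually significant (p < ``p_cutoff``)
with a common t sign become candidate regions; runs shorter than
``min_probes`` (default 3) are discarded.

Each region gets a region-level p value from a pooled-variance t test on
the per-sample region means of smoothed M, an ``area`` (sum of |t| over
member probes), and a rank (ascending region p, ties by descending area,
then coordinates).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import MethylationMatrix, ProbeSet, TDMR

logger = logging.getLogger(__name__)

#: p assigned when the pooled variance is zero but the group means differ
_P_FLOOR = np.nextafter(0.0, 1.0)


def cluster_probes(probes: ProbeSet, max_gap: int = 300) -> np.ndarray:
    """Dense cluster ids for the genomic probes (aligned to probe order).

    Consecutive genomic probes on the same chromosome whose start-to-start
    gap is <= ``max_gap`` share a cluster; clusters never span
    chromosomes.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    gen = probes.genomic
    chrom = gen["chrom"].to_numpy()
    start = gen["start"].to_numpy()
    if len(gen) == 0:
        return np.array([], dtype=int)
    new_cluster = np.ones(len(gen), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    close = (start[1:] - start[:-1]) <= max_gap
    new_cluster[1:] = ~(same_chrom & close)
    return np.cumsum(new_cluster) - 1


def smooth_m(
    matrix: MethylationMatrix, clusters: np.ndarray, window: int = 300
) -> MethylationMatrix:
    """Triangular-kernel smoothing of M within clusters, per sample.

    Each probe's value becomes ``sum_j w_ij M_j / sum_j w_ij`` over probes
    j of the same cluster with ``|start_i - start_j| <= window``, where
    ``w_ij = 1 - |start_i - start_j| / window``. Smoothing never crosses
    cluster boundaries; singleton clusters are returned unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = matrix.values.to_numpy(dtype=float)
    start = matrix.probes["start"].to_numpy()
    out = np.empty_like(x)
    for cid in np.unique(clusters):
        idx = np.flatnonzero(clusters == cid)
        if len(idx) == 1:
            out[idx] = x[idx]
            continue
        pos = start[idx]
        d = np.abs(pos[:, None] - pos[None, :])
        w = np.clip(1.0 - d / window, 0.0, None)
        out[idx] = (w @ x[idx]) / w.sum(axis=1)[:, None]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MethylationMatrix(
        values=values, probes=matrix.probes, samples=matrix.samples
    )


def pooled_ttest(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t test along axis 1.

    Returns ``(t, p, zero_var_flag)``; p is two-sided with
    ``n1 + n2 - 2`` degrees of freedom. Probes with zero pooled variance
    get t = 0, p = 1 when the means agree, and the smallest positive p
    (flagged) when they differ.
    """
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    zero_var = se == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff / np.where(zero_var, 1.0, se))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    flagged = zero_var & (diff != 0.0)
    with np.errstate(invalid="ignore"):
        t = np.where(flagged, np.sign(diff) * np.inf, t)
    p = np.where(zero_var, np.where(flagged, _P_FLOOR, 1.0), p)
    return t, p, flagged


def probe_ttest(
    matrix: MethylationMatrix, group1: list[str], group2: list[str]
) -> pd.DataFrame:
    """Per-probe statistics comparing group1 to group2 on (smoothed) M.

    Returns a DataFrame aligned to the matrix rows with columns probe_id,
    chrom, start, length, delta_m (group1 - group2), t_stat, p_value,
    q_value (Benjamini-Hochberg, informational only) and zero_var_flag.
    """
    for g, name in ((group1, "group1"), (group2, "group2")):
        missing = [s for s in g if s not in matrix.values.columns]
        if missing:
            raise ValueError(f"{name}: unknown sample ids {missing}")
    g1 = matrix.values[group1].to_numpy(dtype=float)
    g2 = matrix.values[group2].to_numpy(dtype=float)
    t, p, flagged = pooled_ttest(g1, g2)
    out = matrix.probes[["probe_id", "chrom", "start", "length"]].copy()
    out["delta_m"] = g1.mean(axis=1) - g2.mean(axis=1)
    out["t_stat"] = t
    out["p_value"] = p
    out["q_value"] = multipletests(p, method="fdr_bh")[1]
    out["zero_var_flag"] = flagged
    return out


def _significant_runs(
    p: np.ndarray, t: np.ndarray, p_cutoff: float, min_probes: int
) -> list[tuple[int, int]]:
    """Maximal [i, j) index runs with p < cutoff and a common t sign."""
    sig = (p < p_cutoff) & (t != 0.0)
    sign = np.sign(t)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(p)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i + 1
        while j < n and sig[j] and sign[j] == sign[i]:
            j += 1
        if j - i >= min_probes:
            runs.append((i, j))
        i = j
    return runs


def _region_p(
    matrix: MethylationMatrix | None,
    probe_ids: np.ndarray,
    group1: list[str] | None,
    group2: list[str] | None,
) -> float:
    if matrix is None or group1 is None or group2 is None:
        return np.nan
    sub = matrix.values.loc[probe_ids]
    means1 = sub[group1].mean(axis=0).to_numpy()[None, :]
    means2 = sub[group2].mean(axis=0).to_numpy()[None, :]
    _, p, _ = pooled_ttest(means1, means2)
    return float(p[0])


def _permutation_region_p(
    cluster_t: np.ndarray,
    cluster_p: np.ndarray,
    observed_area: float,
    p_cutoff: float,
    min_probes: int,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Empirical p for a region's area under within-cluster probe shuffling."""
    count = 0
    idx = np.arange(len(cluster_t))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        runs = _significant_runs(cluster_p[perm], cluster_t[perm], p_cutoff, min_probes)
        best = max(
            (np.abs(cluster_t[perm][i:j]).sum() for i, j in runs), default=0.0
        )
        if best >= observed_area:
            count += 1
    return (count + 1) / (n_perm + 1)


def call_regions(
    stats: pd.DataFrame,
    clusters: np.ndarray,
    p_cutoff: float = 0.005,
    min_probes: int = 3,
    matrix: MethylationMatrix | None = None,
    group1: list[str] | None = None,
    group2: list[str] | None = None,
    region_p_mode: str = "ttest",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[TDMR]:
    """Aggregate per-probe statistics into ranked T-DMRs.

    Within each cluster, maximal runs of consecutive probes with
    p < ``p_cutoff`` and a common t sign become regions; runs with fewer
    than ``min_probes`` members are excluded. The region span runs from
    the first member probe's start to the last member probe's end
    (half-open). The region p value comes from a pooled-variance t test
    on per-sample region means (``region_p_mode="ttest"``, requires
    ``matrix`` and the groups) or from within-cluster probe shuffling
    (``region_p_mode="permutation"``).
    """
    if region_p_mode not in ("ttest", "permutation"):
        raise ValueError(f"unknown region_p_mode {region_p_mode!r}")
    if len(stats) != len(clusters):
        raise ValueError("stats and clusters length mismatch")
    rng = np.random.default_rng(seed)
    t_all = stats["t_stat"].to_numpy(dtype=float)
    p_all = stats["p_value"].to_numpy(dtype=float)
    dm_all = stats["delta_m"].to_numpy(dtype=float)
    chrom_all = stats["chrom"].to_numpy()
    start_all = stats["start"].to_numpy()
    length_all = stats["length"].to_numpy()
    ids_all = stats["probe_id"].to_numpy()

    regions: list[TDMR] = []
    for cid in np.unique(clusters):
        idx = np.flatnonzero(clusters == cid)
        runs = _significant_runs(p_all[idx], t_all[idx], p_cutoff, min_probes)
        for i, j in runs:
            member = idx[i:j]
            area = float(np.abs(t_all[member]).sum())
            if region_p_mode == "ttest":
                rp = _region_p(matrix, ids_all[member], group1, group2)
            else:
                rp = _permutation_region_p(
                    t_all[idx], p_all[idx], area, p_cutoff, min_probes, n_perm, rng
                )
            regions.append(
                TDMR(
                    chrom=str(chrom_all[member[0]]),
                    start=int(start_all[member[0]]),
                    end=int(start_all[member[-1]] + length_all[member[-1]]),
                    probe_ids=tuple(ids_all[member]),
                    direction=int(np.sign(t_all[member[0]])),
                    delta_m=float(dm_all[member].mean()),
                    area=area,
                    region_p=rp,
                    cluster_id=int(cid),
                )
            )
    return rank_regions(regions)


def rank_regions(regions: list[TDMR]) -> list[TDMR]:
    """Assign 1-based ranks: ascending region p, then descending area,
    then coordinates; NaN p values sort last. Stable and deterministic."""

    def key(r: TDMR):
        p = r.region_p if np.isfinite(r.region_p) else np.inf
        return (p, -r.area, r.chrom, r.start, r.end)

    ordered = sorted(regions, key=key)
    return [r.with_annotation(rank=i + 1) for i, r in enumerate(ordered)]
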