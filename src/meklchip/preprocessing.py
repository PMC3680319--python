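"""QC and normalization of raw two-channel intensities into M values.

The processing chain, applied in this order by
:func:`relative_methylation`:

1. intensity floor — clamp non-positive/tiny intensities so logs exist;
2. signal-score QC — fraction of genomic probes whose input-channel
   intensity exceeds a high quantile (default 0.90) of the anti-genomic
   background probes; samples under the threshold (default 0.85) are
   flagged;
3. within-sample dye-bias correction — a smooth trend of
   M = log2(enriched/input) on A = (log2 enriched + log2 input)/2 is
   fitted on the control probes and subtracted from every probe's M;
4. between-sample quantile normalization of the M matrix;
5. the genomic-probe M matrix is returned.

The dye-bias trend can be estimated either by a least-squares cubic
B-spline fit (default; a true projection, so correcting twice is a no-op
to machine precision) or by classic lowess (``method="lowess"``).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .types import ArraySample, ExperimentBundle, MethylationMatrix, ProbeSet

logger = logging.getLogger(__name__)

MIN_CONTROL_PROBES = 50


def apply_intensity_floor(sample: ArraySample, floor: float = 1.0) -> ArraySample:
    """Clamp intensities below ``floor`` (log-safety); warns when applied."""
    n_low = int((sample.input_intensity < floor).sum()) + int(
        (sample.enriched_intensity < floor).sum()
    )
    if n_low:
        logger.warning(
            "sample %s: clamped %d intensities to floor %g",
            sample.sample_id,
            n_low,
            floor,
        )
    return replace(
        sample,
        input_intensity=np.maximum(sample.input_intensity, floor),
        enriched_intensity=np.maximum(sample.enriched_intensity, floor),
    )


def signal_score(
    sample: ArraySample, probes: ProbeSet, background_quantile: float = 0.90
) -> float:
    """Fraction of genomic probes ranking above the anti-genomic background.

    The background reference is the ``background_quantile`` of the
    anti-genomic probes' input-channel intensities; the score is the
    fraction of genomic probes whose input-channel intensity strictly
    exceeds it. A well-hybridized array scores close to 1 (rule of thumb:
    above 0.85).
    """
    if not 0.0 < background_quantile < 1.0:
        raise ValueError("background_quantile must be in (0, 1)")
    anti = probes.table["is_antigenomic"].to_numpy()
    if not anti.any():
        raise ValueError("no anti-genomic probes: signal score undefined")
    genomic = probes.genomic_mask
    if not genomic.any():
        raise ValueError("no genomic probes")
    cut = np.quantile(sample.input_intensity[anti], background_quantile)
    return float(np.mean(sample.input_intensity[genomic] > cut))


def _m_a(sample: ArraySample) -> tuple[np.ndarray, np.ndarray]:
    li = np.log2(sample.input_intensity)
    le = np.log2(sample.enriched_intensity)
    return le - li, 0.5 * (le + li)


def _spline_trend(
    a_ctrl: np.ndarray, m_ctrl: np.ndarray, a_all: np.ndarray, n_knots: int = 8
) -> np.ndarray:
    """Least-squares cubic B-spline fit of M on A over the control probes.

    Knots at quantiles of the control A values; evaluation clamps A to the
    control range (constant extrapolation). Being an ordinary
    least-squares projection, the fit of already-corrected residuals is
    identically zero, which makes the correction idempotent.
    """
    lo, hi = float(a_ctrl.min()), float(a_ctrl.max())
    if hi - lo < 1e-12:
        return np.full_like(a_all, float(m_ctrl.mean()))
    interior = np.quantile(a_ctrl, np.linspace(0, 1, n_knots + 2)[1:-1])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    design = BSpline.design_matrix(a_ctrl, knots, 3).toarray()
    coef, *_ = np.linalg.lstsq(design, m_ctrl, rcond=None)
    a_eval = np.clip(a_all, lo, hi)
    return BSpline.design_matrix(a_eval, knots, 3).toarray() @ coef


def _lowess_trend(
    a_ctrl: np.ndarray, m_ctrl: np.ndarray, a_all: np.ndarray, span: float
) -> np.ndarray:
    fit = sm_lowess(m_ctrl, a_ctrl, frac=span, it=0, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    return np.interp(np.clip(a_all, xs[0], xs[-1]), xs, ys)


def correct_dye_bias(
    sample: ArraySample,
    probes: ProbeSet,
    span: float = 0.4,
    method: str = "spline",
) -> ArraySample:
    """Remove the intensity-dependent dye bias from one sample.

    Fits the M-vs-A trend on control probes only and subtracts the trend,
    evaluated at each probe's own A, from every probe's M. The corrected
    channels are reconstructed from (A, corrected M) — the change is split
    evenly between the channels so each probe's mean log intensity A is
    preserved exactly. After correction the control probes' M is centered
    on zero across the intensity range.

    ``method="spline"`` (default) uses a least-squares cubic B-spline —
    an idempotent projection; ``method="lowess"`` uses classic locally
    weighted regression with window fraction ``span``.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    ctrl = probes.table["is_control"].to_numpy()
    n_ctrl = int(ctrl.sum())
    if n_ctrl < MIN_CONTROL_PROBES:
        raise ValueError(
            f"only {n_ctrl} control probes; need >= {MIN_CONTROL_PROBES} for a "
            "stable trend fit"
        )
    m, a = _m_a(sample)
    if method == "spline":
        trend = _spline_trend(a[ctrl], m[ctrl], a)
    elif method == "lowess":
        trend = _lowess_trend(a[ctrl], m[ctrl], a, span)
    else:
        raise ValueError(f"unknown method {method!r}")
    m_corrected = m - trend
    return replace(
        sample,
        input_intensity=np.exp2(a - 0.5 * m_corrected),
        enriched_intensity=np.exp2(a + 0.5 * m_corrected),
    )


def quantile_normalize(matrix, rtol: float = 1e-9, atol: float = 1e-12):
    """Force every sample (column) onto the common reference distribution.

    The reference is the across-sample mean of the sorted columns. Ties
    within a column all receive the mean of the reference values at the
    tied positions, so the output is invariant to the within-tie order;
    values equal up to ``atol + rtol * |v|`` count as tied, so ties that
    differ only by floating-point round-off are still averaged together.
    Accepts a DataFrame (returned as DataFrame) or a 2-D array.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a probes x samples matrix")
    n, k = x.shape
    if k < 2:
        logger.warning("quantile_normalize: single sample, returned unchanged")
        return matrix.copy() if is_frame else x.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        gaps = np.diff(sorted_col)
        tol = atol + rtol * np.maximum(
            np.abs(sorted_col[1:]), np.abs(sorted_col[:-1])
        )
        group = np.cumsum(np.concatenate([[True], gaps > tol])) - 1
        group_mean = np.bincount(group, weights=reference) / np.bincount(group)
        col_out = np.empty(n)
        col_out[order] = group_mean[group]
        out[:, j] = col_out
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def qc_table(bundle: ExperimentBundle) -> pd.DataFrame:
    """Per-sample QC report (signal score and flag) after preprocessing."""
    return bundle.sample_frame()[["sample_id", "tissue", "signal_score", "qc_flag"]]


def relative_methylation(
    bundle: ExperimentBundle,
    span: float = 0.4,
    background_quantile: float = 0.90,
    signal_threshold: float = 0.85,
    intensity_floor: float = 1.0,
    method: str = "spline",
    drop_flagged: bool = False,
    normalize_channels_separately: bool = False,
) -> MethylationMatrix:
    """Full preprocessing: floor -> QC -> dye correction -> quantile norm.

    Samples whose signal score falls below ``signal_threshold`` are
    flagged (and dropped only when ``drop_flagged``); flags and scores are
    written back onto the bundle's samples. By default quantile
    normalization is applied to the M values; with
    ``normalize_channels_separately`` the two log-intensity channels are
    normalized across samples before the ratio is formed.
    """
    if not bundle.samples:
        raise ValueError("bundle has no samples")
    if not bundle.probes.genomic_mask.any():
        raise ValueError("bundle has no genomic probes")

    floored = [apply_intensity_floor(s, intensity_floor) for s in bundle.samples]
    logger.info("preprocessing order: floor -> signal QC -> dye correction -> "
                "quantile normalization")

    for orig, s in zip(bundle.samples, floored):
        score = signal_score(s, bundle.probes, background_quantile)
        flag = score < signal_threshold
        orig.signal_score = s.signal_score = score
        orig.qc_flag = s.qc_flag = flag
        if flag:
            logger.warning(
                "sample %s flagged: signal score %.3f < %.3f",
                s.sample_id,
                score,
                signal_threshold,
            )
    kept = [s for s in floored if not (drop_flagged and s.qc_flag)]
    if not kept:
        raise ValueError("all samples failed signal-score QC")

    corrected = [correct_dye_bias(s, bundle.probes, span, method) for s in kept]

    genomic = bundle.probes.genomic_mask
    probe_ids = bundle.probes.table.loc[genomic, "probe_id"].to_numpy()
    if normalize_channels_separately:
        li = np.column_stack([np.log2(s.input_intensity[genomic]) for s in corrected])
        le = np.column_stack(
            [np.log2(s.enriched_intensity[genomic]) for s in corrected]
        )
        m = quantile_normalize(le) - quantile_normalize(li)
    else:
        m = np.column_stack(
            [
                np.log2(s.enriched_intensity[genomic])
                - np.log2(s.input_intensity[genomic])
                for s in corrected
            ]
        )
        m = quantile_normalize(m)

    values = pd.DataFrame(m, index=probe_ids, columns=[s.sample_id for s in corrected])
    samples_df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in corrected],
            "tissue": [s.tissue for s in corrected],
            "input_ng": [s.input_ng for s in corrected],
            "replicate": [s.replicate for s in corrected],
            "signal_score": [s.signal_score for s in corrected],
            "qc_flag": [s.qc_flag for s in corrected],
        }
    )
    return MethylationMatrix(
        values=values,
        probes=bundle.probes.genomic.reset_index(drop=True),
        samples=samples_df,
    )
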