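"""Normalization: spike-in size factors, TPM, filters, quantile and batch.

The normalization chain converts raw counts into values comparable across
samples and states:

* RNAseq / PROseq: median-of-ratios size factors computed from spike-in rows
  only (spike-ins see library depth but no biology), then reference-anchored
  quantile normalization onto the mean of the sorted control-ESC replicates.
  Anchoring everything — including the depleted libraries — on one reference
  assumes expression follows the same distribution in both states and
  compensates for the weaker depletion efficiency in the differentiated state.
* PROseq additionally receives a per-feature location-only batch adjustment on
  the log2(x+1) scale before quantile normalization, and the lowest percentile
  of features (by mean) is excluded afterwards.
* CAGE: tags per million, then the same quantile normalization.

Filters return row subsets and never alter surviving values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = [
    "spikein_size_factors",
    "apply_size_factors",
    "cage_tpm",
    "expressed_filter",
    "quantile_normalize_to_reference",
    "batch_adjust",
    "exclude_lowest_percentile",
]


class NormalizationError(ValueError):
    pass


def _values(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def spikein_size_factors(spike_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from spike-in counts.

    For sample j the factor is the median over spike-ins i of
    ``k_ij / g_i`` with ``g_i`` the geometric mean of spike-in i across
    samples; spike-ins with a zero count in any sample are excluded (their
    geometric mean is not informative).
    """
    k = spike_counts.to_numpy(dtype=float)
    ok = (k > 0).all(axis=1)
    if ok.sum() == 0:
        raise NormalizationError("no spike-in has nonzero counts in every sample")
    logk = np.log(k[ok])
    log_g = logk.mean(axis=1)
    ratios = np.exp(logk - log_g[:, None])
    factors = np.median(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise NormalizationError("degenerate size factor computed")
    return pd.Series(factors, index=spike_counts.columns, name="size_factor")


def apply_size_factors(
    counts, factors: pd.Series, spike_ids=None
) -> ExpressionMatrix:
    """Divide each sample column by its size factor; spike-in rows (if named
    via ``spike_ids``) are dropped from the output."""
    values = _values(counts)
    missing = [c for c in values.columns if c not in factors.index]
    if missing:
        raise NormalizationError(f"missing size factor for samples: {missing}")
    out = values / factors.reindex(values.columns)
    if spike_ids is not None:
        out = out.loc[[f for f in out.index if f not in set(spike_ids)]]
    assay = counts.assay if isinstance(counts, ExpressionMatrix) else "unknown"
    return ExpressionMatrix(values=out, stage="size_normalized", assay=assay)


def cage_tpm(cluster_counts) -> ExpressionMatrix:
    """Tags per million mapped tags; column totals are computed before any
    cluster filtering, so each unfiltered column sums to 1e6."""
    values = _values(cluster_counts)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise NormalizationError(f"zero total tag count in samples: {bad}")
    out = values * 1e6 / totals
    assay = cluster_counts.assay if isinstance(cluster_counts, ExpressionMatrix) else "CAGE"
    return ExpressionMatrix(values=out, stage="tpm", assay=assay)


def expressed_filter(expr, design: pd.DataFrame) -> pd.Index:
    """Features with values > 0 in ALL replicates of at least one
    (state, condition) cell.  Returns the surviving feature index."""
    values = _values(expr)
    design = design.set_index("sample_id") if "sample_id" in design.columns and design.index.name != "sample_id" else design
    keep = pd.Series(False, index=values.index)
    cols = [c for c in values.columns if c in design.index]
    meta = design.loc[cols]
    for _, group in meta.groupby(["state", "condition"], observed=True):
        samples = list(group.index)
        if samples:
            keep |= (values[samples] > 0).all(axis=1)
    return values.index[keep]


def quantile_normalize_to_reference(expr, reference_samples) -> ExpressionMatrix:
    """Force every column onto the reference distribution.

    The reference vector is the element-wise mean of the SORTED reference
    columns; a column's rank-r value becomes reference entry r.  Tied input
    values receive the mean of the reference entries their rank range spans,
    which makes the operation idempotent.
    """
    values = _values(expr)
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise NormalizationError("reference_samples must be non-empty")
    missing = [s for s in reference_samples if s not in values.columns]
    if missing:
        raise NormalizationError(f"reference samples not in matrix: {missing}")
    ref = np.sort(values[reference_samples].to_numpy(dtype=float), axis=0).mean(axis=1)
    n = len(ref)
    out = {}
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        if len(v) != n:
            raise NormalizationError("column length mismatch")
        order = np.argsort(v, kind="mergesort")
        mapped = np.empty(n, dtype=float)
        mapped[order] = ref
        s = pd.Series(mapped)
        out[col] = s.groupby(pd.Series(v)).transform("mean").to_numpy()
    result = pd.DataFrame(out, index=values.index)
    if isinstance(expr, ExpressionMatrix):
        return expr.advance(result, "quantile_normalized")
    return ExpressionMatrix(values=result, stage="quantile_normalized", assay="unknown")


def _check_batch_estimable(meta: pd.DataFrame) -> None:
    cells = meta.groupby(["state", "condition"], observed=True).groups
    batches = meta.groupby("batch").groups
    for cell, cell_samples in cells.items():
        cell_set = set(cell_samples)
        for b, batch_samples in batches.items():
            if cell_set == set(batch_samples):
                raise NormalizationError(
                    f"batch {b!r} is confounded with cell (state, condition)={cell}"
                )


def batch_adjust(expr, design: pd.DataFrame) -> ExpressionMatrix:
    """Location-only batch adjustment on the log2(x+1) scale.

    Per feature, residuals after removing (state x condition) group means are
    averaged within each batch and subtracted from that batch's samples; the
    log is then inverted.  Residuals sum to zero per feature, so the grand
    mean is preserved.  A single batch is an identity (nothing to adjust).
    """
    values = _values(expr)
    design = design.set_index("sample_id") if design.index.name != "sample_id" else design
    meta = design.loc[[c for c in values.columns if c in design.index]]
    stage_src = expr if isinstance(expr, ExpressionMatrix) else ExpressionMatrix(
        values=values, stage="size_normalized", assay="unknown"
    )
    if meta["batch"].nunique() < 2:
        return stage_src.advance(values.copy(), "batch_adjusted")
    _check_batch_estimable(meta)
    log = np.log2(values + 1.0)
    cell_key = meta["state"].astype(str) + "|" + meta["condition"].astype(str)
    cell_mean = log.T.groupby(cell_key).transform("mean").T
    resid = log - cell_mean
    batch_mean = resid.T.groupby(meta["batch"]).transform("mean").T
    adjusted = (2.0 ** (log - batch_mean) - 1.0).clip(lower=0.0)
    return stage_src.advance(adjusted, "batch_adjusted")


def exclude_lowest_percentile(expr, percentile: float = 1.0) -> pd.Index:
    """Drop features whose mean value falls below the given percentile of the
    feature-mean distribution; returns the surviving feature index."""
    if not (0 <= percentile < 100):
        raise NormalizationError("percentile must be in [0, 100)")
    values = _values(expr)
    means = values.mean(axis=1)
    if percentile == 0:
        return values.index
    cut = np.percentile(means.to_numpy(), percentile)
    return values.index[means >= cut]
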