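"""Descriptive stratifications of exosome sensitivity.

Three views of how decay relates to expression:

* quintile stratification — genes are split into five equal-size groups by
  their normalized control-sample signal (PROseq for transcription, RNAseq
  for RNA level) and the sensitivity distribution is summarized per quintile;
  the trend of median sensitivity across quintiles is the headline statistic.
* state regions — genes are assigned to lower-in-ESC / lower-in-EBd3 /
  diagonal bands of the control ESC-vs-EBd3 scatter by the state log2 fold
  change, and sensitivity distributions are compared between regions.
* exon profiles — per-exon depletion/control log2 fold changes along each
  gene, 5' to 3'; a flat profile (small max deviation from the gene-level
  fold change) indicates full-length stabilization rather than accumulation
  of prematurely terminated 5' fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sensitivity import compute_log2fc, group_means

__all__ = [
    "QuintileAssignment",
    "assign_quintiles",
    "quintile_sensitivity_summary",
    "assign_state_regions",
    "exon_profile",
]

REGIONS = ("lower_in_ESC", "lower_in_EBd3", "diagonal")


@dataclass
class QuintileAssignment:
    """Rank-based quintiles (1 = lowest values) with the 4 cut values."""

    assignments: pd.Series  # feature -> 1..5
    thresholds: np.ndarray  # 20/40/60/80th percentiles of the stratifier
    stratifier: str = ""

    def features_in(self, q: int) -> pd.Index:
        return self.assignments.index[self.assignments == q]


def assign_quintiles(values: pd.Series, stratifier: str = "") -> QuintileAssignment:
    """Split features into 5 near-equal rank groups (stable order on ties)."""
    n = len(values)
    if n < 5:
        raise ValueError("need at least 5 features to form quintiles")
    order = np.argsort(values.to_numpy(), kind="mergesort")
    q = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(order, 5), start=1):
        q[chunk] = i
    thresholds = np.percentile(values.to_numpy(), [20, 40, 60, 80])
    return QuintileAssignment(
        assignments=pd.Series(q, index=values.index, name="quintile"),
        thresholds=thresholds,
        stratifier=stratifier,
    )


def quintile_sensitivity_summary(
    quintiles: QuintileAssignment, sensitivity: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-quintile sensitivity summaries, pairwise Mann-Whitney tests and a
    monotone-trend statistic (Spearman of quintile index vs median).

    Features are the intersection of the two inputs; an empty quintile is an
    error.
    """
    common = quintiles.assignments.index.intersection(sensitivity.index)
    q = quintiles.assignments.reindex(common)
    s = sensitivity.reindex(common)
    rows = []
    groups = {}
    for k in range(1, 6):
        vals = s[q == k].dropna()
        if len(vals) == 0:
            raise ValueError(f"quintile {k} is empty")
        groups[k] = vals
        rows.append(
            {
                "quintile": k,
                "n": len(vals),
                "median": float(vals.median()),
                "q25": float(vals.quantile(0.25)),
                "q75": float(vals.quantile(0.75)),
            }
        )
    summary = pd.DataFrame(rows).set_index("quintile")
    tests = []
    for a in range(1, 6):
        for b in range(a + 1, 6):
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            tests.append({"quintile_a": a, "quintile_b": b, "U": float(u), "p_value": float(p)})
    medians = summary["median"].to_numpy()
    if np.allclose(medians, medians[0]):
        trend = 0.0
    else:
        trend = float(stats.spearmanr(np.arange(1, 6), medians).statistic)
    return summary, pd.DataFrame(tests), trend


def assign_state_regions(
    expr_esc: pd.Series,
    expr_ebd3: pd.Series,
    band: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Partition features by the control state log2 fold change:
    > band -> lower_in_ESC, < -band -> lower_in_EBd3, else diagonal."""
    fc = compute_log2fc(expr_ebd3, expr_esc, pseudocount)
    region = pd.Series("diagonal", index=fc.index, name="region", dtype=object)
    region[fc > band] = "lower_in_ESC"
    region[fc < -band] = "lower_in_EBd3"
    return region


def exon_profile(
    exon_counts: pd.DataFrame,
    design: pd.DataFrame,
    factor: str,
    state: str,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-exon depletion-vs-control log2 fold changes along each gene.

    ``exon_counts`` rows are ``<gene_id>|e<k>`` with k numbered 5'->3'.
    Returns (profile, flatness): profile has one row per exon with its fold
    change and the gene-level fold change computed from the summed exon
    counts; flatness is max_k |exon FC - gene FC| per gene (0 = perfectly
    uniform stabilization).
    """
    ids = exon_counts.index.to_series().str.rsplit("|", n=1, expand=True)
    if ids.shape[1] != 2 or ids.isna().any().any():
        raise ValueError("exon ids must look like '<gene_id>|e<k>'")
    gene_of = ids[0]
    exon_k = ids[1].str.lstrip("e").astype(int)

    mean_kd = group_means(exon_counts, design, state=state, condition=factor)
    mean_ctrl = group_means(exon_counts, design, state=state, condition="control")
    exon_fc = compute_log2fc(mean_kd, mean_ctrl, pseudocount)

    gene_kd = mean_kd.groupby(gene_of).sum()
    gene_ctrl = mean_ctrl.groupby(gene_of).sum()
    gene_fc = compute_log2fc(gene_kd, gene_ctrl, pseudocount)

    profile = pd.DataFrame(
        {
            "gene_id": gene_of,
            "exon_index": exon_k,
            "exon_log2fc": exon_fc,
            "gene_log2fc": gene_fc.reindex(gene_of).to_numpy(),
        }
    ).sort_values(["gene_id", "exon_index"])
    flatness = (
        (profile["exon_log2fc"] - profile["gene_log2fc"]).abs().groupby(profile["gene_id"]).max()
    )
    flatness.name = "flatness"
    return profile, flatness
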