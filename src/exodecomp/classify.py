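"""Rule-based attribution of state expression changes to transcription vs decay.

Genes whose RNA level differs between the two cell states (|log2 FC| > 0.5 by
RNAseq in control samples) are split by whether the transcriptional change
(PROseq log2 FC) agrees in sign with the RNA change (concordant) or not
(discordant), and by whether the transcript is exosome sensitive (> 0.5) in
the cell state where it is the LOWER expressed.  Genes transcriptionally
upregulated upon depletion in that state (PROseq KD/control log2 FC >= 0.5)
are set aside as likely indirect effects.  The resulting classes:

    discordant & sensitive    -> mainly_degradation
    concordant & sensitive    -> degradation_and_transcription
    concordant & insensitive  -> mainly_transcription
    discordant & insensitive  -> other

Boundary handling follows the printed thresholds strictly: |rna_fc| <= 0.5 is
excluded, sensitivity exactly 0.5 falls on the insensitive side, and a KD
fold change of exactly 0.5 is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = (
    "mainly_degradation",
    "degradation_and_transcription",
    "mainly_transcription",
    "other",
)

EXCLUDED = "excluded"


@dataclass(frozen=True)
class Thresholds:
    """Classifier cut-offs (defaults are the printed values)."""

    fc_threshold: float = 0.5
    sens_threshold: float = 0.5
    kd_threshold: float = 0.5
    #: |pro_fc| <= dead_band counts as "no clear transcriptional change"
    #: (discordant with any RNA change); 0 reduces to a pure sign rule, which
    #: is a coin flip for genes whose transcription genuinely does not change.
    #: The default reuses the universal 0.5 log2 cutoff.
    dead_band: float = 0.5


def assign_direction_and_quadrant(
    rna_fc: float, pro_fc: float, fc_threshold: float = 0.5, dead_band: float = 0.5
):
    """Direction of the state RNA change and its agreement with transcription.

    Returns ``(direction, quadrant)`` with direction in {"up_in_EBd3",
    "down_in_EBd3"} and quadrant in {"concordant", "discordant"}, or
    ``(None, None)`` if ``|rna_fc| <= fc_threshold`` (gene excluded).
    """
    if not (np.isfinite(rna_fc) and np.isfinite(pro_fc)):
        raise ValueError("fold changes must be finite")
    if abs(rna_fc) <= fc_threshold:
        return None, None
    direction = "up_in_EBd3" if rna_fc > 0 else "down_in_EBd3"
    if abs(pro_fc) <= dead_band:
        quadrant = "discordant"
    else:
        quadrant = "concordant" if np.sign(pro_fc) == np.sign(rna_fc) else "discordant"
    return direction, quadrant


def filter_kd_transcription(pro_log2fc_kd: float, threshold: float = 0.5) -> bool:
    """Keep a gene iff it is not transcriptionally upregulated upon depletion
    (strict: a KD log2 FC of exactly ``threshold`` is dropped)."""
    return bool(pro_log2fc_kd < threshold)


def assign_class(quadrant: str, sensitivity: float, sens_threshold: float = 0.5) -> str:
    if quadrant not in ("concordant", "discordant"):
        raise ValueError(f"bad quadrant {quadrant!r}")
    sensitive = sensitivity > sens_threshold
    if quadrant == "discordant":
        return "mainly_degradation" if sensitive else "other"
    return "degradation_and_transcription" if sensitive else "mainly_transcription"


def decide_call(
    rna_fc: float,
    pro_fc: float,
    sens_low_state: float,
    pro_kd_fc_low_state: float,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Scalar end-to-end decision for one gene; the vectorized path and the
    synthetic ground truth both reduce to this rule set."""
    direction, quadrant = assign_direction_and_quadrant(
        rna_fc, pro_fc, thresholds.fc_threshold, thresholds.dead_band
    )
    if direction is None:
        return {"direction": None, "quadrant": None, "class": EXCLUDED, "flag": ""}
    if sens_low_state is None or (
        isinstance(sens_low_state, float) and np.isnan(sens_low_state)
    ):
        return {
            "direction": direction,
            "quadrant": quadrant,
            "class": "other",
            "flag": "missing_sensitivity",
        }
    if not filter_kd_transcription(pro_kd_fc_low_state, thresholds.kd_threshold):
        return {
            "direction": direction,
            "quadrant": quadrant,
            "class": "other",
            "flag": "kd_upregulated",
        }
    cls = assign_class(quadrant, sens_low_state, thresholds.sens_threshold)
    return {"direction": direction, "quadrant": quadrant, "class": cls, "flag": ""}


def classify_genes(
    rna_state_fc: pd.Series,
    pro_state_fc: pd.Series,
    sens_esc: pd.Series,
    sens_ebd3: pd.Series,
    pro_kd_fc_esc: pd.Series,
    pro_kd_fc_ebd3: pd.Series,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Vectorized classification over a gene universe.

    All inputs are aligned on ``rna_state_fc.index``; sensitivities and KD
    fold changes missing for a gene (NaN after reindexing) yield class
    "other" with a flag, matching the scalar rule.
    """
    idx = rna_state_fc.index
    rna = rna_state_fc.to_numpy(dtype=float)
    pro = pro_state_fc.reindex(idx).to_numpy(dtype=float)
    se = sens_esc.reindex(idx).to_numpy(dtype=float)
    sb = sens_ebd3.reindex(idx).to_numpy(dtype=float)
    ke = pro_kd_fc_esc.reindex(idx).to_numpy(dtype=float)
    kb = pro_kd_fc_ebd3.reindex(idx).to_numpy(dtype=float)

    included = np.abs(rna) > thresholds.fc_threshold
    up = rna > 0
    # lower-expressed state: the state the transcript is DOWN in
    low_is_esc = up
    sens_low = np.where(low_is_esc, se, sb)
    kd_low = np.where(low_is_esc, ke, kb)

    band = np.abs(pro) <= thresholds.dead_band
    concordant = (~band) & (np.sign(pro) == np.sign(rna))

    cls = np.full(len(idx), EXCLUDED, dtype=object)
    flag = np.full(len(idx), "", dtype=object)
    direction = np.where(up, "up_in_EBd3", "down_in_EBd3").astype(object)
    direction[~included] = None
    quadrant = np.where(concordant, "concordant", "discordant").astype(object)
    quadrant[~included] = None

    missing = included & (np.isnan(pro) | np.isnan(sens_low) | np.isnan(kd_low))
    kd_fail = included & ~missing & (kd_low >= thresholds.kd_threshold)
    ok = included & ~missing & ~kd_fail
    sensitive = sens_low > thresholds.sens_threshold

    cls[missing] = "other"
    flag[missing] = "missing_sensitivity"
    cls[kd_fail] = "other"
    flag[kd_fail] = "kd_upregulated"
    cls[ok & concordant & sensitive] = "degradation_and_transcription"
    cls[ok & concordant & ~sensitive] = "mainly_transcription"
    cls[ok & ~concordant & sensitive] = "mainly_degradation"
    cls[ok & ~concordant & ~sensitive] = "other"

    return pd.DataFrame(
        {
            "gene_id": idx,
            "direction": direction,
            "quadrant": quadrant,
            "class": cls,
            "flag": flag,
            "rna_log2fc_state": rna,
            "pro_log2fc_state": pro,
            "low_state": np.where(low_is_esc, "ESC", "EBd3"),
            "sensitivity_low_state": sens_low,
            "pro_log2fc_kd_low_state": kd_low,
        },
        index=idx,
    )


def class_feature_report(
    calls: pd.DataFrame,
    gene_features: pd.DataFrame,
    metrics: dict[str, pd.Series],
    classes: tuple[str, ...] = CLASSES[:3],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class feature summaries and pairwise Mann-Whitney tests.

    Parameters
    ----------
    calls : classification table from :func:`classify_genes`.
    gene_features : DataFrame indexed by gene_id with at least ``biotype``,
        ``length`` and ``n_exons`` columns.
    metrics : named per-gene numeric vectors to summarize and test between
        classes (e.g. mean expression, |state log2 FC|).
    classes : classes to report (default: the three regulated classes).

    Returns
    -------
    (summary, tests): summary has one row per class with member count,
    per-biotype fractions (summing to 1 within a class) and metric medians;
    tests has one row per (metric, class pair) with the two-sided
    Mann-Whitney U and p-value.  Pairs involving a class with fewer than two
    members are skipped (flagged via tested=False).
    """
    missing = set(calls["gene_id"]) - set(gene_features.index)
    if missing:
        raise ValueError(f"genes missing from annotation: {sorted(missing)[:5]} ...")
    members = {c: calls.index[calls["class"] == c] for c in classes}
    all_metrics = dict(metrics)
    all_metrics.setdefault("gene_length_log2", np.log2(gene_features["length"].astype(float)))
    all_metrics.setdefault("exon_count", gene_features["n_exons"].astype(float))

    rows = []
    for c in classes:
        ids = members[c]
        row = {"class": c, "n": len(ids)}
        bt = gene_features.loc[ids, "biotype"].value_counts(normalize=True)
        for b in sorted(set(gene_features["biotype"])):
            row[f"frac_{b}"] = float(bt.get(b, 0.0))
        for name, vec in all_metrics.items():
            vals = vec.reindex(ids).dropna()
            row[f"median_{name}"] = float(vals.median()) if len(vals) else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("class")

    test_rows = []
    cl = list(classes)
    for name, vec in all_metrics.items():
        for i in range(len(cl)):
            for j in range(i + 1, len(cl)):
                a = vec.reindex(members[cl[i]]).dropna()
                b = vec.reindex(members[cl[j]]).dropna()
                if len(a) < 2 or len(b) < 2:
                    test_rows.append(
                        {"metric": name, "class_a": cl[i], "class_b": cl[j],
                         "U": np.nan, "p_value": np.nan, "tested": False}
                    )
                    continue
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                test_rows.append(
                    {"metric": name, "class_a": cl[i], "class_b": cl[j],
                     "U": float(u), "p_value": float(p), "tested": True}
                )
    return summary, pd.DataFrame(test_rows)


def evaluate_recovery(calls: pd.DataFrame, true_class: pd.Series) -> dict:
    """Confusion matrix and per-class precision/recall against ground truth.

    ``true_class`` must cover every called gene.  Accuracy is reported over
    genes whose true class is defined (not "excluded").
    """
    missing = set(calls["gene_id"]) - set(true_class.index)
    if missing:
        raise ValueError(f"truth missing for genes: {sorted(missing)[:5]} ...")
    truth = true_class.reindex(calls.index)
    called = calls["class"]
    confusion = pd.crosstab(truth, called, rownames=["truth"], colnames=["called"])
    defined = truth != EXCLUDED
    accuracy = float((truth[defined] == called[defined]).mean()) if defined.any() else np.nan
    per_class = {}
    for c in CLASSES:
        tp = int(((truth == c) & (called == c)).sum())
        fp = int(((truth != c) & (called == c)).sum())
        fn = int(((truth == c) & (called != c)).sum())
        per_class[c] = {
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "n_true": tp + fn,
        }
    return {"confusion": confusion, "accuracy": accuracy, "per_class": per_class}
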