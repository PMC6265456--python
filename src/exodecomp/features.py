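"""PROMPT and eRNA feature definition from CAGE tag clusters.

PROMPTs (promoter upstream transcripts) initiate antisense, up to ~2 kb
upstream of a gene's TSS, and are canonical nuclear exosome substrates.  They
are called here from CAGE evidence alone: a genic TSS is "anchored" when a
sense tag cluster lies within 100 bp of it, and the PROMPT is the closest
antisense cluster whose summit is at most 2 kb upstream (gene-relative) of
that TSS.  Expression is then quantified in a fixed 2-kb window downstream of
the PROMPT TSS on the PROMPT strand; eRNAs are quantified in 1-kb windows
downstream of each of the two divergent TSSs of pre-established enhancers.

Distances are measured to cluster summits.  All intervals are 0-based,
half-open.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import GeneModel, PromptRecord, TagCluster

__all__ = [
    "cluster_ctss",
    "filter_minor_intragenic_clusters",
    "define_prompts",
    "prompt_window",
    "quantify_windows",
]

DEFAULT_MERGE_DISTANCE = 20
DEFAULT_ANCHOR_WINDOW = 100
DEFAULT_MAX_DISTANCE = 2000
PROMPT_WINDOW_SIZE = 2000


def cluster_ctss(
    ctss: pd.DataFrame, merge_distance: int = DEFAULT_MERGE_DISTANCE
) -> tuple[list[TagCluster], pd.DataFrame]:
    """Merge per-bp CAGE TSSs (CTSSs) into tag clusters.

    ``ctss`` needs columns chrom, strand, pos plus one or more count columns.
    Two CTSSs on the same strand join one cluster iff their gap (position
    difference) is <= ``merge_distance``; cluster counts are the sums of
    member counts and the summit is the member with maximal total signal
    (leftmost on ties).

    Returns (clusters, counts) with counts indexed by cluster_id.
    """
    count_cols = [c for c in ctss.columns if c not in ("chrom", "strand", "pos")]
    if not count_cols:
        raise ValueError("ctss table has no count columns")
    agg = ctss.groupby(["chrom", "strand", "pos"], as_index=False)[count_cols].sum()
    clusters: list[TagCluster] = []
    rows = []
    cid = 0
    for (chrom, strand), grp in agg.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        counts = grp[count_cols].to_numpy(dtype=float)
        total = counts.sum(axis=1)
        breaks = np.flatnonzero(np.diff(pos) > merge_distance) + 1
        for member_idx in np.split(np.arange(len(pos)), breaks):
            cid += 1
            p = pos[member_idx]
            t = total[member_idx]
            summit = int(p[int(np.argmax(t))])  # argmax: leftmost on ties
            c_counts = counts[member_idx].sum(axis=0)
            clusters.append(
                TagCluster(
                    cluster_id=f"TC{cid:06d}",
                    chrom=str(chrom),
                    strand=str(strand),
                    start=int(p[0]),
                    end=int(p[-1]) + 1,
                    summit=summit,
                    total_expression=float(t.sum()),
                )
            )
            rows.append(dict(zip(count_cols, c_counts), cluster_id=f"TC{cid:06d}"))
    counts_df = pd.DataFrame(rows).set_index("cluster_id")[count_cols] if rows else \
        pd.DataFrame(columns=count_cols)
    return clusters, counts_df


def filter_minor_intragenic_clusters(
    clusters: Iterable[TagCluster],
    genes: Iterable[GeneModel],
    avg_expression: pd.Series,
    min_fraction: float = 0.015,
) -> list[TagCluster]:
    """Drop lowly expressed TSSs within genes.

    A cluster lying fully inside a gene on the gene's strand is removed iff
    its share of the summed replicate-average expression of all same-strand
    clusters within that gene is below ``min_fraction``.  Antisense or
    intergenic clusters are never dropped.
    """
    clusters = list(clusters)
    genes_by_key = defaultdict(list)
    for g in genes:
        genes_by_key[(g.chrom, g.strand)].append(g)
    # assign clusters to containing same-strand genes
    gene_members: dict[str, list[TagCluster]] = defaultdict(list)
    host: dict[str, list[str]] = defaultdict(list)
    for c in clusters:
        for g in genes_by_key.get((c.chrom, c.strand), ()):
            if g.start <= c.start and c.end <= g.end:
                gene_members[g.gene_id].append(c)
                host[c.cluster_id].append(g.gene_id)
    drop = set()
    for gene_id, members in gene_members.items():
        total = float(sum(avg_expression.get(c.cluster_id, 0.0) for c in members))
        if total <= 0:
            continue
        for c in members:
            if avg_expression.get(c.cluster_id, 0.0) / total < min_fraction:
                drop.add(c.cluster_id)
    return [c for c in clusters if c.cluster_id not in drop]


def prompt_window(prompt_tss: int, strand: str, size: int = PROMPT_WINDOW_SIZE) -> tuple[int, int]:
    """Quantification window extending ``size`` bp downstream (3'-ward) of the
    PROMPT TSS on the PROMPT strand, as a half-open interval."""
    if strand == "+":
        return prompt_tss, prompt_tss + size
    return prompt_tss - size + 1, prompt_tss + 1


def define_prompts(
    genes: Iterable[GeneModel],
    clusters: Iterable[TagCluster],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    anchor_window: int = DEFAULT_ANCHOR_WINDOW,
    window_size: int = PROMPT_WINDOW_SIZE,
) -> list[PromptRecord]:
    """Call PROMPTs: nearest upstream antisense cluster per anchored genic TSS.

    For every annotated TSS of every gene that is supported by a sense cluster
    within ``anchor_window`` bp, emit at most one PROMPT: the antisense
    cluster whose summit is nearest strictly upstream of the genic TSS
    (gene-relative) with distance <= ``max_distance``.  Equidistant antisense
    clusters are broken by higher total expression, then by cluster id.
    Duplicate (cluster, gene) pairs arising from alternative TSSs collapse to
    the record with the smallest distance.
    """
    by_key: dict[tuple[str, str], list[TagCluster]] = defaultdict(list)
    for c in clusters:
        by_key[(c.chrom, c.strand)].append(c)
    for key in by_key:
        by_key[key].sort(key=lambda c: c.summit)

    def summits(chrom, strand):
        cl = by_key.get((chrom, strand), [])
        return cl, np.array([c.summit for c in cl])

    best: dict[tuple[str, str], PromptRecord] = {}
    for g in genes:
        anti = "-" if g.strand == "+" else "+"
        sense_cl, sense_pos = summits(g.chrom, g.strand)
        anti_cl, anti_pos = summits(g.chrom, anti)
        if len(anti_cl) == 0 or len(sense_cl) == 0:
            continue
        for t in g.tss_positions:
            if np.abs(sense_pos - t).min() > anchor_window:
                continue  # TSS not CAGE-supported
            if g.strand == "+":
                dist = t - anti_pos
            else:
                dist = anti_pos - t
            ok = np.flatnonzero((dist > 0) & (dist <= max_distance))
            if ok.size == 0:
                continue
            cand = sorted(
                ok,
                key=lambda i: (dist[i], -anti_cl[i].total_expression, anti_cl[i].cluster_id),
            )
            i = cand[0]
            c = anti_cl[i]
            ws, we = prompt_window(c.summit, anti, window_size)
            rec = PromptRecord(
                prompt_id=f"PROMPT_{g.gene_id}_{c.cluster_id}",
                host_gene_id=g.gene_id,
                host_tss=t,
                chrom=g.chrom,
                strand=anti,
                prompt_tss=c.summit,
                cluster_id=c.cluster_id,
                window_start=ws,
                window_end=we,
                distance=int(dist[i]),
            )
            key = (g.gene_id, c.cluster_id)
            if key not in best or rec.distance < best[key].distance:
                best[key] = rec
    return sorted(best.values(), key=lambda r: r.prompt_id)


def quantify_windows(
    windows: pd.DataFrame,
    fragments: pd.DataFrame,
    stranded: bool = True,
    contig_lengths: Optional[dict[str, int]] = None,
) -> pd.Series | pd.DataFrame:
    """Count signal fragments overlapping each window (half-open intervals).

    ``windows``: columns window_id, chrom, strand, start, end.
    ``fragments``: columns chrom, strand, start, end, optionally sample_id.
    A fragment overlapping two windows counts in both.  Windows extending
    beyond contig bounds are clipped with a warning.
    """
    w = windows.copy()
    if contig_lengths is not None or (w["start"] < 0).any():
        clipped = False
        w["start"] = w["start"].clip(lower=0)
        if (windows["start"] < 0).any():
            clipped = True
        if contig_lengths is not None:
            for chrom, L in contig_lengths.items():
                m = w["chrom"] == chrom
                if (w.loc[m, "end"] > L).any():
                    clipped = True
                w.loc[m, "end"] = w.loc[m, "end"].clip(upper=L)
        if clipped:
            warnings.warn("windows extending beyond contig bounds were clipped")

    sample_groups = (
        fragments.groupby("sample_id") if "sample_id" in fragments.columns else [(None, fragments)]
    )
    results = {}
    for sample, frags in sample_groups:
        index: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        keys = ["chrom", "strand"] if stranded else ["chrom"]
        for key, grp in frags.groupby(keys):
            index[key if len(keys) > 1 else (key,)] = (
                np.sort(grp["start"].to_numpy()),
                np.sort(grp["end"].to_numpy()),
            )
        counts = np.zeros(len(w), dtype=np.int64)
        for k, row in enumerate(w.itertuples()):
            key = (row.chrom, row.strand) if stranded else (row.chrom,)
            if key not in index:
                continue
            starts, ends = index[key]
            # overlap: frag.start < w.end and frag.end > w.start
            n_start_ok = np.searchsorted(starts, row.end, side="left")
            n_end_bad = np.searchsorted(ends, row.start, side="right")
            counts[k] = n_start_ok - n_end_bad
        results[sample] = counts
    if list(results) == [None]:
        return pd.Series(results[None], index=w["window_id"].to_numpy(), name="count")
    return pd.DataFrame(results, index=w["window_id"].to_numpy())
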