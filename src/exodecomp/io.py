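"""Readers and writers for the text formats the pipeline exchanges.

GTF is written 1-based inclusive (the GTF convention) and read back through
gffutils; everything else is TSV/BED with BED-style 0-based half-open
coordinates, matching the in-memory convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import EnhancerRecord, ExpressionMatrix, GeneModel, TagCluster

__all__ = [
    "write_gtf",
    "read_gtf",
    "write_bed",
    "write_clusters_bed",
    "read_clusters_bed",
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
]


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    lines = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(
            "\t".join(
                [g.chrom, "exodecomp", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        for k, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                "\t".join(
                    [g.chrom, "exodecomp", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", attrs + f' exon_number "{k}";']
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start - 1, e.end)
                for e in db.features_of_type("exon")
                if e.attributes["gene_id"][0] == g.attributes["gene_id"][0]
            )
        )
        genes.append(
            GeneModel(
                gene_id=g.attributes["gene_id"][0],
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                exons=exons,
                biotype=g.attributes.get("gene_biotype", ["protein_coding"])[0],
            )
        )
    return genes


def write_bed(records: Iterable[tuple], path) -> None:
    """BED6 lines from (chrom, start, end, name, score, strand) tuples."""
    lines = ["\t".join(str(x) for x in rec) for rec in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_clusters_bed(clusters: Iterable[TagCluster], path) -> None:
    write_bed(
        ((c.chrom, c.start, c.end, f"{c.cluster_id}|summit={c.summit}", 0, c.strand)
         for c in clusters),
        path,
    )


def read_clusters_bed(path) -> list[TagCluster]:
    clusters = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name, _, strand = line.split("\t")
        cid, summit = name.split("|summit=")
        clusters.append(
            TagCluster(
                cluster_id=cid, chrom=chrom, strand=strand,
                start=int(start), end=int(end), summit=int(summit),
            )
        )
    return clusters


def enhancers_to_bed_records(enhancers: Iterable[EnhancerRecord]):
    for e in enhancers:
        yield (e.chrom, e.center_start, e.center_end, e.enhancer_id, 0, ".")


def write_matrix(expr, path, assay: str | None = None, stage: str | None = None) -> None:
    """TSV matrix plus a sidecar ``<path>.meta.json`` recording stage/assay."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if isinstance(expr, ExpressionMatrix):
        assay = assay or expr.assay
        stage = stage or expr.stage
    values.to_csv(path, sep="\t", index_label="feature_id")
    meta = {"assay": assay, "stage": stage, "n_features": int(values.shape[0]),
            "n_samples": int(values.shape[1])}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_matrix(path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ExpressionMatrix(
        values=values, stage=meta.get("stage", "raw"), assay=meta.get("assay", "unknown")
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
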