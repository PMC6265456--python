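"""Core domain types shared across the pipeline.

Coordinates are BED-style throughout: 0-based, half-open intervals.
GTF conversion (1-based, inclusive) happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

BIOTYPES = ("protein_coding", "lncRNA", "other_ncRNA")
STATES = ("ESC", "EBd3")
CONDITIONS = ("control", "RRP40_KD", "RBM7_KD")
ASSAYS = ("RNAseq", "PROseq", "CAGE")

#: Processing stages an expression matrix may pass through, with their rank in
#: the allowed order.  ``tpm`` is the CAGE counterpart of ``size_normalized``.
#: Batch adjustment (PROseq) happens before quantile normalization, matching
#: the order in which the assays' normalized values are produced.
STAGE_RANK = {
    "raw": 0,
    "size_normalized": 1,
    "tpm": 1,
    "batch_adjusted": 2,
    "quantile_normalized": 3,
}


class StageError(ValueError):
    """Raised on an expression-matrix stage transition against the declared order."""


@dataclass(frozen=True)
class GeneModel:
    """A merged transcription unit: the unit of all quantification.

    ``span`` runs from the most 5' TSS to the most distal 3' end; exons are
    sorted, disjoint sub-intervals of the span.  The primary TSS is the span's
    5' end on the gene's strand.
    """

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    tss_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if not self.tss_positions:
            object.__setattr__(self, "tss_positions", (self.tss,))

    @property
    def tss(self) -> int:
        """Primary TSS genomic position (5' end on the gene's strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_5to3(self) -> list[tuple[int, int]]:
        """Exons ordered 5' -> 3' along the gene's strand."""
        return list(self.exons) if self.strand == "+" else list(self.exons)[::-1]


@dataclass(frozen=True)
class TagCluster:
    """A CAGE tag cluster: merged run of nearby CTSSs on one strand.

    ``summit`` is the position of maximal tag signal within the cluster
    (leftmost on ties) and serves as the cluster's representative TSS.
    """

    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    total_expression: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"{self.cluster_id}: summit outside interval")


@dataclass(frozen=True)
class PromptRecord:
    """A PROMPT: antisense tag cluster just upstream of a host gene TSS.

    The quantification window spans 2 kb downstream of the PROMPT TSS on the
    PROMPT strand (i.e. away from the host gene).
    """

    prompt_id: str
    host_gene_id: str
    host_tss: int
    chrom: str
    strand: str  # PROMPT strand (opposite of host gene)
    prompt_tss: int
    cluster_id: str
    window_start: int
    window_end: int
    distance: int


@dataclass(frozen=True)
class EnhancerRecord:
    """A bidirectionally transcribed enhancer with two 1-kb eRNA windows."""

    enhancer_id: str
    chrom: str
    center_start: int
    center_end: int
    tss_plus: int
    tss_minus: int
    window_plus: tuple[int, int]
    window_minus: tuple[int, int]


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with an explicit processing stage."""

    values: pd.DataFrame  # index: feature_id, columns: sample_id
    stage: str
    assay: str

    def __post_init__(self) -> None:
        if self.stage not in STAGE_RANK:
            raise StageError(f"unknown stage {self.stage!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at ``stage``, enforcing forward-only transitions."""
        if stage not in STAGE_RANK:
            raise StageError(f"unknown stage {stage!r}")
        if STAGE_RANK[stage] <= STAGE_RANK[self.stage]:
            raise StageError(f"cannot move from {self.stage!r} to {stage!r}")
        return ExpressionMatrix(values=values, stage=stage, assay=self.assay)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        """Row subset at the same stage (filters never alter surviving values)."""
        return ExpressionMatrix(
            values=self.values.loc[feature_ids], stage=self.stage, assay=self.assay
        )
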