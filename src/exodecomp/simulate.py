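"""Synthetic data generator with known transcription/decay ground truth.

The generative model mirrors the biology being inferred downstream.  Each gene
g has a state-specific transcription rate tau_gs (expected PROseq signal, in
count units at library factor 1) and a decay susceptibility delta_gs in
[0, 1): the fraction of its nascent output removed by the nuclear exosome in
state s.  Depletion of the exosome is partial; a per-state residual decay
eps_s in [0, 1] remains (1 = depletion had no effect).  Expected signals:

    PROseq (transcription):  tau_gs                  in every condition
    RNAseq / CAGE (RNA):     tau_gs * (1 - delta_gs)          in control
                             tau_gs * (1 - eps_s * delta_gs)  under depletion

so depletion stabilizes decayed RNAs without touching transcription.  Counts
are negative binomial around these means (gamma-Poisson; Poisson at
dispersion 0), scaled by per-sample library factors carried identically by
spike-ins, and PROseq counts additionally carry a per-(gene, batch)
multiplicative batch effect emulating different sequencing times.

Ground-truth regulatory classes are computed by applying the classifier rules
of :mod:`exodecomp.classify` to the noise-free generative means, so that truth
and calls share definitions by construction.

Randomness: one root seed; per-component child streams are spawned from
``numpy.random.SeedSequence(seed)`` in a fixed order (annotation, design,
spike-ins, truth, features, counts), so every output is reproducible and
components are insensitive to each other's draw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .classify import Thresholds, decide_call
from .sensitivity import population_sensitivity
from .types import EnhancerRecord, GeneModel, TagCluster

__all__ = [
    "GeneratorConfig",
    "CapacityError",
    "generate_annotation",
    "make_design",
    "make_spikeins",
    "make_truth",
    "make_feature_truth",
    "build_cage_clusters",
    "simulate_counts",
    "generate_dataset",
    "SyntheticDataset",
]


class CapacityError(RuntimeError):
    """Annotation does not fit in the requested genome length."""


@dataclass
class GeneratorConfig:
    """All generator knobs with the study's default conditions.

    Expression scale corresponds to a deeply sequenced bulk experiment
    (median expected gene count ~800 at library factor 1, ~2 orders of
    magnitude dynamic range either way).  Depletion efficiency is lower in
    the differentiated state (eps_EBd3 > eps_ESC).
    """

    seed: int = 0
    # annotation
    n_genes: int = 2000
    n_enhancers: int = 75
    genome_length: Optional[int] = None  # None: fit exactly what is placed
    prompt_fraction: float = 0.2
    chrom: str = "chr1"
    # spike-ins
    n_spikeins: int = 50
    spike_abundance_median: float = 1000.0
    spike_abundance_log2_sd: float = 1.0
    # expression model
    tau_median: float = 800.0
    tau_log2_sd: float = 2.0
    #: residual transcriptional drift of UNregulated genes between states;
    #: regulated genes carry their changes via effect_log2fc instead.  Kept
    #: well inside the 0.5 log2 decision threshold so scenario classes stay
    #: separable in the noise-free truth.
    state_jitter_log2_sd: float = 0.1
    frac_regulated: float = 0.25
    regulated_split: tuple[float, float, float] = (2 / 3, 1 / 6, 1 / 6)
    effect_log2fc: float = 2.0
    delta_strong: float = 0.8
    delta_base: float = 0.0
    epsilon_esc: float = 0.1
    epsilon_ebd3: float = 0.4
    dispersion: float = 0.05
    # optional couplings between decay and transcription
    delta_coupling: str = "none"  # none | inverse_tau | state_low | invariant_random
    delta_max: float = 0.85  # inverse_tau: trend value at the lowest-tau gene
    #: per-gene scatter around the inverse-tau trend; a noiseless rank-coupled
    #: delta would be a monotone transform of expression that quantile
    #: normalization cancels exactly, which no real coupling is
    delta_coupling_noise_sd: float = 0.15
    coupling_fraction: float = 0.5  # state_low / invariant_random subset size
    delta_state: float = 0.7  # state_low / invariant_random susceptibility
    # PROMPTs / eRNAs: much weaker than genes even when stabilized, strongly
    # but variably decay-susceptible
    prompt_tau_median: float = 15.0
    prompt_tau_log2_sd: float = 1.2
    prompt_delta_range: tuple[float, float] = (0.7, 0.97)
    enhancer_tau_median: float = 12.0
    enhancer_delta_range: tuple[float, float] = (0.7, 0.97)
    cage_scale: float = 0.3
    # library and batch effects
    library_factor_log2_sd: float = 0.35
    proseq_batch_log2_shift: float = 0.35
    proseq_batch_log2_sd: float = 0.15

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_genes: int,
    n_enhancers: int,
    genome_length: Optional[int] = None,
    seed=0,
    prompt_fraction: float = 0.3,
    chrom: str = "chr1",
) -> tuple[list[GeneModel], list[EnhancerRecord], pd.DataFrame]:
    """Place non-overlapping genes and enhancers on one synthetic chromosome.

    Entities are laid out left to right with random inter-entity gaps of at
    least 3.5 kb, guaranteeing >= 3 kb upstream clearance for every gene so a
    latent PROMPT TSS (antisense, 200-2000 bp upstream of the gene TSS) never
    collides with a neighbour.  Each enhancer carries two divergent TSSs with
    1-kb eRNA windows.  Deterministic for a fixed seed.

    Returns (genes, enhancers, prompt_table); prompt_table has one row per
    gene: gene_id, has_prompt, prompt_tss, prompt_strand, distance.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed)
    entities = ["gene"] * n_genes + ["enh"] * n_enhancers
    rng.shuffle(entities)

    genes: list[GeneModel] = []
    enhancers: list[EnhancerRecord] = []
    cursor = 1000  # left margin
    gi = ei = 0
    for kind in entities:
        gap = int(rng.integers(3500, 12001))
        start = cursor + gap
        if kind == "gene":
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = rng.choice(
                ["protein_coding", "lncRNA", "other_ncRNA"], p=[0.75, 0.15, 0.10]
            )
            lam = 4.0 if biotype == "protein_coding" else 1.5
            n_exons = int(min(1 + rng.poisson(lam), 15))
            exon_lens = rng.integers(100, 401, n_exons)
            intron_lens = rng.integers(200, 2001, max(n_exons - 1, 0))
            exons = []
            pos = start
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k])))
                pos = exons[-1][1]
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            end = exons[-1][1]
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=tuple(exons),
                    biotype=str(biotype),
                )
            )
            cursor = end
        else:
            ei += 1
            width = int(rng.integers(200, 401))
            tss_minus = start
            tss_plus = start + width - 1
            enhancers.append(
                EnhancerRecord(
                    enhancer_id=f"E{ei:04d}",
                    chrom=chrom,
                    center_start=start,
                    center_end=start + width,
                    tss_plus=tss_plus,
                    tss_minus=tss_minus,
                    window_plus=(tss_plus, tss_plus + 1000),
                    window_minus=(tss_minus - 999, tss_minus + 1),
                )
            )
            cursor = tss_plus + 1000  # reserve the plus window
        if genome_length is not None and cursor > genome_length:
            raise CapacityError(
                f"placed {gi} genes / {ei} enhancers but ran past "
                f"genome_length={genome_length} at position {cursor}"
            )

    # latent PROMPT TSSs: antisense, 200-2000 bp upstream of the gene TSS
    rows = []
    for g in genes:
        has = bool(rng.random() < prompt_fraction)
        if has:
            d = int(rng.integers(201, 2001))
            if g.strand == "+":
                p_tss, p_strand = g.tss - d, "-"
            else:
                p_tss, p_strand = g.tss + d, "+"
        else:
            d, p_tss, p_strand = 0, -1, "."
        rows.append(
            {
                "gene_id": g.gene_id,
                "has_prompt": has,
                "prompt_tss": p_tss,
                "prompt_strand": p_strand,
                "distance": d,
            }
        )
    prompt_table = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return genes, enhancers, prompt_table


# ---------------------------------------------------------------------------
# design, spike-ins


def make_design(seed=0, library_factor_log2_sd: float = 0.35) -> pd.DataFrame:
    """Sample sheet: RNAseq in triplicate, CAGE and PROseq in duplicate, for
    {ESC, EBd3} x {control, RRP40_KD, RBM7_KD}.  PROseq replicates were
    sequenced at two different times (batches seq1/seq2, balanced across
    conditions); the other assays are single-batch."""
    rng = _rng(seed)
    rows = []
    reps = {"RNAseq": 3, "PROseq": 2, "CAGE": 2}
    for assay in ("RNAseq", "PROseq", "CAGE"):
        for state in ("ESC", "EBd3"):
            for condition in ("control", "RRP40_KD", "RBM7_KD"):
                for rep in range(1, reps[assay] + 1):
                    batch = f"seq{rep}" if assay == "PROseq" else f"{assay}_b1"
                    rows.append(
                        {
                            "sample_id": f"{assay}_{state}_{condition}_r{rep}",
                            "assay": assay,
                            "state": state,
                            "condition": condition,
                            "replicate": rep,
                            "batch": batch,
                            "library_factor": float(
                                2.0 ** rng.normal(0.0, library_factor_log2_sd)
                            ),
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def make_spikeins(
    seed=0,
    n_spikeins: int = 50,
    abundance_median: float = 1000.0,
    abundance_log2_sd: float = 1.0,
) -> pd.DataFrame:
    """Spike-in set: per-assay-constant true abundances (no state/condition
    effect); expected count = abundance x library factor."""
    if n_spikeins < 20:
        raise ValueError("at least 20 spike-ins required")
    rng = _rng(seed)
    ab = abundance_median * 2.0 ** rng.normal(0.0, abundance_log2_sd, n_spikeins)
    return pd.DataFrame(
        {"spike_id": [f"SPIKE_{i:03d}" for i in range(1, n_spikeins + 1)],
         "true_abundance": ab}
    ).set_index("spike_id", drop=False)


# ---------------------------------------------------------------------------
# ground truth


def _rank_pct(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x, kind="mergesort"), kind="mergesort")
    return order / max(len(x) - 1, 1)


def make_truth(
    genes: list[GeneModel], cfg: GeneratorConfig, seed=0
) -> pd.DataFrame:
    """Per-gene transcription rates, decay susceptibilities and implied class.

    Scenario planting (delta_coupling="none"): a fraction of genes is
    regulated between states, split into transcription-driven (tau shifted by
    effect_log2fc, baseline decay), decay-driven (tau equal up to jitter,
    delta_strong in the lower state) and combined (both).  Every gene carries
    a small state-specific log2 jitter on tau: no real gene is transcribed
    identically in two states, and this places the decay-driven genes'
    transcriptional fold change at a small nonzero value instead of exactly 0.

    Optional couplings replace the delta assignment:

    - ``inverse_tau``: delta_gs decreases linearly in the within-state rank of
      tau_gs, from delta_max down to ~0 (lowly transcribed genes are the
      preferential decay substrates).
    - ``state_low``: a subset of genes is transcriptionally downregulated in
      one state and additionally decayed (delta_state) in that same state.
    - ``invariant_random``: same transcriptional structure as ``state_low``
      but delta_state is assigned to an independent random subset in BOTH
      states, decoupling sensitivity from the state difference.
    """
    rng = _rng(seed)
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    tau_base = cfg.tau_median * 2.0 ** rng.normal(0.0, cfg.tau_log2_sd, n)
    jitter = rng.normal(0.0, cfg.state_jitter_log2_sd, n)
    tau_esc = tau_base * 2.0 ** (-jitter / 2)
    tau_eb = tau_base * 2.0 ** (jitter / 2)
    delta_esc = np.full(n, cfg.delta_base)
    delta_eb = np.full(n, cfg.delta_base)
    scenario = np.full(n, "null", dtype=object)

    def plant_tau_effect(i: int, down_state: str) -> None:
        nonlocal tau_esc, tau_eb
        if down_state == "ESC":
            tau_esc[i] *= 2.0 ** (-cfg.effect_log2fc)
        else:
            tau_eb[i] *= 2.0 ** (-cfg.effect_log2fc)

    if cfg.delta_coupling in ("none", "inverse_tau"):
        n_reg = int(round(cfg.frac_regulated * n))
        reg = rng.permutation(n)[:n_reg]
        w = np.array(cfg.regulated_split, dtype=float)
        w = w / w.sum()
        n_mt = int(round(w[0] * n_reg))
        n_md = int(round(w[1] * n_reg))
        groups = {
            "transcription": reg[:n_mt],
            "degradation": reg[n_mt : n_mt + n_md],
            "both": reg[n_mt + n_md :],
        }
        for name, idxs in groups.items():
            for i in idxs:
                down = "ESC" if rng.random() < 0.5 else "EBd3"
                scenario[i] = f"{name}_down_{down}"
                if name in ("transcription", "both"):
                    plant_tau_effect(i, down)
                if name in ("degradation", "both"):
                    if down == "ESC":
                        delta_esc[i] = cfg.delta_strong
                    else:
                        delta_eb[i] = cfg.delta_strong
        if cfg.delta_coupling == "inverse_tau":
            noise = rng.normal(0.0, cfg.delta_coupling_noise_sd, (2, n))
            delta_esc = np.clip(
                cfg.delta_max * (1.0 - _rank_pct(tau_esc)) + noise[0], 0.0, 0.95
            )
            delta_eb = np.clip(
                cfg.delta_max * (1.0 - _rank_pct(tau_eb)) + noise[1], 0.0, 0.95
            )
            scenario = np.array(
                [s + "|inverse_tau" for s in scenario], dtype=object
            )
    elif cfg.delta_coupling in ("state_low", "invariant_random"):
        n_reg = int(round(cfg.coupling_fraction * n))
        reg = rng.permutation(n)[:n_reg]
        down_states = np.where(rng.random(n_reg) < 0.5, "ESC", "EBd3")
        for i, down in zip(reg, down_states):
            scenario[i] = f"state_reg_down_{down}"
            plant_tau_effect(i, down)
        if cfg.delta_coupling == "state_low":
            for i, down in zip(reg, down_states):
                if down == "ESC":
                    delta_esc[i] = cfg.delta_state
                else:
                    delta_eb[i] = cfg.delta_state
        else:
            hot = rng.permutation(n)[:n_reg]
            delta_esc[hot] = cfg.delta_state
            delta_eb[hot] = cfg.delta_state
    else:
        raise ValueError(f"unknown delta_coupling {cfg.delta_coupling!r}")

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "scenario": scenario,
            "tau_ESC": tau_esc,
            "tau_EBd3": tau_eb,
            "delta_ESC": delta_esc,
            "delta_EBd3": delta_eb,
            "epsilon_ESC": cfg.epsilon_esc,
            "epsilon_EBd3": cfg.epsilon_ebd3,
        }
    ).set_index("gene_id", drop=False)
    return annotate_truth_class(truth)


def annotate_truth_class(
    truth: pd.DataFrame, thresholds: Thresholds = Thresholds(), pseudocount: float = 1.0
) -> pd.DataFrame:
    """Apply the classifier rules to the noise-free generative means.

    True RNA means are tau*(1-delta) in control; the true transcriptional KD
    fold change is 0 (the exosome does not touch transcription); the true
    sensitivity is delta*(1-eps)/(1-eps*delta).
    """
    rna_esc = truth["tau_ESC"] * (1 - truth["delta_ESC"])
    rna_eb = truth["tau_EBd3"] * (1 - truth["delta_EBd3"])
    rna_fc = np.log2(rna_eb + pseudocount) - np.log2(rna_esc + pseudocount)
    pro_fc = np.log2(truth["tau_EBd3"] + pseudocount) - np.log2(
        truth["tau_ESC"] + pseudocount
    )
    sens_esc = population_sensitivity(truth["delta_ESC"], truth["epsilon_ESC"])
    sens_eb = population_sensitivity(truth["delta_EBd3"], truth["epsilon_EBd3"])
    out = truth.copy()
    out["true_rna_log2fc"] = rna_fc
    out["true_pro_log2fc"] = pro_fc
    out["true_sens_ESC"] = np.asarray(sens_esc)
    out["true_sens_EBd3"] = np.asarray(sens_eb)
    calls = [
        decide_call(
            r, p, se if r > 0 else sb, 0.0, thresholds
        )
        for r, p, se, sb in zip(rna_fc, pro_fc, out["true_sens_ESC"], out["true_sens_EBd3"])
    ]
    out["true_direction"] = [c["direction"] for c in calls]
    out["true_quadrant"] = [c["quadrant"] for c in calls]
    out["true_class"] = [c["class"] for c in calls]
    return out


def make_feature_truth(
    prompt_table: pd.DataFrame,
    enhancers: list[EnhancerRecord],
    cfg: GeneratorConfig,
    seed=0,
) -> pd.DataFrame:
    """Expression parameters for PROMPT and eRNA features (canonical exosome
    substrates: lowly transcribed, highly decay-susceptible in both states)."""
    rng = _rng(seed)
    rows = []
    for gene_id, row in prompt_table.iterrows():
        if not row["has_prompt"]:
            continue
        tau = cfg.prompt_tau_median * 2.0 ** rng.normal(0.0, cfg.prompt_tau_log2_sd)
        j = rng.normal(0.0, cfg.state_jitter_log2_sd)
        delta = float(rng.uniform(*cfg.prompt_delta_range))
        rows.append(
            {
                "feature_id": f"PROMPT_{gene_id}",
                "kind": "PROMPT",
                "tau_ESC": tau * 2.0 ** (-j / 2),
                "tau_EBd3": tau * 2.0 ** (j / 2),
                "delta_ESC": delta,
                "delta_EBd3": delta,
            }
        )
    for enh in enhancers:
        for side in ("plus", "minus"):
            tau = cfg.enhancer_tau_median * 2.0 ** rng.normal(0.0, cfg.prompt_tau_log2_sd)
            j = rng.normal(0.0, cfg.state_jitter_log2_sd)
            delta = float(rng.uniform(*cfg.enhancer_delta_range))
            rows.append(
                {
                    "feature_id": f"{enh.enhancer_id}_{side}",
                    "kind": "eRNA",
                    "tau_ESC": tau * 2.0 ** (-j / 2),
                    "tau_EBd3": tau * 2.0 ** (j / 2),
                    "delta_ESC": delta,
                    "delta_EBd3": delta,
                }
            )
    cols = ["feature_id", "kind", "tau_ESC", "tau_EBd3", "delta_ESC", "delta_EBd3"]
    df = pd.DataFrame(rows, columns=cols)
    df["epsilon_ESC"] = cfg.epsilon_esc
    df["epsilon_EBd3"] = cfg.epsilon_ebd3
    return df.set_index("feature_id", drop=False)


# ---------------------------------------------------------------------------
# CAGE tag-cluster geometry


def build_cage_clusters(
    genes: list[GeneModel],
    prompt_table: pd.DataFrame,
    enhancers: list[EnhancerRecord],
    seed=0,
) -> list[TagCluster]:
    """One tag cluster per active TSS: genic TSSs (sense, within a few bp of
    the annotated TSS), latent PROMPT TSSs (antisense upstream) and the two
    divergent enhancer TSSs.  Counts live in the CAGE matrix keyed by
    cluster_id."""
    rng = _rng(seed)
    clusters = []

    def add(cluster_id, chrom, strand, summit):
        left = int(rng.integers(0, 6))
        width = left + 1 + int(rng.integers(3, 15))
        clusters.append(
            TagCluster(
                cluster_id=cluster_id,
                chrom=chrom,
                strand=strand,
                start=summit - left,
                end=summit - left + width,
                summit=summit,
            )
        )

    for g in genes:
        add(f"TC_{g.gene_id}", g.chrom, g.strand, g.tss)
    for gene_id, row in prompt_table.iterrows():
        if row["has_prompt"]:
            add(f"TC_PROMPT_{gene_id}", clusters[0].chrom, row["prompt_strand"],
                int(row["prompt_tss"]))
    for enh in enhancers:
        add(f"TC_{enh.enhancer_id}_plus", enh.chrom, "+", enh.tss_plus)
        add(f"TC_{enh.enhancer_id}_minus", enh.chrom, "-", enh.tss_minus)
    return clusters


# ---------------------------------------------------------------------------
# count simulation


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson: var = mu + dispersion * mu^2."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    return rng.poisson(lam)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="mergesort")
        base[order[:short]] += 1
    return base


def _abundance(
    tau_esc, tau_eb, delta_esc, delta_eb, eps_esc, eps_eb, state: str, condition: str,
    assay: str,
):
    tau = tau_esc if state == "ESC" else tau_eb
    if assay == "PROseq":
        return tau
    delta = delta_esc if state == "ESC" else delta_eb
    if condition == "control":
        return tau * (1.0 - delta)
    eps = eps_esc if state == "ESC" else eps_eb
    return tau * (1.0 - eps * delta)


def simulate_counts(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    design: pd.DataFrame,
    spikes: pd.DataFrame,
    dispersion: float = 0.05,
    seed=0,
    feature_truth: Optional[pd.DataFrame] = None,
    cage_scale: float = 0.3,
    proseq_batch_log2_shift: float = 0.35,
    proseq_batch_log2_sd: float = 0.15,
    per_exon: bool = True,
) -> dict[str, pd.DataFrame]:
    """Draw raw count tables for all assays (spike-in rows included for
    RNAseq and PROseq; CAGE is normalized by total tags so it carries none).

    Returns a dict with keys "RNAseq", "PROseq", "CAGE" and, when
    ``per_exon`` is set, "RNAseq_exon": per-exon rows apportioned from each
    gene's count proportionally to exon length (uniform full-length
    stabilization; exon ids are ``<gene_id>|e<k>`` in 5'->3' order).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rngs = dict(zip(("RNAseq", "PROseq", "CAGE", "batch"),
                    (np.random.default_rng(c) for c in ss.spawn(4))))

    ft = feature_truth if feature_truth is not None else pd.DataFrame(
        columns=["feature_id", "kind", "tau_ESC", "tau_EBd3",
                 "delta_ESC", "delta_EBd3", "epsilon_ESC", "epsilon_EBd3"]
    ).set_index(pd.Index([], name="feature_id"))

    def rows_for(assay: str) -> pd.DataFrame:
        parts = [truth[["tau_ESC", "tau_EBd3", "delta_ESC", "delta_EBd3",
                        "epsilon_ESC", "epsilon_EBd3"]]]
        if len(ft):
            parts.append(ft[["tau_ESC", "tau_EBd3", "delta_ESC", "delta_EBd3",
                             "epsilon_ESC", "epsilon_EBd3"]])
        df = pd.concat(parts)
        if assay == "CAGE":
            df = df.copy()
            df[["tau_ESC", "tau_EBd3"]] *= cage_scale
            df.index = [f"TC_{f}" for f in df.index]
        return df

    out: dict[str, pd.DataFrame] = {}
    batch_factors: dict[str, pd.Series] = {}
    for assay in ("RNAseq", "PROseq", "CAGE"):
        params = rows_for(assay)
        samples = design[design["assay"] == assay]
        if samples.empty:
            continue
        if assay == "PROseq":
            batches = sorted(samples["batch"].unique())
            shifts = {}
            for k, b in enumerate(batches):
                sign = 1.0 if k % 2 == 0 else -1.0
                shifts[b] = 2.0 ** (
                    sign * proseq_batch_log2_shift
                    + rngs["batch"].normal(0.0, proseq_batch_log2_sd, len(params))
                )
                batch_factors[b] = pd.Series(shifts[b], index=params.index)
        cols = {}
        for _, s in samples.iterrows():
            mu = np.array([
                _abundance(
                    p.tau_ESC, p.tau_EBd3, p.delta_ESC, p.delta_EBd3,
                    p.epsilon_ESC, p.epsilon_EBd3, s["state"], s["condition"], assay,
                )
                for p in params.itertuples()
            ]) * s["library_factor"]
            if assay == "PROseq":
                mu = mu * shifts[s["batch"]]
            cols[s["sample_id"]] = _nb_draw(rngs[assay], mu, dispersion)
        counts = pd.DataFrame(cols, index=params.index)
        counts.index.name = "feature_id"
        if assay in ("RNAseq", "PROseq"):
            mu_spike = spikes["true_abundance"].to_numpy()[:, None] * \
                samples["library_factor"].to_numpy()[None, :]
            spike_counts = pd.DataFrame(
                _nb_draw(rngs[assay], mu_spike, dispersion),
                index=spikes.index, columns=samples["sample_id"],
            )
            counts = pd.concat([counts, spike_counts])
            counts.index.name = "feature_id"
        out[assay] = counts

    if per_exon and "RNAseq" in out:
        exon_rows = []
        exon_index = []
        rna = out["RNAseq"]
        for g in genes:
            lens = np.array([e - s for s, e in g.exons_5to3()], dtype=float)
            gene_counts = rna.loc[g.gene_id].to_numpy()
            alloc = np.stack(
                [_largest_remainder(int(c), lens) for c in gene_counts], axis=1
            )
            for k in range(len(lens)):
                exon_index.append(f"{g.gene_id}|e{k + 1:02d}")
            exon_rows.append(alloc)
        out["RNAseq_exon"] = pd.DataFrame(
            np.vstack(exon_rows), index=pd.Index(exon_index, name="feature_id"),
            columns=rna.columns,
        )
    out["_proseq_batch_factors"] = pd.DataFrame(batch_factors) if batch_factors else pd.DataFrame()
    return out


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genes: list[GeneModel]
    enhancers: list[EnhancerRecord]
    prompt_table: pd.DataFrame
    clusters: list[TagCluster]
    design: pd.DataFrame
    spikes: pd.DataFrame
    truth: pd.DataFrame
    feature_truth: pd.DataFrame
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def gene_features(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "biotype": [g.biotype for g in self.genes],
                "length": [g.length for g in self.genes],
                "n_exons": [g.n_exons for g in self.genes],
            }
        ).set_index("gene_id")


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate annotation, design, truth and counts from one root seed."""
    ss = np.random.SeedSequence(cfg.seed)
    s_ann, s_design, s_spike, s_truth, s_feat, s_counts = ss.spawn(6)
    genes, enhancers, prompt_table = generate_annotation(
        cfg.n_genes, cfg.n_enhancers, cfg.genome_length,
        seed=np.random.default_rng(s_ann),
        prompt_fraction=cfg.prompt_fraction, chrom=cfg.chrom,
    )
    design = make_design(np.random.default_rng(s_design), cfg.library_factor_log2_sd)
    spikes = make_spikeins(
        np.random.default_rng(s_spike), cfg.n_spikeins,
        cfg.spike_abundance_median, cfg.spike_abundance_log2_sd,
    )
    truth = make_truth(genes, cfg, np.random.default_rng(s_truth))
    rng_feat = np.random.default_rng(s_feat)
    feature_truth = make_feature_truth(prompt_table, enhancers, cfg, rng_feat)
    clusters = build_cage_clusters(genes, prompt_table, enhancers, rng_feat)
    counts = simulate_counts(
        genes, truth, design, spikes, cfg.dispersion, s_counts,
        feature_truth=feature_truth, cage_scale=cfg.cage_scale,
        proseq_batch_log2_shift=cfg.proseq_batch_log2_shift,
        proseq_batch_log2_sd=cfg.proseq_batch_log2_sd,
    )
    return SyntheticDataset(
        config=cfg, genes=genes, enhancers=enhancers, prompt_table=prompt_table,
        clusters=clusters, design=design, spikes=spikes, truth=truth,
        feature_truth=feature_truth, counts=counts,
    )
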