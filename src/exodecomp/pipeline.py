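"""End-to-end orchestration: generate -> normalize -> features -> sensitivity
-> stratify -> classify, with a single config and a machine-readable manifest.

Every stage writes plain TSV/BED/GTF/JSON outputs into the run directory; the
manifest records the full parameter set, the stages run, sha256 checksums of
every output and headline metrics.  Runs are deterministic: re-running with
the same config reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as clf
from . import features as feat
from . import normalize as norm
from . import sensitivity as sens
from . import stratify as strat
from .io import (
    enhancers_to_bed_records,
    write_bed,
    write_clusters_bed,
    write_gtf,
    write_matrix,
    write_table,
)
from .simulate import GeneratorConfig, SyntheticDataset, generate_dataset
from .types import ExpressionMatrix

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("generate", "normalize", "features", "sensitivity", "stratify", "classify")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # classifier thresholds (printed defaults)
    fc_threshold: float = 0.5
    sens_threshold: float = 0.5
    kd_threshold: float = 0.5
    dead_band: float = 0.5
    # stratification / normalization parameters
    band: float = 0.5
    pseudocount: float = 1.0
    percentile_cut: float = 1.0
    merge_distance: int = 20
    anchor_window: int = 100
    max_distance: int = 2000
    min_fraction: float = 0.015
    # stage toggles
    run_features: bool = True
    run_sensitivity: bool = True
    run_stratify: bool = True
    run_classify: bool = True

    def __post_init__(self):
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        if not (0 <= self.percentile_cut < 100):
            raise ValueError("percentile_cut must be in [0, 100)")
        for name in ("fc_threshold", "sens_threshold", "kd_threshold", "dead_band", "band"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def seed(self) -> int:
        return self.generator.seed

    _TUPLE_FIELDS = ("regulated_split", "prompt_delta_range", "enhancer_delta_range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in self._TUPLE_FIELDS:
            d["generator"][name] = list(d["generator"][name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        for name in cls._TUPLE_FIELDS:
            if name in gen:
                gen[name] = tuple(gen[name])
        return cls(generator=GeneratorConfig(**gen), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def thresholds(self) -> clf.Thresholds:
        return clf.Thresholds(
            fc_threshold=self.fc_threshold,
            sens_threshold=self.sens_threshold,
            kd_threshold=self.kd_threshold,
            dead_band=self.dead_band,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ctrl_samples(design: pd.DataFrame, assay: str, state: str = "ESC") -> list[str]:
    m = (design["assay"] == assay) & (design["state"] == state) & (
        design["condition"] == "control"
    )
    return list(design.loc[m, "sample_id"])


def normalize_dataset(ds: SyntheticDataset, config: RunConfig) -> dict[str, ExpressionMatrix]:
    """Apply each assay's normalization chain; returns normalized matrices
    plus size factors under keys 'RNAseq', 'PROseq', 'CAGE', 'RNAseq_exon',
    '_size_factors'."""
    design = ds.design
    spike_ids = list(ds.spikes.index)
    out: dict = {"_size_factors": {}}

    # RNAseq: spike size factors -> expressed filter -> quantile normalization
    raw_rna = ExpressionMatrix(ds.counts["RNAseq"], stage="raw", assay="RNAseq")
    sf_rna = norm.spikein_size_factors(raw_rna.values.loc[spike_ids])
    em = norm.apply_size_factors(raw_rna, sf_rna, spike_ids)
    em = em.subset(norm.expressed_filter(em, design))
    out["RNAseq"] = norm.quantile_normalize_to_reference(
        em, _ctrl_samples(design, "RNAseq")
    )
    out["_size_factors"]["RNAseq"] = sf_rna

    # per-exon RNAseq values share the gene-level size factors
    if "RNAseq_exon" in ds.counts:
        exon = ExpressionMatrix(ds.counts["RNAseq_exon"], stage="raw", assay="RNAseq")
        out["RNAseq_exon"] = norm.apply_size_factors(exon, sf_rna)

    # PROseq: size factors -> filter -> batch adjust -> quantile -> percentile cut
    raw_pro = ExpressionMatrix(ds.counts["PROseq"], stage="raw", assay="PROseq")
    sf_pro = norm.spikein_size_factors(raw_pro.values.loc[spike_ids])
    em = norm.apply_size_factors(raw_pro, sf_pro, spike_ids)
    em = em.subset(norm.expressed_filter(em, design))
    em = norm.batch_adjust(em, design)
    em = norm.quantile_normalize_to_reference(em, _ctrl_samples(design, "PROseq"))
    em = em.subset(norm.exclude_lowest_percentile(em, config.percentile_cut))
    out["PROseq"] = em
    out["_size_factors"]["PROseq"] = sf_pro

    # CAGE: TPM -> expressed filter -> minor intragenic cluster filter -> quantile
    raw_cage = ExpressionMatrix(ds.counts["CAGE"], stage="raw", assay="CAGE")
    em = norm.cage_tpm(raw_cage)
    em = em.subset(norm.expressed_filter(em, design))
    cluster_map = {c.cluster_id: c for c in ds.clusters}
    avg = em.values.mean(axis=1)
    kept = feat.filter_minor_intragenic_clusters(
        [cluster_map[i] for i in em.values.index if i in cluster_map],
        ds.genes,
        avg,
        config.min_fraction,
    )
    keep_ids = [c.cluster_id for c in kept] + [
        i for i in em.values.index if i not in cluster_map
    ]
    em = em.subset([i for i in em.values.index if i in set(keep_ids)])
    out["CAGE"] = norm.quantile_normalize_to_reference(em, _ctrl_samples(design, "CAGE"))
    return out


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the configured stages into ``outdir``; returns the run directory.

    On failure a ``FAILED`` marker naming the stage is left next to whatever
    partial outputs were produced, and a :class:`PipelineError` is raised.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    manifest: dict = {"config": config.to_dict(), "stages": [], "metrics": {}}
    try:
        # ------------------------------------------------------------ generate
        ds = generate_dataset(config.generator)
        config.to_yaml(out / "config.yaml")
        write_gtf(ds.genes, out / "annotation.gtf")
        write_bed(enhancers_to_bed_records(ds.enhancers), out / "enhancers.bed")
        write_clusters_bed(ds.clusters, out / "clusters.bed")
        write_table(ds.design, out / "design.tsv")
        write_table(ds.spikes, out / "spikes.tsv")
        write_table(ds.truth, out / "truth.tsv")
        write_table(ds.feature_truth, out / "feature_truth.tsv")
        for assay in ("RNAseq", "PROseq", "CAGE", "RNAseq_exon"):
            write_matrix(ds.counts[assay], out / f"counts_{assay}.tsv",
                         assay=assay.replace("_exon", ""), stage="raw")
        manifest["stages"].append("generate")

        # ----------------------------------------------------------- normalize
        stage = "normalize"
        normalized = normalize_dataset(ds, config)
        for key in ("RNAseq", "PROseq", "CAGE", "RNAseq_exon"):
            write_matrix(normalized[key], out / f"normalized_{key}.tsv")
        for assay, sf in normalized["_size_factors"].items():
            sf.rename_axis("sample_id").reset_index().to_csv(
                out / f"size_factors_{assay}.tsv", sep="\t", index=False
            )
        manifest["stages"].append("normalize")

        # ------------------------------------------------------------ features
        if config.run_features:
            stage = "features"
            cage = normalized["CAGE"]
            avg = cage.values.mean(axis=1)
            clusters = [
                dataclasses.replace(c, total_expression=float(avg.get(c.cluster_id, 0.0)))
                for c in ds.clusters
                if c.cluster_id in set(cage.values.index)
            ]
            prompts = feat.define_prompts(
                ds.genes, clusters,
                max_distance=config.max_distance,
                anchor_window=config.anchor_window,
            )
            pdf = pd.DataFrame([dataclasses.asdict(p) for p in prompts])
            write_table(pdf, out / "prompts.tsv")
            planted = ds.prompt_table[ds.prompt_table["has_prompt"]]
            called = {(p.host_gene_id, p.prompt_tss) for p in prompts}
            truth_set = {
                (gid, int(r["prompt_tss"])) for gid, r in planted.iterrows()
            }
            tp = len(called & truth_set)
            manifest["metrics"]["prompt_recall"] = tp / len(truth_set) if truth_set else 1.0
            manifest["metrics"]["prompt_precision"] = tp / len(called) if called else 1.0
            manifest["stages"].append("features")

        # --------------------------------------------------------- sensitivity
        sens_tables: dict[str, pd.DataFrame] = {}
        fold_changes: dict[str, pd.Series] = {}
        if config.run_sensitivity:
            stage = "sensitivity"
            frames = []
            for assay in ("RNAseq", "CAGE"):
                for factor in ("RRP40_KD", "RBM7_KD"):
                    for state in ("ESC", "EBd3"):
                        t = sens.compute_sensitivity(
                            normalized[assay], ds.design, factor, state
                        )
                        t.insert(1, "assay", assay)
                        frames.append(t)
                        sens_tables[f"{assay}:{factor}:{state}"] = t
            write_table(pd.concat(frames, ignore_index=True), out / "sensitivity.tsv")
            fc_rows = {}
            fold_changes["rna_state"] = sens.state_log2fc(
                normalized["RNAseq"], ds.design, pseudocount=config.pseudocount
            )
            fold_changes["pro_state"] = sens.state_log2fc(
                normalized["PROseq"], ds.design, pseudocount=config.pseudocount
            )
            for factor in ("RRP40_KD", "RBM7_KD"):
                fold_changes[f"pro_kd:{factor}:pooled"] = sens.kd_log2fc(
                    normalized["PROseq"], ds.design, factor,
                    pseudocount=config.pseudocount,
                )
                for state in ("ESC", "EBd3"):
                    fold_changes[f"pro_kd:{factor}:{state}"] = sens.kd_log2fc(
                        normalized["PROseq"], ds.design, factor, state,
                        pseudocount=config.pseudocount,
                    )
                    fold_changes[f"rna_kd:{factor}:{state}"] = sens.kd_log2fc(
                        normalized["RNAseq"], ds.design, factor, state,
                        pseudocount=config.pseudocount,
                    )
            fc_df = pd.DataFrame(fold_changes)
            fc_df.rename_axis("feature_id").reset_index().to_csv(
                out / "fold_changes.tsv", sep="\t", index=False
            )
            manifest["stages"].append("sensitivity")

        # ------------------------------------------------------------ stratify
        if config.run_stratify and config.run_sensitivity:
            stage = "stratify"
            gene_ids = ds.truth.index
            summaries = []
            for strat_assay in ("PROseq", "RNAseq"):
                for state in ("ESC", "EBd3"):
                    ctrl = sens.group_means(
                        normalized[strat_assay], ds.design, state=state, condition="control"
                    )
                    ctrl = ctrl[ctrl.index.isin(gene_ids)]
                    stable = sens_tables[f"RNAseq:RRP40_KD:{state}"]["sensitivity"]
                    common = ctrl.index.intersection(stable.index)
                    if len(common) < 5:
                        continue
                    q = strat.assign_quintiles(ctrl.loc[common], stratifier=strat_assay)
                    summary, _, trend = strat.quintile_sensitivity_summary(
                        q, stable.loc[common]
                    )
                    summary = summary.reset_index()
                    summary.insert(0, "stratifier", strat_assay)
                    summary.insert(1, "state", state)
                    summary["trend"] = trend
                    summaries.append(summary)
            write_table(pd.concat(summaries, ignore_index=True), out / "quintile_summary.tsv")

            rna = normalized["RNAseq"]
            esc = sens.group_means(rna, ds.design, state="ESC", condition="control")
            ebd = sens.group_means(rna, ds.design, state="EBd3", condition="control")
            gene_mask = esc.index.isin(gene_ids)
            regions = strat.assign_state_regions(
                esc[gene_mask], ebd[gene_mask], band=config.band,
                pseudocount=config.pseudocount,
            )
            regions.rename_axis("feature_id").reset_index().to_csv(
                out / "regions.tsv", sep="\t", index=False
            )
            profile, flatness = strat.exon_profile(
                normalized["RNAseq_exon"].values, ds.design, "RRP40_KD", "ESC",
                pseudocount=config.pseudocount,
            )
            write_table(profile, out / "exon_profile.tsv")
            flatness.rename_axis("gene_id").reset_index().to_csv(
                out / "exon_flatness.tsv", sep="\t", index=False
            )
            manifest["stages"].append("stratify")

        # ------------------------------------------------------------ classify
        if config.run_classify and config.run_sensitivity:
            stage = "classify"
            gene_ids = ds.truth.index
            rna_fc = fold_changes["rna_state"]
            rna_fc = rna_fc[rna_fc.index.isin(gene_ids)]
            kd_pooled = fold_changes["pro_kd:RRP40_KD:pooled"]
            calls = clf.classify_genes(
                rna_fc,
                fold_changes["pro_state"],
                sens_tables["RNAseq:RRP40_KD:ESC"]["sensitivity"],
                sens_tables["RNAseq:RRP40_KD:EBd3"]["sensitivity"],
                kd_pooled,
                kd_pooled,
                config.thresholds(),
            )
            write_table(calls, out / "calls.tsv")
            recovery = clf.evaluate_recovery(calls, ds.truth["true_class"])
            summary = {
                "seed": config.seed,
                "thresholds": dataclasses.asdict(config.thresholds()),
                "class_counts": calls["class"].value_counts().to_dict(),
                "accuracy_on_defined_truth": recovery["accuracy"],
                "per_class": recovery["per_class"],
            }
            (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
            manifest["metrics"]["class_recovery_accuracy"] = recovery["accuracy"]
            manifest["stages"].append("classify")
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out
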