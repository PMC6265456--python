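# exodecomp

Decompose RNA-abundance differences between two cell states into
transcriptional and nuclear-decay contributions.

When mouse embryonic stem cells (ESC) differentiate into embryoid bodies
(EBd3), the level of every RNA is set jointly by how much is transcribed and
how fast it is degraded — in the nucleus, chiefly by the 3'→5' RNA exosome.
Comparing steady-state RNA measurements (RNAseq, CAGE) with direct
transcription measurements (PROseq) across the two states, with and without
depletion of the exosome core subunit RRP40 (or the NEXT adaptor RBM7), lets
the two contributions be separated. `exodecomp` implements that analysis as a
tested Python library and exercises it end to end on a synthetic generative
model with known ground truth, so every stage is validated against planted
parameters rather than eyeballed.

## The statistic at the core

For each transcript and cell state, the **exosome sensitivity** is

```
s = (E_KD − E_CTRL) / E_KD,     clamped to [0, 1]
```

where `E_KD` and `E_CTRL` are replicate-mean normalized expression values in
the depleted and control libraries. `s = 0` means depletion changed nothing;
`s → 1` means the RNA is detectable mostly when decay is impaired. Under the
package's generative model (control mean ∝ τ(1−δ), depleted mean ∝ τ(1−εδ),
with τ the transcription rate, δ the decayed fraction and ε the residual
decay under partial depletion), the population value of `s` is
`δ(1−ε)/(1−εδ)` — so planted susceptibilities are directly recoverable.

Around the statistic the package provides:

- **synthetic data** (`exodecomp.simulate`): annotation, replicate design,
  spike-ins, negative-binomial counts for RNAseq (triplicate), PROseq and
  CAGE (duplicate) across {ESC, EBd3} × {control, RRP40, RBM7 depletion},
  with PROMPT/eRNA-producing loci and a PROseq batch effect;
- **normalization** (`exodecomp.normalize`): spike-in median-of-ratios size
  factors, CAGE TPM, expressed-feature filters, reference-anchored quantile
  normalization, a location-only batch adjustment, lowest-percentile
  exclusion;
- **feature calling** (`exodecomp.features`): CTSS tag clustering, PROMPT
  definition (closest antisense cluster ≤ 2 kb upstream of a CAGE-supported
  TSS), eRNA windows, strand-aware window quantification;
- **stratified analyses** (`exodecomp.stratify`): sensitivity by expression
  quintile, by state-difference region, per-exon fold-change profiles;
- **classification** (`exodecomp.classify`): the rule-based assignment of
  genes to `mainly_degradation`, `degradation_and_transcription`,
  `mainly_transcription` or `other`, plus truth-recovery evaluation;
- **orchestration** (`exodecomp.pipeline` and the `exodecomp` CLI): one
  config, deterministic outputs, a manifest with checksums.

## Worked example

`examples/04_classify_regulation.py` runs the full chain on 1000 synthetic
genes and compares calls with the generative truth:

```
confusion matrix (rows: truth, columns: called):
class                          degradation_and_transcription  mainly_degradation  mainly_transcription  other
true_class
degradation_and_transcription                             32                   0                     7      2
mainly_degradation                                         3                  38                     0      1
mainly_transcription                                       0                   0                   165      2

recovery over genes with a defined true class: 0.940 (n=250)
mainly_degradation precision: 1.000
```

Reading: of the 250 genes whose true regulatory mode is defined (their RNA
level changes more than 2^0.5-fold between states), 94% are assigned their
true class from the noisy data; every gene called "mainly degradation" truly
is one. The remaining confusion is concentrated where it must be — genes
whose decay signal sits near the 0.5 sensitivity threshold, or whose ~zero
transcriptional change is flipped across the concordance boundary by
replicate noise.

The other examples generate a dataset (`01`), recover planted decay
susceptibilities through the sensitivity statistic (`02`), call PROMPTs and
score them against planted loci (`03`), and run the full pipeline with its
manifest (`05`). Each prints what it computes and what the numbers mean.

## Command line

```
exodecomp run --outdir runs/demo --seed 7        # full pipeline
exodecomp generate --outdir runs/raw             # synthetic data only
exodecomp normalize --counts counts_RNAseq.tsv --design design.tsv \
    --assay RNAseq --output normalized.tsv
exodecomp features --annotation annotation.gtf --clusters clusters.bed \
    --output prompts.tsv
```

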