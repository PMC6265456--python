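"""Call PROMPTs from CAGE tag clusters and score them against planted truth.

A PROMPT is the closest antisense tag cluster up to 2 kb upstream of a
CAGE-supported gene TSS; expression is quantified in a 2-kb window downstream
of the PROMPT TSS on the PROMPT strand.
"""

import exodecomp as xd
from exodecomp.features import define_prompts

cfg = xd.GeneratorConfig(seed=3, n_genes=400, n_enhancers=20, prompt_fraction=0.4)
ds = xd.generate_dataset(cfg)

prompts = define_prompts(ds.genes, ds.clusters)
planted = ds.prompt_table[ds.prompt_table["has_prompt"]]
called = {(p.host_gene_id, p.prompt_tss) for p in prompts}
truth = {(g, int(r["prompt_tss"])) for g, r in planted.iterrows()}
tp = len(called & truth)

print(f"planted PROMPTs: {len(truth)}   called: {len(called)}")
print(f"recall: {tp / len(truth):.3f}   precision: {tp / len(called):.3f}")
p = prompts[0]
print(f"\nexample call: {p.prompt_id}")
print(f"  host gene {p.host_gene_id} TSS {p.host_tss}, "
      f"PROMPT TSS {p.prompt_tss} on '{p.strand}', distance {p.distance} bp")
print(f"  quantification window [{p.window_start}, {p.window_end})")
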