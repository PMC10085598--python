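"""Genomic landscape of the 23 m6A regulators: per-sample tumor mutation
burden (synonymous + nonsynonymous counts), per-gene non-silent mutation
frequency, a waterfall-style alteration grid, and gene-level CNV gain/loss
frequencies.  Writes tables under results/genomics/."""

from _shared import RESULTS, ensure_dir, load_cohort
from m6astrat.mutation_genomics import (cnv_frequency, compute_tmb,
                                        gene_mutation_frequency,
                                        waterfall_summary)

out = ensure_dir(RESULTS / "genomics")
cohort = load_cohort(seed=0)
panel = cohort.config.panel.genes
samples = cohort.expression.sample_ids

tmb = compute_tmb(cohort.mutations, samples)
tmb.to_csv(out / "tmb.tsv", sep="\t")

freq = gene_mutation_frequency(cohort.mutations, len(samples), panel=panel)
freq.sort_values(ascending=False).to_csv(out / "mutation_frequency.tsv", sep="\t")

wf = waterfall_summary(cohort.mutations, top_n=20, cohort_n=len(samples))
wf["grid"].to_csv(out / "waterfall_grid.tsv", sep="\t")

cnv = cnv_frequency(cohort.copynumber, panel)
cnv.to_csv(out / "cnv_frequency.tsv", sep="\t")

print(f"TMB: median {tmb['tmb'].median():.0f} mutations/sample "
      f"(range {tmb['tmb'].min()}-{tmb['tmb'].max()})")
top = freq.sort_values(ascending=False).head(3)
print("most mutated regulators: "
      + ", ".join(f"{g} ({100 * v:.0f}%)" for g, v in top.items()))
print(f"{wf['n_altered_patients']} of {len(samples)} patients carry a "
      f"non-silent alteration in a top-20 gene")
print(f"mean CNV gain fraction over the panel: {cnv['gain_fraction'].mean():.2f}")
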