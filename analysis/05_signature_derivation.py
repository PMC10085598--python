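"""Derivation of the m6A-related gene signature: moderated-F differential
expression across the three m6A clusters with pairwise contrasts, the Venn
intersection of the three significant sets, and the univariate Cox screen
(p < 0.01) on the intersected genes.  Writes results/signature/."""

import json

from _shared import RESULTS, ensure_dir, load_cohort
from m6astrat.diffexpr import moderated_f_test, venn_intersect
from m6astrat.survival import cox_screen

out = ensure_dir(RESULTS / "signature")
cohort = load_cohort(seed=0)
clusters = cohort.truth_samples.set_index("sample_id")["cluster"]

deg = moderated_f_test(cohort.expression, clusters, p_threshold=0.01)
deg.table.to_csv(out / "deg_table.tsv", sep="\t")
per_contrast = deg.significant_per_contrast()
intersect = venn_intersect(list(per_contrast.values()))
intersect = [g for g in intersect if g not in set(cohort.config.panel.genes)]
(out / "intersect_genes.txt").write_text("\n".join(intersect) + "\n")

clin = cohort.clinical.aligned(cohort.expression.sample_ids)
cox = cox_screen(cohort.expression.values.loc[intersect],
                 clin["os_time"].to_numpy(), clin["os_event"].to_numpy(),
                 p_threshold=0.01)
cox.to_csv(out / "cox_screen.tsv", sep="\t")
prognostic = list(cox.index[cox["significant"]])
(out / "prognostic_genes.txt").write_text("\n".join(prognostic) + "\n")

tg = cohort.truth_genes.set_index("gene")
planted = set(tg.index[tg["prognostic"]])
recall = len(planted & set(prognostic)) / len(planted)
print(f"moderated-F prior: d0 = {deg.d0:.1f}, s0^2 = {deg.s0_sq:.3f}")
print("significant genes per contrast: "
      + ", ".join(f"{k}: {len(v)}" for k, v in per_contrast.items()))
print(f"Venn intersection: {len(intersect)} genes")
print(f"Cox screen keeps {len(prognostic)} prognostic genes "
      f"(recall of planted signature: {recall:.2f})")
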