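"""The m6A score: patient gene-clusters on the prognostic signature, the
PCA score (PC1 + PC2 per sample), median high/low stratification, survival
separation, the regulator prognostic network, and the score's associations
with TMB, PD-L1 (CD274) expression and immune enrichment.  Writes
results/score/."""

import numpy as np

from _shared import RESULTS, ensure_dir, load_cohort
from m6astrat.enrichment import ssgsea
from m6astrat.mutation_genomics import compute_tmb
from m6astrat.scoring import (gene_cluster_assign, m6a_score,
                              regulator_network, score_associations)
from m6astrat.survival import choose_cutpoint, logrank_test

out = ensure_dir(RESULTS / "score")
cohort = load_cohort(seed=0)
prog_file = RESULTS / "signature" / "prognostic_genes.txt"
if prog_file.exists():
    prognostic = prog_file.read_text().split()
else:  # standalone run: use the planted signature
    tg = cohort.truth_genes.set_index("gene")
    prognostic = sorted(tg.index[tg["prognostic"]])

gene_labels, _ = gene_cluster_assign(cohort.expression, prognostic, k=3,
                                     reps=250, seed=2)
clin = cohort.clinical.aligned(cohort.expression.sample_ids)
times = clin["os_time"].to_numpy()
events = clin["os_event"].to_numpy()

st = m6a_score(cohort.expression, prognostic, times=times, events=events,
               cut_method="median")
st.table.to_csv(out / "score_table.tsv", sep="\t")
lr = logrank_test(times, events, st.table["group"].to_numpy())

tmb = compute_tmb(cohort.mutations, cohort.expression.sample_ids)
enr = ssgsea(cohort.expression, cohort.immune_gene_sets(),
             min_max_normalize=True).scores
assoc = score_associations(st, tmb=tmb["tmb"],
                           marker_expr=cohort.expression.values.loc[["CD274"]],
                           immune_scores=enr)
assoc.to_csv(out / "associations.tsv", sep="\t", index=False)

net = regulator_network(cohort.expression, cohort.clinical, cohort.config.panel)
net["nodes"].to_csv(out / "network_nodes.tsv", sep="\t", index=False)
net["edges"].to_csv(out / "network_edges.tsv", sep="\t", index=False)

# TMB stratification reuses the cutpoint machinery on TMB values
tmb_thr, tmb_groups = choose_cutpoint(tmb["tmb"].to_numpy(), times, events,
                                      method="median")
lr_tmb = logrank_test(times, events, tmb_groups)

n_high = int((st.table["group"] == "high").sum())
print(f"score threshold {st.threshold:.3f} (median); "
      f"high/low = {n_high}/{len(st.table) - n_high}")
print(f"log-rank high vs low score: chi2 = {lr.statistic:.2f}, p = {lr.p_value:.2e}")
row = assoc[assoc['feature'] == 'tmb'].iloc[0]
print(f"Spearman(score, TMB): rho = {row['statistic']:.3f}, p = {row['p']:.2e}")
pd_row = assoc[assoc['feature'] == 'CD274'].iloc[0]
print(f"PD-L1 (CD274) high vs low score: Wilcoxon p = {pd_row['p']:.2e}")
risk = (net["nodes"]["direction"] == "risk").sum()
print(f"regulator network: {risk} risk / {len(net['nodes']) - risk} favorable "
      f"nodes, {len(net['edges'])} co-expression edges")
print(f"TMB median split: log-rank p = {lr_tmb.p_value:.2e}")
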