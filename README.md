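# m6astrat

Subtyping and prognostic scoring of tumor cohorts by the expression of
N6-methyladenosine (m6A) regulator genes.

m6A is a reversible mRNA modification handled by a small panel of enzymes
and binding proteins — "writers" (METTL3, METTL14, WTAP, ...), "erasers"
(FTO, ALKBH5) and "readers" (YTHDF1-3, IGF2BP1-3, ...). In stomach
adenocarcinoma and other tumors, the joint expression pattern of this
23-gene panel stratifies patients into molecular subtypes with distinct
immune microenvironments and survival. This package implements that
analysis chain as a tested, reusable library for anyone who wants to run
the same workflow on their own expression/clinical/mutation tables or
audit its statistical behavior on fully ground-truthed synthetic cohorts:

1. **Consensus clustering** of the regulator panel (Monti-style
   subsampling, 1−Pearson average-linkage base clusterer, CDF/Δ-area model
   selection over k = 2–9);
2. **Immune characterization** by single-sample gene set enrichment
   (ssGSEA running sum with exponent α = 0.25), ESTIMATE-style
   immune/stromal scores with the cosine purity transform, and
   signature-matrix deconvolution (NNLS or ν-SVR);
3. **Signature derivation**: moderated-F differential expression across
   the clusters (closed-form empirical-Bayes variance shrinkage), Venn
   intersection of the pairwise contrasts, and a univariate Cox screen at
   p < 0.01;
4. **The m6A score**: z-score the prognostic genes, PCA with samples as
   observations, score = PC1 + PC2 per sample, median (or maximal
   log-rank) high/low stratification:

   m6A score_i = PC1_i + PC2_i

5. **Downstream statistics**: Kaplan–Meier / k-group log-rank, Cox
   proportional hazards (Newton–Raphson on the partial likelihood, Efron
   or Breslow ties), tumor mutation burden (synonymous + nonsynonymous
   counts per sample), CNV gain/loss frequencies, Spearman score–TMB
   association, and a two-cohort clinical comparison table.

A synthetic-cohort generator (`m6astrat.synthetic_cohort`) plants every
piece of structure the analysis assumes — cluster means on the regulators,
a latent prognostic score driving survival and mutation burden, an immune
block shifted in one cluster — so each stage can be tested against known
truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/03_regulator_subtypes.py
python analysis/06_m6a_score.py
```

prints (numbers from the shipped default seed):

```
cohort: 400 samples x 2074 genes
planted clusters: {'A': 134, 'B': 133, 'C': 133}
censoring: 0.52; score-TMB Spearman: 0.368

delta-area advises k = 3; analysis pins k = 3
cluster sizes: A: 133, B: 134, C: 133
agreement with planted subtypes: ARI = 1.000
log-rank across clusters: chi2 = 17.28, p = 1.77e-04

score threshold -0.309 (median); high/low = 200/200
log-rank high vs low score: chi2 = 55.88, p = 7.71e-14
Spearman(score, TMB): rho = 0.372, p = 1.48e-14
```

That is: the Δ-area rule recovers the planted three subtypes exactly, the
subtypes separate in survival, and the PCA score stratifies patients into
a high-score group with worse outcome whose mutation burden association
matches the planted rank correlation of 0.35. The remaining drivers under
`analysis/` cover the regulator genomic landscape (02), the immune
microenvironment (04), signature derivation (05) and the two-cohort
clinical table (07). A thin CLI (`m6a-stratify simulate|run`) wraps the
same library calls.

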