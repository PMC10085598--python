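"""Tumor mutation burden, mutation frequencies, waterfall summaries and CNV
gain/loss frequencies.

TMB counts synonymous plus nonsynonymous records per sample (no per-megabase
normalization unless a capture size is given); mutation frequency counts a
sample once per gene and considers non-silent records only.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from m6astrat.io_core import CopyNumberTable, MutationTable, NONSILENT_CLASSES

logger = logging.getLogger(__name__)


def compute_tmb(muts: MutationTable, samples: Sequence[str],
                capture_size_mb: float | None = None) -> pd.DataFrame:
    """Per-sample mutation count over all variant classes.

    Samples with no records get 0; records for samples outside the cohort
    are dropped with a warning.  With ``capture_size_mb`` a per-megabase
    rate column is added.
    """
    samples = list(samples)
    df = muts.data
    outside = ~df["sample_id"].isin(samples)
    if outside.any():
        logger.warning("compute_tmb: dropped %d records for samples outside the cohort",
                       int(outside.sum()))
        df = df.loc[~outside]
    counts = df.groupby("sample_id").size().reindex(samples, fill_value=0)
    out = pd.DataFrame({"tmb": counts.astype(int)})
    out.index.name = "sample_id"
    if capture_size_mb is not None:
        out["tmb_per_mb"] = out["tmb"] / capture_size_mb
    return out


def gene_mutation_frequency(muts: MutationTable, cohort_n: int,
                            panel: Sequence[str] | None = None) -> pd.Series:
    """Fraction of samples carrying >=1 non-silent record per gene.

    A sample counts once per gene regardless of how many records it has.
    Genes in ``panel`` that are never mutated are reported as 0.
    """
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    df = muts.data
    nonsilent = df[df["variant_classification"].isin(NONSILENT_CLASSES)]
    carriers = nonsilent.drop_duplicates(["gene", "sample_id"]).groupby("gene").size()
    freq = carriers / cohort_n
    if panel is not None:
        freq = freq.reindex(list(panel), fill_value=0.0)
    freq.name = "mutation_frequency"
    return freq


def waterfall_summary(muts: MutationTable, top_n: int = 20,
                      cohort_n: int | None = None) -> dict:
    """Oncoplot-style grid of the most frequently altered genes.

    Genes are sorted by non-silent carrier frequency (descending, ties
    alphabetical); a sample/gene cell with more than one variant class
    becomes ``multi_hit``.  Returns the grid, the sorted gene order and the
    count of altered patients.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = muts.data
    nonsilent = df[df["variant_classification"].isin(NONSILENT_CLASSES)]
    carriers = nonsilent.drop_duplicates(["gene", "sample_id"]).groupby("gene").size()
    order = (carriers.rename("n").reset_index()
             .sort_values(["n", "gene"], ascending=[False, True]))
    genes = order["gene"].head(top_n).tolist()

    cells = (nonsilent[nonsilent["gene"].isin(genes)]
             .groupby(["gene", "sample_id"])["variant_classification"]
             .agg(lambda s: s.iloc[0] if s.nunique() == 1 else "multi_hit"))
    grid = cells.unstack(fill_value="")
    grid = grid.reindex(genes)
    altered = int(nonsilent["sample_id"].nunique())
    return {"grid": grid, "gene_order": genes, "n_altered_patients": altered,
            "cohort_n": cohort_n}


def cnv_frequency(cn: CopyNumberTable, panel: Sequence[str]) -> pd.DataFrame:
    """Per-gene copy-number gain and loss fractions over the panel.

    gain = fraction of samples with state > 0, loss = fraction with
    state < 0; genes absent from the table are reported (NaN rows).
    """
    df = cn.data
    n = df["sample_id"].nunique()
    rows = []
    missing = []
    for gene in panel:
        sub = df[df["gene"] == gene]
        if sub.empty:
            missing.append(gene)
            rows.append((gene, np.nan, np.nan))
            continue
        rows.append((gene, float((sub["cn_state"] > 0).sum() / n),
                     float((sub["cn_state"] < 0).sum() / n)))
    if missing:
        logger.warning("cnv_frequency: %d panel genes absent from the table: %s",
                       len(missing), missing[:10])
    out = pd.DataFrame(rows, columns=["gene", "gain_fraction", "loss_fraction"])
    return out.set_index("gene")
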