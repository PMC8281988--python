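"""Differential expression and the mutation-/WT-specific gene partition.

Pathway-level phenotyping needs to know which transcriptional changes
are attributable to the mutant alone. Both the wild-type and the mutant
condition are compared against the control with a negative-binomial Wald
test (DESeq2, via pydeseq2: median-of-ratios size factors, trended
dispersion shrinkage); genes differentially expressed only in the
control-vs-mutant comparison are "mutation-specific", genes responding
only in control-vs-WT are "WT-specific".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["DE_COLUMNS", "GenePartition", "de_test", "partition_genes"]

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "baseline_mean", "log2_fold_change", "pvalue", "padj"]


@dataclass(frozen=True)
class GenePartition:
    """Disjoint split of DE genes by which comparison they respond in."""

    mutation_specific: frozenset
    wt_specific: frozenset
    shared: frozenset
    alpha: float

    def __post_init__(self) -> None:
        if self.mutation_specific & self.wt_specific or \
           self.mutation_specific & self.shared or self.wt_specific & self.shared:
            raise ValueError("partition sets must be pairwise disjoint")


def de_test(
    counts: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    quiet: bool = True,
) -> pd.DataFrame:
    """Negative-binomial Wald test of ``group_b`` relative to ``group_a``.

    Returns one row per gene, in the input gene order, with the log2
    fold change of b over a, the Wald p-value and its BH adjustment.
    Genes with zero counts in every sample get NaN p-values and are
    treated as not differentially expressed downstream.
    """
    if counts.value_space != "counts":
        raise ValueError(f"expected a counts matrix, got {counts.value_space}")
    values = counts.data.to_numpy()
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integer-valued")
    for name, group in (("group_a", group_a), ("group_b", group_b)):
        if len(group) < 2:
            raise ValueError(f"{name} has {len(group)} sample(s); at least 2 required")
        missing = [s for s in group if s not in counts.data.columns]
        if missing:
            raise ValueError(f"{name} samples absent from the matrix: {missing}")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    samples = list(group_a) + list(group_b)
    mat = counts.data[samples].T.round().astype(int)
    meta = pd.DataFrame(
        {"condition": ["a"] * len(group_a) + ["b"] * len(group_b)}, index=samples
    )
    dds = DeseqDataSet(
        counts=mat, metadata=meta, design="~condition", quiet=quiet
    )
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "b", "a"], quiet=quiet)
    ds.summary()
    res = ds.results_df.reindex(counts.gene_ids)
    out = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "baseline_mean": res["baseMean"].to_numpy(),
            "log2_fold_change": res["log2FoldChange"].to_numpy(),
            "pvalue": res["pvalue"].to_numpy(),
            "padj": res["padj"].to_numpy(),
        }
    )
    n_de = int((out["padj"] <= 0.05).sum())
    logger.info("DE test: %d genes, %d with padj <= 0.05", len(out), n_de)
    return out


def _de_genes(de: pd.DataFrame, alpha: float) -> set:
    """Genes called DE at ``alpha``; undefined padj counts as not-DE."""
    mask = de["padj"].notna() & (de["padj"] <= alpha)
    return set(de.loc[mask, "gene_id"])


def partition_genes(
    de_ctrl_vs_wt: pd.DataFrame,
    de_ctrl_vs_mut: pd.DataFrame,
    alpha: float = 0.05,
) -> GenePartition:
    """Split DE genes into mutation-specific / WT-specific / shared sets."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    universe_wt = set(de_ctrl_vs_wt["gene_id"])
    universe_mut = set(de_ctrl_vs_mut["gene_id"])
    if universe_wt != universe_mut:
        raise ValueError(
            "the two DE tables must cover the same gene universe "
            f"({len(universe_wt ^ universe_mut)} genes differ)"
        )
    wt_de = _de_genes(de_ctrl_vs_wt, alpha)
    mut_de = _de_genes(de_ctrl_vs_mut, alpha)
    return GenePartition(
        mutation_specific=frozenset(mut_de - wt_de),
        wt_specific=frozenset(wt_de - mut_de),
        shared=frozenset(wt_de & mut_de),
        alpha=alpha,
    )
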