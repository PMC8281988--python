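"""Gene-set handling and pathway-level impact calls.

Pathway phenotyping re-runs the overall decision tree on the z-score
matrix restricted to each pathway's usable genes — the intersection of
the pathway with the measured genes and with either the WT-specific or
the mutation-specific DE gene set. WT-specific rows probe loss of normal
function; mutation-specific rows probe function newly acquired by the
mutant. The classifier itself is identical in both subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Thresholds,
    classify,
    correlation_matrix,
    evaluate_comparison,
    impact_direction_score,
)
from .diffexp import GenePartition, de_test, partition_genes
from .matrix import Comparison, ExpressionMatrix, SampleAnnotation

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "eligible_pathways",
    "pathway_evip",
    "overlap_report",
    "PathwayImpactModel",
    "PathwayImpactResults",
]

logger = logging.getLogger(__name__)

SUBSET_TYPES = ("wt_specific", "mutation_specific")


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source_path: str | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Parse a Gene Matrix Transposed file: name, description, genes...

    Genes repeated within one line are deduplicated (first occurrence
    kept) with a warning; a repeated set name is a hard error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(parts)} fields found)"
                )
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes within set {name!r} "
                    "were deduplicated",
                    stacklevel=2,
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, str(path))


def eligible_pathways(
    gs: GeneSetCollection,
    subset: set,
    measured: set,
    min_genes: int = 10,
) -> dict[str, list[str]]:
    """Usable genes per pathway: pathway ∩ subset ∩ measured.

    Pathways with fewer than ``min_genes`` usable genes are dropped (the
    boundary is inclusive: exactly ``min_genes`` is retained).
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if not subset:
        warnings.warn("empty gene subset: no pathway is eligible", stacklevel=2)
        return {}
    usable: dict[str, list[str]] = {}
    for name, genes in gs.sets.items():
        kept = [g for g in genes if g in subset and g in measured]
        if len(kept) >= min_genes:
            usable[name] = kept
        else:
            logger.info(
                "pathway %s dropped: %d usable gene(s) < min_genes=%d",
                name, len(kept), min_genes,
            )
    return usable


def pathway_evip(
    z: ExpressionMatrix,
    annot: SampleAnnotation,
    comparison: Comparison,
    usable: dict[str, list[str]],
    th: Thresholds,
    subset_type: str,
) -> pd.DataFrame:
    """Run the full decision tree per pathway on the restricted matrix.

    P-values are adjusted across the eligible pathways of this subset
    type (one multiplicity family per variant per subset type).
    """
    if subset_type not in SUBSET_TYPES:
        raise ValueError(f"unknown subset type {subset_type!r}")
    names = sorted(usable)  # GMT order must not influence the calls
    evals = []
    for name in names:
        sub = z.subset_genes(usable[name])
        corr = correlation_matrix(sub)
        evals.append(evaluate_comparison(corr, annot, comparison))
    adj = {
        key: th.adjust([e[key].pvalue for e in evals])
        for key in ("impact", "direction", "disting")
    }
    rows = []
    for i, (name, ev) in enumerate(zip(names, evals)):
        gate = (
            (adj["impact"][i], adj["direction"][i], adj["disting"][i])
            if th.use_c_pval
            else (ev["impact"].pvalue, ev["direction"].pvalue, ev["disting"].pvalue)
        )
        call = classify(ev["triplet"], th, *gate)
        score_p = adj["direction"][i] if th.use_c_pval else ev["direction"].pvalue
        rows.append(
            {
                "pathway": name,
                "subset_type": subset_type,
                "variant": comparison.mutant,
                "wt": comparison.wt,
                "n_genes_used": len(usable[name]),
                "call": call,
                "impact_pval": ev["impact"].pvalue,
                "impact_pval_adj": float(adj["impact"][i]),
                "direction_pval": ev["direction"].pvalue,
                "direction_pval_adj": float(adj["direction"][i]),
                "disting_pval": ev["disting"].pvalue,
                "disting_pval_adj": float(adj["disting"][i]),
                "impact_direction_score": impact_direction_score(
                    ev["triplet"], float(score_p), th.max_direction_score
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway", "subset_type", "variant", "wt", "n_genes_used", "call",
            "impact_pval", "impact_pval_adj", "direction_pval",
            "direction_pval_adj", "disting_pval", "disting_pval_adj",
            "impact_direction_score",
        ],
    )


def overlap_report(usable: dict[str, list[str]]):
    """Gene-membership matrix and exact intersection sizes (UpSet-style).

    Returns ``(membership, intersections)``: a boolean gene x pathway
    DataFrame, and a table counting genes per exact membership pattern.
    """
    if not usable:
        raise ValueError("need at least one pathway")
    names = sorted(usable)
    genes = sorted(set().union(*(set(g) for g in usable.values())))
    membership = pd.DataFrame(
        {name: [g in set(usable[name]) for g in genes] for name in names},
        index=pd.Index(genes, name="gene_id"),
    )
    patterns = membership.groupby(names).size().reset_index(name="n_genes")
    patterns["pathways"] = patterns[names].apply(
        lambda row: "&".join(n for n in names if row[n]), axis=1
    )
    intersections = (
        patterns[["pathways", "n_genes"]]
        .sort_values("n_genes", ascending=False)
        .reset_index(drop=True)
    )
    return membership, intersections


class PathwayImpactModel:
    """Pathway-level phenotyping: DE partition then per-pathway decision tree.

    Parameters
    ----------
    zscores
        The same z-score matrix used for the overall call.
    counts
        Raw counts (genes x samples) for the DE stage; its gene universe
        is intersected with the z-score matrix so the partitions stay
        consistent with the correlation analysis.
    annotation
        Sample map and comparisons shared with the overall stage.
    gene_sets
        Pathway collection (e.g. MSigDB hallmark GMT).
    """

    def __init__(
        self,
        zscores: ExpressionMatrix,
        counts: ExpressionMatrix,
        annotation: SampleAnnotation,
        gene_sets: GeneSetCollection,
        thresholds: Thresholds | None = None,
        de_alpha: float = 0.05,
    ) -> None:
        if zscores.value_space != "zscore":
            raise ValueError("expected a z-score matrix")
        if counts.value_space != "counts":
            raise ValueError("expected a counts matrix")
        annotation.validate_against(zscores)
        if not annotation.comparisons:
            raise ValueError("annotation lists no comparisons")
        self.zscores = zscores
        self.counts = counts
        self.annotation = annotation
        self.gene_sets = gene_sets
        self.thresholds = thresholds or Thresholds()
        self.de_alpha = de_alpha

    def fit(self, quiet: bool = True) -> "PathwayImpactResults":
        th = self.thresholds
        measured = set(self.zscores.gene_ids)
        # DE universe: measured genes only, keeping partitions consistent
        # with the correlation analysis
        de_universe = [g for g in self.counts.gene_ids if g in measured]
        counts = self.counts.subset_genes(de_universe)
        de_tables: dict[tuple[str, str], pd.DataFrame] = {}
        partitions: dict[str, GenePartition] = {}
        call_frames: list[pd.DataFrame] = []
        for comp in self.annotation.comparisons:
            ctrl = self.annotation.samples_of(comp.control)
            wt = self.annotation.samples_of(comp.wt)
            mut = self.annotation.samples_of(comp.mutant)
            key_wt, key_mut = (comp.control, comp.wt), (comp.control, comp.mutant)
            if key_wt not in de_tables:
                de_tables[key_wt] = de_test(counts, ctrl, wt, quiet=quiet)
            if key_mut not in de_tables:
                de_tables[key_mut] = de_test(counts, ctrl, mut, quiet=quiet)
            part = partition_genes(de_tables[key_wt], de_tables[key_mut], self.de_alpha)
            partitions[comp.mutant] = part
            for subset_type, subset in (
                ("wt_specific", part.wt_specific),
                ("mutation_specific", part.mutation_specific),
            ):
                usable = eligible_pathways(
                    self.gene_sets, set(subset), measured, th.min_genes
                )
                if not usable:
                    warnings.warn(
                        f"no eligible pathway for {comp.mutant} ({subset_type})",
                        stacklevel=2,
                    )
                    continue
                call_frames.append(
                    pathway_evip(self.zscores, self.annotation, comp, usable, th,
                                 subset_type)
                )
        calls = (
            pd.concat(call_frames, ignore_index=True)
            if call_frames
            else pathway_evip(self.zscores, self.annotation,
                              self.annotation.comparisons[0], {}, th,
                              "wt_specific")
        )
        return PathwayImpactResults(self, de_tables, partitions, calls)


class PathwayImpactResults:
    """DE tables, gene partitions, and the per-pathway call table."""

    def __init__(self, model, de_tables, partitions, calls: pd.DataFrame) -> None:
        self.model = model
        self.de_tables = de_tables
        self.partitions = partitions
        self.calls = calls

    def partition_frame(self) -> pd.DataFrame:
        rows = []
        for variant, part in self.partitions.items():
            for subset_type, genes in (
                ("mutation_specific", part.mutation_specific),
                ("wt_specific", part.wt_specific),
                ("shared", part.shared),
            ):
                rows.extend(
                    {"variant": variant, "subset_type": subset_type, "gene_id": g}
                    for g in sorted(genes)
                )
        return pd.DataFrame(rows, columns=["variant", "subset_type", "gene_id"])

    def summary(self) -> str:
        lines = ["Pathway impact phenotyping results", "=" * 70]
        for variant, part in self.partitions.items():
            lines.append(
                f"{variant}: {len(part.mutation_specific)} mutation-specific, "
                f"{len(part.wt_specific)} WT-specific, {len(part.shared)} shared "
                f"DE genes (alpha={part.alpha})"
            )
        lines.append("-" * 70)
        if len(self.calls):
            cols = ["pathway", "subset_type", "variant", "n_genes_used", "call",
                    "impact_pval_adj", "impact_direction_score"]
            with pd.option_context("display.float_format", "{:.4g}".format):
                lines.append(self.calls[cols].to_string(index=False))
        else:
            lines.append("(no eligible pathway)")
        lines.append("=" * 70)
        return "\n".join(lines)
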