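"""Expression tables, sample annotation, and the TPM -> z-score pipeline.

The pipeline consumes a gene x sample TPM table (or a pre-computed
z-score matrix in the same layout), removes low-expressed genes, applies
log2(x + 1), and standardises each gene across *all* samples of the run,
controls included, so that every condition is scored against the same
reference distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "Comparison",
    "SampleAnnotation",
    "read_tpm_table",
    "read_counts_table",
    "accept_precomputed_zscores",
    "read_annotation",
    "filter_low_expression",
    "log2_transform",
    "zscore_transform",
    "tpm_to_zscores",
]

logger = logging.getLogger(__name__)

VALUE_SPACES = ("tpm", "log2", "zscore", "counts")
ZSCORE_ATOL = 1e-9


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric matrix with a declared value space.

    ``value_space`` is one of ``tpm``, ``log2``, ``zscore`` or ``counts``
    and controls which invariants are enforced: TPM and counts must be
    non-negative, and z-score rows must have mean 0 and sample standard
    deviation 1 (rows that were constant before standardisation are
    dropped by :func:`zscore_transform` instead).
    """

    data: pd.DataFrame
    value_space: str
    check_zscore_rows: bool = True

    def __post_init__(self) -> None:
        if self.value_space not in VALUE_SPACES:
            raise ValueError(f"unknown value space {self.value_space!r}")
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if self.value_space in ("tpm", "counts") and values.size and values.min() < 0:
            raise ValueError(f"{self.value_space} values must be non-negative")
        if self.value_space == "zscore" and self.check_zscore_rows and df.shape[1] >= 2:
            means = values.mean(axis=1)
            sds = values.std(axis=1, ddof=1)
            bad = np.where(
                (np.abs(means) > ZSCORE_ATOL) | (np.abs(sds - 1.0) > ZSCORE_ATOL)
            )[0]
            if bad.size:
                raise ValueError(
                    f"gene {df.index[bad[0]]!r} violates the z-score row invariant"
                )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Pure restriction to a gene list (order preserved as given)."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from the matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[list(genes)].copy(),
            self.value_space,
            check_zscore_rows=False,
        )

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        """Write as TSV, optionally preceded by '# ' provenance comments."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class Comparison:
    """One (control, wild-type, mutant) overexpression design triple."""

    control: str
    wt: str
    mutant: str

    def __post_init__(self) -> None:
        if len({self.control, self.wt, self.mutant}) != 3:
            raise ValueError(
                f"control/wt/mutant conditions must be pairwise distinct, got "
                f"({self.control!r}, {self.wt!r}, {self.mutant!r})"
            )


@dataclass
class SampleAnnotation:
    """Maps samples to conditions and lists the comparison design."""

    sample_to_condition: dict[str, str]
    comparisons: list[Comparison] = field(default_factory=list)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_to_condition.items() if c == condition]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.sample_to_condition]
        if missing:
            raise ValueError(f"samples without a condition: {missing[:5]}")
        for comp in self.comparisons:
            for cond in (comp.control, comp.wt, comp.mutant):
                n = len(self.samples_of(cond))
                if n < 2:
                    raise ValueError(
                        f"condition {cond!r} has {n} replicate(s); at least 2 required"
                    )
                if n < 3:
                    warnings.warn(
                        f"condition {cond!r} has only {n} replicates; at least "
                        "three biological replicates are recommended",
                        stacklevel=2,
                    )


def _read_table(path) -> pd.DataFrame:
    """Shared TSV reader with explicit duplicate / non-numeric diagnostics."""
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
    if header is None or len(header) < 2:
        raise ValueError(f"{path}: expected a header row with at least one sample")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"{path}: duplicate sample id {s!r}")
        seen.add(s)
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False
    )
    df.columns = samples
    dup_genes = df.index[df.index.duplicated()]
    if len(dup_genes):
        raise ValueError(f"{path}: duplicate gene id {dup_genes[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return numeric


def read_tpm_table(path) -> ExpressionMatrix:
    """Read a gene x sample TPM table (TSV, header = sample ids)."""
    return ExpressionMatrix(_read_table(path), "tpm")


def read_counts_table(path) -> ExpressionMatrix:
    """Read a gene x sample raw-count table (same layout as TPM)."""
    return ExpressionMatrix(_read_table(path), "counts")


def accept_precomputed_zscores(path) -> ExpressionMatrix:
    """Read an externally standardised matrix (e.g. L1000 z-scores).

    The values are passed through untouched: external z-scores may have
    been standardised against a different population, so the per-row
    mean-0/sd-1 invariant is intentionally not enforced.
    """
    return ExpressionMatrix(_read_table(path), "zscore", check_zscore_rows=False)


def read_annotation(path, comparisons: list[Comparison] | None = None) -> SampleAnnotation:
    """Read a two-column (sample_id, condition) TSV annotation."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample_id, condition)")
    samples = df.iloc[:, 0]
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    mapping = dict(zip(samples, df.iloc[:, 1]))
    return SampleAnnotation(mapping, comparisons or [])


def filter_low_expression(m: ExpressionMatrix, min_tpm: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose maximum TPM over all samples is below ``min_tpm``.

    A gene expressed in any condition is kept, which downstream stages
    (correlation and differential expression) rely on. The boundary is
    inclusive: a gene reaching exactly ``min_tpm`` survives.
    """
    if m.value_space != "tpm":
        raise ValueError(f"expected a TPM matrix, got {m.value_space}")
    if min_tpm < 0:
        raise ValueError("min_tpm must be non-negative")
    keep = m.data.max(axis=1) >= min_tpm
    if not keep.any():
        raise ValueError(f"no gene reaches min_tpm={min_tpm}; nothing to analyse")
    logger.info(
        "low-expression filter: retained %d of %d genes (min_tpm=%g)",
        int(keep.sum()), m.shape[0], min_tpm,
    )
    return ExpressionMatrix(m.data.loc[keep].copy(), "tpm")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a TPM matrix."""
    if m.value_space != "tpm":
        raise ValueError(f"expected a TPM matrix, got {m.value_space}")
    return ExpressionMatrix(np.log2(m.data + 1.0), "log2")


def zscore_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene across all samples (controls included).

    Uses the sample standard deviation (n - 1 denominator). Genes that
    are constant across all samples carry no rank information and would
    only create tie blocks in the Spearman step, so they are dropped
    with a logged warning.
    """
    if m.value_space != "log2":
        raise ValueError(f"expected a log2 matrix, got {m.value_space}")
    if m.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    sds = m.data.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        logger.warning(
            "dropping %d constant gene(s) at the z-score stage: %s",
            int(constant.sum()), list(m.data.index[constant][:5]),
        )
    kept = m.data.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sds[~constant], axis=0)
    return ExpressionMatrix(z, "zscore")


def tpm_to_zscores(m: ExpressionMatrix, min_tpm: float = 1.0) -> ExpressionMatrix:
    """Full preprocessing chain: low-TPM filter -> log2(x+1) -> z-score."""
    return zscore_transform(log2_transform(filter_low_expression(m, min_tpm)))
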