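"""Overall variant impact calls from replicate correlation structure.

A variant is phenotyped by comparing three distributions of Spearman
correlations between z-scored expression signatures: wild-type replicate
self-correlation (WT signal strength), mutant replicate self-correlation
(mutant signal strength), and WT-vs-mutant cross-correlation (signature
identity). A Kruskal-Wallis "impact test" on the three distributions
decides whether the mutant signature differs from wild-type at all;
impactful variants are split into GOF / LOF / COF by a rank-sum
"direction test" of the two self-correlation distributions, and
non-impactful ones into Neutral / non-informative by a rank-sum
"distinguishability test" of the cross-correlations against a null built
from mutant-vs-control pairs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .matrix import Comparison, ExpressionMatrix, SampleAnnotation, tpm_to_zscores
from .stats import (
    TestResult,
    average_ranks,
    benjamini_hochberg,
    bonferroni,
    kruskal_wallis,
    ranksum_two_sided,
)

__all__ = [
    "CALLS",
    "Thresholds",
    "CorrelationTriplet",
    "ImpactCall",
    "correlation_matrix",
    "build_triplet",
    "impact_test",
    "direction_test",
    "disting_test",
    "impact_direction_score",
    "classify",
    "VariantImpactModel",
    "VariantImpactResults",
]

logger = logging.getLogger(__name__)

#: the five mutually exclusive decision-tree outcomes
CALLS = ("GOF", "LOF", "COF", "Neutral", "NI")


@dataclass(frozen=True)
class Thresholds:
    """Decision-tree gates and preprocessing knobs.

    Defaults are the published defaults for 4-replicate RNA-seq designs
    (p-value gates relaxed from 0.05 to 0.1 to compensate for the lower
    replicate count relative to 8-replicate L1000 screens).

    conn_thresh
        adjusted-p cutoff of the Kruskal-Wallis impact test; at or below
        it the variant is impactful.
    mut_wt_rep_thresh
        adjusted-p cutoff of the direction test (mutant-self vs WT-self
        rank-sum); above it an impactful variant is COF.
    disting_thresh
        adjusted-p cutoff of the distinguishability test separating
        Neutral from non-informative.
    mut_wt_rep_rank_diff
        minimum difference of median self-correlation (mutant minus WT)
        required to commit to GOF/LOF rather than COF; 0 means any
        nonzero difference suffices.
    cond_max_diff_thresh
        quality gate: if the spread (max - min) of the per-condition
        self-correlation medians within one comparison exceeds it, the
        row is flagged (but the call is not changed).
    use_c_pval
        gate on multiplicity-corrected p-values (True) or raw ones.
    correction
        "bh" (Benjamini-Hochberg, default) or "bonferroni".
    """

    conn_thresh: float = 0.1
    mut_wt_rep_thresh: float = 0.1
    disting_thresh: float = 0.1
    mut_wt_rep_rank_diff: float = 0.0
    cond_max_diff_thresh: float = 0.2
    use_c_pval: bool = True
    min_tpm: float = 1.0
    min_genes: int = 10
    correction: str = "bh"
    max_direction_score: float = 20.0

    def __post_init__(self) -> None:
        for name in ("conn_thresh", "mut_wt_rep_thresh", "disting_thresh"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.correction not in ("bh", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")

    def adjust(self, pvals) -> np.ndarray:
        if self.correction == "bonferroni":
            return bonferroni(pvals)
        return benjamini_hochberg(pvals)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CorrelationTriplet:
    """The four correlation distributions feeding the decision tree.

    ``wt_self`` and ``mut_self`` hold the n(n-1)/2 unordered within-
    condition pairs (diagonal excluded); ``wt_mut`` the n_wt * n_mut
    cross pairs; ``null_dist`` the mutant-vs-control pairs that anchor
    the distinguishability test.
    """

    wt_self: np.ndarray
    mut_self: np.ndarray
    wt_mut: np.ndarray
    null_dist: np.ndarray
    n_wt: int
    n_mut: int
    n_ctrl: int

    def __post_init__(self) -> None:
        expect = {
            "wt_self": self.n_wt * (self.n_wt - 1) // 2,
            "mut_self": self.n_mut * (self.n_mut - 1) // 2,
            "wt_mut": self.n_wt * self.n_mut,
            "null_dist": self.n_mut * self.n_ctrl,
        }
        for name, size in expect.items():
            vec = getattr(self, name)
            if vec.size != size:
                raise ValueError(f"{name} has {vec.size} values, expected {size}")
            if vec.size and (vec.min() < -1.0 - 1e-12 or vec.max() > 1.0 + 1e-12):
                raise ValueError(f"{name} contains values outside [-1, 1]")


@dataclass(frozen=True)
class ImpactCall:
    """Per-variant prediction with all test p-values and the score."""

    variant: str
    wt: str
    call: str
    impact_pval: float
    impact_pval_adj: float
    direction_pval: float
    direction_pval_adj: float
    disting_pval: float
    disting_pval_adj: float
    impact_direction_score: float
    n_replicates: dict[str, int] = field(default_factory=dict)
    cond_max_diff_flag: bool = False

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def correlation_matrix(z: ExpressionMatrix) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation matrix over the gene axis.

    Each sample column is rank-transformed (average ranks) and the
    Pearson correlation of the rank vectors is taken, which equals the
    pairwise Spearman rho. Symmetric with a unit diagonal.
    """
    if z.value_space != "zscore":
        raise ValueError(f"expected a z-score matrix, got {z.value_space}")
    n_genes, n_samples = z.shape
    if n_samples < 2 or n_genes < 3:
        raise ValueError("need at least 2 samples and 3 genes")
    values = z.data.to_numpy()
    constant = np.all(values == values[0, :], axis=0)
    if constant.any():
        bad = z.sample_ids[int(np.argmax(constant))]
        raise ValueError(f"sample {bad!r} is constant across genes")
    ranks = np.column_stack([average_ranks(values[:, j]) for j in range(n_samples)])
    corr = np.corrcoef(ranks, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=z.sample_ids, columns=z.sample_ids)


def _self_pairs(corr: pd.DataFrame, samples: list[str]) -> np.ndarray:
    sub = corr.loc[samples, samples].to_numpy()
    iu = np.triu_indices(len(samples), k=1)
    return sub[iu]


def build_triplet(
    corr: pd.DataFrame, annot: SampleAnnotation, comparison: Comparison
) -> CorrelationTriplet:
    """Extract the four correlation distributions for one comparison."""
    groups = {}
    for role, cond in (
        ("control", comparison.control),
        ("wt", comparison.wt),
        ("mutant", comparison.mutant),
    ):
        samples = [s for s in corr.index if annot.sample_to_condition.get(s) == cond]
        if len(samples) < 2:
            raise ValueError(
                f"condition {cond!r} ({role}) has {len(samples)} replicate(s) "
                "in the correlation matrix; at least 2 required"
            )
        groups[role] = samples
    wt, mut, ctrl = groups["wt"], groups["mutant"], groups["control"]
    return CorrelationTriplet(
        wt_self=_self_pairs(corr, wt),
        mut_self=_self_pairs(corr, mut),
        wt_mut=corr.loc[wt, mut].to_numpy().ravel(),
        null_dist=corr.loc[mut, ctrl].to_numpy().ravel(),
        n_wt=len(wt),
        n_mut=len(mut),
        n_ctrl=len(ctrl),
    )


def impact_test(t: CorrelationTriplet) -> TestResult:
    """Kruskal-Wallis test of (WT-self, mutant-self, WT-vs-mutant)."""
    return kruskal_wallis([t.wt_self, t.mut_self, t.wt_mut])


def direction_test(t: CorrelationTriplet) -> TestResult:
    """Two-sided rank-sum of mutant-self vs WT-self correlations."""
    return ranksum_two_sided(t.mut_self, t.wt_self)


def disting_test(t: CorrelationTriplet) -> TestResult:
    """Two-sided rank-sum of WT-vs-mutant correlations against the null."""
    if t.null_dist.size == 0:
        raise ValueError("empty null distribution")
    return ranksum_two_sided(t.wt_mut, t.null_dist)


def impact_direction_score(
    t: CorrelationTriplet, direction_p_adj: float, cap: float = 20.0
) -> float:
    """Signed -log10 of the (adjusted) direction-test p-value.

    Positive when the mutant replicate consistency exceeds the WT's,
    negative when it falls short, zero when p = 1 or the medians tie.
    Underflowing p-values are capped so sparkler coordinates stay finite.
    """
    if not (0.0 <= direction_p_adj <= 1.0):
        raise ValueError("adjusted p-value outside [0, 1]")
    diff = float(np.median(t.mut_self) - np.median(t.wt_self))
    if direction_p_adj == 1.0 or diff == 0.0:
        return 0.0
    mag = cap if direction_p_adj == 0.0 else min(-math.log10(direction_p_adj), cap)
    return math.copysign(mag, diff)


def classify(
    t: CorrelationTriplet,
    th: Thresholds,
    impact_p: float,
    direction_p: float,
    disting_p: float,
) -> str:
    """Run the decision tree on one comparison's (gate) p-values.

    The caller passes whichever p-values the configuration gates on
    (corrected across the run's variants when ``use_c_pval`` is set).
    """
    median_diff = float(np.median(t.mut_self) - np.median(t.wt_self))
    if impact_p <= th.conn_thresh:
        if direction_p > th.mut_wt_rep_thresh:
            return "COF"
        if median_diff > th.mut_wt_rep_rank_diff:
            return "GOF"
        if median_diff < -th.mut_wt_rep_rank_diff:
            return "LOF"
        # median tie (or |diff| within the rank-diff gate) despite a
        # significant direction test: no direction can be committed to
        logger.info("direction test significant but median difference within gate; COF")
        return "COF"
    if disting_p <= th.disting_thresh and float(
        np.median(t.wt_mut) - np.median(t.null_dist)
    ) > 0:
        return "Neutral"
    return "NI"


def evaluate_comparison(
    corr: pd.DataFrame, annot: SampleAnnotation, comparison: Comparison
) -> dict:
    """Raw test results and summary medians for one comparison."""
    t = build_triplet(corr, annot, comparison)
    ctrl_samples = [
        s for s in corr.index
        if annot.sample_to_condition.get(s) == comparison.control
    ]
    self_medians = {
        comparison.control: float(np.median(_self_pairs(corr, ctrl_samples))),
        comparison.wt: float(np.median(t.wt_self)),
        comparison.mutant: float(np.median(t.mut_self)),
    }
    return {
        "triplet": t,
        "impact": impact_test(t),
        "direction": direction_test(t),
        "disting": disting_test(t),
        "self_medians": self_medians,
    }


class VariantImpactModel:
    """Overall impact phenotyping for a set of (control, WT, mutant) designs.

    Parameters
    ----------
    zscores
        Gene x sample matrix in z-score space (from :func:`tpm_to_zscores`
        or an external standardisation).
    annotation
        Sample -> condition map plus the comparison triples to call.
    thresholds
        Decision-tree gates; defaults are the published defaults.

    Examples
    --------
    >>> model = VariantImpactModel.from_tpm(tpm, annotation)   # doctest: +SKIP
    >>> results = model.fit()                                  # doctest: +SKIP
    >>> print(results.summary())                               # doctest: +SKIP
    """

    def __init__(
        self,
        zscores: ExpressionMatrix,
        annotation: SampleAnnotation,
        thresholds: Thresholds | None = None,
    ) -> None:
        if zscores.value_space != "zscore":
            raise ValueError("VariantImpactModel expects a z-score matrix")
        if not annotation.comparisons:
            raise ValueError("annotation lists no comparisons")
        annotation.validate_against(zscores)
        self.zscores = zscores
        self.annotation = annotation
        self.thresholds = thresholds or Thresholds()

    @classmethod
    def from_tpm(
        cls,
        tpm: ExpressionMatrix,
        annotation: SampleAnnotation,
        thresholds: Thresholds | None = None,
    ) -> "VariantImpactModel":
        """Build the model from a TPM table via filter -> log2 -> z-score."""
        th = thresholds or Thresholds()
        return cls(tpm_to_zscores(tpm, th.min_tpm), annotation, th)

    def fit(self) -> "VariantImpactResults":
        """Correlate, test, adjust across variants, and classify."""
        th = self.thresholds
        corr = correlation_matrix(self.zscores)
        evals = [
            evaluate_comparison(corr, self.annotation, comp)
            for comp in self.annotation.comparisons
        ]
        adj = {
            key: th.adjust([e[key].pvalue for e in evals])
            for key in ("impact", "direction", "disting")
        }
        calls = []
        for i, (comp, ev) in enumerate(zip(self.annotation.comparisons, evals)):
            gate = (
                (adj["impact"][i], adj["direction"][i], adj["disting"][i])
                if th.use_c_pval
                else (ev["impact"].pvalue, ev["direction"].pvalue, ev["disting"].pvalue)
            )
            call = classify(ev["triplet"], th, *gate)
            score_p = adj["direction"][i] if th.use_c_pval else ev["direction"].pvalue
            medians = list(ev["self_medians"].values())
            calls.append(
                ImpactCall(
                    variant=comp.mutant,
                    wt=comp.wt,
                    call=call,
                    impact_pval=ev["impact"].pvalue,
                    impact_pval_adj=float(adj["impact"][i]),
                    direction_pval=ev["direction"].pvalue,
                    direction_pval_adj=float(adj["direction"][i]),
                    disting_pval=ev["disting"].pvalue,
                    disting_pval_adj=float(adj["disting"][i]),
                    impact_direction_score=impact_direction_score(
                        ev["triplet"], float(score_p), th.max_direction_score
                    ),
                    n_replicates={
                        comp.control: ev["triplet"].n_ctrl,
                        comp.wt: ev["triplet"].n_wt,
                        comp.mutant: ev["triplet"].n_mut,
                    },
                    cond_max_diff_flag=(max(medians) - min(medians))
                    > th.cond_max_diff_thresh,
                )
            )
        return VariantImpactResults(self, corr, calls)


class VariantImpactResults:
    """Fitted impact calls with sparkler coordinates and output writers."""

    def __init__(
        self,
        model: VariantImpactModel,
        correlations: pd.DataFrame,
        calls: list[ImpactCall],
    ) -> None:
        self.model = model
        self.correlations = correlations
        self.calls = calls

    @property
    def thresholds(self) -> Thresholds:
        return self.model.thresholds

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {
                "variant": c.variant,
                "wt": c.wt,
                "call": c.call,
                "impact_pval": c.impact_pval,
                "impact_pval_adj": c.impact_pval_adj,
                "direction_pval": c.direction_pval,
                "direction_pval_adj": c.direction_pval_adj,
                "disting_pval": c.disting_pval,
                "disting_pval_adj": c.disting_pval_adj,
                "impact_direction_score": c.impact_direction_score,
                "n_replicates": json.dumps(c.n_replicates, sort_keys=True),
                "cond_max_diff_flag": c.cond_max_diff_flag,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def sparkler_frame(self) -> pd.DataFrame:
        """Sparkler coordinates: x = -log10 adjusted impact p, y = score."""
        cap = self.thresholds.max_direction_score
        rows = []
        for c in self.calls:
            x = cap if c.impact_pval_adj == 0 else min(-math.log10(c.impact_pval_adj), cap)
            rows.append(
                {"variant": c.variant, "x": x, "y": c.impact_direction_score,
                 "call": c.call}
            )
        return pd.DataFrame(rows)

    def provenance(self, extra: dict | None = None) -> list[str]:
        """Header comment lines recording version, config hash, thresholds."""
        from . import __version__

        cfg = {"thresholds": self.thresholds.to_dict(), **(extra or {})}
        blob = json.dumps(cfg, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
        lines = [f"evip2 version {__version__}", f"config sha256[:16] {digest}"]
        lines += [f"{k} = {v}" for k, v in self.thresholds.to_dict().items()]
        return lines

    def _write(self, frame: pd.DataFrame, path, extra: dict | None = None) -> None:
        with open(path, "w") as fh:
            for line in self.provenance(extra):
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", index=False)

    def to_tsv(self, path) -> None:
        self._write(self.to_frame(), path)

    def sparkler_to_tsv(self, path) -> None:
        self._write(self.sparkler_frame(), path)

    def plot_sparkler(self, path=None, ax=None):
        from .plots import sparkler_plot

        return sparkler_plot(self.sparkler_frame(), path=path, ax=ax)

    def plot_correlation_heatmap(self, path=None, ax=None):
        from .plots import correlation_heatmap

        return correlation_heatmap(self.correlations, path=path, ax=ax)

    def summary(self) -> str:
        """Human-readable table of the calls and their test p-values."""
        df = self.to_frame()
        lines = [
            "Variant impact phenotyping results",
            "=" * 70,
            f"comparisons: {len(df)}   correction: {self.thresholds.correction}"
            f"   gates: conn={self.thresholds.conn_thresh}"
            f" dir={self.thresholds.mut_wt_rep_thresh}"
            f" disting={self.thresholds.disting_thresh}",
            "-" * 70,
        ]
        cols = ["variant", "wt", "call", "impact_pval_adj",
                "direction_pval_adj", "disting_pval_adj", "impact_direction_score"]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(df[cols].to_string(index=False))
        lines.append("=" * 70)
        return "\n".join(lines)
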