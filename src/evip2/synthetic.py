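"""Synthetic overexpression experiments for testing and calibration.

The generator emulates the bulk RNA-seq design the classifier is built
for: a handful of conditions (control, wild-type, one or more mutants),
each with a few replicates, measured over a few thousand genes. Counts
are negative-binomial around log-normal baseline means with a
mean-dependent dispersion; condition-specific expression "programs"
shift chosen genes by a log2 effect shared across that condition's
replicates, which is what creates replicate consistency and signature
identity. Per-condition replicate noise can wash a condition's signal
out again (e.g. to model a destabilised mutant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Thresholds, classify, correlation_matrix, evaluate_comparison
from .matrix import Comparison, ExpressionMatrix, SampleAnnotation, tpm_to_zscores

__all__ = [
    "Program",
    "SimSpec",
    "generate_experiment",
    "mock_fdr_simulation",
    "scenario_spec",
    "SCENARIOS",
]


@dataclass(frozen=True)
class Program:
    """A condition-specific expression program.

    ``genes`` are row indices into the simulated matrix; ``log2_effect``
    is the shared mean shift applied to those genes in every replicate
    of ``condition``.
    """

    condition: str
    genes: tuple[int, ...]
    log2_effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_effect):
            raise ValueError("log2 effect must be finite")


@dataclass
class SimSpec:
    """Full description of one synthetic experiment.

    The defaults mirror the validation design the classifier was built
    against: four replicates per condition and a transcriptome-scale
    gene panel. ``baseline_log_mean``/``baseline_log_sd`` parameterise
    the log-normal distribution of per-gene mean counts; dispersion
    follows the standard decreasing trend ``d0 + d1 / mu``.
    ``replicate_noise_sd`` (global or per-condition) adds independent
    N(0, sd) jitter on the log2 mean per gene per replicate.
    """

    n_genes: int = 2000
    conditions: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "WT": 4, "MUT": 4}
    )
    comparisons: list[Comparison] = field(default_factory=list)
    programs: list[Program] = field(default_factory=list)
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 2.0
    replicate_noise_sd: float | dict[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        for cond, n in self.conditions.items():
            if n < 2:
                raise ValueError(f"condition {cond!r} needs >= 2 replicates, got {n}")
        for prog in self.programs:
            if prog.condition not in self.conditions:
                raise ValueError(f"program condition {prog.condition!r} unknown")
            if any(g < 0 or g >= self.n_genes for g in prog.genes):
                raise ValueError("program gene index out of range")
        if not self.comparisons:
            conds = list(self.conditions)
            if len(conds) >= 3:
                self.comparisons = [
                    Comparison(conds[0], conds[1], c) for c in conds[2:]
                ]

    def noise_sd(self, condition: str) -> float:
        if isinstance(self.replicate_noise_sd, dict):
            return float(self.replicate_noise_sd.get(condition, 0.0))
        return float(self.replicate_noise_sd)


def generate_experiment(
    spec: SimSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation]:
    """Simulate counts and TPM for one experiment.

    Returns ``(counts, tpm, annotation)``; TPM is the per-sample
    counts-per-million rescaling of the count matrix (gene lengths are
    taken as equal, which is immaterial to rank-based downstream steps).
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    base_mu = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    dispersion = spec.dispersion_intercept + spec.dispersion_slope / base_mu

    columns: dict[str, np.ndarray] = {}
    mapping: dict[str, str] = {}
    for cond, n_rep in spec.conditions.items():
        log2_shift = np.zeros(spec.n_genes)
        for prog in spec.programs:
            if prog.condition == cond:
                log2_shift[list(prog.genes)] += prog.log2_effect
        sd = spec.noise_sd(cond)
        for rep in range(n_rep):
            shift = log2_shift.copy()
            if sd > 0:
                shift = shift + rng.normal(0.0, sd, spec.n_genes)
            mu = base_mu * np.exp2(shift)
            # NB(mean mu, dispersion a): n = 1/a, p = n / (n + mu)
            n_param = 1.0 / dispersion
            counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
            sample = f"{cond}_r{rep + 1}"
            columns[sample] = counts
            mapping[sample] = cond

    counts_df = pd.DataFrame(columns, index=gene_ids)
    counts_m = ExpressionMatrix(counts_df, "counts")
    tpm_df = counts_df / counts_df.sum(axis=0) * 1e6
    tpm_m = ExpressionMatrix(tpm_df, "tpm")
    annot = SampleAnnotation(mapping, list(spec.comparisons))
    return counts_m, tpm_m, annot


#: canonical single-comparison scenarios with a known ground-truth call
SCENARIOS = ("neutral", "lof", "gof", "cof")

#: replicate-level biological noise (sd of the per-gene log2 jitter) used
#: by the canonical scenarios; without it, replicates within a condition
#: share a nearly identical signal and the direction test resolves
#: arbitrarily small consistency differences, which biological replicates
#: do not exhibit
SCENARIO_NOISE_SD = 0.5


def scenario_spec(kind: str, seed: int = 0, n_genes: int = 800) -> SimSpec:
    """A single-comparison experiment whose true call is known.

    ``neutral``: the mutant shares the wild-type's expression program.
    ``lof``: the wild type drives a program the mutant has lost entirely.
    ``gof``: the mutant gains a strong program the wild type lacks.
    ``cof``: wild type and mutant drive equally strong programs on
    interleaved (baseline-matched) but disjoint gene sets, so both are
    internally consistent yet mutually uncorrelated.
    """
    wt_program = Program("WT", tuple(range(0, 150)), 2.0)
    programs = {
        "neutral": [wt_program, Program("MUT", tuple(range(0, 150)), 2.0)],
        "lof": [wt_program],
        "gof": [Program("MUT", tuple(range(150, 350)), 3.0)],
        "cof": [
            Program("WT", tuple(range(0, 300, 2)), 2.0),
            Program("MUT", tuple(range(1, 300, 2)), 2.0),
        ],
    }
    if kind not in programs:
        raise ValueError(f"unknown scenario {kind!r}; pick one of {SCENARIOS}")
    return SimSpec(
        n_genes=n_genes,
        conditions={"control": 4, "WT": 4, "MUT": 4},
        programs=programs[kind],
        replicate_noise_sd=SCENARIO_NOISE_SD,
        seed=seed,
    )


def mock_fdr_simulation(
    n_null_replicates: int = 12,
    group_size: int = 4,
    iterations: int = 1000,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    n_genes: int = 2000,
    include_pathways: bool = False,
    pathway_iterations: int = 5,
    gene_sets=None,
    de_alpha: float = 0.05,
) -> dict[str, float]:
    """Empirical false-positive rate of the classifier on null data.

    A single null condition of exchangeable replicates is simulated,
    preprocessed once, and reduced to its sample correlation matrix.
    Each iteration draws a disjoint mock-mutant and mock-WT group of
    ``group_size`` replicates (the leftover replicates act as the mock
    control) and classifies the comparison at the given thresholds; any
    GOF / LOF / COF call counts as a false positive, since every group
    is drawn from the same condition.

    When ``include_pathways`` is set, a reduced number of iterations
    additionally runs the DE partition + pathway stage against the
    provided gene sets and counts non-neutral, non-NI pathway rows as
    pathway-level false positives.

    Returns a dict with key ``overall`` (and ``wt_specific_pathways`` /
    ``mutation_specific_pathways`` when pathways are included), each a
    false-positive fraction in [0, 1].
    """
    if n_null_replicates < 2 * group_size:
        raise ValueError(
            f"cannot draw two disjoint groups of {group_size} from "
            f"{n_null_replicates} replicates"
        )
    th = thresholds or Thresholds()
    rng = np.random.default_rng(seed)
    spec = SimSpec(
        n_genes=n_genes,
        conditions={"null": n_null_replicates},
        comparisons=[],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts, tpm, _ = generate_experiment(spec)
    zscores = tpm_to_zscores(tpm, th.min_tpm)
    corr = correlation_matrix(zscores)
    samples = list(corr.index)

    false_positives = 0
    draws: list[tuple[list[str], list[str], list[str]]] = []
    for _ in range(iterations):
        perm = rng.permutation(len(samples))
        mut = [samples[i] for i in perm[:group_size]]
        wt = [samples[i] for i in perm[group_size : 2 * group_size]]
        ctrl = [samples[i] for i in perm[2 * group_size :]]
        draws.append((ctrl, wt, mut))
        annot, comp = _mock_annotation(ctrl, wt, mut)
        ev = evaluate_comparison(corr, annot, comp)
        # single mock variant per run: the adjusted p equals the raw p
        call = classify(
            ev["triplet"], th,
            ev["impact"].pvalue, ev["direction"].pvalue, ev["disting"].pvalue,
        )
        if call in ("GOF", "LOF", "COF"):
            false_positives += 1
    out = {"overall": false_positives / iterations}

    if include_pathways:
        if gene_sets is None:
            raise ValueError("include_pathways requires gene_sets")
        from .pathways import PathwayImpactModel

        fp = {"wt_specific": 0, "mutation_specific": 0}
        rows = {"wt_specific": 0, "mutation_specific": 0}
        for ctrl, wt, mut in draws[:pathway_iterations]:
            annot, comp = _mock_annotation(ctrl, wt, mut)
            annot.comparisons = [comp]
            model = PathwayImpactModel(
                zscores, counts, annot, gene_sets, thresholds=th, de_alpha=de_alpha
            )
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = model.fit()
            for subset_type in fp:
                sub = res.calls[res.calls["subset_type"] == subset_type]
                rows[subset_type] += len(sub)
                fp[subset_type] += int(sub["call"].isin(["GOF", "LOF", "COF"]).sum())
        for subset_type in fp:
            out[f"{subset_type}_pathways"] = (
                fp[subset_type] / rows[subset_type] if rows[subset_type] else 0.0
            )
    return out


def _mock_annotation(ctrl, wt, mut):
    mapping = {s: "mock_control" for s in ctrl}
    mapping.update({s: "mock_WT" for s in wt})
    mapping.update({s: "mock_MUT" for s in mut})
    comp = Comparison("mock_control", "mock_WT", "mock_MUT")
    return SampleAnnotation(mapping, [comp]), comp
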