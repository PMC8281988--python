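# Methods

## Model and assumptions

The classifier treats a variant's transcriptomic phenotype as a point in
correlation space rather than in expression space. All inference is done
on Spearman rank correlations between per-sample signatures, after
per-gene z-scoring across every sample in the run (controls included).
This makes the method invariant to monotone per-sample distortions and
to the absolute scale of expression, at the cost of assuming that
replicate-to-replicate correlation is an adequate summary of signature
strength. The decision tree assumes:

* replicates of a condition are exchangeable (no batch structure within
  a condition);
* the control condition defines "background": mutant-vs-control
  correlations are a valid null for judging whether WT-vs-mutant
  similarity is real signal;
* at least 2 replicates per condition are present (3+ recommended; the
  p-value resolution of the rank tests is limited by the 6-vs-6 and
  16-vs-16 group sizes a 4-replicate design yields).

The three hypothesis tests are deliberately nonparametric
(Kruskal–Wallis, two-sided unpaired rank-sum). The rank-sum test uses
the unpaired (Mann–Whitney) form because the compared distributions
have different sizes by construction (e.g. 6 self-correlations vs 16
cross-correlations at n=4); a paired form is not defined on these
inputs. Exact enumeration of the rank-sum null is used for pooled sizes
≤ 12 without ties (C(12,6)=924 subsets keeps this trivial), otherwise a
normal approximation with tie and continuity corrections. The
Kruskal–Wallis p comes from the chi-square approximation with tie
correction.

One caveat is inherent to the design: the correlation values inside one
comparison share replicates and are therefore dependent, while both
tests assume independent observations. The p-values are consequently
approximate; the mock-comparison calibration below is the empirical
check that the resulting false-positive rate stays inside the working
cutoff.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_tpm` | 1 | a gene is kept if its max TPM over all samples ≥ this |
| `conn_thresh` | 0.1 | adjusted-p gate of the impact (KW) test |
| `mut_wt_rep_thresh` | 0.1 | adjusted-p gate of the direction test |
| `disting_thresh` | 0.1 | adjusted-p gate of the Neutral/NI test |
| `mut_wt_rep_rank_diff` | 0 | minimum median self-correlation difference to commit to GOF/LOF |
| `cond_max_diff_thresh` | 0.2 | quality flag on the spread of per-condition self-correlation medians |
| `use_c_pval` | true | gate on corrected rather than raw p-values |
| `min_genes` | 10 | minimum usable genes per pathway |
| `de_alpha` | 0.05 | adjusted-p cutoff defining differential expression |

The 0.1 gates are the published working values for 4-replicate RNA-seq
designs (relaxed from 0.05 used with 8-replicate L1000 screens). The
p-value gates must lie in (0,1).

Design choices where the published description left room:

* **Correction family.** Benjamini–Hochberg by default (a Bonferroni
  switch is provided); the family is the set of variants in one run,
  separately per test, and for pathway calls the set of eligible
  pathways per variant per subset type.
* **TPM filter scope.** A gene survives if its *maximum* TPM over all
  samples reaches `min_tpm` (inclusive boundary): a gene silent in
  control but induced by the mutant must stay measurable.
* **log2 pseudocount.** log2(x+1), defined at zero and standard for TPM.
* **z-score denominator.** Sample standard deviation (n−1); rows
  constant across all samples are dropped with a warning, since a
  constant row carries no rank information and would only add tie
  blocks.
* **`mut_wt_rep_rank_diff`** is read as the minimum difference of
  median self-correlation (mutant − WT) needed to commit to a
  direction; at the default 0 any nonzero difference suffices, making
  the default a no-op. A median tie with a significant direction test
  falls back to COF (logged; essentially impossible with continuous
  correlations except by construction).
* **`cond_max_diff_thresh`** acts as a flag-only quality gate: if the
  spread (max − min) of the control/WT/mutant self-correlation medians
  exceeds it, the row is flagged (`cond_max_diff_flag`) but the call is
  not altered — the least-surprise reading of a parameter whose gating
  role is otherwise undocumented.
* **Neutral requires directionality.** The distinguishability test is
  two-sided, so Neutral additionally requires
  median(`wt_mut`) > median(`null`): "more similar to WT than to
  control", not merely "different from the null".
* **Direction-score underflow.** |score| = −log10(adjusted p) is capped
  at 20 so sparkler coordinates stay finite when p underflows.
* **Pathway restriction.** The global z-score matrix is sliced to a
  pathway's genes rather than re-standardised: z-scores are per-gene,
  so the restriction is well-defined and keeps pathway and overall
  calls on the same scale.

## Differential-expression stage

The DE test behind the gene partition is DESeq2's negative-binomial
Wald test, called through `pydeseq2` (median-of-ratios size factors,
trended dispersion shrinkage, BH-adjusted p-values). Genes with
undefined adjusted p (all-zero counts, or otherwise untestable) are
treated as not differentially expressed. The DE universe is restricted
to genes that survive the expression filter so the partition is
consistent with the correlation analysis. Cook's-distance outlier
refitting is effectively inactive at the 4-replicate design sizes used
here. Set-level behaviour (recovery of strong planted effects, mirror
symmetry of the partition under input swap) is the tested contract, not
bit-identity of any particular DESeq2 version.

## Synthetic data

`evip2.synthetic` generates the experimental design the classifier
expects: negative-binomial counts with log-normal baseline means
(log-mean 5, log-sd 2, i.e. a realistic several-decade dynamic range),
dispersion following the standard decreasing trend 0.05 + 2/µ, and
per-condition expression "programs" — shared log2 mean shifts on chosen
gene sets — which are what create replicate consistency and signature
identity. TPM is the counts-per-million rescaling of the same matrix
(equal gene lengths; immaterial to rank-based steps). Everything is
deterministic given the seed.

The canonical scenarios (`scenario_spec`) use 800 genes, 4 replicates
per condition, and a replicate-level log2 jitter of sd 0.5. That jitter
models biological replicate variability; without it, replicates within
a condition share an almost identical signal, the six within-condition
correlations collapse into a very tight cluster, and the direction test
resolves arbitrarily small consistency differences — a regime real
biological replicates do not occupy. Scenario definitions:

* *neutral* — mutant shares the WT's 150-gene, 4-fold program;
* *lof* — WT drives the program, the mutant has lost it;
* *gof* — the mutant gains a 200-gene, 8-fold program the WT lacks;
* *cof* — WT and mutant drive equally strong programs on interleaved
  (baseline-matched) but disjoint 150-gene sets.

What the generator does **not** emulate: batch effects, library-size
artefacts beyond simple scaling, gene–gene correlation within programs
beyond the shared shift, compositional interactions between many
conditions, and real pathway topology. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
model, not performance on any particular real dataset.

## False-discovery calibration

The mock-comparison simulation draws a single null condition of 12
exchangeable replicates (2,000 genes), preprocesses it once, and for
1000 iterations samples a disjoint mock-mutant and mock-WT group of 4
replicates (the remaining 4 act as the mock control, which the
Neutral/NI branch requires), classifying each draw at default
thresholds. Any GOF/LOF/COF call is a false positive. With a single
mock variant per draw the corrected p equals the raw p, so the
simulation measures the raw decision-tree operating point. Observed
false-positive fractions are in the 5–9% range across seeds, inside the
10% working cutoff. Pathway-level false-positive fractions are exposed
behind `include_pathways`; because each pathway iteration needs two
DESeq2 fits, the default iteration count for that level is small, and
under the null the DE partitions are nearly always too small to leave
any eligible pathway.

Problem sizes used throughout (2,000 genes for calibration, 400–1,000
genes for unit-level simulations, 4 replicates per condition) match the
regime the method targets while keeping every simulation reproducible
on a laptop in seconds to minutes.

## Known limitations

* P-values are approximate under the dependence noted above; the
  calibration bound, not the nominal level, is the operational
  guarantee.
* The method compares *signatures*, not mechanisms: a variant that
  changes expression through an artefact (dosage, clone effects) is
  indistinguishable from a genuine functional change.
* Pathway calls inherit the DE stage's power: with few replicates,
  small true programs may not yield 10 usable genes and are silently
  ineligible (logged).
* External z-score inputs are accepted as-is; their standardisation
  population is the caller's responsibility.
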