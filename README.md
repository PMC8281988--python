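# evip2 — expression-based variant impact phenotyping

`evip2` classifies the functional impact of a gene variant from the
transcriptome changes it induces. The experimental design it serves is
overexpression screening: a control construct (e.g. GFP or empty
vector), the wild-type ORF, and one or more mutant ORFs are each
expressed in replicate in the same cell line and profiled by RNA-seq (or
L1000). From the replicate expression signatures alone, each variant is
called one of:

| call | meaning |
|------|---------|
| **GOF** | gain-of-function — mutant signature stronger / more consistent than WT |
| **LOF** | loss-of-function — no effect or mild effect compared to WT |
| **COF** | change-of-function — impactful, but neither direction reaches significance |
| **Neutral** | same as WT |
| **NI** | non-informative — signatures too noisy to distinguish from background |

It is aimed at cancer-genomics and functional-genomics groups that need
variant-level (and pathway-level) function calls without reporter assays.

## Method

Gene-level TPM values are filtered (genes with max TPM < 1 removed),
log2(x+1) transformed, and z-scored per gene across **all** samples,
controls included. Pairwise Spearman rank correlations between sample
signatures give, for each (control, WT, mutant) comparison, four
correlation distributions:

* `wt_self` — WT replicate self-correlation (signal strength), all
  n(n−1)/2 replicate pairs;
* `mut_self` — mutant replicate self-correlation;
* `wt_mut` — WT×mutant cross-correlations (signature identity);
* `null` — mutant×control correlations, the background distribution.

A decision tree then assigns the call:

1. **Impact test** — Kruskal–Wallis on (`wt_self`, `mut_self`,
   `wt_mut`). If the Benjamini–Hochberg-adjusted p ≤ `conn_thresh`
   (default 0.1) the variant is impactful.
2. **Direction test** (impactful variants) — two-sided rank-sum of
   `mut_self` vs `wt_self`. Not significant → **COF**; significant with
   median(`mut_self`) > median(`wt_self`) → **GOF**, below → **LOF**.
3. **Distinguishability test** (non-impactful variants) — two-sided
   rank-sum of `wt_mut` vs `null`. Significant *and* the mutant more
   similar to WT than to control → **Neutral**, otherwise **NI**.

The *impact direction score* is the signed −log10 adjusted direction-test
p (positive when mutant consistency exceeds WT's); sparkler plots show
−log10 adjusted impact p against this score.

**Pathway-level calls** (`evip2 pathways`): WT and mutant are each
compared to the control with DESeq2 (via `pydeseq2`); genes
differentially expressed only against the mutant are *mutation-specific*,
only against the WT *WT-specific*. The same decision tree is re-run on
the z-score matrix restricted to each pathway's usable genes (pathway ∩
subset ∩ measured, minimum 10 genes), separately per subset, with BH
correction across pathways.

## Worked example

```python
from evip2 import VariantImpactModel, generate_experiment
from evip2.synthetic import scenario_spec

# a synthetic 4-replicate experiment in which the mutant has lost the
# wild-type's 150-gene expression program
_, tpm, annot = generate_experiment(scenario_spec("lof", seed=7))
results = VariantImpactModel.from_tpm(tpm, annot).fit()
print(results.summary())
```

```
Variant impact phenotyping results
======================================================================
comparisons: 1   correction: bh   gates: conn=0.1 dir=0.1 disting=0.1
----------------------------------------------------------------------
variant wt call  impact_pval_adj  direction_pval_adj  disting_pval_adj  impact_direction_score
    MUT WT  LOF         2.19e-05            0.002165         1.545e-06                  -2.665
======================================================================
```

The impact test rejects indistinguishability (adjusted p ≈ 2.2e−05), the
direction test finds the mutant's replicate consistency significantly
*below* the WT's (adjusted p ≈ 0.0022, score −2.67), so the variant is
called loss-of-function.

The same pipeline from the shell, on a generated fixture bundle:

```bash
evip2 fixtures -o demo --seed 7          # counts, TPM, annotation, toy GMT
evip2 run --tpm demo/tpm.tsv --annotation demo/annotation.tsv \
          --comparisons demo/comparisons.yaml -o demo_out
evip2 pathways --tpm demo/tpm.tsv --counts demo/counts.tsv \
          --annotation demo/annotation.tsv --comparisons demo/comparisons.yaml \
          --gmt demo/pathways.gmt -o demo_pw
```

`demo_out/predictions.tsv` holds one row per (WT, mutant) comparison
with all raw and adjusted p-values; `sparkler.tsv` the plot coordinates.
Every output file starts with `#` header lines recording the tool
version, a config hash, and all effective thresholds.

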