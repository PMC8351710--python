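# lncarray

Mining long non-coding RNA (lncRNA) expression out of legacy 3' expression
arrays by probe-level re-annotation, with the downstream clinical association,
survival and enrichment analyses that turn a re-annotated probe set into a
candidate prognostic lncRNA.

## The problem

3' expression arrays (e.g. the Human Genome U133 Plus 2.0 platform) measure
each target with a set of ~11–22 25-nt oligonucleotide probes, grouped by
vendor probe-set definitions that predate current transcript annotation.
Many probe sets in fact interrogate lncRNAs that were unannotated when the
platform was designed, so the vendor's gene assignments hide usable lncRNA
signal in thousands of archived tumor cohorts. `lncarray` rebuilds the
probe-to-transcript map from sequence and carries the result through the
standard mining pipeline:

1. **Re-annotation** — every probe sequence is mapped against a transcript
   reference by exact matching (a k-mer-seeded substring index, verified
   against the transcript string). A probe set is assigned to transcript *T*
   iff (i) at least `min_probes` (default 4, "more than three") distinct
   probes support *T*, (ii) every supporting probe matches with **zero
   mismatches** over its full length, and (iii) every supporting probe
   matches **exactly one** transcript in the reference.
2. **Summarization** — probe-level log2 intensities collapse to one value
   per assigned transcript (median by default).
3. **Differential expression** — two-group pooled-variance *t* test
   (equivalent to a two-group one-way ANOVA, *F* = *t*²), or a paired *t*
   test, with Benjamini–Hochberg *q*-values.
4. **Median split & association** — samples are dichotomized at the median
   of the candidate transcript's expression (ties to the low group) and each
   clinicopathological covariate is tested against the split: Pearson
   chi-squared without continuity correction for categorical covariates,
   one-way ANOVA for continuous ones.
5. **Survival** — Kaplan–Meier curves, the unweighted log-rank test, and a
   univariate Cox proportional-hazards fit (Breslow ties, Newton–Raphson)
   reporting the hazard ratio HR = exp(β) with a 95% Wald CI.
6. **Enrichment** — GSEA between the low/high groups: genes ranked by
   signal-to-noise, weighted Kolmogorov–Smirnov running-sum enrichment
   score, phenotype-permutation null (seeded), NES, permutation *p* and BH
   *q* across sets; plus a local hypergeometric over-representation test for
   a query gene list (e.g. a leading edge) against a GMT collection.

A seeded synthetic-study generator (`lncarray.synthetic_data`) emulates the
whole input stack — reference FASTA, probe-tab, probe-level expression,
clinical table, survival table, GMT — with planted ground truth (probe map,
expression shifts, covariate links, hazard ratio) so every stage can be
validated by recovery.

## Worked example

```python
import numpy as np
import lncarray as la

# a paper-shaped synthetic study: 226 tumors + 50 normals, 40 probe sets of
# 11 probes, planted -2 log2 tumor shift on one lncRNA, planted HR 0.48
reference, study, gene_sets = la.simulate_paperlike(seed=1)

assignments = la.reannotate(reference.probes, reference.transcripts)
print(sum(a.status == "assigned" for a in assignments), "of", len(assignments))
# 40 of 40

expr = la.summarize_expression(study.probe_expr, assignments)
de = la.differential_expression(expr, study.clinical["cohort"])
top = de.sort_values("p_value").iloc[0]
print(top["feature_id"], round(top["log2_fold_change"], 2))
# TX0000 -1.77

split = la.median_split(expr.loc[top["feature_id"], study.split.index])
print((split == "low").sum(), (split == "high").sum())
# 113 113

surv = study.survival
cox = la.cox_univariate(surv["time_months"], surv["event"],
                        (surv["group"] == "high").astype(float))
print(f"HR {cox.hazard_ratio:.2f} ({cox.ci_low:.2f}~{cox.ci_high:.2f})")
# HR 0.51 (0.35~0.74)
```

The numbers above are what this code prints at seed 1: all 40 probe sets
survive the three criteria (at a 5% probe mismatch rate and 5% ambiguity
rate, almost every 11-probe set keeps the 4 clean probes it needs); the
planted transcript tops the differential-expression table (its measured
shift sits below the planted −2 because the target also carries a
per-sample latent deviation); the median split is 113/113; and the Cox fit
recovers a hazard ratio near the planted 0.48, with seed-to-seed sampling
noise.

Or from the shell:

```bash
lncarray simulate --preset paperlike --seed 1 --out study/
lncarray reannotate --probes study/probes.tsv --reference study/reference.fasta \
    --biotypes study/biotypes.tsv --out assignments.tsv
lncarray survive --survival study/survival.tsv --out curves.tsv
```

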