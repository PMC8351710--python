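# Methods

## Probe re-annotation

Each 3'-array probe set is a bag of ~11–22 25-nt probes. `reannotate`
discards the vendor probeset→gene definitions and rebuilds them from
sequence against a user-supplied transcript reference (FASTA, optionally
with a biotype sidecar). Matching is exact and full-length: a probe matches
a transcript iff the probe sequence (or, with `allow_revcomp`, its reverse
complement) equals a transcript substring character for character. There is
no mismatch tolerance, no gapped alignment, and no genome-aware (intronic)
mapping — probes on 3' arrays were designed against transcript sequence, so
transcript-space exact matching is the appropriate primitive.

The index seeds each query with its leading `word_size`-mer (default 12)
and verifies every candidate placement against the transcript string, so
`word_size` affects speed only; an oracle test asserts identity with a
naive sliding-window scan at several word sizes. k-mers containing `N` are
not indexed and verification cannot succeed across an `N`, so ambiguous
reference bases never match. Sequences are uppercased on construction
(case-insensitive matching).

Assignment applies three criteria per probe set:

- **uniqueness (per probe):** a probe contributes evidence only if it
  matches exactly one transcript within the uniqueness scope. The default
  scope is the whole supplied reference — stricter, since a probe that also
  hits a coding transcript is a cross-hybridization risk. A `lncRNA_only`
  scope is available (matches to non-lncRNA transcripts are disregarded
  before the uniqueness count) because the appropriate scope depends on how
  complete the supplied reference is. Multiple placements of a probe at
  different offsets of the *same* transcript count as one probe→transcript
  pair: uniqueness is over transcripts, not offsets.
- **support (per set):** the set is assigned to transcript *T* iff at least
  `min_probes` (default 4, i.e. "more than three") distinct probe positions
  contribute evidence for *T*. Evidence is counted over distinct
  `probe_index` values; exact duplicate rows collapse, and two different
  sequences claiming the same probe index are an input error.
- **unambiguity (per set):** if a second transcript independently reaches
  `min_probes` from the same set the set is `rejected_ambiguous`. Sets whose
  matching probes were all discarded as multi-transcript are
  `rejected_nonunique`; all other failures are `rejected_too_few`.

Output order is sorted by probeset id and evidence sets are sorted, so the
result is invariant to input ordering. Raising `min_probes` can only remove
assignments (monotonicity; tested).

## Summarization and differential expression

Probe-level matrices are pandas DataFrames keyed `"<probeset>:<index>"`,
assumed already log2-transformed and normalized (no background correction
or CEL parsing). `summarize_expression` takes the median (default) or mean
of a transcript's matched probes per sample, pooling probes across probe
sets when several sets were assigned to one transcript; the median is the
default because it is robust to a residual bad probe.

`differential_expression` uses the pooled-variance two-sample *t* test in
unpaired mode — the two-group special case of one-way ANOVA (*F* = *t*², an
identity the tests assert) — with Welch's correction behind a flag, and the
paired *t* test in paired mode (pair ids must form a perfect matching).
*q*-values are Benjamini–Hochberg across all features. A feature with zero
variance in both groups and equal means reports *p* = 1 with a
`zero_variance` flag rather than NaN; zero variance with unequal means
reports *p* = 0 with the same flag. No specific significance threshold is
claimed to reproduce any published candidate count; the (*q* cutoff,
|log2FC| cutoff) pair is configuration, defaulting to *q* < 0.05 with no
fold-change cutoff.

`ddct_fold_change` is the standard relative-quantification formula
2^−(ΔCt_condition − ΔCt_calibrator).

## Median split and association

`median_split` labels values ≤ median "low" and > median "high". Ties at
the median go low — some deterministic rule is required, and with distinct
values this yields ⌈n/2⌉/⌊n/2⌋ (226 → 113/113, 293 → 147/146, matching the
published cohort headers). All-identical values are a degenerate split and
raise.

Categorical covariates are tested with the Pearson chi-squared statistic
**without** Yates continuity correction — the convention that reproduces,
at 3-decimal rounding, every exactly printed *p* in the published cohort
tables (verified in the acceptance suite); Yates and Fisher's exact are
available as options. Missing covariate values are dropped per covariate
(pairwise deletion), so `n_used` varies between rows of one report, as in
the published M-stage row (145 + 145 of 293). All-zero levels are dropped
and the degrees of freedom recomputed. Continuous covariates use classical
one-way ANOVA. The published table reports its continuous rows as
"mean ± SD" but prints SE-sized dispersions; this package's reports label
the column as standard error and compute it as such. *p*-values are rounded
for display only; full precision is kept internally.

## Survival

Kaplan–Meier curves and the unweighted log-rank test come from lifelines.
The univariate Cox model is implemented directly: Newton–Raphson on the log
partial likelihood with step-halving, convergence at |Δloglik| < 1e-9, max
50 iterations, Breslow tie handling by default with Efron behind a flag.
Breslow is the default because it is the simplest standard choice and makes
the score test at β = 0 coincide with the log-rank chi-squared for a binary
covariate — an internal consistency check the tests enforce to 1e-6. The
implementation is cross-checked against lifelines' Cox fit on untied data
(identical to 1e-5) and under Efron ties. Monotone likelihood (complete
separation) raises a `ConvergenceError` rather than returning a huge
coefficient; the detection thresholds are |β| > 20 or vanishing
information. The 95% CI is Wald on the log-hazard scale, exponentiated —
matching the `HR (low~high)` reporting style. Cox estimates are invariant
to strictly monotone time transforms (tested), as the partial likelihood
depends on time only through ranks.

Reproduction of the published cohort hazard ratios (0.48, 0.73, 0.64)
requires the original cohort data and is documented as out of scope; the
survival stage is instead validated by null CI coverage and planted-HR
recovery simulations.

## Enrichment

`rank_genes` scores each gene by signal-to-noise between the high and low
groups: (mean_hi − mean_lo)/(sd_hi + sd_lo), each sd floored at 0.2·|mean|
and at 1e-4, following the GSEA convention that stops near-constant genes
from dominating; ties break by gene id for determinism. `enrichment_score`
is the classic weighted KS running sum (default weight 1): hits add their
normalized |metric|^weight, misses subtract 1/(N−k), and the ES is the
signed extremum. The running sum ends at 0 by construction. Degenerate
case: when the gene set covers the entire universe there are no misses and
the textbook miss term is 0/0; the uniform CDF i/N is used as the reference
instead, which makes the ES exactly 0 at weight 0 (the natural null value).
When all hit metrics are zero, equal hit steps are used.

`gsea_permutation` permutes phenotype labels with
`numpy.random.default_rng(seed)` (bit-reproducible; capped with a warning
when fewer distinct label arrangements exist). Per set: NES = ES divided by
the mean |null ES| of matching sign, and the permutation *p* is the
plus-one sign-conditional estimate (1 + #{same-sign null ≥ observed}) /
(1 + #same-sign null) — never exactly 0, and approximately uniform under
the null (a calibration the acceptance suite measures by KS distance). The
FDR is Benjamini–Hochberg over the per-set permutation *p*-values — a
deliberate simplification of the original pooled-NES permutation FDR,
chosen for transparency; the conventional 0.05 cutoff is the default. Null
ES values are computed vectorized from per-permutation hit positions (the
running-sum extremum can only occur immediately before or after a hit, so
2k candidates per set suffice).

A known property worth stating: the ES saturates once a set occupies the
extreme ranks, so on small universes (tens of genes) the permutation *p*
discriminates weakly between a strong and a very strong set even when the
ranking signal is unambiguous. The end-to-end pipeline test therefore
checks that the planted set leads the positive-ES table and that its
leading edge recovers the planted genes, rather than demanding an extreme
*p* on a 40-transcript universe.

`overrepresentation_test` is a one-sided hypergeometric tail
(`scipy.stats.hypergeom.sf`) of the query/set overlap in a finite universe,
BH-corrected across sets — a local stand-in for web-based gene-ontology
over-representation tools, which are out of scope. The pipeline queries the
10 highest-ranked leading-edge members of the best-q GSEA set ("top 10" is
defined as leading-edge members in ranking order, since no formal
definition exists for it).

## Synthetic data

The generator emulates the structure, not the biology, of a 3'-array lncRNA
cohort study:

- **Reference/probes:** random uniform ACGT transcripts (default 60 of
  400–1200 nt, half lncRNA), 40 probe sets of 11 25-nt probes lifted from
  distinct random offsets of their source transcripts. A `mismatch_rate`
  fraction of probes get one random substitution (they then match nothing);
  an `ambiguous_rate` fraction are copied into a decoy transcript at a
  non-overlapping position (they then match two transcripts and fail
  uniqueness). Random 25-mer collisions have probability ~L·4⁻²⁵ and are
  ignored. The truth object records every injection and can state the
  expected assignment map for any `min_probes`.
- **Expression:** probe value = transcript baseline (U(6,10) log2 units)
  + planted tumor/normal shift + N(0, noise_sd = 0.4) probe noise. The
  target transcript carries an extra N(0,1) per-sample deviation so its
  median split is informative. "Co-expressed" transcripts are raised by
  `coexpression_strength` (default 0.8) log2 units in high-split samples —
  a coordinated mean shift with independent noise, the construction a
  phenotype-permutation null can detect. (A shared continuous latent factor
  was considered and rejected: it makes the co-expressed block cluster
  under *any* permutation, which is exactly the inter-gene-correlation
  regime where rank-based ES saturates and permutation *p*-values lose
  power.)
- **Clinical/survival:** covariates are drawn per tumor sample from
  group-conditional level probabilities keyed to the target's median split;
  the `paperlike` preset uses the published cohort's printed marginal
  proportions (EGFR 54.0% vs 33.6% mutated, etc., age SE 0.66·√113 ≈ 7 as
  the SD) so synthetic cohorts resemble the study shape. Survival is
  exponential with rate log(2)/50 months · exp(β·1[high]) (β = log 0.48 in
  the preset), censored by an independent Uniform(0, u) time with u solved
  numerically so the expected censoring fraction is met (default 0.5).
  Normals carry no covariates or survival, as in a real tumor/normal array
  series.
- **Determinism:** one `numpy.random.SeedSequence(seed)` spawns a child
  stream per component; identical (parameters, seed) give byte-identical
  outputs, which the tests assert.

What passing on synthetic data does **not** show: the generator has no
spatial array artifacts, batch effects, probe affinity biases,
non-exponential hazards, or realistic transcriptome sequence composition
(shared exons, paralogs, repeats). Exact-match re-annotation on real
platforms therefore faces many more multi-mapping probes than the uniform
random reference produces; the uniqueness criterion exists precisely for
that case, and the generator's `ambiguous_rate` only samples it.

## Problem sizes and numerical choices

The validation studies run at desk scale, chosen as the smallest sizes at
which the measured properties are stable: 2000-feature null matrices for
type-I-error calibration; 200 replicates for Cox coverage/recovery (n = 200
null, n = 400 at planted HR 0.5 with 30% censoring); 200 null gene sets at
n_perm = 1000 for GSEA calibration; universes ≤ 50 for the exhaustive
hypergeometric oracle; and a 226 + 50-sample, 60-transcript paper-shaped
pipeline run. Tolerances: type-I error 0.05 ± 0.015; Cox coverage in
[0.90, 0.99] and planted-HR recovery within [0.4, 0.62] in ≥ 90% of
replicates; GSEA null-p KS distance < 0.15. Tie-breaks are deterministic
throughout (gene id in rankings, low group at the median, stable sorts).
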