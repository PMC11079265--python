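# Methods

This note documents the models and procedures implemented in `subgwas`, the
assumptions behind them, the synthetic-data generators that exercise them,
and the numerical and design choices made where more than one reading was
defensible.

## Event phenotyping

**Model.** A participant's event history for a trait (AF or MI) is derived
from hospital diagnosis records carrying an ICD-9 or ICD-10 code, a date and
a role (*main* = primary diagnosis of the visit, *bi* = secondary). Trait
membership is prefix-based after stripping dots — AF is ICD-10 I48 or ICD-9
427.3, MI is ICD-10 I21–I24 or ICD-9 410 — so subcodes such as 427.31 or
I21.4 match their roots. The first event is the earliest trait record of
*any* role. A later record opens a new event only when (a) its date is more
than the gap threshold after the last counted event and (b) it is a main
diagnosis, or a secondary diagnosis that is the sole diagnosis record (any
code) of that participant-day. Secondary diagnoses accompanied by other
records are treated as administrative restatements of known disease, not new
events. Non-qualifying records do not reset the gap clock.

Classification: zero events → control candidate; two or more events →
recurrent (no exclusions apply); exactly one event → excluded if the death
registry lists a trait code among the primary/secondary causes, or if death
or the censoring date falls within the relapse window after the event
(5 years AF, 7 years MI — the window within which most second events are
observed to occur); otherwise single. Controls must be event-free for *both*
traits; a participant with events of only the other trait is neither case
nor control ("other") and is dropped from that trait's analyses.

**Numerical choices.** "More than 1 month" is implemented as strictly more
than 30 days (configurable); calendar-month arithmetic is ambiguous at month
boundaries. "Less than w years" uses calendar-year arithmetic
(`add_years`, with 29 Feb clamping to 28 Feb) and strict comparison, so an
event exactly w years before censoring survives. Death-registry entries
never create clinical events; they only trigger exclusions. A death date
preceding the first event raises a data-integrity error rather than
silently classifying.

**Baseline comparison.** Continuous characteristics use the two-sided
pooled-variance Student's t-test (Welch available behind a flag); binary
characteristics use Fisher's exact test on the 2×2 table. With the standard
set of eight characteristics (age at first event, diabetes, hypertension,
BMI, smoking, cholesterol, systolic and diastolic blood pressure) the
Bonferroni per-test level is 0.05/8 = 6.25×10⁻³. Missing values are dropped
per characteristic; a group with fewer than two non-missing continuous
values yields a not-computable (NaN) row instead of an exception.

## Registry simulation

Participants are planted, not sampled post-hoc from labels: each draws a
first event (per-year hazard over the follow-up span), optionally a second
event at a uniform gap (lower bound above the 30-day threshold), optionally
death at a delay after the last event with a configurable probability that
the cause is the trait itself. The truth label is computed at construction
from this skeleton with the same calendar arithmetic the classifier uses, so
recovery tests validate the classifier against construction, not against a
re-derivation. Noise that can never flip a label is layered on top:
secondary-role trait records within the gap window of a counted event,
secondary records with same-day companion diagnoses, and unrelated
background diagnoses (kept off protected sole-diagnosis days). A small
fraction of participants (2% by default) is planted exactly on the decision
boundaries — gaps of exactly 30 and 31 days, single events exactly at and
one day inside the relapse-window boundary — where classification rules are
most fragile.

The generator emulates registry *structure* (dates, roles, versions,
same-day groups, death causes), not realistic ICD code frequencies, coding
drift, or family relatedness; passing recovery tests demonstrates the
correctness of the counting and exclusion logic, not robustness to
real-world coding noise.

## Summary-statistics simulation and meta-analysis

Per-cohort effects are generated at the summary level under an additive
log-odds model: for a variant with minor allele frequency *p* and effective
sample size n_eff = n_case·n_ctrl/(n_case+n_ctrl), the standard error is
se = 1/√(2·n_eff·p(1−p)) and the estimate is the planted β plus se-scaled
Gaussian noise. Planted regions place their causal variants within ±50 kb of
the region position; region positions must be ≥ 1 Mb apart so truth regions
stay separable under the 500-kb chaining rule. Causal frequencies default to
0.1–0.5 (common-variant signals); the overall spectrum is uniform on the
configured MAF range. A configurable fraction of cohort-B variants is stored
with ref/alt swapped and the effect re-signed, to exercise harmonization. A
configurable fraction of causal variants is made effectively monomorphic in
cohort B (minor allele count below the QC threshold), emulating variants
absent from one panel: downstream they survive through cohort A alone and
the meta-analysis reports them with `?` in the direction string.
`gen_analysis_suite` derives the single-event, recurrent-event and full
analyses from one shared variant scaffold (positions, alleles, frequencies)
with independent sampling noise, activating each planted region group in the
analyses it belongs to.

The individual-level generator is separate: Hardy–Weinberg genotypes at
uniform MAFs, covariates (birth year, sex, batch, four PC stand-ins), and a
logistic phenotype model. The per-cohort association is a plain
covariate-adjusted logistic regression with Wald tests — a deliberate,
documented simplification of mixed-model association: it ignores relatedness
and extreme case–control imbalance, which the synthetic cohorts do not
exhibit. Monomorphic SNPs and non-converged fits are dropped and counted.

**Meta-analysis.** Fixed-effect inverse-variance weighting with weights
1/se²; z = β/se, p = 2Φ(−|z|). QC drops MAC < 3 or info < 0.3 (union of two
strict exclusions, the standard practice; intersection available). Inclusion
requires MAF > 1% in at least one present cohort, strict. Variant identity
is chromosome+position with swap-aware allele reconciliation; strand-
ambiguous A/T and C/G pairs are kept with a warning rather than
frequency-inferred, since imputed panels are strand-aligned in practice.
Single-cohort rows pass through unchanged and are thresholded identically to
two-cohort rows.

**Regions.** Significance is strict (p < 5×10⁻⁸). Clumping is transitive
chaining — a variant joins the current region while less than 500 kb from
the previous member — rather than lead-anchored ±500 kb windows; chaining is
what produces the large many-SNP regions seen in practice, and it makes the
output a partition invariant to row order. Lead SNP is the lowest-p member,
ties to the lowest position. Two subgroup regions are *common* when they
share a SNP or any members lie < 500 kb apart, computed as connected
components of the overlap graph so that multi-way overlaps merge
consistently; the same rule flags overlap with the full-GWAS region set.
Nearest-gene annotation takes the gene containing the lead, else the
minimal boundary distance, ties alphabetically (logged).

## PheWAS

The scan threshold is 0.05/(n_phenocodes × n_set), where n_set counts unique
SNP identifiers in the set (all genome-wide-significant SNPs assigned to the
set, not just region leads) and n_phenocodes defaults to the table's count
(1,326 in the emulated resource). Comparisons are strict. SNPs missing from
the phenome table are logged, not errors. Per phenotype only the lowest-p
SNP is kept, ties to the lexicographically smallest identifier. Null
phenome tables draw p uniform(0,1) per cell, so the family-wise error of a
scan is controlled at ~0.05 by construction; the calibration test checks
this empirically over repeated scans.

## Co-expression networks

Adjacency is Aᵢⱼ = |pearson(i,j)|⁶ with zero diagonal (the diagonal must be
zeroed for wTO ≤ 1; soft power 6 is the WGCNA default emphasising strong
correlations). Connectivity kᵢ = Σ_{u≠i} Aᵢᵤ, and
wTOᵢⱼ = (Aᵢⱼ + Σ_{k≠i,j} AᵢₖAₖⱼ)/(min(kᵢ,kⱼ)+1−Aᵢⱼ), computed by matrix
multiplication (the zero diagonal removes the self terms) and verified
against a double-loop oracle to 10⁻¹². Per tissue, the ⌈0.15·M⌉ strongest
of the M stored upper-triangle edges survive. Egos rank by *direct* edge
weight to the target only; a target with no surviving edges yields an empty,
flagged ego. The cross-tissue merge weight is Σ_w wTO²_{ij,w} over the
tissues in which the neighbor makes the target's top 25 — implemented
literally with no normalisation by tissue count, as printed; a mean over
tissues would change rankings and is deliberately not substituted. Merging
happens before the top-25 cut, and the shared-neighbor filter (genes in ≥ 2
merged egos) comes last. All top-k boundaries break ties lexicographically
and log them, for determinism. Constant-expression genes are dropped per
tissue before correlation.

**Expression simulation.** Each target anchors a latent factor; module genes
load √c on it (c = module correlation, default 0.9) so their pairwise and
gene–target correlations are c. Consecutive target pairs share a fraction of
module genes (default 0.5): shared genes load on the normalised sum of the
two factors, and the pair's factors are correlated at 2c−1, which is exactly
the correlation needed for a shared gene to correlate at c with *both*
targets (hence the requirement c ≥ 0.5 whenever overlap is requested).
Background genes are independent or share a weak global factor. Modules are
planted identically in every tissue with independent sample draws. The
default module size equals the 25-gene neighborhood cap so the planted
design is recoverable in full; the generator emulates module structure, not
heavy-tailed expression distributions, batch effects or tissue-specific
module membership.

**Enrichment.** Over-representation p is the hypergeometric upper tail
P(X ≥ k) for k annotated study genes, K annotated background genes, study
size n, background N; fold enrichment is (k/n)/(K/N); terms with K = 0 are
skipped; FDR is Benjamini–Hochberg across tested terms with significance at
FDR < 0.05. Annotation is taken as flat term sets (GMT); no ontology-graph
propagation is performed.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) uses: 50 random adjacency
matrices of 10–40 genes for the wTO oracle; 10⁴ random rows for the IVW
oracle; 10 registries of 2,000 participants for phenotyping recovery;
5 two-cohort suites of 4,000 variants with 3+3+3 planted regions for region
labelling; 100 null phenome scans of 1,326 phenocodes × 20 SNPs plus 5
planted-hit scans; one 7-tissue panel of 200 genes × 200 samples for network
recovery; and a 36-cell (N ≤ 200) grid for the enrichment oracle. The test
suite uses the same or smaller sizes per module and larger seed sweeps where
the property is about stability across seeds.

## Known limitations

- The logistic association ignores relatedness, saddlepoint correction and
  case–control imbalance; it is calibrated only for the balanced synthetic
  cohorts generated here.
- No linkage disequilibrium is simulated between variants, so region
  recovery tests the clustering rule, not LD-aware clumping.
- Harmonization trusts chromosome+position identity and strand alignment;
  palindromic variants are flagged, never frequency-resolved.
- Calendar-year window arithmetic clamps 29 February; a day-count window
  (365.25·w) would shift classifications within two days of the boundary.
- The wTO merge weight is un-normalised across tissues, so targets observed
  in more tissues accumulate larger weights by construction.
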