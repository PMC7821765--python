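# Methods

`cardiovar` reimplements, as a tested pipeline, the variant-prioritization
analysis used in targeted-panel studies of ventricular tachycardia (VT):
three clinical arms (VT secondary to coronary heart disease, CHD VT; VT
with dilated cardiomyopathy, DCM VT; idiopathic VT, iVT) plus an
unaffected control group are sequenced over a 96-gene cardiac panel, raw
calls are reduced to a rare-variant analysis set, each variant receives
an in-silico consensus pathogenicity class and an ACMG/AMP verdict, and
the arms are compared by molecular burden, functional gene category and
clinical covariates.

## Filtering cascade

Four ordered stages reduce raw annotated calls to the analysis set;
every stage is accounted in a `FilterTrace` with the invariant
`n_input = n_removed + n_kept` and chained inputs.

1. **Common-variant removal.** A variant is common iff its allele
   frequency *strictly exceeds* the MAF cutoff (default 0.5%) in any
   listed frequency database (ESP6500, 1000 Genomes), or it is a member
   of dbSNP130 when that database is listed. Strict comparison is used
   so that "remove above 0.5%" and "rare means ≤ 0.5%" are both
   satisfied; the disjunctive any-database rule follows the usual
   screening convention. dbSNP130 is modeled as membership, not a
   frequency. ExAC is annotated and used in frequency averaging but is
   not a removal database by default. A variant absent from every
   database cannot exceed the cutoff and is rare: absence is a
   first-class state distinct from frequency 0.
2. **Synonymous removal.** `synonymous_snv` effects are dropped;
   stop-gains, indels and splice-site variants are kept.
3. **Control subtraction.** Variants observed in the unaffected
   comparison group are removed by identifier.
4. **Curation.** A user-supplied, reproducible exclusion list (empty by
   default). Published analyses typically apply a manual curation step
   whose criteria are not mechanizable; externalizing the list keeps
   the cascade deterministic. Stale exclusion ids warn rather than
   fail.

The first three stages commute (each is a pointwise predicate), which
the suite verifies; raising the cutoff can only grow the kept set.

## Consensus pathogenicity class

Ten dbNSFP-style predictors (SIFT, PolyPhen2 HDIV/HVAR, LRT,
MutationTaster, MutationAssessor, FATHMM, RadialSVM, LR, MetaSVM) each
call a variant damaging or tolerated. The ordinal class is a band rule
on the damaging count *d*: class I (highest pathogenic potential)
*d* ≥ 7; class II 4–6; class III 1–3; class IV (benign) 0. Missing
calls count as not-damaging — the band is keyed to the absolute
damaging count — and `n_available` is surfaced so users can gate on
predictor coverage. The classifier is monotone: flipping any single
call to damaging never lowers severity.

## ACMG/AMP verdicts

Evidence codes (PVS1; PS1–4; PM1–6; PP1–5; BA1; BS1–4; BP1–6) are
*inputs* — the package does not auto-assign evidence from annotations.
`acmg_combine` implements the 2015 combining rules for
pathogenic / likely pathogenic / benign / likely benign, returning VUS
when no rule fires or when rules fire on both sides (contradictory
evidence). When an ingested ClinVar-style assertion and the local
combination disagree, the ingested assertion is the reported tier by
default (it is the curated final verdict); both remain available.

## Burden and category tables

Burden is counted over *carried instances* (a variant carried by two
patients counts twice). For each arm and cumulative class threshold
(I, I/II, I/II/III): the number and percentage of patients carrying at
least one qualifying variant; the cumulative qualifying instances; the
share of the arm's total carried instances; and instances per positive
patient. Zygosity is stored but burden counts carriers, the standard
descriptive choice for small arms.

Functional-category tables map each gene to one of seven categories
(cell membrane, cytoskeleton, sarcomere, metabolism, intercalated
disc, ion flux, nucleus; the packaged 96-gene map is a curated config
file, replaceable by the user). Pooled scope counts unique variants;
per-arm scope counts carried instances.

All printed percentages are half-up rounded to one decimal (two for
instances-per-positive) so that every table cell recomputes exactly
from its integer numerator and denominator; a zero denominator yields
an explicit undefined value, never 0.

## Statistics

Continuous covariates are screened with Shapiro–Wilk (`p > 0.05` →
treated as normal) and compared with the tie-corrected Kruskal–Wallis
test; the overall p uses the chi-square approximation by default, with
an exact permutation enumeration available for tiny samples. Pairwise
post-hocs are Dunn's rank comparisons on the pooled ranks with the
pooled tie-corrected variance and Bonferroni adjustment capped at 1 —
the default pairwise output of mainstream clinical-statistics
software. Carrier-count comparisons use the Pearson chi-square test
(uncorrected), switching to the two-sided Fisher exact test for 2×2
tables with any expected count below 5. Two-sided Fisher p-values are
defined by point-probability summation (outcomes no more probable than
the observed table), documented here because two-sided conventions
differ. Displayed p-values are formatted to three decimals ("0.000"
below 0.0005); full precision is kept internally.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without
protected patient data. It simulates the latent pathogenicity class
*first* and the predictor calls *second* — the inverse of the analysis
direction — so ground truth exists for recovery tests, and it records
everything in a ledger (per-variant flags and latent class; per-carriage
rows).

Default conditions emulate the targeted-panel VT study structure:

* arms of 23 (CHD VT), 32 (DCM VT), 37 (iVT) patients and 60 controls;
* 2,403 raw calls over the 96-gene panel, split by two knobs
  (`frac_common = 0.63`, `frac_synonymous = 0.53` of the remainder)
  chosen once so that, with a 19% control-overlap rate, the cascade
  lands near 340 analysis variants;
* class mix over variants (0.156, 0.228, 0.508, 0.108), the class
  composition of a ~307-variant analysis set;
* per-class target mean reference frequencies (2.79·10⁻⁴, 2.67·10⁻³,
  3.72·10⁻³, 1.92·10⁻²) — severer classes are rarer. Frequencies are
  drawn lognormal (σ = 1) around the per-class mean after an
  absent-from-all-databases probability (0.70, 0.40, 0.30, 0.05);
  removal-database draws are capped at the 0.5% cutoff with the
  balance assigned to ExAC, so rare variants survive filtering while
  the class means stay on target;
* predictor calls: damaging count uniform within the class band, with
  an optional independent missing-call rate (default 0);
* carriage: per patient and class, Poisson counts with per-arm rates
  equal to class-specific instance totals divided by arm size
  (e.g. CHD VT class I rate 13/23), sampling distinct variants from the
  class pool. The fraction of patients positive for a class is then
  `1 − exp(−rate)`;
* clinical covariates: age, BMI, QRS and QT are normal per arm
  (mean ± SD parameterization); LVEF, LA, LV EDD and LV ESD are
  logistic with location = the arm median and scale = IQR/(2 ln 3)
  (median/IQR parameterization with mild skew-free tails), all clipped
  to physiologic bounds; NYHA, sex and familial status are categorical
  with per-arm probabilities. Controls carry no cardiology work-up
  (those fields are absent).

What the generator does **not** emulate: linkage/haplotype structure,
per-gene variant-density differences (uniform by default; a per-gene
weight vector is a config knob), relatedness, sequencing/calling error,
or correlation between predictor tools beyond the shared latent class.
Passing recovery tests therefore demonstrates that the pipeline's
counting and classification are correct under the assumed generative
structure, not that the biological assumptions hold in real data.

## Reference reconstructions

`cardiovar.reference` rebuilds minimal cohorts and variant sets that
realize the published integer summaries of the emulated study (tier
counts over 307 variants; per-arm burden integers; category-by-class
cells; the control group's 2,150 → 1,675 → 68 → 58 filtering
composition). These are used by the acceptance checks to verify that
the pipeline's arithmetic reproduces every recomputable printed
percentage. One published cell (sarcomere, class II) recomputes to
28.3% from its own integers (34 of 120); the reconstruction asserts the
recomputed value.

## Numerical choices and degenerate inputs

* Rounding is decimal half-up everywhere, computed over exact
  rationals for integer ratios to avoid binary-float artifacts.
* Empty classes and zero denominators report `None`/undefined, not 0.
* Kruskal–Wallis with all observations tied, constant samples in the
  normality gate, groups under 2 observations, and contingency tables
  with a zero margin raise typed errors rather than returning NaN.
* Indels are left-normalized on ingest (shared suffix then prefix
  trimmed, VCF anchor retained); coordinates are 1-based VCF
  convention.
* VCF float INFO fields are re-parsed from the raw text because htslib
  returns single-precision values, which would break exact write/read
  round-trips.

## Problem sizes used by the test suite

The suite runs the generator at 300–10,000-variant pool sizes:
10,000 for the frequency-spectrum ordering check, 600 for structural
checks, and 200 replicates of the full study-sized configuration
(2,403 calls, 92 + 60 subjects) for carrier-rate recovery within three
Monte-Carlo standard errors. Exhaustive oracles cover all 1,024
predictor-call patterns, all ACMG code subsets up to size 4, Fisher
2×2 tables with margins ≤ 12, and a 10⁴-replicate exchangeable null
for Kruskal–Wallis type-I calibration (5% ± 1%).

## Known limitations

* Evidence-code assignment, predictor scoring and annotation are out
  of scope: the package consumes them as inputs.
* The curation stage reproduces a published analysis only if the same
  exclusion list is supplied.
* Per-arm class-share figures with unstated denominators in published
  summaries are not reproduced.
* The generator's carriage model is independent across classes and
  patients; real cohorts show gene- and family-level clustering.
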