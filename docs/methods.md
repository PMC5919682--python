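# Methods

## Problem and scope

The package prioritizes germline variants from targeted panel sequencing of
cancer-predisposition genes in prostate-cancer (PrCa) index cases selected
for early onset and/or familial clustering. It consumes variant calls (VCF
v4.2, GRCh37, 1-based) with a per-variant annotation table, per-patient
family-history metadata, and control carrier counts. Read alignment,
variant calling, Sanger validation, wet-lab genotyping and the external
predictor tools themselves are upstream: their outputs are inputs here and
are never recomputed.

## Filter cascade

Five conjunctive rules, each with literal boundary semantics:

| rule | keep condition | boundary |
|---|---|---|
| in-house | cohort fraction ≤ 0.10 | strict removal above 10% |
| quality | depth > 20 and VAF ∈ [0.30, 0.70] | depth strict, VAF inclusive |
| rarity | max available MAF ≤ 0.001 | inclusive |
| consequence | not synonymous; intronic only if ≤ 12 bp from a boundary | inclusive |
| clinical | no database asserts benign / likely benign | — |

Decisions that were genuinely open: the MAF rule takes the **maximum** over
available reference populations (a variant common anywhere is not rare);
missing annotations (no MAF, no assertion, no in-house fraction) never
remove a variant, matching the retention of database-absent variants for
review; caller merging is a **union** with per-caller provenance (a
majority-of-three mode is available but off by default, since requiring
concordance trades sensitivity for specificity and the upstream import used
all three callers jointly). Multi-allelic records are decomposed to
biallelic records before filtering, as every rule is per-alt-allele.
Because the rules are conjunctive the kept set is invariant under filter
order; the audit table reports the first failed rule in a fixed canonical
order purely for readability.

## Predictor consensus

Missense variants qualify as "potentially pathogenic" when at least 12 of
the 15 predictors call them pathogenic and at least 3 of those are
conservation tools. The denominator stays 15 even when tools are missing —
a missing output counts against qualification — because the quorum is
defined against the full panel; an of-available-tools mode exists behind a
config flag, off by default. Where only percentile-normalized rankscores
are available, a call is pathogenic at rankscore ≥ 0.5 (per-tool cutoffs
configurable); the packaged fixtures store rankscores chosen to encode the
categorical patterns, since the downstream logic keys on the consensus
outcome, not raw scores. Splice-site calls qualify at ≥3 of 4 splice
predictors, or with a pathogenic/likely-pathogenic clinical assertion at
weaker predictor support. In-frame indels stay unclassified unless a
clinical database asserts them pathogenic (the incidental-finding route).

## ACMG-AMP engine

The engine re-implements the 2015 joint-consensus combining rules rather
than wrapping an external interpreter. Evidence codes are inputs, with two
exceptions: PS4 can be derived from carrier counts (two-sided Fisher p <
α with case enrichment), and any code can be added through the manual
overlay (idempotent union, provenance recorded). Conflict handling: the
verdict is VUS only when a complete pathogenic-side rule *and* a complete
benign-side rule fire simultaneously; a lone benign-supporting code (e.g.
BP1 beside PS4+PM1+PM2+PP3) does not veto a pathogenic-side combination —
this is required to reproduce published missense classifications and
matches common interpreter behaviour. PP5/BP6 (reputable source) are
accepted for fidelity to published evidence sets although later guidance
deprecates them. Evidence marked "not determined" stays unclassified
rather than defaulting to VUS.

## Case-control testing

Two-sided Fisher exact p-values use the conventional minimum-likelihood
summation over the conditional hypergeometric support (the test suite
verifies exact agreement with a brute-force enumeration for every 2×2
table with N ≤ 60). Carrier-level tables (individuals) are the default
against genotyped panels; allele-level tables serve reference populations
where only allele counts are public. No multiple-testing correction is
applied, matching how such screens report unadjusted values. The
clinicopathological association test collapses each feature level to a 2×2
against carrier status; being an exact test on discrete tables it is
conservative — its null rejection rate sits at or below α, never above,
which is what the calibration check asserts.

## Eligibility criteria

A-group (familial/hereditary PrCa): A1 = ≥3 first-degree relatives with
PrCa at any age; A2 = ≥2 first-degree relatives with PrCa, affected-set
average age at diagnosis ≤65 with at least one affected diagnosed before
61; A3 = index diagnosed before 61 with ≥2 first/second-degree PrCa
relatives and the three youngest affected averaging ≤65. B-group: B1 =
index diagnosed before 56 with ≥3 first/second-degree relatives with
cancer and the three youngest diagnoses averaging ≤55; B2 = a second
primary besides PrCa; B3 = relatives with rare cancers (default list:
bilateral breast, male breast, brain), early-onset non-PrCa cancer
(default: diagnosed at ≤50), or clustering (≥2 relatives) of breast,
colon or gastric cancers. Interpretation choices: "cases"/"diagnoses" in
the averaging clauses include the index (this reproduces the published
per-patient flags); relative counts exclude the index (A1 has a config
switch); B3 ignores PrCa in relatives since the clause concerns *other*
cancer types; "early-onset" for the index means diagnosis at or before 55,
and B1's "before 56" is treated as the same threshold. Missing ages make a
clause evaluate false with a logged warning, never true.

## Carrier accounting

A patient is a carrier iff ≥1 variant in a qualifying tier survives two
exclusions: missense variants in a mismatch-repair gene whose matched
tumor immunohistochemistry shows retained expression, and variants flagged
incidental. Gene attribution picks one gene per carrier: truncating
variants outrank missense; remaining ties break by smaller case-control
p-value, then alphabetically. Summary fractions use the published
denominators (cohort, A-group, B-group, early-onset set, carrier set) and
round to one decimal, half away from zero — the convention that matches
every published fraction. Per-gene counts are reported both attributed and
raw (all carriers of a surviving variant in the gene).

## Synthetic data

The fixture cohort packages the 18 published panel variants (with their
genomic positions, HGVS strings, population frequencies, clinical
assertions, predictor profiles and per-carrier eligibility flags) planted
in the 19 published carrier identifiers. REF/ALT alleles for the indels
are placeholders (the public record prints cDNA changes, not VCF alleles);
downstream logic keys on consequence class, so this is immaterial. The 102
non-carrier patients are generated deterministically from four
family-history templates so the cohort marginals are exact: 45 A-group, 86
B-group, 10 dual, 64 early-onset. Per-patient family structures of
non-carriers are synthetic reconstructions satisfying those marginals,
not per-patient truth — tests against them validate the accounting logic,
not the unpublished individual histories. Which 7 of the 18 carriers are
early-onset is likewise not public at patient level; the five B1 carriers
are forced early-onset by their published flags, and two further carriers
(both with B2-only flags, which leave the index age free) complete the
published count of 7.

The cohort simulator plants per-gene carriers as clean truncating template
variants (so recovery tests exercise the whole pipeline, not predictor
noise) and draws eligibility flags from per-criterion motifs; composing
motifs can co-trigger correlated criteria, so requested prevalences are
approximate marginal targets, while seed determinism is exact. Default
prevalences approximate the study composition (~37% A, ~70% B). The
predictor-matrix simulator draws rankscores uniformly on the two sides of
the 0.5 cutoff and records every noise flip, so recovery accuracy can be
recomputed by replaying the flip log. Neither simulator models sequencing
reads, relatedness between patients, or pedigree genotypes of relatives.

## Problem sizes and numerical choices

Exhaustive verifications are sized to run on one CPU in minutes: all 2^15
predictor profiles; all ACMG evidence sets of size ≤6 from the 28 codes
(~5×10^5); every 2×2 table with N ≤ 60 against the enumeration oracle;
10^4 random profiles for consensus monotonicity; 1000 null replicates for
type-I calibration; n = 2000 for carrier-frequency recovery (3 binomial
SEs ≈ ±1.5 points at 5%). Oracle comparisons use relative tolerance 1e-9;
the two-sided Fisher summation includes ties up to a 1e-9 relative slack,
the standard guard against floating-point equality on hypergeometric
point probabilities. All randomness flows through numpy Generator seeds;
reruns are byte-identical.

## Known limitations

The per-variant p-values of the original control screen for two recurrent
missense variants derive from supplementary genotype frequencies that are
not part of the packaged fixtures; carrier-mode tables built from
main-text counts give smaller p-values, so those two printed values are
not reproduced here (the allele-mode interface accepts the supplementary
counts if obtained). The engine does not re-derive automatic ACMG codes
from raw annotations — they are inputs, as in the original analysis. IHC
and incidental-finding exclusions depend on externally supplied flags.
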