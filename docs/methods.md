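# Methods

## Scope and data model

The package analyses one cohort at a time, joined from three tables:
per-patient clinical/cytogenetic attributes, somatic variant calls with QC
and oncogenicity annotations, and allele-specific copy-number segments
(GRCh38, autosomes only; sex chromosomes are rejected at parse time).
Coordinates are 1-based, fully closed intervals. Variant allele fractions
are stored as fractions in [0, 1]; TSV input may carry percent under a
`vaf_pct` column, converted on read. Cytogenetic findings arrive with
precomputed `mds_defining` / `eln_adverse` flags — full ISCN parsing is
out of scope. FLT3-ITD, FLT3-TKD, KMT2A-PTD and fusions are ordinary
variant rows with dedicated classes, because they are detected outside
exome SNV calling (fragment analysis / PCR) but must be reasoned over
jointly with SNVs and indels.

## Variant filtering

Rules and boundary semantics, applied to every variant with the complete
violation list recorded per row:

| rule | condition | boundary |
|---|---|---|
| impact | snpEff-style impact MODERATE or HIGH | — |
| min_reads | supporting reads ≥ 8 | inclusive |
| min_vaf (unpaired only) | VAF > 0.05 | strict |
| max_popaf (unpaired only) | population AF ≤ 0.001 | inclusive |
| cadd_extended | CADD > 15 for extended-list genes | strict |
| benign_excluded | curation class not benign / likely benign | — |

A missing CADD on an extended-list gene fails the rule (conservative) and
is logged; a missing population AF on an *unpaired* variant is an error
because the rule cannot be evaluated, while on a paired variant the rule
is simply inapplicable. Special-event classes bypass the impact and CADD
rules (they are not impact-annotated SNVs) but keep the oncogenicity gate.
Clinical reasoning downstream uses only oncogenic / likely-oncogenic
(O/LO) variants; the classifiers additionally re-filter defensively so a
stray VUS can never trigger a category.

## Classification engines

Precedence orders are explicit and tested:

- WHO17: MRC criteria (history, MDS-defining cytogenetics, MLD) strictly
  precede the provisional RUNX1m entity.
- WHO22: NUP98 rearrangement > AML-MR (MR-gene mutation, MDS-defining
  cytogenetics, or MDS/MDS-MPN history) > AML-DD.
- ICC22: NUP98 > TP53 (O/LO at VAF ≥ 0.10) > AML-MR (MR genes + RUNX1, or
  MDS-defining cytogenetics) > AML-NOS. The published ICC hierarchy places
  recurrent abnormalities above TP53, hence NUP98 > TP53 here; the two
  never compete in this cohort. The TP53 VAF cutoff of 0.10 follows the
  ICC definition. Ontogeny is appended to the criteria list as a qualifier
  but never changes the ICC22 category.

MDS/MPN history is treated identically to MDS history wherever the systems
accept "MDS or MDS/MPN". Unchanged-patient counts in flow tables use the
bucket correspondence MRC↔MR and NOS↔DD/NOS; the disparity report applies
the same DD↔NOS equivalence and labels each discordant patient with one of
three causes (RUNX1-only, ontogeny-only, TP53 reassignment).

Four asymmetries are enforced as property tests over randomized patients:
MLD never changes a 2022 category; toggling MDS history never changes
ICC22; adding a lone RUNX1 mutation never changes WHO22; a NUP98 fusion
forces the NUP98 entity under both 2022 systems.

## ELN risk

Only the intermediate and adverse tiers are reachable: cohort eligibility
excludes favorable recurrent abnormalities, and NPM1/bZIP-CEBPA logic is
deliberately out of scope. ELN2017 flags RUNX1/ASXL1/TP53 and FLT3-ITD
with high allelic ratio (ratio defaults to unknown → not high, with a
warning, since per-patient ratios are rarely available); ELN2022 flags
TP53 and all MR genes including RUNX1 and drops the allelic-ratio
distinction. On this genetic space ELN2017-adverse implies ELN2022-adverse,
which the suite asserts.

## CN-LOH integration

Event classes derive from allele-specific copy numbers: CN-LOH iff
(major, minor) = (2, 0); gain if total > 2; loss if total < 2. Gene–segment
pairing requires the full gene locus inside the segment (segments are
megabase-scale, so partial-overlap subtleties are immaterial and the rule
is deterministic). Zygosity interpretation uses strict thresholds — VAF >
0.70 homozygous-compatible, VAF < 0.50 mutation-after-CN-LOH — and labels
the band between as ambiguous rather than forcing it, since the source
phrasing is "generally". Events without a VAF (KMT2A-PTD) are ambiguous.
Patient-level counts ignore segment multiplicity. The packaged segment
table stores one published row whose start exceeded its end with the two
positions sorted, and encodes the footnoted homozygous RUNX1 copy loss as
a (0, 0) LOSS segment over the RUNX1 locus (coordinates are a synthetic
stand-in, flagged in the data file). Gene loci come from a small packaged
GRCh38 table, approximate to the kilobase; users may extend it.

## Statistics

Pairwise co-occurrence uses the two-sided Fisher exact test on the O/LO
incidence matrix (genes mutated in ≥ `min_mutated` patients, default 4;
FLT3-ITD/TKD collapse to one FLT3 column by default). P-values are
unadjusted by design, matching the analysis the package models; a
Benjamini–Hochberg option exists for users. The sample odds ratio is
reported with infinity on a zero denominator; degenerate margins yield
p = 1. The implementation is checked against an exhaustive hypergeometric
enumeration oracle on tables up to n = 30.

Group comparisons: Wilcoxon rank-sum for two groups (exact method when the
pooled n ≤ 50 and there are no ties, mid-rank normal approximation
otherwise — the switch keeps small-cohort results reproducible),
Kruskal–Wallis for three or more, Fisher for 2×2 categorical tables. The
rank test's type-I error is verified at ~0.05 over 1000 seeded replicates
and its power at > 0.9 for a 2-SD shift at n = 20/20.

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank test (lifelines). Burden strata: > 3 O/LO mutations, > 4 variants
of any class, or > 1 mutation among MR genes plus RUNX1; each rule
partitions the cohort. Without censoring the estimator equals 1 − ECDF of
the event times, which the suite asserts exactly.

## Synthetic cohort

The fixture encodes the modeled study's printed aggregates as *structure*,
patient by patient, with no randomness: stratum sizes (27/26/16), the
criteria mix (23 MLD, 11 histories all with MLD, 12 MLD-sole, 4
cytogenetics-only), the RUNX1 carrier decomposition (16 + 10, with the
10 split 6 history / 2 MLD / 2 cytogenetics and one extra single-VUS
carrier), the MR-mutation aggregates (40 patients, 18 multi-MR; 46 and 29
with RUNX1), actionable lesions (15 ITD, 7 TKD, 20 IDH1/2, 5 overlapping,
union 37), three NUP98 rearrangements, one TP53 case at VAF 0.40, and
exactly one patient with no O/LO mutation. Construction self-checks every
constraint and raises naming the violated one. Concrete gene choices
inside strata follow the strongest reported pairs (BCOR with RUNX1, ASXL1
with EZH2) but are otherwise arbitrary; the aggregate counts depend only
on set membership. Ages, sex and blood counts approximate the published
medians per stratum and are range-checked only.

What the fixture does **not** emulate: real per-patient follow-up (survival
times are seeded exponentials with hazard increasing in O/LO burden, fixed
internal seed, so survival runs are deterministic smoke tests, not
reproductions of published curves), clonal VAF structure beyond the CN-LOH
rules, the full 339-variant oncoplot, and the real co-occurrence p-values
— the true mutation matrix is not public, so tests assert mechanics
(enumeration oracles, planted structure at scale) rather than published
significance levels. Passing tests therefore demonstrate the *rules* are
implemented faithfully on a cohort with the published structure, not that
any real patient-level dataset is reproduced.

`random_cohort` draws arbitrary-size cohorts from per-lesion prevalences
(defaults near the fixture's marginal rates) with a mandatory seed, for
sampling-error and scale tests.

## Known limitations

- Eligibility gating is minimal: therapy-related AML raises an error, and
  favorable/adverse cytogenetic logic beyond the boolean flags is not
  modeled.
- The 40-gene and 148-gene lists are editable defaults covering every gene
  the modeled analysis names; site panels will differ and can be swapped
  in as plain text files.
- ELN adverse totals on the fixture (35 and 47 of 69) are structural
  consequences of the fixture's gene assignments, not calibrated targets.
- Problem sizes in the statistical property suite (n = 30 enumeration
  bound, 1000-replicate calibration, 100-replicate log-rank power at
  n = 100/100) were chosen to make the whole suite run in seconds on one
  core while keeping Monte-Carlo error well inside the asserted bands.
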