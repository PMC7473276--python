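# Methods

## The derivation being studied

A person's recorded Indigenous status in administrative data is three-valued
(Indigenous / non-Indigenous / missing) and varies legitimately between
records: identification is by self-report and depends on context.  The
derived Indigenous Status Flag (ISF) collapses a person's records to one
status in two steps with a shared threshold rule — within each of five
datasets (midwives' notifications MNS, birth registrations, hospital
morbidity, emergency department, death registrations), then across the
per-dataset statuses:

* 0 non-missing inputs → missing;
* 1 input → as recorded;
* 2 inputs → Indigenous iff at least 1 is Indigenous;
* ≥ 3 inputs → Indigenous iff at least 2 are Indigenous.

Missing values never count toward a threshold.  Two consequences shape
everything downstream and are verified exhaustively in the tests:
(i) *monotonicity* — flipping one record toward Indigenous can never demote
a derived status; (ii) *single-misclassification robustness* — one stray
record among three or more consistent ones never flips the dataset status.
A deliberate corollary: a child identified on exactly one dataset out of
three or more is **not** flagged, which is the mechanism behind the
"identified on the midwives' record but not by the flag" group discussed
below.

Only a child's dedicated child-status field on MNS/birth-registration
records feeds the child's own ISF (the field exists on registrations from
2007 and on the MNS from 2012; before that the child's perinatal records
contribute nothing to the child's flag).  Parental status fields on a
child's records feed no one's ISF; a parent's flag is derived solely from
records on which the parent is the subject.  A person whose flag is missing
is treated as not identified.

## The three ascertainment methods

* **A**: child's own flag is Indigenous.
* **B**: the flag of the child, mother, father, or any of four linked
  grandparents is Indigenous.  A ⊆ B structurally.  Only these six named
  relatives are consulted.
* **C**: per perinatal dataset — if the child-status field is non-missing,
  the dataset contributes "child recorded Indigenous"; if missing, it falls
  back to the maternal status (both datasets) or paternal status
  (registration only).  Contributions are OR-ed across the two datasets.  A
  non-missing non-Indigenous child status *blocks* the parental fallback for
  that dataset: this strict reading is what allows children recorded
  Indigenous on the midwives' record to stay outside Method C's registration
  pathway, matching the observed post-2012 step change.  The OR-across-
  datasets reading also means a child with both child-status fields missing
  is identified if either dataset's parental fields say Indigenous.

Children enter the analysis only if born in the study window (2000–2013)
and linked to a mother; exclusions are counted and logged.

## The synthetic population

No real linked extract can ship with the package, so a seeded generator
produces populations whose statistical structure carries the features the
comparison exploits.  Per family: one study child, a mother (always
generated; link configurable), a father linked with probability 0.93, the
maternal grandparent pair linked with probability 0.80 and the paternal pair
with 0.62 unconditionally (sampled at 0.62/0.93 given a linked father, since
paternal grandparents can only be linked through him) — the configured
completeness rates of the emulated study setting.  Ten percent of families
carry Indigenous heritage; their parental ground-truth composition is
both-parents 0.40, mother-only 0.26, father-only 0.22, neither 0.12, with
grandparents Indigenous with probability 0.92 given their child (the parent)
is.  "Truth" here means *would identify given full opportunity*; it exists
only so recovery tests have a referent and is never a claim about the
validity of the real methods.

Recording is per-field Bernoulli conditioned on truth.  False
identification is not modelled (the phenomenon of interest is
under-identification), so a non-Indigenous subject is always recorded
non-Indigenous, and every field is independently blanked to missing with
probability 0.04.  The propensity for a truly Indigenous subject is a
product of:

* a per-dataset base (children: MNS 0.92, registration 0.78, hospital 0.78,
  emergency 0.72, death 0.92; adults: 0.90 own records, 0.95 maternal and
  0.90 paternal perinatal fields);
* area modifiers by disadvantage quintile (1.00 down to 0.72 for the least
  disadvantaged) and remoteness (1.00 very remote down to 0.84 major city),
  applied to **every** family member's fields — under-identification is an
  area-correlated, family-level phenomenon;
* a parental-composition modifier on the child's own fields (both 1.00,
  mother-only 0.90, father-only 0.42, neither 0.60) — children whose
  heritage is through the father alone are the classically under-ascertained
  group;
* a log-normal family frailty (sd 0.40, median 1) shared by the whole
  family, which creates the mid-propensity band responsible for
  within-person inconsistency between records;
* for the MNS child field only, the combined context modifier is damped by
  an exponent of 0.35: the status question there is put to the mother
  directly at the birth, so this field's completeness depends far less on
  context than other collections.  This is what makes the post-2012
  "identified on the midwives' field but nowhere else" group non-empty, as
  observed in practice.

Family geography is drawn from an urban-skewed profile for father-only and
neither-composition families and a disadvantage-skewed profile otherwise;
geography is missing with probability 0.05.  Record counts are MNS exactly
one, registration Bernoulli 0.90, child morbidity Poisson (1.1 hospital,
1.3 emergency), adult morbidity Poisson 1.3 per dataset, death records rare
— placeholders, since no per-dataset counts are published for the emulated
setting.  Birth years are drawn with a mild linear weight (+2 % per year) so
identified counts trend upward.

Perinatal outcomes depend on an area-disadvantage score $d \in [0,1]$
(0.6 × quintile scale + 0.4 × remoteness scale; 0.5 if missing):
gestational age ~ Normal(39.2 − 1.2 d, 1.7 + 0.7 d) clipped to [20, 44]
weeks; birthweight ~ Normal(3350 + 115·male − 240 d + 165·(GA − 40), 420) g;
P(Apgar ≥ 9 at 1 min) = 0.64 − 0.11 d; stillbirth probability
0.006 + 0.008 d.  Because ascertainment propensity and outcomes share the
same disadvantage score, differentially ascertained subgroups differ in
measured outcomes — the core confounding the comparison is designed to
expose.

What the generator does **not** emulate: probabilistic-linkage errors
(links are taken as given), sibling structure and multiple births, real
geographic boundaries (area variables are categorical attributes),
interstate births, false-positive identification, and any drift of
propensities over calendar time other than the era rules.  Passing tests
therefore demonstrate correctness of the algorithms and the direction of
selection effects under this mechanism, not the real-world magnitudes of
any cohort difference.

## Perinatal classification

Preterm categories use half-open intervals — extremely < 28, very [28, 32),
moderate-to-late [32, 37), term ≥ 37 completed weeks — resolving the
boundary overlap in commonly printed labels ("28–32", "32–37", "> 37") in
favour of the WHO convention that 37 completed weeks is term.  Low birth
weight is strictly < 2,500 g.  SGA is birthweight strictly below the 10th
percentile for sex × completed gestational week; the national reference
distribution is not redistributable, so the default reference is empirical
(self-referenced from the supplied records, cells under 50 births pooled
with adjacent earlier weeks, cut-offs made non-decreasing in week), and an
external cut-off table (`sex, week, cutoff_g`) can be supplied instead.
Self-referencing calibrates overall SGA prevalence to ≈ 10 % by
construction, which is itself a test.  Apgar ≥ 9 at 1 minute is taken from
the midwives' record.  LBW/SGA/Apgar are tabulated among live births;
stillbirths remain in all cohort counts.  Tables report missing as its own
stratum level, so either "of live born" or "of non-missing" denominators can
be recovered.

## Statistical layer

* Binomial CIs are Clopper–Pearson exact (the plain reading of "a binomial
  distribution"), via statsmodels' beta method; Wilson is available as an
  option.  Exactness costs conservatism: empirical coverage is ≥ 95 %, not
  = 95 %.
* Temporal trends are OLS of annual identified count on calendar year
  (single years, not two-year bands), slope CI from the t distribution;
  outlier sensitivity removes explicitly named years (e.g. 2012–2013 for
  Method C) rather than using automated detection.
* Rate ratios come from a Poisson GLM of annual identified counts with
  categorical year (reference 2000) and log total births as offset; Wald
  CIs; the saturated model reduces to the closed-form proportion ratio,
  which the tests check to 1e-9.  A zero count in a year legitimately gives
  a zero rate ratio.
* The step-change decomposition re-evaluates Method C with the MNS
  child-status field masked; children identified only with the field
  unmasked, and not in Method B, are attributed to the field's
  introduction.  With era-aware data this attribution is structurally zero
  before 2012.

## Numerical and design notes

* All tables round-trip through CSV with missing encoded as empty fields;
  string identifiers are read back as strings.  Fixed (config, seed) runs
  are byte-reproducible, recorded in a manifest of SHA-256 digests.
* Problem sizes used by the test suite: the generator's statistical checks
  run at 10,000 families (linkage rates within 3 SE, SGA calibration);
  structural set properties at 100 populations of 1,000 families; machinery
  calibrations at 10,000 draws per binomial cell, 500 trend replicates and
  60 rate-ratio replicates — sizes at which the checked properties are
  well-resolved while the whole suite stays fast.
* The `p_any_grandparent_linked` config value (0.91) is the implied
  any-grandparent rate and is carried for documentation/validation; the
  generator samples the pair rates.
* Degenerate inputs: empty populations yield empty tables; an empty records
  table yields all-missing flags; trend fits require ≥ 3 years; rate-ratio
  fits require positive totals ≥ counts; SGA classification of an uncovered
  (sex, week) cell is an error naming the cell.

## Known limitations

The generator's propensity model is the simplest mechanism that reproduces
the qualitative ascertainment pattern (smallest cohort from the child-only
flag; additional children from relative- and perinatal-based methods being
more urban, less disadvantaged, with better perinatal outcomes; a positive
post-2012 step attributable to the MNS child field).  Magnitudes of cohort
differences are not calibrated to any published table and should not be
read as estimates.  Method B consults only the six named relatives;
sibling-triggered extraction criteria of the underlying data request are
out of scope, as is the linkage process itself.
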