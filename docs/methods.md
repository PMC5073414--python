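# Methods

## Linkage procedure

A source extract (immigration landings or death registrations) is linked to
a population registry in stages; a record that links in one stage leaves the
pipeline, the remainder flow onward.

1. **Standardization.** Names are uppercased, stripped of diacritics and
   punctuation; surnames additionally receive a NYSIIS phonetic code;
   postal codes are mapped to a coarse city code through a longest-prefix
   conversion table.  Matching only ever sees standardized fields.
2. **Blocking.** Each pass partitions both files into mutually exclusive,
   exhaustive blocks keyed by standardized fields (sex first, then NYSIIS
   code or birth year), and only within-block pairs are compared.  Records
   missing a key field either form their own block (`own_block`, preserving
   the partition property) or are compared against every value of that
   field (`broadcast`, used so that missing-sex records are not structurally
   unlinkable under sex stratification).
3. **Deterministic cascade.** A pass links a source record iff *exactly
   one* registry record in its block agrees on every match field; missing
   counts as disagreement and ambiguous records (two or more agreeing
   candidates) are deliberately deferred rather than tie-broken — with very
   common surnames a tie-break would manufacture false links.  The default
   cascade runs strict-to-lenient: (1) exact surname + first given name +
   full birth date + sex; (2) NYSIIS surname + given initial + birth date +
   sex; (3) exact surname + birth date without sex (rescues missing-sex
   records); for death files also (4) given name + transposition-tolerant
   birth date + death date within 30 days of the registry last-contact
   date.  Production systems do not publish their pass parameters; this
   cascade is declared, fully overridable configuration.
4. **Probabilistic passes.** Surviving records are scored with
   Fellegi–Sunter log2-odds weights (see README for the formulas).  A
   field missing on either side contributes zero — no evidence — rather
   than a disagreement penalty: death registrations legally require only
   sex and dates, and penalizing absence would re-create the very bias the
   evaluation stage is supposed to measure.  Per source record the
   highest-weight candidate is linked outright when it is definite
   (`W >= t_upper`, default 8 bits) *and* beats the runner-up by at least a
   margin (default 1 bit); possible matches (`W >= t_lower`, default 4
   bits) and close-definite ones join the review queue; the rest flow on.
5. **Review.** The grey zone is adjudicated by a deterministic stand-in for
   clerical review: accept iff weight ≥ a floor (default `t_lower`), the
   two files' city codes agree (UNKNOWN never counts as agreement; the
   requirement can be waived), and no competitor sits within the configured
   gap.
6. **Resolution.** For files declared unique-per-person, one-to-one
   enforcement keeps the best claimant per registry person (deterministic >
   probabilistic > review, then weight, then earlier pass, then stable
   order).  The demo source kinds are instead deduplicated by their
   retention rules: death files keep the best-quality link, ties broken by
   the death date closest to the registry last-contact date; immigration
   files keep the earliest landing date.  Running strict one-to-one before
   dedup would turn genuine within-source duplicates into unlinked records
   instead of deduplicated ones, so the pipeline applies one-to-one only
   when `unique_per_person` is set and otherwise leaves same-key claims to
   the dedup rule.  Every linked registry person then receives an opaque
   surrogate link key (sequential per run; salted-hash and stable across
   runs when a salt is supplied — the package holds no real identifiers, so
   cryptographic derivation from health numbers is out of scope).
7. **Evaluation.** Linkage rates overall / per stratum / per event-year
   band, the deterministic–probabilistic–unlinked method mix, pooled
   two-proportion standardized differences between linked and unlinked
   composition (continuous overload uses averaged variances), and — on
   synthetic data — precision, recall and F1 against ground truth.  No
   p-values: at registry scale every difference is "significant"; only
   effect sizes are reported.  Rates print at 1 decimal, standardized
   differences at 2, both half-up.

## NYSIIS

The original 1970 rule set is implemented (initial replacements MAC→MCC,
KN→NN, K→C, PH/PF→FF, SCH→SSS; terminal EE/IE→Y and DT/RT/RD/NT/ND→D;
iterative interior transforms with doubled letters collapsed; terminal
S / AY / A cleanup).  The code head is the first letter after the initial
replacement (KNIGHT → NAGT).  Two deliberate choices: the *original*
variant rather than the later "modified" one, and an uncapped code length —
truncation to 6 characters (offered as a flag) loses discrimination among
long surnames.  Only surnames are coded; given names are cleaned but not
phonetically coded, and only the first given name is used for matching
(the full list is retained).  The variant and cap are recorded in the run
log.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-condition definition, not a fixture.
It emulates, with one RNG substream per sub-generator so adding one does
not perturb the others:

* **Skewed surnames.** A general list sampled with a shallow power law
  (exponent 0.6 over ~260 names) overlaid, for a configurable fraction of
  persons (default 0.15), with a steep power law (exponent 1.2) over a pool
  of 20 surnames of ≤4 letters.  This reproduces the known failure mode —
  subpopulations in which a handful of very short surnames dominate and
  name agreement carries little identifying information — without encoding
  ethnicity.  Registry persons are identity-distinct: full
  (surname, first given, birth date, sex) collisions are resampled, so
  ground truth is unambiguous and noise-free data is perfectly linkable,
  while surname-level collisions (the phenomenon of interest) remain.
* **Field corruption.** Independent per-field operators at configured
  rates: `typo` (one random edit that always changes the value),
  `phonetic_swap` (substitution within a shipped table of same-NYSIIS
  spelling classes, so the corrupted surname stays in the same phonetic
  block), `date_transpose` (day/month swap when the day is a valid month),
  `drop` (missing).  Defaults: typo 0.05, phonetic swap 0.03, transposition
  0.02, missingness 0.03 per field.  No published estimates of the real
  databases' corruption rates exist; these defaults are declared
  generator settings, not estimates of any real system.
* **Era-dependent quality.** A multiplier per 5-year event band scales all
  corruption rates; the default curve (4.0 / 3.0 / 2.2 / 1.5 / 1.0 / 0.5
  from 1985 to 2010+) makes older records dirtier and produces the
  characteristic rising era series.
* **Unlinkable records.** With probability `unlinkable_frac` (default
  0.05) a source record is an invention with freshly generated identifiers
  — never a copy — so no accidental true match exists; for death files
  these skew toward perinatal deaths with birth ≈ death date, emulating
  neonatal deaths never issued a registration number.
* **Duplicates.** With probability `dup_frac` (default 0.02) a truth person
  contributes a second source record differing in event date.

It does **not** emulate: realistic demography (household structure,
migration dynamics, age pyramids), non-Latin scripts or transliteration,
correlated corruption across fields, or drifting identifiers (name changes
at marriage).  Passing tests therefore demonstrate the pipeline's behaviour
under this error model, not performance guarantees on any real registry.

## Numerical and design choices

* Weights in log base 2 (bits); the base only rescales thresholds.
  Default thresholds `t_lower=4`, `t_upper=8` bits and a 1-bit runner-up
  margin are explicit stand-ins for production settings that are not
  published; equivalence with any particular system is not claimed.
* Classification boundary conventions: `W == t_upper` is definite,
  `W == t_lower` is possible.
* Ties in candidate ranking break by registry key; dedup and one-to-one
  ties break by tier, weight, pass, then stable input order — every run is
  deterministic, and identical configuration + seed gives byte-identical
  artifacts.
* EM runs on agree/disagree/missing vectors under conditional
  independence, missing entries contributing to neither class; parameters
  are clipped to (1e-6, 1-1e-6), iteration stops when the largest change
  falls below `tol` (default 1e-6) or at `max_iter`; the match class is
  relabelled so mean(m) > mean(u).  Degenerate inputs (all vectors
  identical, fewer than two fields) raise rather than return nonsense.
* The pooled two-proportion standardized-difference form was chosen
  because, applied to the shipped benchmark tables' printed counts, it
  reproduces every printed standardized difference exactly — the strongest
  available evidence of the convention those tables used.  Whether
  continuous variables used pooled or unpooled variance is not documented
  anywhere; the continuous overload uses averaged variances and says so.
* Deterministic passes whose comparators are all equality-like are matched
  through a hash on (block key, canonical values) — exact and linear; the
  transposition-tolerant comparator canonicalizes to (year, min, max) of
  month/day; only windowed date comparison falls back to a within-block
  scan.

## Problem sizes

The test suite and acceptance script exercise: oracle-equivalence fixtures
at ≤200 records (where brute-force all-pairs comparison is feasible);
binomial/era property checks at 10^4 records; EM recovery at 5×10^4
simulated vectors; and full end-to-end runs at a 50,000-person registry
against 10,000 source records — the scale at which blocked candidate counts
(~10^5–10^6 pairs per probabilistic pass) remain comfortable on one CPU.
The era-monotonicity check uses a dedicated four-era configuration with a
strong quality gradient (multipliers 5.0/3.0/1.6/0.6 and elevated base
corruption at 12,000×12,000 records): under the default curve the late eras
saturate against the constant unlinkable floor — exactly as published era
series flatten in their final bands — leaving adjacent-band differences
below binomial noise, so the check is run where the signal is resolvable
(adjacent gaps ≳4 standard errors).

## Known limitations

* No string-similarity partial agreement (Jaro–Winkler bands); agreement is
  binary per field, so a one-letter typo and a completely different value
  weigh the same disagreement.
* The review stage is a deterministic rule, not a human; it cannot overturn
  definite matches and adjudicates only the grey zone.
* u-probabilities are configured per pass rather than estimated per block;
  the EM estimator is provided but the demo pipelines use declared values.
* Linkage-error *correction* (weighting, prior-informed imputation) is out
  of scope; the package measures bias, it does not repair it.
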