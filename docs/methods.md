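# Methods

## Scoring model

The package scores a cohort of self-reported phenotype profiles in two
layers. Each phenotype `F_i` gets a score `S_i`, the number of distinct
participants holding at least one *valid* value for it — a participant is
counted once per phenotype regardless of how many values they list. Each
participant then gets a participation index

    P-index_j = 100 * sum_{i in valid, j validly reports i} S_i / sum_{i in valid} S_i

in [0, 100]. The denominator ("theoretical maximum") is the raw sum a
participant reporting every valid phenotype would attain. Because `S_i`
appears both as the per-phenotype weight and in the denominator, the
identity `sum_j raw_j = sum_i S_i^2` holds exactly; the suite asserts it
against a brute-force double loop on random cohorts.

Assumptions worth making explicit:

* validity is binary — any non-empty answer outside the invalid-string set
  earns full credit, so "no" is worth as much as "yes" and magnitudes are
  never parsed for scoring;
* the score table is a property of the whole cohort: adding one
  participant's report in principle changes every `S_i`, but ranking,
  suggestion gains and the monotonicity properties are all stated *holding
  the score table fixed*, which is also how the suggested-gain arithmetic
  is quoted;
* deduplication happens at load: repeated (participant, phenotype, value)
  records collapse to one, and comparisons of names and values are
  case-insensitive with first-seen casing preserved.

## Validity and filtering

Invalid values (defaults): "unsure", "not applicable", "other/don't
know/no response", "no response", "not sure", "unspecified"; matching is on
the trimmed, casefolded string. Phenotype filters (defaults, all
configurable through `ExclusionConfig`):

* administrative names, matched exactly and case-insensitively: enrolled,
  consent, account created, eligibility screening, participant id, exam —
  fields a database generates for every enrollee;
* genome-data fields, matched by substring keyword: sequencing,
  genotyping, genome data, 23andme, variant. Substring matching is used
  because such labels vary freely ("whole-exome sequencing data", …); the
  keyword list is deliberately user-replaceable since any given database
  will have its own conventions;
* `min_share`: phenotypes validly reported by fewer than 2 participants
  are dropped — a phenotype nobody shares cannot power an association
  analysis, and the floor also neutralizes junk phenotypes uploaded to game
  the ranking. The floor is enforced at ≥ 2 and can only be raised.

If every phenotype is filtered away the filter raises (the denominator
would be 0); the `run_pipeline` convenience instead reports an all-zero
P-index table for such degenerate cohorts, which is the only sensible
answer for, say, a cohort in which nobody reported anything.

## Survey normalization

Checklist questionnaires surface only ticked items, so a taker who ticked
nothing leaves no trace. Participation is *detected* when a profile
surfaces at least one item of the survey (threshold configurable;
surfacing even a non-informative answer counts, since it proves the survey
was opened); detected takers get every missing item of that survey filled
with the literal "no", flagged as provenance "imputed" in the normalized
output. Filling never alters existing entries and is idempotent.
Non-checklist (demographic) surveys are never filled — imputing "no" for a
blood type would be nonsense. The synonym map ships with six default
replacements (survey-prefix labels onto their plain names, Race onto
Race/ethnicity, Gender onto Sex/Gender, the date-of-birth format variant
onto Date of Birth) and must be acyclic, making it idempotent.

## Quantitative phenotype selection

The QtP-index needs a list of quantitative traits. Real deployments curate
this list by hand; the package supplies a heuristic stand-in: a phenotype
qualifies if its score is ≥ 10 (configurable) and at least 80% of its
valid values begin numerically ("170 cm", "140 lbs", "5.5"). The 80%
fraction tolerates stray free-text answers without admitting categorical
fields. A hand-curated list can always be passed directly to
`compute_qtp_index`.

## Statistical tests

Two standard tests are exposed behind the analytics surface, both
delegating to scipy: the exact binomial test of equal male/female
enrollment (one- or two-sided; the two-sided p is the sum of outcome
probabilities not exceeding the observed one's) and the two-sided Wilcoxon
rank-sum comparison of P-index distributions. The rank-sum test uses the
exact null distribution when the pooled sample is ≤ 12 and tie-free, else
the normal approximation with tie-corrected variance and a 0.5 continuity
correction. The test suite checks both against independent full-enumeration
oracles written from scratch.

## Stratification and geography

Stratification groups participants by the valid values of one reported
field; participants reporting several distinct values (e.g. listing two
genders) form their own combined stratum, which keeps the two-group sex
comparison clean. Groups below `min_group` (default 30) are dropped.
Per-group summaries use strict thresholds (> 90, < 10) and the standard
midpoint median.

Zip codes are normalized to 5 digits (whitespace trimmed, ZIP+4 suffix
dropped, left-zero-padded), looked up in a `zip,latitude,longitude`
gazetteer, and clustered into one-degree cells keyed by
(floor(latitude), ceiling(longitude)). Mathematical floor/ceiling is used,
so a U.S. longitude of −71.06 ceils to −71; exact-integer coordinates land
in the cell they name. Cells report member count, median P-index and a
plot point at the median unrounded member coordinates.

## Synthetic cohort generator

The generator emulates the statistical structure of a scraped
open-enrollment cohort, not its content. Each participant draws a latent
class — `zero` (appears only in the roster; probability `p_zero` = 0.27),
`full` (answers every survey; `p_full_taker` = 0.30), or `partial` — and a
sex, state and zip. The class probabilities are the package's reference
conditions, sized to the real cohort's observed shares of non-contributors
and near-complete survey takers, and they produce the characteristic
bimodal P-index distribution. The default catalog has 17 surveys with the
questionnaire sizes of the real cohort's survey roster; the 13-item
demographic survey (non-checklist) carries Sex/Gender, State, Zip code,
height, weight and blood pressures, and the remaining 16 are checklists.

Remaining defaults, chosen once as field-realistic values:

* partial takers answer each checklist survey with probability 0.25 and
  the demographic survey with probability 0.9 (demographics are cheap to
  share); with 16 checklist surveys this puts partial takers' P-indexes in
  the 10–60 band, between the two modes;
* each checklist item is ticked "yes" with probability 0.3 — high for a
  disease, but checklist items include common traits (cavities, myopia)
  whose prevalence exceeds 50%, and the rate keeps a taken survey visible
  (an all-"no" survey leaves no trace, exactly as on real profile pages);
* sex ratio 58.2% male among reporters with 0.5% non-binary, mirroring
  the reported enrollment imbalance; `sex_effect` = 0.15 adds to females'
  per-survey answer probability, reproducing a median P-index gap on the
  scale of the reported one (~12 points);
* 2% of emitted values are corrupted to a random invalid string and 2% of
  records are exactly duplicated, exercising the validity and
  deduplication paths;
* 8 states with fixed weights, 5 zips each, placed in disjoint per-state
  bounding boxes so geographic clustering has known structure.

All sampling flows through one seeded numpy Generator: a fixed seed gives
byte-identical outputs. What the generator does *not* emulate: disease
comorbidity, any genotype data, free-text label noise beyond the six
synonym pairs, and longitudinal repeat measurements — so passing the
recovery tests shows the pipeline arithmetic is right under the stated
structure, not that real scraped data is this clean.

## Problem sizes and numerical choices

The parameter-recovery checks run the full pipeline on one generated
cohort of n = 2000 (class-fraction recovery within three binomial standard
errors) and on 50 replicates of n = 1000 for the Wilcoxon sex comparison;
the oracle-equivalence sweep uses 1000 random cohorts of up to 20
participants × 15 phenotypes. P-indexes are kept at full float precision
internally and rounded only for display (default 2 decimals,
configurable). Ranking is deterministic: descending P-index, ties broken
by ascending participant id. Tie-free exactness thresholds, the strict
distribution thresholds and the min-group floor are all exposed as
parameters with the defaults above.

## Known limitations

* Participation detection cannot see takers who answered "no" to every
  item of a checklist survey; their missing credit is irreducible from
  profile data alone.
* The quantitative-trait heuristic can admit numeric-looking
  non-quantities (zip codes) and miss quantities written as words; curated
  lists are preferred when available.
* Per-phenotype weighting beyond `S_i` (e.g. domain-biased rankings) is
  out of scope; the index treats all valid phenotypes alike by design.
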