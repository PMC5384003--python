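"""Survey normalization: synonym reconciliation, participation detection and
implicit-"no" filling.

Checklist surveys surface only the items a participant checked, so a taker
who answered "no" to everything looks identical to a non-taker.  Once a
participant is *detected* as a survey taker (they surface at least one item
from the survey), every missing item of that survey is filled with the
literal value ``"no"``.  Value validity is defined here as well: an answer is
valid unless it is empty or one of a configurable set of non-informative
strings ("unsure", "not sure", ...).  A negative answer ("no") is valid — it
is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import Cohort, Profile, SurveyDefinition

__all__ = [
    "DEFAULT_INVALID_VALUES",
    "DEFAULT_SYNONYMS",
    "FillReport",
    "is_valid_value",
    "validate_synonym_map",
    "apply_synonym_map",
    "detect_survey_participation",
    "fill_survey_negatives",
]

#: Answers that carry no information and earn no phenotype credit.
DEFAULT_INVALID_VALUES: frozenset[str] = frozenset({
    "unsure",
    "not applicable",
    "other/don't know/no response",
    "no response",
    "not sure",
    "unspecified",
})

#: Default survey-label synonym replacements (source → canonical).
DEFAULT_SYNONYMS: dict[str, str] = {
    "1.3 --- Weight": "Weight",
    "1.2 --- Height": "Height",
    "1.1 --- Blood Type": "Blood Type",
    "Race": "Race/ethnicity",
    "Gender": "Sex/Gender",
    "Date of Birth (mm/dd/yyyy)": "Date of Birth",
}


def is_valid_value(raw_value: str,
                   invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES) -> bool:
    """True iff the trimmed, casefolded value is non-empty and not in the invalid set."""
    v = raw_value.strip().casefold()
    return bool(v) and v not in invalid_values


def validate_synonym_map(mapping: Mapping[str, str]) -> None:
    """Reject maps where a canonical name is itself a source (cycles / chains).

    Acyclicity guarantees that applying the map twice equals applying it once.
    """
    sources = {k.strip().casefold() for k in mapping}
    for canonical in mapping.values():
        if canonical.strip().casefold() in sources:
            raise ValueError(
                f"synonym map is not idempotent: canonical name {canonical!r} "
                "is also a source")


def apply_synonym_map(cohort: Cohort,
                      mapping: Mapping[str, str] | None = None) -> Cohort:
    """Rewrite source phenotype names to their canonical names.

    If a participant carries both the source and the canonical phenotype, the
    value sets are merged and deduplicated.  The input cohort is never
    modified; when no source name occurs anywhere it is returned as-is,
    otherwise a rewritten copy is returned.
    """
    if mapping is None:
        mapping = DEFAULT_SYNONYMS
    validate_synonym_map(mapping)
    folded = {k.strip().casefold(): v.strip() for k, v in mapping.items()}
    if not any(profile.has(src) for src in folded for profile in cohort):
        return cohort  # no source name present: nothing to rewrite
    out = Cohort()
    for profile in cohort:
        new = out.ensure(profile.participant_id)
        for name, values in profile.items():
            target = folded.get(name.strip().casefold(), name)
            for value in values:
                new.add(target, value)
    return out


def detect_survey_participation(profile: Profile, survey: SurveyDefinition,
                                min_answers: int = 1) -> bool:
    """True iff the profile surfaces at least ``min_answers`` of the survey's items.

    Any value counts, valid or not: surfacing an answer proves the survey was
    taken even when the answer itself is non-informative.
    """
    hits = 0
    for name in survey.phenotype_names:
        if profile.has(name):
            hits += 1
            if hits >= min_answers:
                return True
    return False


@dataclass
class FillReport:
    """Audit of implicit-"no" imputation."""

    n_imputed: int = 0
    n_takers: int = 0
    #: (participant_id, casefolded phenotype name) of every imputed entry.
    imputed: set[tuple[str, str]] = field(default_factory=set)

    def is_imputed(self, participant_id: str, phenotype: str) -> bool:
        return (participant_id, phenotype.strip().casefold()) in self.imputed


def fill_survey_negatives(cohort: Cohort,
                          catalog: Sequence[SurveyDefinition],
                          min_answers: int = 1,
                          fill_value: str = "no") -> Cohort:
    """Fill missing checklist-survey items with "no" for detected takers.

    Only surveys flagged ``checklist`` are filled.  Existing entries are never
    altered or removed, so the operation is idempotent and entry counts are
    non-decreasing.  Returns a new cohort with a :class:`FillReport` attached
    as ``cohort.fill_report``.
    """
    report = FillReport()
    out = Cohort()
    checklists = [s for s in catalog if s.checklist]
    for profile in cohort:
        new = out.ensure(profile.participant_id)
        for name, values in profile.items():
            for value in values:
                new.add(name, value)
        for survey in checklists:
            if not detect_survey_participation(profile, survey, min_answers):
                continue
            report.n_takers += 1
            for name in survey.phenotype_names:
                if not new.has(name):
                    new.add(name, fill_value)
                    report.n_imputed += 1
                    report.imputed.add(
                        (profile.participant_id, name.strip().casefold()))
    out.fill_report = report
    return out
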