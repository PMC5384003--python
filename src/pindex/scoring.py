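"""Phenotype scores, validity filtering, the participation index and ranking.

Each phenotype F_i earns a *phenotype score* S_i equal to the number of
distinct participants with a valid value for it.  A participant's
*participation index* (P-index) is

    P = 100 * (sum of S_i over phenotypes the participant validly reports)
            / (sum of S_i over all M valid phenotypes)

so the index runs from 0 (nothing reported) to 100 (every valid phenotype
reported).  Phenotypes reported by many participants therefore carry more
weight — more reporters means more statistical power for association studies
downstream.  The quantitative-trait variant (QtP-index) applies the same
formula to a restricted list of numeric-valued phenotypes.

P-index tables are plain :class:`pandas.DataFrame` objects with columns
``participant_id``, ``raw_sum``, ``p_index`` and (after ranking) ``rank``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .io import Cohort, Profile
from .normalization import DEFAULT_INVALID_VALUES, is_valid_value

__all__ = [
    "DEFAULT_ADMINISTRATIVE_NAMES",
    "DEFAULT_GENOTYPE_KEYWORDS",
    "ExclusionConfig",
    "PhenotypeScoreTable",
    "ValidPhenotypeTable",
    "score_phenotypes",
    "filter_valid_phenotypes",
    "compute_p_index",
    "rank_participants",
    "select_quantitative_phenotypes",
    "compute_qtp_index",
    "suggest_phenotypes",
]

#: Site bookkeeping fields generated for every enrollee regardless of any
#: actual phenotype reporting; excluded from scoring (matched exactly,
#: case-insensitively).
DEFAULT_ADMINISTRATIVE_NAMES: frozenset[str] = frozenset({
    "enrolled",
    "consent",
    "account created",
    "eligibility screening",
    "participant id",
    "exam",
})

#: Substrings marking fields that describe the participant's genome rather
#: than a phenotype (e.g. "whole-genome sequencing data").
DEFAULT_GENOTYPE_KEYWORDS: frozenset[str] = frozenset({
    "sequencing",
    "genotyping",
    "genome data",
    "23andme",
    "variant",
})

_NUMERIC_LEADING = re.compile(r"^[<>~≈]?\s*[+-]?(\d+([.,]\d*)?|[.]\d+)")


@dataclass(frozen=True)
class ExclusionConfig:
    """Filters defining which phenotypes count toward the P-index.

    ``min_share`` is the minimum number of participants that must validly
    report a phenotype for it to be valid; at least 2, so a phenotype nobody
    else shares earns no credit (raising it further tightens the filter).
    """

    administrative_names: frozenset[str] = DEFAULT_ADMINISTRATIVE_NAMES
    genotype_keywords: frozenset[str] = DEFAULT_GENOTYPE_KEYWORDS
    min_share: int = 2

    def __post_init__(self):
        if self.min_share < 2:
            raise ValueError("min_share must be >= 2")


class PhenotypeScoreTable:
    """Mapping phenotype name → score S_i (case-insensitive lookup)."""

    def __init__(self, scores: Iterable[tuple[str, int]] = ()):
        # fold(name) -> (display name, score)
        self._data: dict[str, tuple[str, int]] = {}
        for name, score in scores:
            self.set(name, score)

    def set(self, name: str, score: int) -> None:
        if score < 0:
            raise ValueError("phenotype score must be >= 0")
        self._data[name.strip().casefold()] = (name.strip(), int(score))

    def __getitem__(self, name: str) -> int:
        return self._data[name.strip().casefold()][1]

    def get(self, name: str, default=None):
        entry = self._data.get(name.strip().casefold())
        return default if entry is None else entry[1]

    def __contains__(self, name: str) -> bool:
        return name.strip().casefold() in self._data

    def __len__(self) -> int:
        return len(self._data)

    def items(self) -> Iterator[tuple[str, int]]:
        """(display name, score) pairs in insertion order."""
        for display, score in self._data.values():
            yield display, score

    def names(self) -> list[str]:
        return [d for d, _ in self._data.values()]

    def scores(self) -> list[int]:
        return [s for _, s in self._data.values()]

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.items()), name="score")

    def __repr__(self) -> str:
        return f"PhenotypeScoreTable({len(self)} phenotypes)"


class ValidPhenotypeTable(PhenotypeScoreTable):
    """The M phenotypes surviving the validity filters, with ΣS as denominator."""

    def __init__(self, scores: Iterable[tuple[str, int]],
                 dropped: Mapping[str, str] | None = None):
        super().__init__(scores)
        if len(self) == 0:
            raise ValueError("no valid phenotypes: denominator would be 0")
        #: display name -> exclusion reason for phenotypes removed by filtering
        self.dropped: dict[str, str] = dict(dropped or {})
        self.denominator = sum(self.scores())
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")

    @property
    def n_valid(self) -> int:
        return len(self)

    def __repr__(self) -> str:
        return (f"ValidPhenotypeTable({len(self)} phenotypes, "
                f"denominator={self.denominator})")


def score_phenotypes(cohort: Cohort,
                     invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                     ) -> PhenotypeScoreTable:
    """Score every phenotype by the number of participants validly reporting it.

    A participant contributes at most one point per phenotype no matter how
    many values they list.  Phenotypes seen only with invalid values stay in
    the table with score 0.
    """
    table = PhenotypeScoreTable()
    counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for profile in cohort:
        for name, values in profile.items():
            key = name.strip().casefold()
            display.setdefault(key, name)
            counts.setdefault(key, 0)
            if any(is_valid_value(v, invalid_values) for v in values):
                counts[key] += 1
    for key, n in counts.items():
        table.set(display[key], n)
    return table


def filter_valid_phenotypes(table: PhenotypeScoreTable,
                            config: ExclusionConfig | None = None,
                            ) -> ValidPhenotypeTable:
    """Drop administrative, genotype-related and under-shared phenotypes.

    Raises ``ValueError`` if nothing survives (the P-index denominator would
    be zero).
    """
    if config is None:
        config = ExclusionConfig()
    admin = {a.strip().casefold() for a in config.administrative_names}
    keywords = [k.strip().casefold() for k in config.genotype_keywords]
    survivors: list[tuple[str, int]] = []
    dropped: dict[str, str] = {}
    for name, score in table.items():
        key = name.strip().casefold()
        if key in admin:
            dropped[name] = "administrative"
        elif any(k in key for k in keywords):
            dropped[name] = "genotype"
        elif score < config.min_share:
            dropped[name] = "low_share"
        else:
            survivors.append((name, score))
    return ValidPhenotypeTable(survivors, dropped)


def _raw_sum(profile: Profile, valid: ValidPhenotypeTable,
             invalid_values: frozenset[str]) -> int:
    total = 0
    for name, values in profile.items():
        score = valid.get(name)
        if score is not None and any(is_valid_value(v, invalid_values) for v in values):
            total += score
    return total


def compute_p_index(cohort: Cohort, valid: ValidPhenotypeTable,
                    invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                    ) -> pd.DataFrame:
    """P-index per participant: 100 × (Σ S_i over validly reported i) / ΣS.

    Returns a DataFrame with columns ``participant_id``, ``raw_sum``,
    ``p_index``; participants with no valid phenotypes score 0.
    """
    rows = []
    denom = valid.denominator
    for profile in cohort:
        raw = _raw_sum(profile, valid, invalid_values)
        rows.append((profile.participant_id, raw, 100.0 * raw / denom))
    return pd.DataFrame(rows, columns=["participant_id", "raw_sum", "p_index"])


def rank_participants(ptable: pd.DataFrame) -> pd.DataFrame:
    """Assign ordinal ranks 1..N by descending p_index, ties by ascending id."""
    out = ptable.sort_values(
        ["p_index", "participant_id"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def select_quantitative_phenotypes(cohort: Cohort,
                                   table: PhenotypeScoreTable,
                                   min_score: int = 10,
                                   numeric_fraction: float = 0.8,
                                   invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                                   ) -> list[str]:
    """Pick phenotypes that look quantitative and are widely enough shared.

    A phenotype qualifies when its score is at least ``min_score`` and at
    least ``numeric_fraction`` of its valid values parse as numeric-leading
    ("170 cm", "140 lbs", "5.5").
    """
    candidates = {name.strip().casefold(): name for name, score in table.items()
                  if score >= min_score}
    n_numeric: dict[str, int] = {}
    n_valid: dict[str, int] = {}
    for profile in cohort:
        for name, values in profile.items():
            key = name.strip().casefold()
            if key not in candidates:
                continue
            for v in values:
                if not is_valid_value(v, invalid_values):
                    continue
                n_valid[key] = n_valid.get(key, 0) + 1
                if _NUMERIC_LEADING.match(v.strip()):
                    n_numeric[key] = n_numeric.get(key, 0) + 1
    selected = []
    for key, display in candidates.items():
        total = n_valid.get(key, 0)
        if total and n_numeric.get(key, 0) / total >= numeric_fraction:
            selected.append(display)
    return selected


def compute_qtp_index(cohort: Cohort,
                      quantitative: Sequence[str],
                      table: PhenotypeScoreTable,
                      invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                      ) -> pd.DataFrame:
    """QtP-index: the P-index restricted to a quantitative phenotype list.

    Denominator is ΣS over the quantitative list only.
    """
    if not quantitative:
        raise ValueError("quantitative phenotype list is empty")
    restricted = ValidPhenotypeTable(
        [(name, table[name]) for name in quantitative])
    return compute_p_index(cohort, restricted, invalid_values)


def suggest_phenotypes(profile: Profile, valid: ValidPhenotypeTable,
                       k: int = 3,
                       invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                       ) -> list[tuple[str, int, float]]:
    """The k highest-scoring valid phenotypes the participant has yet to report.

    Each suggestion carries the P-index gain the participant would realize by
    providing a valid value, quoted at current scores (the score table is not
    recomputed for the hypothetical new report).  Returns (name, score, gain)
    triples, by descending score, ties by name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = []
    for name, score in valid.items():
        values = profile.values(name)
        if not any(is_valid_value(v, invalid_values) for v in values):
            missing.append((name, score))
    missing.sort(key=lambda t: (-t[1], t[0]))
    denom = valid.denominator
    return [(name, score, 100.0 * score / denom) for name, score in missing[:k]]
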