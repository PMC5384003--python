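"""Reading and writing cohort profile tables, survey catalogs and zip gazetteers.

The on-disk profile format is the three-column, tab-separated table a profile
scraper would emit::

    participant_id<TAB>phenotype<TAB>value

with an optional header line beginning ``participant_id``.  A row of the form
``participant_id<TAB><TAB>`` (empty phenotype and value) is an *empty marker*:
it records that a participant is enrolled without asserting any phenotype, so
cohorts with zero-contribution participants round-trip without a side file.
Alternatively a *roster* (one participant id per line) may enumerate all
enrolled participants.

Phenotype names and values are whitespace-trimmed on load; comparisons are
case-insensitive but the first-seen casing is preserved for output.  Duplicate
(participant, phenotype, value) triples are silently dropped and counted in
the cohort's :class:`LoadReport` — a participant is credited at most once per
phenotype.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import yaml

__all__ = [
    "Profile",
    "Cohort",
    "LoadReport",
    "SurveyDefinition",
    "ZipGazetteer",
    "ProfileParseError",
    "parse_profile_table",
    "write_profile_table",
    "load_roster",
    "load_survey_catalog",
    "load_gazetteer",
]

PROFILE_HEADER = "participant_id\tphenotype\tvalue"


class ProfileParseError(ValueError):
    """Raised for a malformed profile-table line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _fold(s: str) -> str:
    return s.strip().casefold()


class Profile:
    """One participant's deduplicated phenotype → values mapping.

    Values for a phenotype form an ordered set: insertion order is kept,
    duplicates (case-insensitive, trimmed) are rejected by :meth:`add`.
    """

    __slots__ = ("participant_id", "_entries")

    def __init__(self, participant_id: str):
        pid = participant_id.strip()
        if not pid:
            raise ValueError("participant_id must be non-empty")
        self.participant_id = pid
        # fold(name) -> [display_name, [values...], {fold(value), ...}]
        self._entries: dict[str, list] = {}

    def add(self, phenotype: str, value: str) -> bool:
        """Add one (phenotype, value) record; return False if it was a duplicate."""
        name = phenotype.strip()
        if not name:
            raise ValueError("phenotype name must be non-empty")
        val = value.strip()
        key = name.casefold()
        entry = self._entries.get(key)
        if entry is None:
            self._entries[key] = [name, [val], {val.casefold()}]
            return True
        if val.casefold() in entry[2]:
            return False
        entry[1].append(val)
        entry[2].add(val.casefold())
        return True

    def has(self, phenotype: str) -> bool:
        return _fold(phenotype) in self._entries

    def values(self, phenotype: str) -> list[str]:
        entry = self._entries.get(_fold(phenotype))
        return list(entry[1]) if entry else []

    def phenotype_names(self) -> list[str]:
        """Display names, in first-seen order."""
        return [e[0] for e in self._entries.values()]

    def items(self) -> Iterator[tuple[str, list[str]]]:
        for e in self._entries.values():
            yield e[0], list(e[1])

    @property
    def n_entries(self) -> int:
        return sum(len(e[1]) for e in self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Profile):
            return NotImplemented
        return self.participant_id == other.participant_id and {
            k: v[1] for k, v in self._entries.items()
        } == {k: v[1] for k, v in other._entries.items()}

    def __repr__(self) -> str:
        return f"Profile({self.participant_id!r}, {len(self)} phenotypes)"


@dataclass
class LoadReport:
    """Audit counts from a profile-table load."""

    n_lines: int = 0
    n_records: int = 0
    n_duplicates: int = 0
    n_empty_markers: int = 0


class Cohort:
    """All enrolled participants, including those who contributed nothing.

    ``n_participants`` counts every enrolled participant; profiles may be
    empty when a roster (or empty-marker rows) enumerate non-contributors.
    """

    def __init__(self, profiles: Iterable[Profile] = ()):
        self._profiles: dict[str, Profile] = {}
        self.load_report: LoadReport | None = None
        self.fill_report = None  # set by normalization.fill_survey_negatives
        for p in profiles:
            self.add_profile(p)

    def add_profile(self, profile: Profile) -> None:
        if profile.participant_id in self._profiles:
            raise ValueError(f"duplicate participant_id {profile.participant_id!r}")
        self._profiles[profile.participant_id] = profile

    def ensure(self, participant_id: str) -> Profile:
        """Return the participant's profile, creating an empty one if absent."""
        pid = participant_id.strip()
        prof = self._profiles.get(pid)
        if prof is None:
            prof = Profile(pid)
            self._profiles[pid] = prof
        return prof

    def get(self, participant_id: str) -> Profile | None:
        return self._profiles.get(participant_id.strip())

    def __getitem__(self, participant_id: str) -> Profile:
        return self._profiles[participant_id.strip()]

    def __contains__(self, participant_id: str) -> bool:
        return participant_id.strip() in self._profiles

    @property
    def profiles(self) -> list[Profile]:
        return list(self._profiles.values())

    @property
    def ids(self) -> list[str]:
        return list(self._profiles)

    @property
    def n_participants(self) -> int:
        return len(self._profiles)

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[Profile]:
        return iter(self._profiles.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return set(self._profiles) == set(other._profiles) and all(
            self._profiles[k] == other._profiles[k] for k in self._profiles
        )

    def __repr__(self) -> str:
        return f"Cohort({self.n_participants} participants)"


@dataclass(frozen=True)
class SurveyDefinition:
    """A survey questionnaire: its name, phenotype list and checklist flag.

    ``checklist`` marks surveys that surface only affirmative answers on
    public profiles, so takers' missing items imply "no".
    """

    survey_name: str
    phenotype_names: tuple[str, ...]
    checklist: bool = True

    def __post_init__(self):
        if not self.survey_name.strip():
            raise ValueError("survey name must be non-empty")
        if not self.phenotype_names:
            raise ValueError(f"survey {self.survey_name!r}: empty phenotype list")
        folds = [_fold(n) for n in self.phenotype_names]
        if len(set(folds)) != len(folds):
            raise ValueError(f"survey {self.survey_name!r}: duplicate phenotype names")

    def __contains__(self, phenotype: str) -> bool:
        return _fold(phenotype) in {_fold(n) for n in self.phenotype_names}


class ZipGazetteer:
    """zip code → (latitude, longitude) lookup."""

    def __init__(self, entries: Iterable[tuple[str, float, float]] = (), n_dropped: int = 0):
        self._coords: dict[str, tuple[float, float]] = {}
        self.n_dropped = n_dropped
        for z, lat, lon in entries:
            self.add(z, lat, lon)

    def add(self, zip_code: str, latitude: float, longitude: float) -> None:
        if not (-90.0 <= latitude <= 90.0):
            raise ValueError(f"latitude {latitude} out of range")
        if not (-180.0 <= longitude <= 180.0):
            raise ValueError(f"longitude {longitude} out of range")
        self._coords[zip_code.strip()] = (float(latitude), float(longitude))

    def get(self, zip_code: str) -> tuple[float, float] | None:
        return self._coords.get(zip_code.strip())

    def __contains__(self, zip_code: str) -> bool:
        return zip_code.strip() in self._coords

    def __len__(self) -> int:
        return len(self._coords)

    def items(self) -> Iterator[tuple[str, tuple[float, float]]]:
        return iter(self._coords.items())


def _open_text(source, mode: str = "r"):
    """Return (file_object, needs_close) for a path or file-like source."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def parse_profile_table(source: str | os.PathLike | IO[str],
                        roster: Sequence[str] | None = None) -> Cohort:
    """Parse a 3-column profile TSV into a :class:`Cohort`.

    Parameters
    ----------
    source
        Path or open text stream of the tab-separated table.
    roster
        Optional list of all enrolled participant ids; participants absent
        from the table get empty profiles, so N = len(roster) rather than the
        number of distinct ids seen.
    """
    fh, needs_close = _open_text(source)
    report = LoadReport()
    cohort = Cohort()
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            report.n_lines += 1
            if lineno == 1 and line.startswith("participant_id"):
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ProfileParseError(
                    lineno, f"expected 3 tab-separated fields, got {len(fields)}")
            pid, name, value = fields
            if not pid.strip():
                raise ProfileParseError(lineno, "empty participant_id")
            if not name.strip():
                if value.strip():
                    raise ProfileParseError(lineno, "empty phenotype name with a value")
                cohort.ensure(pid)  # empty marker row
                report.n_empty_markers += 1
                continue
            if cohort.ensure(pid).add(name, value):
                report.n_records += 1
            else:
                report.n_duplicates += 1
    finally:
        if needs_close:
            fh.close()
    if roster is not None:
        for pid in roster:
            if pid.strip():
                cohort.ensure(pid)
    cohort.load_report = report
    return cohort


def write_profile_table(cohort: Cohort, dest: str | os.PathLike | IO[str]) -> None:
    """Write a cohort back to the profile TSV format.

    Empty profiles are written as empty-marker rows so that
    ``parse_profile_table(write_profile_table(c))`` reproduces ``c`` without
    needing a roster.
    """
    fh, needs_close = _open_text(dest, "w")
    try:
        fh.write(PROFILE_HEADER + "\n")
        for profile in cohort:
            if len(profile) == 0:
                fh.write(f"{profile.participant_id}\t\t\n")
                continue
            for name, values in profile.items():
                for value in values:
                    for s in (name, value):
                        if "\t" in s or "\n" in s:
                            raise ValueError(
                                f"field {s!r} contains a tab or newline")
                    fh.write(f"{profile.participant_id}\t{name}\t{value}\n")
    finally:
        if needs_close:
            fh.close()


def load_roster(source: str | os.PathLike | IO[str]) -> list[str]:
    """Load a roster file: one participant id per line, blanks ignored."""
    fh, needs_close = _open_text(source)
    try:
        return [line.strip() for line in fh if line.strip()]
    finally:
        if needs_close:
            fh.close()


def load_survey_catalog(source: str | os.PathLike | IO[str]) -> list[SurveyDefinition]:
    """Load a survey catalog from YAML.

    The document is a list of surveys::

        - name: "Trait & Disease Survey: Blood"
          checklist: true
          phenotypes: [Anemia, Hemophilia, ...]
    """
    fh, needs_close = _open_text(source)
    try:
        data = yaml.safe_load(fh)
    finally:
        if needs_close:
            fh.close()
    if data is None:
        return []
    if not isinstance(data, list):
        raise ValueError("survey catalog must be a YAML list of surveys")
    surveys: list[SurveyDefinition] = []
    seen: set[str] = set()
    for doc in data:
        if not isinstance(doc, dict) or "name" not in doc or "phenotypes" not in doc:
            raise ValueError("each survey needs 'name' and 'phenotypes' keys")
        name = str(doc["name"])
        if _fold(name) in seen:
            raise ValueError(f"duplicate survey name {name!r}")
        seen.add(_fold(name))
        phenos = doc["phenotypes"]
        if not isinstance(phenos, list) or not phenos:
            raise ValueError(f"survey {name!r}: phenotypes must be a non-empty list")
        surveys.append(SurveyDefinition(
            survey_name=name,
            phenotype_names=tuple(str(p) for p in phenos),
            checklist=bool(doc.get("checklist", True)),
        ))
    return surveys


def dump_survey_catalog(catalog: Sequence[SurveyDefinition],
                        dest: str | os.PathLike | IO[str]) -> None:
    """Write a survey catalog as YAML (inverse of :func:`load_survey_catalog`)."""
    docs = [
        {"name": s.survey_name, "checklist": s.checklist,
         "phenotypes": list(s.phenotype_names)}
        for s in catalog
    ]
    fh, needs_close = _open_text(dest, "w")
    try:
        yaml.safe_dump(docs, fh, sort_keys=False, allow_unicode=True)
    finally:
        if needs_close:
            fh.close()


def load_gazetteer(source: str | os.PathLike | IO[str]) -> ZipGazetteer:
    """Load a ``zip,latitude,longitude`` CSV, dropping (and counting) bad rows."""
    fh, needs_close = _open_text(source)
    try:
        reader = csv.DictReader(fh)
        required = {"zip", "latitude", "longitude"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError("gazetteer CSV must have columns zip,latitude,longitude")
        gaz = ZipGazetteer()
        for row in reader:
            try:
                lat = float(row["latitude"])
                lon = float(row["longitude"])
                zipc = (row["zip"] or "").strip()
                if not zipc:
                    raise ValueError("empty zip")
                gaz.add(zipc, lat, lon)
            except (TypeError, ValueError):
                gaz.n_dropped += 1
        return gaz
    finally:
        if needs_close:
            fh.close()
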