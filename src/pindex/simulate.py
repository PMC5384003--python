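"""Synthetic cohort generation.

Emulates the structure of an open-enrollment, self-reported phenotype cohort
as it appears on public profile pages: a large block of enrollees who never
report anything, a block of highly engaged participants who answer every
checklist survey, and partial takers in between; checklist surveys surface
only "yes" answers (the implicit-"no" convention), demographics (sex, state,
zip) come from a separate non-checklist survey, a small fraction of values
are non-informative strings, and occasional exact duplicate records appear.

Every draw is routed through one seeded numpy Generator, so a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Cohort, SurveyDefinition, ZipGazetteer, parse_profile_table
from .normalization import DEFAULT_INVALID_VALUES

__all__ = [
    "SurveySpec",
    "SimParams",
    "SimResult",
    "default_survey_catalog",
    "generate_cohort",
    "generate_gazetteer",
    "state_zip_codes",
    "state_box",
]

SEX_DISPLAY = {"male": "Male", "female": "Female", "other": "Non-binary"}


@dataclass(frozen=True)
class SurveySpec:
    name: str
    n_phenotypes: int
    checklist: bool = True


#: 17 surveys with the questionnaire sizes of the real cohort's catalog;
#: the 13-item Participant Survey is the non-checklist demographic one.
DEFAULT_SURVEYS: tuple[SurveySpec, ...] = (
    SurveySpec("Legacy Trait Survey", 23),
    SurveySpec("Legacy Extended Trait Survey", 34),
    SurveySpec("Participant Survey", 13, checklist=False),
    SurveySpec("Blood Survey", 13),
    SurveySpec("Cancers Survey", 25),
    SurveySpec("Circulatory System Survey", 28),
    SurveySpec("Congenital Traits Survey", 22),
    SurveySpec("Digestive System Survey", 23),
    SurveySpec("Endocrine and Metabolic Survey", 18),
    SurveySpec("Genitourinary Systems Survey", 15),
    SurveySpec("Musculoskeletal Survey", 23),
    SurveySpec("Nervous System Survey", 22),
    SurveySpec("Respiratory System Survey", 9),
    SurveySpec("Skin Survey", 16),
    SurveySpec("Vision and Hearing Survey", 25),
    SurveySpec("Basic Phenotypes Survey", 9),
    SurveySpec("Absolute Pitch Survey", 4),
)

DEFAULT_STATES: tuple[tuple[str, float], ...] = (
    ("Massachusetts", 0.30),
    ("California", 0.20),
    ("Missouri", 0.15),
    ("New York", 0.10),
    ("Texas", 0.08),
    ("Washington", 0.07),
    ("Minnesota", 0.06),
    ("Utah", 0.04),
)

DEMOGRAPHIC_CORE = ("Sex/Gender", "State", "Zip code", "Height", "Weight",
                    "Diastolic blood pressure", "Systolic blood pressure")


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults are the package's reference conditions.

    ``p_zero`` and ``p_full_taker`` set the sizes of the non-contributing and
    fully engaged latent classes; partial takers answer each checklist survey
    with probability ``p_survey_answer`` (plus ``sex_effect`` for females,
    producing the higher female participation the index is meant to surface).
    """

    n_participants: int = 2000
    surveys: tuple[SurveySpec, ...] = DEFAULT_SURVEYS
    p_zero: float = 0.27
    p_full_taker: float = 0.30
    p_survey_answer: float = 0.25
    p_demographic_answer: float = 0.9
    p_yes: float = 0.3
    sex_ratio_male: float = 0.582
    p_sex_other: float = 0.005
    sex_effect: float = 0.15
    states: tuple[tuple[str, float], ...] = DEFAULT_STATES
    zips_per_state: int = 5
    p_invalid_value: float = 0.02
    p_duplicate_record: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("p_zero", "p_full_taker", "p_survey_answer",
                     "p_demographic_answer", "p_yes", "sex_ratio_male",
                     "p_sex_other", "p_invalid_value", "p_duplicate_record"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_zero + self.p_full_taker > 1.0:
            raise ValueError("p_zero + p_full_taker must not exceed 1")
        if self.sex_effect < 0:
            raise ValueError("sex_effect must be >= 0")
        if not self.states:
            raise ValueError("at least one state required")
        if abs(sum(w for _, w in self.states) - 1.0) > 1e-9:
            raise ValueError("state weights must sum to 1")
        if self.zips_per_state < 1:
            raise ValueError("zips_per_state must be >= 1")


def default_survey_catalog(params: SimParams) -> list[SurveyDefinition]:
    """Build SurveyDefinitions for the parameterized survey sizes.

    Non-checklist surveys carry the demographic core fields (Sex/Gender,
    State, Zip code) padded with generic demographic items; checklist surveys
    get trait names unique across the catalog.
    """
    catalog: list[SurveyDefinition] = []
    seen: set[str] = set()
    for idx, spec in enumerate(params.surveys, start=1):
        if spec.checklist:
            names = tuple(f"{spec.name}: Trait {j:02d}"
                          for j in range(1, spec.n_phenotypes + 1))
        else:
            core = DEMOGRAPHIC_CORE[:spec.n_phenotypes]
            pad = tuple(f"{spec.name}: Field {j:02d}"
                        for j in range(1, spec.n_phenotypes - len(core) + 1))
            names = core + pad
        for n in names:
            if n.casefold() in seen:
                raise ValueError(f"duplicate phenotype name {n!r} across surveys")
            seen.add(n.casefold())
        catalog.append(SurveyDefinition(spec.name, names, spec.checklist))
    return catalog


def state_zip_codes(params: SimParams) -> dict[str, list[str]]:
    """Deterministic synthetic zip codes per state (no randomness)."""
    return {
        name: [f"{(i + 1) * 1000 + j:05d}" for j in range(params.zips_per_state)]
        for i, (name, _) in enumerate(params.states)
    }


def state_box(state_index: int) -> tuple[float, float, float, float]:
    """Disjoint (lat_min, lat_max, lon_min, lon_max) bounding box per state."""
    lat0 = 25.0 + 3.0 * state_index
    lon0 = -122.0 + 4.0 * state_index
    return (lat0, lat0 + 1.5, lon0, lon0 + 1.5)


def generate_gazetteer(params: SimParams) -> ZipGazetteer:
    """Synthetic gazetteer placing each state's zips inside its bounding box."""
    rng = np.random.default_rng([params.seed, 7])
    gaz = ZipGazetteer()
    zips = state_zip_codes(params)
    for i, (name, _) in enumerate(params.states):
        lat_min, lat_max, lon_min, lon_max = state_box(i)
        for z in zips[name]:
            gaz.add(z,
                    float(rng.uniform(lat_min, lat_max)),
                    float(rng.uniform(lon_min, lon_max)))
    return gaz


@dataclass
class SimResult:
    """Generated inputs plus the latent truth behind them."""

    profiles_tsv: str
    roster: list[str]
    truth: pd.DataFrame  # participant_id, latent_class, sex, state, zip

    def cohort(self) -> Cohort:
        import io as _io
        return parse_profile_table(_io.StringIO(self.profiles_tsv),
                                   roster=self.roster)


def generate_cohort(params: SimParams) -> SimResult:
    """Generate a profile TSV, roster and truth table under ``params``.

    Latent classes: "zero" participants appear only in the roster; "full"
    participants answer every survey; "partial" participants answer each
    checklist survey independently.  Checklist surveys emit only the "yes"
    rows; a taken survey with no "yes" answers therefore leaves no trace,
    exactly as on real profile pages.
    """
    rng = np.random.default_rng(params.seed)
    catalog = default_survey_catalog(params)
    checklist = [s for s in catalog if s.checklist]
    demographic = [s for s in catalog if not s.checklist]
    invalid_pool = sorted(DEFAULT_INVALID_VALUES)
    state_names = [n for n, _ in params.states]
    state_w = np.array([w for _, w in params.states])
    zips = state_zip_codes(params)

    ids = [f"hu{i:06d}" for i in range(params.n_participants)]
    rows: list[str] = []
    truth_rows = []

    def emit(pid: str, name: str, value: str) -> None:
        if rng.random() < params.p_invalid_value:
            value = invalid_pool[rng.integers(len(invalid_pool))]
        rows.append(f"{pid}\t{name}\t{value}")
        if rng.random() < params.p_duplicate_record:
            rows.append(f"{pid}\t{name}\t{value}")

    for pid in ids:
        u = rng.random()
        if u < params.p_zero:
            latent = "zero"
        elif u < params.p_zero + params.p_full_taker:
            latent = "full"
        else:
            latent = "partial"
        if rng.random() < params.p_sex_other:
            sex = "other"
        else:
            sex = "male" if rng.random() < params.sex_ratio_male else "female"
        state = state_names[rng.choice(len(state_names), p=state_w)]
        zip_code = zips[state][rng.integers(params.zips_per_state)]
        truth_rows.append((pid, latent, sex, state, zip_code))
        if latent == "zero":
            continue

        # demographic survey
        if latent == "full" or rng.random() < params.p_demographic_answer:
            for survey in demographic:
                for name in survey.phenotype_names:
                    if name == "Sex/Gender":
                        emit(pid, name, SEX_DISPLAY[sex])
                    elif name == "State":
                        emit(pid, name, state)
                    elif name == "Zip code":
                        emit(pid, name, zip_code)
                    elif name == "Height":
                        emit(pid, name, f"{rng.integers(150, 200)} cm")
                    elif name == "Weight":
                        emit(pid, name, f"{rng.integers(45, 120)} kg")
                    elif name == "Diastolic blood pressure":
                        emit(pid, name, str(rng.integers(60, 100)))
                    elif name == "Systolic blood pressure":
                        emit(pid, name, str(rng.integers(95, 160)))
                    else:
                        emit(pid, name, f"category {rng.integers(1, 6)}")

        # checklist surveys: only "yes" rows surface
        p_take = params.p_survey_answer
        if sex == "female":
            p_take = min(1.0, p_take + params.sex_effect)
        for survey in checklist:
            taken = latent == "full" or rng.random() < p_take
            if not taken:
                continue
            hits = rng.random(len(survey.phenotype_names)) < params.p_yes
            for name, hit in zip(survey.phenotype_names, hits):
                if hit:
                    emit(pid, name, "yes")

    tsv = "participant_id\tphenotype\tvalue\n" + "".join(r + "\n" for r in rows)
    truth = pd.DataFrame(truth_rows, columns=["participant_id", "latent_class",
                                              "sex", "state", "zip"])
    return SimResult(profiles_tsv=tsv, roster=ids, truth=truth)
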