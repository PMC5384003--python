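"""End-to-end pipeline: normalize → score → filter → P-index → rank → QtP.

Convenience wiring of the module operations in their canonical order, used
by the CLI, the examples and the acceptance machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import Cohort, SurveyDefinition
from .normalization import (DEFAULT_INVALID_VALUES, apply_synonym_map,
                            fill_survey_negatives)
from .scoring import (ExclusionConfig, PhenotypeScoreTable, ValidPhenotypeTable,
                      compute_p_index, compute_qtp_index, filter_valid_phenotypes,
                      rank_participants, score_phenotypes,
                      select_quantitative_phenotypes)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: Cohort                     # normalized (synonyms applied, negatives filled)
    score_table: PhenotypeScoreTable
    valid_table: ValidPhenotypeTable | None  # None when nothing survived filtering
    ptable: pd.DataFrame               # ranked: participant_id, raw_sum, p_index, rank
    quantitative: list[str]
    qtp_table: pd.DataFrame | None     # ranked QtP table, or None if no quantitative traits


def run_pipeline(cohort: Cohort,
                 catalog: Sequence[SurveyDefinition] = (),
                 synonyms: Mapping[str, str] | None = None,
                 exclusions: ExclusionConfig | None = None,
                 invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                 quantitative_min_score: int = 10,
                 ) -> PipelineResult:
    """Run the full scoring pipeline on a raw cohort.

    Degenerate cohorts where no phenotype survives filtering (e.g. nobody
    reported anything) yield an all-zero P-index table instead of an error.
    """
    normalized = apply_synonym_map(cohort, synonyms)
    if catalog:
        normalized = fill_survey_negatives(normalized, catalog)
    score_table = score_phenotypes(normalized, invalid_values)
    try:
        valid = filter_valid_phenotypes(score_table, exclusions)
    except ValueError:
        valid = None
    if valid is None:
        ptable = pd.DataFrame({
            "participant_id": normalized.ids,
            "raw_sum": 0,
            "p_index": 0.0,
        })
        return PipelineResult(normalized, score_table, None,
                              rank_participants(ptable), [], None)
    ptable = rank_participants(compute_p_index(normalized, valid, invalid_values))
    quantitative = select_quantitative_phenotypes(
        normalized, valid, min_score=quantitative_min_score,
        invalid_values=invalid_values)
    qtp = None
    if quantitative:
        qtp = rank_participants(
            compute_qtp_index(normalized, quantitative, valid, invalid_values))
    return PipelineResult(normalized, score_table, valid, ptable,
                          quantitative, qtp)
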