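"""Cohort-level analytics on P-index tables.

Prevalence from checklist yes/no answers, distribution summaries of the
(typically bimodal) P-index, the exact binomial sex-ratio test, the
Wilcoxon rank-sum comparison of P-index distributions, stratification by a
reported field (state, sex), and degree-cell geographic clustering of
geocoded participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Cohort, ZipGazetteer
from .normalization import DEFAULT_INVALID_VALUES, is_valid_value

__all__ = [
    "PIndexDistribution",
    "prevalence_table",
    "pindex_distribution",
    "binomial_sex_test",
    "wilcoxon_rank_sum",
    "field_groups",
    "stratify_by_field",
    "normalize_zip",
    "geocode_participants",
    "cluster_geopoints",
]

DEFAULT_YES_VALUES = frozenset({"yes"})
DEFAULT_NO_VALUES = frozenset({"no"})


def prevalence_table(cohort: Cohort, phenotypes: Sequence[str],
                     yes_values: frozenset[str] = DEFAULT_YES_VALUES,
                     no_values: frozenset[str] = DEFAULT_NO_VALUES,
                     ) -> pd.DataFrame:
    """Per-phenotype prevalence among yes/no respondents.

    prevalence_percent = 100 * n_yes / (n_yes + n_no); NaN when nobody
    answered either way.  A participant listing both a yes- and a no-valued
    entry is counted as yes.  Rows are sorted by descending prevalence.
    Assumes checklist negatives have already been filled.
    """
    yes = {v.casefold() for v in yes_values}
    no = {v.casefold() for v in no_values}
    counts = {p.strip().casefold(): [p.strip(), 0, 0] for p in phenotypes}
    for profile in cohort:
        for name, values in profile.items():
            entry = counts.get(name.strip().casefold())
            if entry is None:
                continue
            folded = {v.strip().casefold() for v in values}
            if folded & yes:
                entry[1] += 1
            elif folded & no:
                entry[2] += 1
    rows = []
    for display, n_yes, n_no in counts.values():
        total = n_yes + n_no
        prev = 100.0 * n_yes / total if total else float("nan")
        rows.append((display, n_yes, n_no, prev))
    df = pd.DataFrame(rows, columns=["phenotype", "n_yes", "n_no",
                                     "prevalence_percent"])
    return df.sort_values("prevalence_percent", ascending=False,
                          kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class PIndexDistribution:
    """Summary of a P-index distribution (strict thresholds)."""

    n_above_hi: int
    n_below_lo: int
    n_zero: int
    median_all: float
    median_nonzero: float


def pindex_distribution(ptable: pd.DataFrame, hi: float = 90.0,
                        lo: float = 10.0) -> PIndexDistribution:
    """Counts above/below the strict thresholds plus overall and nonzero medians."""
    if len(ptable) == 0:
        raise ValueError("empty P-index table")
    p = ptable["p_index"].to_numpy(dtype=float)
    nonzero = p[p > 0]
    return PIndexDistribution(
        n_above_hi=int((p > hi).sum()),
        n_below_lo=int((p < lo).sum()),
        n_zero=int((p == 0).sum()),
        median_all=float(np.median(p)),
        median_nonzero=float(np.median(nonzero)) if nonzero.size else float("nan"),
    )


def binomial_sex_test(n_male: int, n_female: int, sided: str = "two") -> float:
    """Exact binomial test of equal male/female participation (null p = 0.5).

    ``sided="one"`` gives the upper tail P(X >= n_male); ``"two"`` the exact
    two-sided p (sum of outcome probabilities no larger than the observed
    one's).
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("counts must be non-negative")
    n = n_male + n_female
    if n < 1:
        raise ValueError("need at least one observation")
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    return float(sps.binomtest(n_male, n, 0.5, alternative=alternative).pvalue)


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b <= 12) and tie-free; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def field_groups(ptable: pd.DataFrame, cohort: Cohort, field_phenotype: str,
                 invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                 ) -> dict[str, list[float]]:
    """P-index values grouped by a reported field (e.g. "State", "Sex/Gender").

    Participants lacking a valid value for the field are excluded.  A
    participant reporting several distinct values (e.g. listing two genders)
    forms/joins a combined stratum labelled with the sorted values joined by
    ``" / "``.
    """
    pidx = dict(zip(ptable["participant_id"], ptable["p_index"]))
    groups: dict[tuple[str, ...], list[float]] = {}
    labels: dict[tuple[str, ...], str] = {}
    for profile in cohort:
        values = [v for v in profile.values(field_phenotype)
                  if is_valid_value(v, invalid_values)]
        if not values or profile.participant_id not in pidx:
            continue
        distinct: dict[str, str] = {}
        for v in values:
            distinct.setdefault(v.strip().casefold(), v.strip())
        key = tuple(sorted(distinct))
        labels.setdefault(key, " / ".join(distinct[k] for k in sorted(distinct)))
        groups.setdefault(key, []).append(pidx[profile.participant_id])
    return {labels[k]: v for k, v in groups.items()}


def stratify_by_field(ptable: pd.DataFrame, cohort: Cohort,
                      field_phenotype: str, min_group: int = 30,
                      hi: float = 90.0, lo: float = 10.0,
                      invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                      ) -> pd.DataFrame:
    """Group participants by a reported field and summarize each group's P-index.

    Grouping follows :func:`field_groups`; groups smaller than ``min_group``
    are dropped.  Returns columns label, n, median_p_index, pct_above_90,
    pct_below_10, sorted by descending median.
    """
    rows = []
    for label, vals in field_groups(ptable, cohort, field_phenotype,
                                    invalid_values).items():
        n = len(vals)
        if n < min_group:
            continue
        arr = np.asarray(vals, dtype=float)
        rows.append((label, n, float(np.median(arr)),
                     100.0 * float((arr > hi).sum()) / n,
                     100.0 * float((arr < lo).sum()) / n))
    df = pd.DataFrame(rows, columns=["label", "n", "median_p_index",
                                     "pct_above_90", "pct_below_10"])
    return df.sort_values("median_p_index", ascending=False,
                          kind="mergesort").reset_index(drop=True)


def normalize_zip(value: str) -> str | None:
    """Normalize a reported zip to a 5-digit key, or None if it cannot be.

    Strips whitespace, drops a ZIP+4 suffix, requires all digits and at most
    5 of them, and left-pads with zeros ("2144" → "02144").
    """
    s = value.strip()
    if "-" in s:
        s = s.split("-", 1)[0].strip()
    if not s or not s.isdigit() or len(s) > 5:
        return None
    return s.zfill(5)


def geocode_participants(cohort: Cohort, gaz: ZipGazetteer,
                         zip_phenotype: str = "Zip code",
                         invalid_values: frozenset[str] = DEFAULT_INVALID_VALUES,
                         ) -> pd.DataFrame:
    """Resolve each participant's reported zip to coordinates.

    Returns one row (participant_id, zip, lat, lon) per participant whose
    first resolvable zip value is in the gazetteer.  The number of
    participants with zip entries that could not be resolved is reported in
    ``df.attrs["n_unmatched"]``.
    """
    rows = []
    n_unmatched = 0
    for profile in cohort:
        values = [v for v in profile.values(zip_phenotype)
                  if is_valid_value(v, invalid_values)]
        if not values:
            continue
        matched = False
        for v in values:
            key = normalize_zip(v)
            if key is not None:
                coords = gaz.get(key)
                if coords is not None:
                    rows.append((profile.participant_id, key, coords[0], coords[1]))
                    matched = True
                    break
        if not matched:
            n_unmatched += 1
    df = pd.DataFrame(rows, columns=["participant_id", "zip", "lat", "lon"])
    df.attrs["n_unmatched"] = n_unmatched
    return df


def cluster_geopoints(points: pd.DataFrame, ptable: pd.DataFrame) -> pd.DataFrame:
    """Cluster geocoded participants into one-degree cells.

    The cell key is (floor(latitude), ceiling(longitude)) — mathematical
    floor/ceiling, so with negative (western) longitudes −71.06 ceils to −71.
    Each cell reports its member count, median P-index, and plot coordinates
    equal to the median *unrounded* latitude and longitude of its members.
    """
    if len(points) == 0:
        raise ValueError("no geocoded points to cluster")
    pidx = dict(zip(ptable["participant_id"], ptable["p_index"]))
    cells: dict[tuple[int, int], list[tuple[str, float, float]]] = {}
    for pid, lat, lon in zip(points["participant_id"], points["lat"], points["lon"]):
        key = (math.floor(lat), math.ceil(lon))
        cells.setdefault(key, []).append((pid, float(lat), float(lon)))
    rows = []
    for (cell_lat, cell_lon), members in sorted(cells.items()):
        ids = [m[0] for m in members]
        lats = np.array([m[1] for m in members])
        lons = np.array([m[2] for m in members])
        med_p = float(np.median([pidx[i] for i in ids if i in pidx])) \
            if any(i in pidx for i in ids) else float("nan")
        rows.append((cell_lat, cell_lon, len(members), med_p,
                     float(np.median(lats)), float(np.median(lons)), ids))
    return pd.DataFrame(rows, columns=["cell_lat", "cell_lon", "n",
                                       "median_p_index", "plot_lat",
                                       "plot_lon", "member_ids"])
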