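"""Independent brute-force oracles and small cohort builders for the tests.

The oracles work directly on raw (participant, phenotype, value) triples and
never touch the package's scoring path, so agreement is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from pindex.io import Cohort
from pindex.normalization import DEFAULT_INVALID_VALUES


def make_cohort(spec: dict[str, dict[str, list[str] | str]]) -> Cohort:
    """Build a cohort from {pid: {phenotype: value or [values]}}."""
    cohort = Cohort()
    for pid, entries in spec.items():
        prof = cohort.ensure(pid)
        for name, values in entries.items():
            if isinstance(values, str):
                values = [values]
            for v in values:
                prof.add(name, v)
    return cohort


def cohort_from_triples(triples, roster=None) -> Cohort:
    cohort = Cohort()
    for pid, name, value in triples:
        cohort.ensure(pid).add(name, value)
    for pid in roster or ():
        cohort.ensure(pid)
    return cohort


def _is_valid(value: str, invalid=DEFAULT_INVALID_VALUES) -> bool:
    v = value.strip().casefold()
    return bool(v) and v not in invalid


def brute_force_scores(triples, invalid=DEFAULT_INVALID_VALUES) -> dict[str, int]:
    """Phenotype scores by direct double loop over raw triples."""
    valid_reporters: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    for pid, name, value in triples:
        key = name.strip().casefold()
        seen.setdefault(key, name.strip())
        valid_reporters.setdefault(key, set())
        if _is_valid(value, invalid):
            valid_reporters[key].add(pid.strip())
    return {seen[k]: len(v) for k, v in valid_reporters.items()}


def brute_force_p_index(triples, roster, valid_scores: dict[str, int],
                        invalid=DEFAULT_INVALID_VALUES) -> dict[str, float]:
    """P-index per participant by direct enumeration against a score table."""
    denom = sum(valid_scores.values())
    folded = {k.strip().casefold(): s for k, s in valid_scores.items()}
    credited: dict[str, set[str]] = {pid: set() for pid in roster}
    for pid, name, value in triples:
        pid = pid.strip()
        key = name.strip().casefold()
        credited.setdefault(pid, set())
        if key in folded and _is_valid(value, invalid):
            credited[pid].add(key)
    return {pid: 100.0 * sum(folded[k] for k in keys) / denom
            for pid, keys in credited.items()}


def random_triples(rng: np.random.Generator, max_participants=20,
                   max_phenotypes=15):
    """Random raw triples with duplicates, invalid and empty values mixed in."""
    n_p = int(rng.integers(1, max_participants + 1))
    n_f = int(rng.integers(1, max_phenotypes + 1))
    values = ["yes", "no", "170 cm", "blue", "unsure", "not sure", ""]
    triples = []
    for i in range(n_p):
        pid = f"P{i:02d}"
        for j in range(n_f):
            if rng.random() < 0.4:
                v = values[rng.integers(len(values))]
                triples.append((pid, f"F{j:02d}", v))
                if rng.random() < 0.1:  # exact duplicate record
                    triples.append((pid, f"F{j:02d}", v))
    roster = [f"P{i:02d}" for i in range(n_p)]
    return triples, roster


def exact_mann_whitney_two_sided(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free inputs).

    p = P(|U - mu| >= |U_obs - mu|) over all C(n, n_a) group assignments.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)
    mu = n_a * n_b / 2.0

    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - n_a * (n_a + 1) / 2.0

    u_obs = u_of(a)
    stat = abs(u_obs - mu)
    hits = total = 0
    for combo in combinations(pooled, n_a):
        total += 1
        if abs(u_of(combo) - mu) >= stat - 1e-12:
            hits += 1
    return hits / total
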