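"""Score a tiny hand-built cohort and suggest each laggard's best next report.

Three participants report height and weight; Cara's only entries are a
non-informative "unsure" plus a height.  The phenotype score S_i counts the
participants with a valid value for phenotype i, and each participant's
P-index is 100 x (sum of S_i they validly report) / (sum of all valid S_i).
"""

from pindex import (Cohort, compute_p_index, filter_valid_phenotypes,
                    rank_participants, score_phenotypes, suggest_phenotypes)

cohort = Cohort()
for pid, entries in {
    "alice": {"Height": "170 cm", "Weight": "70 kg", "Eye Color": "blue"},
    "bob": {"Height": "180 cm", "Weight": "80 kg"},
    "cara": {"Height": "165 cm", "Weight": "unsure"},
}.items():
    profile = cohort.ensure(pid)
    for name, value in entries.items():
        profile.add(name, value)

table = score_phenotypes(cohort)
print("phenotype scores:", dict(table.items()))

valid = filter_valid_phenotypes(table)
print(f"valid phenotypes: {valid.names()}  (theoretical maximum "
      f"raw score {valid.denominator})")

ranked = rank_participants(compute_p_index(cohort, valid))
print(ranked.to_string(index=False))

for _, row in ranked.iterrows():
    if row.p_index < 100:
        for name, score, gain in suggest_phenotypes(
                cohort[row.participant_id], valid, k=1):
            print(f"{row.participant_id} should report {name!r} "
                  f"(score {score}): +{gain:.1f} P-index points")

# "Eye Color" has score 1 (nobody else shares it) so it is filtered out;
# Cara's "unsure" weight earns no credit, hence her 60.0 rather than 100.
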