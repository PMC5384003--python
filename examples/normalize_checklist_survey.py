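"""Implicit-"no" filling for a checklist survey.

Checklist questionnaires only surface the boxes a participant ticked, so a
taker who checked nothing is indistinguishable from a non-taker.  Anyone who
surfaces at least one item from a checklist survey is treated as a taker and
their missing items are filled with "no"; participants with no trace of the
survey are left alone.
"""

from pindex import Cohort, SurveyDefinition, fill_survey_negatives

blood = SurveyDefinition("Blood Survey",
                         ("Anemia", "Hemophilia", "Sickle cell trait"),
                         checklist=True)

cohort = Cohort()
cohort.ensure("dora").add("Anemia", "yes")        # took the survey
cohort.ensure("evan").add("Height", "180 cm")     # never took it

filled = fill_survey_negatives(cohort, [blood])
for profile in filled:
    print(profile.participant_id, dict(profile.items()))
print(f"imputed {filled.fill_report.n_imputed} answers")

# dora gains Hemophilia="no" and Sickle cell trait="no" (now a complete,
# scoreable answer set); evan is untouched because filling "no" for a survey
# he never saw would fabricate data.
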