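"""Synthetic cohort: zero-noise recovery and the diagnosis-drop noise model.

Generates a gold-labeled cohort at the study's default conditions (prevalence
0.668, surgical/medical/unclassified mix 0.604/0.387/0.009), runs the full
pipeline, and scores it against the generated gold labels — first noise-free,
then with each EP diagnosis code instance dropped with probability 0.1,
comparing measured sensitivity with the closed-form expectation.
"""

import math

from eppheno import (
    CohortConfig,
    default_registry,
    evaluate_case_finding,
    expected_sensitivity,
    generate_cohort,
    patient_level_predictions,
    run_case_finding,
)

registry = default_registry()


def score(cfg):
    cohort = generate_cohort(cfg)
    _, decisions = run_case_finding(cohort.encounters, cohort.medications, registry)
    pred = patient_level_predictions(decisions, cohort.gold["patient_id"])
    return cohort, evaluate_case_finding(pred, cohort.gold)


cohort, report = score(CohortConfig(n_patients=2000, seed=42))
print(f"zero noise (n=2000):  sensitivity {report.sensitivity:.1f}%  "
      f"specificity {report.specificity:.1f}%")

cfg = CohortConfig(n_patients=10_000, p_drop_dx=0.1, seed=42)
cohort, report = score(cfg)
expected = expected_sensitivity(cfg)
n_true = int(cohort.gold["ep_true"].sum())
se = math.sqrt(expected * (1 - expected) / n_true)
print(f"10% code drop (n=10,000): measured sensitivity {report.sensitivity:.2f}%  "
      f"expected {100 * expected:.2f}%  (z = {(report.sensitivity / 100 - expected) / se:+.2f})")

print(
    "\nUnder zero noise the generator and classifier are exact inverses, so "
    "both rates are 100%. Under the drop model, sensitivity falls to the "
    "analytic expectation: a case survives a dropped code only if a redundant "
    "branch (a second coded encounter, or methotrexate evidence) still fires."
)
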