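# eppheno

Rule-based case ascertainment of **ectopic pregnancy (EP)** from longitudinal
electronic-health-record data, with the full diagnostic-test validation suite
and a gold-labeled synthetic cohort generator.

Ectopic pregnancy — implantation of a fertilized ovum outside the endometrial
cavity — is life-threatening but increasingly managed in outpatient settings
(methotrexate injection or laparoscopic surgery), so hospital-discharge data
alone miss cases. `eppheno` implements a computable phenotype over coded
encounters (diagnosis and procedure codes, care settings including telephone
appointment visits) and medication administrations, for epidemiologists and
informaticists who need validated EP surveillance from EHR or claims extracts.

## The algorithm

EP-coded encounters within 180 days (inclusive) of the first one form a
*pregnancy episode*; the first encounter's date is the **index date**.
Methotrexate evidence is a registered methotrexate administration (with an
admissible administration subcode) within −30 to +180 days of the index date.
An episode is called an EP case when any of five branches fires (first hit is
reported for attribution):

1. **B1** — ≥2 encounters with a non-abdominal EP diagnosis code, ≥1 in person;
2. **B2** — ≥2 telephone appointment visits (TAVs) with an EP diagnosis code,
   plus methotrexate evidence;
3. **B3** — ≥1 in-person visit with a *specific tubal* code
   (ICD-9 633.10/633.11, ICD-10 O00.10/O00.11);
4. **B4** — any single encounter with a nonspecific EP diagnosis code, plus
   methotrexate evidence;
5. **B5** — a single non-TAV encounter carrying both an EP diagnosis and an EP
   procedure code.

Episodes coded only with abdominal-EP codes (O00.00/O00.01) fire no branch:
B1–B4 ignore abdominal codes, which excludes abdominal-only coding as sole
evidence. A configurable **comparison** variant models the earlier published
algorithm through its documented differences (no TAV channel, no abdominal
exclusion, no diagnosis+procedure branch, 7-day methotrexate pre-window).

Confirmed cases are assigned a treatment modality: **surgical** if any EP
removal surgery occurs within 30 days after the index date (regardless of
methotrexate), else **medical** if methotrexate evidence exists, else
**unclassified**.

Validation against a chart-review gold standard uses sensitivity,
specificity, PPV, NPV, the Youden index `J = sens + spec − 1`, the F-score
`F = 2·PPV·sens/(PPV + sens)`, 3×3 management agreement with overall
accuracy, and Cohen's κ with an asymptotic 95% CI.

## Worked example

```python
from eppheno import binary_metrics
from eppheno.reference import ENHANCED_FULL

print(binary_metrics(ENHANCED_FULL))
```

```
  sensitivity: 97.6 (326/334)
  specificity: 84.9 (141/166)
          ppv: 92.9 (326/351)
          npv: 94.6 (141/149)
 youden_index: 82.5
      f_score: 95.2
```

Of 334 chart-confirmed EP cases, the enhanced rules found 326 (97.6%
sensitivity); 92.9% of the 351 algorithm positives were true cases. The
`examples/` scripts walk through the other capabilities — episode
classification on a hand-built history (`01`), the full metric suite
including management agreement (`02`), and the synthetic pipeline with its
analytic noise model (`03`). The CLI mirrors the same flow from a shell:

```bash
eppheno simulate --out-dir sim --n-patients 500 --seed 7
eppheno classify sim/encounters.csv sim/medications.csv --variant both --out-dir run
eppheno validate run/decisions.csv sim/gold.csv --management run/management.csv
```

## Input formats

Delimited text (comma default), ISO-8601 dates, `|`-separated codes per cell:

| file | columns |
| --- | --- |
| encounters | `patient_id, date, setting, dx_codes, px_codes` |
| medications | `patient_id, date, drug_code, admin_subcode` |
| patients | `patient_id, birth_date` |
| enrollment | `patient_id, start, end` (half-open spans) |
| gold labels | `patient_id, ep_true, management_true` |

`setting` is one of outpatient / inpatient / outside_claim / telephone
(aliases such as `TAV`, `op`, `ip` accepted).

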