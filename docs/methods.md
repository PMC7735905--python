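# Methods

## Scope and model

`eppheno` implements a deterministic computable phenotype for ectopic
pregnancy (EP) over flat longitudinal EHR extracts. The pipeline is:

1. **Potential-case selection** — keep every encounter carrying ≥1 registered
   EP diagnosis *or* EP procedure code. Abdominal-EP-coded encounters are
   kept here; their exclusion happens at classification. An encounter with
   only an EP procedure code can open an episode (the potential-case
   definition admits procedure-only cases); these are flagged in debug logs
   because most branches require diagnosis codes.
2. **Episode construction** — greedy left-to-right grouping per patient: the
   earliest unassigned EP-coded encounter opens an episode and fixes the
   index date; encounters dated ≤ index + 180 days join it; the next one
   beyond opens a new episode. Successive index dates are therefore > 180
   days apart, and the grouping partitions the input.
3. **Methotrexate attachment** — admissible administrations (drug code in
   the registry, administration subcode in the allow-list or allow-list
   empty) within −30/+180 days of the index date, both ends inclusive.
4. **Case finding** — the five branches (README); first hit B1→B5 is the
   reported branch. The yes/no outcome is order-independent because the
   branches are combined by disjunction.
5. **Management** — surgical if an EP-removal-surgery code appears on an
   encounter in [index, index+30] (absolute precedence), else medical if
   methotrexate evidence exists, else unclassified. Reported evidence is the
   earliest qualifying date.
6. **Validation** — 2×2 and 3×3 metrics against gold labels, Cohen's κ.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| episode window | 180 days, inclusive | encounters within it share an episode |
| methotrexate window | −30 / +180 days, inclusive | evidence window around the index date |
| comparison pre-window | 7 days | the older algorithm's methotrexate lookback |
| surgery window | 0 / +30 days, inclusive | surgical-management attribution |
| eligibility | ages 15–44 (completed years), ≥30 enrollment days, study 2009-01-01..2018-12-31 | study inclusion criteria |
| prefix matching | off | exact code match is auditable; prefix mode serves truncated exports |

Inclusive window ends are a deliberate reading of "within *n* days"; each
boundary is unit-tested (−30/−31, +180/+181, day 180/181) and configurable
where genuinely ambiguous (exclusive episode window via
`build_episodes(..., inclusive=False)`; pre-index surgery via
`allow_pre_index_surgery`). Same-day encounters count as distinct encounters
toward B1's "at least 2" — the rules count encounters, not days.

"At least 1 month" of enrollment is implemented as ≥30 days overlapping the
study period (month length is undefined otherwise); enrollment need not
overlap the episode itself. Enrollment spans are half-open `[start, end)` so
contiguous spans do not double-count days.

## Design choices on open points

* **B2 and the abdominal exclusion.** The abdominal-only exclusion is
  realized by B1–B4 ignoring abdominal codes; B2 therefore counts only TAVs
  carrying a non-abdominal EP diagnosis code. B5 is the one branch that
  accepts any EP diagnosis code (abdominal included) when paired with an EP
  procedure code on the same encounter — a same-encounter procedure is
  treated as corroboration strong enough to overcome the abdominal coding's
  known false-positive problem.
* **"EP code" in B1/B2 means a diagnosis code**; procedure codes enter only
  potential-case selection and B5's procedure clause.
* **Outside-claim encounters are in-person** (they are listed opposite TAVs
  wherever the rules distinguish the two), including for B3.
* **B4's "nonspecific" excludes the specific tubal codes** — including them
  would be redundant with B3.
* **The comparison variant is not the original algorithm.** Only its
  documented differences are modeled (no TAVs, no abdominal exclusion, no
  dx+px branch, 7-day pre-window); the original's full CART-derived rule
  tree is not public. Outputs always label it `comparison`.
* **Two classifier implementations.** `classify_enhanced` is a straight-line
  implementation with fixed constants; `classify_with_variant` is the
  configurable machinery. Their equivalence under the enhanced configuration
  is a tested invariant, which guards the toggle semantics.
* **Undefined metrics are reported as `None`**, never 0 or 100 — small
  synthetic cohorts do hit zero denominators.
* **Display rounding is half-up to one decimal** on the percent scale
  (matching validation-table convention: 140/159 = 88.05% → 88.1); full
  precision is kept internally. The Youden index is reported on the percent
  scale. For the comparison matrix the computed Youden is 78.6.
* **κ confidence interval** uses the simple asymptotic normal SE
  `sqrt(po(1−po)/n)/(1−pe)`, truncated to [−1, 1]. The point estimate is
  cross-checked against statsmodels in the tests; the CI method is an
  assumption and is not asserted against any external value.

## Synthetic cohort generator

The generator emulates the *structure* the rules test, not clinical realism:
no hCG values, ultrasound text, or outcome linkage. Defaults are the
validation-study conditions: n=500 potential cases, true-EP prevalence
0.668, management mix surgical/medical/unclassified = 0.604/0.387/0.009,
ages drawn from the sample's published bands, index dates inside
2009-01-01..2018-12-31 with ICD-9-style codes before the national ICD-10
cutover (2015-10-01) and ICD-10 codes after. Branch frequencies are not
published, so the branch mix is uniform by default and explicitly an
invention. Because an unclassified case has neither surgery nor
methotrexate, the branch draw for unclassified cases is renormalized over
the branches that need no methotrexate (B1/B3/B5); a config that makes this
impossible raises a feasibility error.

True cases receive a minimal encounter pattern that satisfies the drawn
branch exactly; non-cases receive either a benign encounter or, with
probability `p_false_dx`, a *near-miss* pattern chosen from the
misclassification modes chart review is known to surface: abdominal-only
coding, a single TAV with a nonspecific code, a single nonspecific encounter
without methotrexate. Under zero noise the generator and enhanced classifier
are exact inverses, so pipeline sensitivity and specificity are exactly
100% — passing that test shows the rules and generator agree on the rule
geometry; it says nothing about performance on real coding behavior, which
only a chart-review validation can establish.

### Noise model and its closed-form expectation

Noise channels: `p_drop_dx` drops each EP diagnosis-code *instance*
independently; `p_abdominal_only` recodes a true case's diagnoses as
abdominal; `p_mtx_outside_window` displaces a methotrexate record to day
+201 (outside attachment). With `q = 1 − p_drop_dx`, survival of a true case
by branch pattern:

* B1 (two single-code encounters): `q²`, plus `2qp` when methotrexate is
  present (a single surviving nonspecific encounter is rescued through B4);
* B2 (two TAVs + methotrexate): `q² + 2qp` when the methotrexate record is
  in-window, else 0;
* B3, B5 (one diagnosis instance): `q`;
* B4: `q` when methotrexate is in-window, else 0;
* abdominal-recoded cases survive only as B5 patterns with the diagnosis
  kept (`q`), since every other branch ignores abdominal codes.

`expected_sensitivity` sums these over the management-conditional branch
distribution. The formula is written independently of the classifier code
path, and simulated sensitivity at n=10,000 is tested to lie within 3
binomial standard errors of it — this validates that the injected noise
matches the stated model.

## Problem sizes

The shipped checks use n=5,000 patients for zero-noise recovery, n=10,000
for the noise response, 10,000 random episodes for the
enhanced-vs-configurable equivalence, and 1,000 random matrices for the
metric identities — sizes at which the binomial standard error of the noise
check (≈0.35 percentage points) is well below the effects being measured,
while the whole suite runs in seconds.

## Known limitations

* Default code lists are placeholders outside the six printed diagnosis
  codes; results on real data depend entirely on the site-supplied registry.
* No ICD-9↔ICD-10 equivalence mapping, OMOP/FHIR ingestion, or
  probabilistic/ML phenotyping.
* The comparison variant approximates the earlier algorithm only up to its
  documented differences.
* Management classification does not distinguish laparoscopy from
  laparotomy, nor model methotrexate dosing; non-EP tubal-surgery codes can
  be added to the surgery registry category by configuration but are not
  shipped.
* Inter-algorithm κ on real data cannot be reproduced here: the joint
  labels behind the published estimate are not available.
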