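"""Validation-metric suite on the embedded reference count matrices.

Feeds the published 500-case validation cross-tabulations through
`binary_metrics` and the 3x3 management matrix through the agreement report,
printing the full statistic suite (percent, one decimal, half-up) with the
(n/N) fractions each number comes from.
"""

from eppheno import binary_metrics, management_agreement_from_matrix
from eppheno.reference import COMPARISON_FULL, ENHANCED_FULL, MANAGEMENT_3X3

print("Enhanced algorithm vs chart review (n=500):")
print(binary_metrics(ENHANCED_FULL))

print("\nComparison algorithm vs chart review (n=500):")
print(binary_metrics(COMPARISON_FULL))

print("\nManagement agreement, electronic vs chart review (n=326):")
print(management_agreement_from_matrix(MANAGEMENT_3X3))

print(
    "\nSensitivity is the share of chart-confirmed cases the algorithm found; "
    "PPV the share of algorithm positives that were real; the Youden index "
    "(sens+spec-100) and F-score (harmonic mean of PPV and sensitivity) "
    "summarize overall performance."
)
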