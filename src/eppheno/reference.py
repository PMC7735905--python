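"""Reference count matrices from the chart-review validation of the algorithm.

These are the published cross-tabulations of algorithm classification against
the chart-review gold standard for the 500-case validation sample (and the
307-case 2009–2014 ICD-9-only subset), plus the 3x3 management-agreement
counts on the 326 cases confirmed by both chart review and the enhanced
algorithm.  They serve as fixtures for the metric suite: feeding them through
:func:`eppheno.metrics.binary_metrics` reproduces the published performance
statistics.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix2x2

__all__ = [
    "ENHANCED_FULL",
    "COMPARISON_FULL",
    "ENHANCED_ICD9_SUBSET",
    "COMPARISON_ICD9_SUBSET",
    "MANAGEMENT_3X3",
]

# Full validation sample (n=500): rows of the published 2x2 are chart review
# yes/no, columns algorithm yes/no.
ENHANCED_FULL = ConfusionMatrix2x2(tp=326, fn=8, fp=25, tn=141)
COMPARISON_FULL = ConfusionMatrix2x2(tp=315, fn=19, fp=26, tn=140)

# 2009-2014 ICD-9-only subset (n=307).
ENHANCED_ICD9_SUBSET = ConfusionMatrix2x2(tp=212, fn=6, fp=16, tn=73)
COMPARISON_ICD9_SUBSET = ConfusionMatrix2x2(tp=206, fn=12, fp=16, tn=73)

# Management agreement on the 326 doubly confirmed cases:
# rows = chart review {surgical, medical, unclassified}, cols = electronic.
MANAGEMENT_3X3 = (
    (181, 5, 11),
    (5, 118, 3),
    (0, 1, 2),
)
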