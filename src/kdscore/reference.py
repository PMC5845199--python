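"""Published reference counts for the six models' external validation.

These are the high/low-risk × resistant/responsive contingency counts
reported when the six scores were applied to a single-center cohort of
504 Kawasaki-disease patients (25 IVIG-resistant, 479 responsive; the
ratio-based combination rule lost 76 patients to incomplete
differential counts).  They are *inputs* to the package — published
integers against which the diagnostic-accuracy routines can be
exercised and checked — not outputs of it.
"""

from __future__ import annotations

from .diagnostics import ConfusionMatrix

#: Cohort margins of the reference validation study.
REFERENCE_COHORT_N = 504
REFERENCE_RESISTANT_N = 25

#: (tp, fp, fn, tn, n_excluded) per model, in the published row order.
REFERENCE_TABLE3_COUNTS: dict[str, tuple[int, int, int, int, int]] = {
    "kobayashi": (18, 184, 7, 295, 0),
    "egami": (11, 88, 14, 391, 0),
    "kawamura": (10, 140, 11, 267, 76),
    "sano": (5, 43, 20, 436, 0),
    "formosa": (17, 248, 8, 231, 0),
    "ours": (18, 120, 7, 359, 0),
}


def reference_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The published per-model 2×2 counts as :class:`ConfusionMatrix`."""
    return {name: ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded=ex)
            for name, (tp, fp, fn, tn, ex) in REFERENCE_TABLE3_COUNTS.items()}
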