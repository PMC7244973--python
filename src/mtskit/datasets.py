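"""Packaged worked example: a published L16 blood-biomarker screening.

A published asthma-diagnosis study assigned 14 complete-blood-count
variables to the first 14 columns of a 16-run two-level orthogonal array
and reported the per-run larger-the-better SN ratios of the asthma group's
Mahalanobis distances.  The design matrix and SN ratios are reproduced
here verbatim so the level-mean/gain arithmetic and the positive-gain
selection rule can be exercised end-to-end without the (non-deposited)
clinical data.  Expected outcome: seven variables carry positive gain —
PDW, MPV, WBC, EO#, LY, LY#, MCHC — with PDW's gain (about 5.11 dB)
dominating.
"""

from __future__ import annotations

import numpy as np

from .taguchi import OrthogonalArray, SNTable, compute_gains

__all__ = [
    "BLOOD_SCREEN_VARIABLES",
    "blood_screen_design",
    "blood_screen_sn_ratios",
    "blood_screen_experiment",
]

#: The 14 complete-blood-count variables assigned to array columns, in
#: column order: basophil count, eosinophil count, lymphocyte ratio,
#: lymphocyte count, mean corpuscular hemoglobin (and concentration),
#: monocyte ratio and count, mean platelet volume, platelet distribution
#: width, platelet count, red cell count, red cell distribution width,
#: white cell count.
BLOOD_SCREEN_VARIABLES: tuple[str, ...] = (
    "BA#", "EO#", "LY", "LY#", "MCH", "MCHC", "MO",
    "MO#", "MPV", "PDW", "PLT", "RBC", "RDW", "WBC",
)

# 16 runs x 14 assigned columns; 1 = variable included, 2 = excluded.
_DESIGN = (
    (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1),
    (1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2),
    (1, 1, 1, 2, 2, 2, 2, 1, 1, 1, 1, 2, 2, 2),
    (1, 1, 1, 2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1),
    (1, 2, 2, 1, 1, 2, 2, 1, 1, 2, 2, 1, 1, 2),
    (1, 2, 2, 1, 1, 2, 2, 2, 2, 1, 1, 2, 2, 1),
    (1, 2, 2, 2, 2, 1, 1, 1, 1, 2, 2, 2, 2, 1),
    (1, 2, 2, 2, 2, 1, 1, 2, 2, 1, 1, 1, 1, 2),
    (2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1),
    (2, 1, 2, 1, 2, 1, 2, 2, 1, 2, 1, 2, 1, 2),
    (2, 1, 2, 2, 1, 2, 1, 1, 2, 1, 2, 2, 1, 2),
    (2, 1, 2, 2, 1, 2, 1, 2, 1, 2, 1, 1, 2, 1),
    (2, 2, 1, 1, 2, 2, 1, 1, 2, 2, 1, 1, 2, 2),
    (2, 2, 1, 1, 2, 2, 1, 2, 1, 1, 2, 2, 1, 1),
    (2, 2, 1, 2, 1, 1, 2, 1, 2, 2, 1, 2, 1, 1),
    (2, 2, 1, 2, 1, 1, 2, 2, 1, 1, 2, 1, 2, 2),
)

# Published per-run larger-the-better SN ratios (dB), runs 1..16.
_SN_RATIOS = (
    8.29, 3.36, 8.38, 3.10, 2.94, 7.87, 2.98, 7.16,
    8.40, 3.54, 7.34, 3.70, 2.10, 9.36, 2.72, 8.50,
)


def blood_screen_design() -> OrthogonalArray:
    """The published 16-run design matrix (14 assigned columns)."""
    return OrthogonalArray(np.array(_DESIGN, dtype=int))


def blood_screen_sn_ratios() -> np.ndarray:
    """The 16 published per-run SN ratios, in decibels."""
    return np.array(_SN_RATIOS, dtype=float)


def blood_screen_experiment() -> SNTable:
    """Recompute level means and gains from the published design and SN ratios."""
    oa = blood_screen_design()
    assignment = {v: i for i, v in enumerate(BLOOD_SCREEN_VARIABLES)}
    return compute_gains(blood_screen_sn_ratios(), oa, assignment)
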