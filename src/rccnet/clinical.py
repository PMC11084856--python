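"""Reference clinical cohort: 50 patients with histopathologically
confirmed renal-tumor subtypes.

These published summary data accompany the classifier as fixtures: the
four worked-example patient vectors (one per subtype, peak enhancement in
HU across the four phases), the cohort composition, mean lesion sizes, and
the diagnostic outcome counts from which per-class accuracy and overall
concordance with histopathology are recomputed.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CohortCounts
from .subtypes import Subtype

__all__ = [
    "WORKED_EXAMPLES",
    "CLINICAL_COUNTS",
    "COHORT_COMPOSITION",
    "MEAN_LESION_SIZE_CM",
]

#: One measured patient vector per subtype:
#: (unenhanced, corticomedullary, nephrographic, excretory) peak HU.
WORKED_EXAMPLES: dict[Subtype, tuple[float, float, float, float]] = {
    Subtype.CCC: (54.0, 163.0, 120.0, 77.0),
    Subtype.PPC: (32.0, 53.0, 65.0, 56.0),
    Subtype.CPC: (28.0, 74.0, 85.0, 60.0),
    Subtype.OCC: (17.0, 99.0, 80.0, 68.0),
}

#: Subtype incidence among the 50 clinical cases.
COHORT_COMPOSITION: dict[str, int] = {"CCC": 25, "PPC": 12, "CPC": 5, "OCC": 8}

#: Mean lesion diameter (cm) per subtype — descriptive only.
MEAN_LESION_SIZE_CM: dict[str, float] = {"CCC": 3.7, "PPC": 2.8, "CPC": 3.5, "OCC": 3.1}

#: Diagnostic outcomes of the classifier against histopathology:
#: 6/25 CCC read as OCC, 5/12 PPC as CCC, 2/5 CPC as OCC, 3/8 OCC as CCC.
CLINICAL_COUNTS = CohortCounts(
    n={"CCC": 25, "PPC": 12, "CPC": 5, "OCC": 8},
    n_correct={"CCC": 19, "PPC": 7, "CPC": 3, "OCC": 5},
    misclassified_as={
        "CCC": {"OCC": 6},
        "PPC": {"CCC": 5},
        "CPC": {"OCC": 2},
        "OCC": {"CCC": 3},
    },
)


def worked_example_matrix() -> tuple[np.ndarray, np.ndarray]:
    """The four worked-example vectors as an (4, 4) array with their
    true subtype indices, in PPC, CPC, OCC, CCC order."""
    order = [Subtype.PPC, Subtype.CPC, Subtype.OCC, Subtype.CCC]
    X = np.array([WORKED_EXAMPLES[s] for s in order])
    y = np.array([int(s) for s in order])
    return X, y
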