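"""Renal-tumor subtype labels and the four contrast-phase feature axes.

The classifier operates on one lesion's peak CT attenuation (Hounsfield
Units) measured in four acquisition phases: unenhanced, corticomedullary,
nephrographic and excretory.  Four histologic subtypes are distinguished,
in a fixed order that every array in the package shares:

    0 PPC  papillary renal cell carcinoma
    1 CPC  chromophobe renal cell carcinoma
    2 OCC  oncocytoma (benign mimic)
    3 CCC  clear cell renal cell carcinoma
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = ["Subtype", "SUBTYPES", "PHASES", "N_SUBTYPES", "N_PHASES", "parse_subtype"]


class Subtype(enum.IntEnum):
    """Histologic subtype, ordered PPC, CPC, OCC, CCC.

    The integer value is the class index used by every array, label vector
    and confusion-matrix axis in the package; the order is immutable.
    """

    PPC = 0
    CPC = 1
    OCC = 2
    CCC = 3

    @property
    def onehot(self) -> np.ndarray:
        """Length-4 one-hot encoding of this subtype."""
        v = np.zeros(4)
        v[self.value] = 1.0
        return v

    @property
    def full_name(self) -> str:
        return _FULL_NAMES[self]


_FULL_NAMES = {
    Subtype.PPC: "papillary renal cell carcinoma",
    Subtype.CPC: "chromophobe renal cell carcinoma",
    Subtype.OCC: "oncocytoma",
    Subtype.CCC: "clear cell renal cell carcinoma",
}

SUBTYPES: tuple[Subtype, ...] = tuple(Subtype)
N_SUBTYPES = 4

#: Contrast phases in acquisition order; also the feature order of every
#: four-vector the package handles.
PHASES: tuple[str, ...] = ("unenhanced", "corticomedullary", "nephrographic", "excretory")
N_PHASES = 4


def parse_subtype(text: str) -> Subtype:
    """Parse a subtype code case-insensitively.

    Raises
    ------
    ValueError
        If ``text`` is not one of PPC, CPC, OCC, CCC.
    """
    try:
        return Subtype[text.strip().upper()]
    except KeyError:
        raise ValueError(
            f"unknown subtype {text!r}; expected one of "
            + ", ".join(s.name for s in Subtype)
        ) from None
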