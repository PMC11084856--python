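"""Cohort CSV and counts CSV reading/writing.

Cohort CSV schema (one record per row)::

    subtype,unenhanced_hu,corticomedullary_hu,nephrographic_hu,excretory_hu
    CCC,54,163,120,77

Subtype codes parse case-insensitively; a file carrying only the four HU
columns is accepted as an unlabeled batch for prediction.  Counts CSV
schema for clinical-cohort arithmetic::

    subtype,n,n_correct,misclassified_as
    CCC,25,19,OCC:6

where ``misclassified_as`` is an optional ``code:count`` list joined by
semicolons.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import CohortCounts
from .generative import LabeledCohort
from .subtypes import PHASES, parse_subtype

__all__ = [
    "CohortFormatError",
    "HU_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_counts_csv",
    "write_counts_csv",
]

HU_COLUMNS = [f"{p}_hu" for p in PHASES]


class CohortFormatError(ValueError):
    """Malformed cohort or counts CSV; the message names the row."""


def read_cohort_csv(path: str | Path) -> LabeledCohort | np.ndarray:
    """Read a cohort CSV, labeled or unlabeled.

    Returns a :class:`LabeledCohort` when the ``subtype`` column is
    present, otherwise the bare (n, 4) HU array.  Row order is preserved.

    Raises
    ------
    CohortFormatError
        On a missing HU column, an unknown subtype code, or a non-numeric
        HU value — naming the offending row (1-based data rows).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: file is empty") from None
    missing = [c for c in HU_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {', '.join(missing)}")

    X = np.empty((len(df), 4))
    for j, col in enumerate(HU_COLUMNS):
        for i, raw in enumerate(df[col]):
            try:
                X[i, j] = float(raw)
            except (TypeError, ValueError):
                raise CohortFormatError(
                    f"{path}: row {i + 1}: non-numeric {col} value {raw!r}"
                ) from None
    if not np.all(np.isfinite(X)):
        i = int(np.argwhere(~np.isfinite(X))[0][0])
        raise CohortFormatError(f"{path}: row {i + 1}: non-finite HU value")

    if "subtype" not in df.columns:
        return X
    labels = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["subtype"]):
        try:
            labels[i] = parse_subtype(raw)
        except ValueError as e:
            raise CohortFormatError(f"{path}: row {i + 1}: {e}") from None
    return LabeledCohort(X=X, y=labels)


def write_cohort_csv(path: str | Path, cohort: LabeledCohort) -> None:
    cohort.to_frame().to_csv(path, index=False)


def write_unlabeled_csv(path: str | Path, X: np.ndarray) -> None:
    pd.DataFrame(np.asarray(X, dtype=float), columns=HU_COLUMNS).to_csv(
        path, index=False
    )


def read_counts_csv(path: str | Path) -> CohortCounts:
    """Read per-subtype clinical outcome counts."""
    df = pd.read_csv(path, dtype=str)
    for col in ("subtype", "n", "n_correct"):
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing column {col!r}")
    n: dict[str, int] = {}
    n_correct: dict[str, int] = {}
    mis: dict[str, dict[str, int]] = {}
    for i, row in df.iterrows():
        try:
            code = parse_subtype(row["subtype"]).name
            n[code] = int(row["n"])
            n_correct[code] = int(row["n_correct"])
        except (TypeError, ValueError) as e:
            raise CohortFormatError(f"{path}: row {i + 1}: {e}") from None
        mis[code] = {}
        raw = row.get("misclassified_as")
        if isinstance(raw, str) and raw.strip():
            for item in raw.split(";"):
                try:
                    target, cnt = item.split(":")
                    mis[code][parse_subtype(target).name] = int(cnt)
                except ValueError as e:
                    raise CohortFormatError(f"{path}: row {i + 1}: {e}") from None
    try:
        return CohortCounts(n=n, n_correct=n_correct, misclassified_as=mis)
    except ValueError as e:
        raise CohortFormatError(f"{path}: {e}") from None


def write_counts_csv(path: str | Path, counts: CohortCounts) -> None:
    rows = []
    for code in counts.n:
        mis = ";".join(f"{t}:{c}" for t, c in counts.misclassified_as.get(code, {}).items())
        rows.append(
            {
                "subtype": code,
                "n": counts.n[code],
                "n_correct": counts.n_correct[code],
                "misclassified_as": mis,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
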