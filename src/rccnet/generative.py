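"""Gaussian class-conditional simulation of four-phase enhancement cohorts.

No public corpus pairs four-phase peak attenuation vectors with confirmed
renal-tumor subtypes, so training data are simulated: each subtype is a
class-conditional model in which every contrast phase is an independent
normal draw, ``x_p ~ Normal(mean[s, p], sd[s, p])`` for subtype ``s`` and
phase ``p``.  Phases are sampled independently (no covariance) and values
are not truncated to physiologic HU ranges — the class-conditional
densities are exactly the stated normals.

The shipped :func:`default_params` are illustrative stand-ins: the class
means are the four worked-example patient vectors printed for the clinical
cohort, with a common 15 HU standard deviation per phase.  Any external
parameterization is supplied via :meth:`GenerativeParams.from_yaml`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import TextIO

import numpy as np
import pandas as pd
import yaml

from .subtypes import N_PHASES, N_SUBTYPES, PHASES, SUBTYPES, Subtype, parse_subtype

__all__ = [
    "GenerativeParams",
    "LabeledCohort",
    "CohortSummary",
    "default_params",
    "sample_cohort",
    "summarize_cohort",
]


@dataclasses.dataclass(frozen=True)
class GenerativeParams:
    """Per-subtype, per-phase normal parameters defining the simulator.

    Parameters
    ----------
    mean : (4, 4) ndarray
        Mean peak enhancement in HU; rows are subtypes in PPC, CPC, OCC,
        CCC order, columns the phases in acquisition order.
    sd : (4, 4) ndarray
        Per-phase standard deviations in HU, all >= 0.
    priors : (4,) ndarray
        Class prior probabilities; uniform by default.  Used by the Bayes
        oracle and by prevalence-weighted sampling, never by balanced
        sampling.
    """

    mean: np.ndarray
    sd: np.ndarray
    priors: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(N_SUBTYPES, 0.25)
    )

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        priors = np.asarray(self.priors, dtype=float)
        if mean.shape != (N_SUBTYPES, N_PHASES):
            raise ValueError(f"mean must be 4x4, got {mean.shape}")
        if sd.shape != (N_SUBTYPES, N_PHASES):
            raise ValueError(f"sd must be 4x4, got {sd.shape}")
        if not np.all(np.isfinite(mean)):
            raise ValueError("mean contains non-finite entries")
        if not np.all(np.isfinite(sd)) or np.any(sd < 0):
            raise ValueError("sd entries must be finite and >= 0")
        if priors.shape != (N_SUBTYPES,) or np.any(priors < 0):
            raise ValueError("priors must be a length-4 non-negative vector")
        if not np.isclose(priors.sum(), 1.0, atol=1e-9):
            raise ValueError(f"priors must sum to 1, got {priors.sum()}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "priors", priors)

    def fingerprint(self) -> str:
        """Short stable hash of the parameter values, for model provenance."""
        h = hashlib.sha256()
        for a in (self.mean, self.sd, self.priors):
            h.update(np.ascontiguousarray(a, dtype=float).tobytes())
        return h.hexdigest()[:16]

    # -- config round trip ------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for s in SUBTYPES:
            out[s.name] = {
                "mean": {p: float(self.mean[s, i]) for i, p in enumerate(PHASES)},
                "sd": {p: float(self.sd[s, i]) for i, p in enumerate(PHASES)},
            }
        out["priors"] = [float(p) for p in self.priors]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        mean = np.zeros((N_SUBTYPES, N_PHASES))
        sd = np.zeros((N_SUBTYPES, N_PHASES))
        for s in SUBTYPES:
            try:
                block = d[s.name]
            except KeyError:
                raise ValueError(f"config missing subtype block {s.name!r}") from None
            for i, p in enumerate(PHASES):
                try:
                    mean[s, i] = float(block["mean"][p])
                    sd[s, i] = float(block["sd"][p])
                except KeyError as e:
                    raise ValueError(
                        f"config block {s.name!r} missing key {e.args[0]!r}"
                    ) from None
        priors = np.asarray(d.get("priors", [0.25] * 4), dtype=float)
        return cls(mean=mean, sd=sd, priors=priors)

    def to_yaml(self, stream: TextIO | None = None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream: TextIO | str) -> "GenerativeParams":
        return cls.from_dict(yaml.safe_load(stream))


#: Printed four-phase patient vectors (HU) used as illustrative class means,
#: in PPC, CPC, OCC, CCC order.
_EXAMPLE_MEANS = np.array(
    [
        [32.0, 53.0, 65.0, 56.0],   # PPC: weak, homogeneous enhancement
        [28.0, 74.0, 85.0, 60.0],   # CPC: intermediate enhancement
        [17.0, 99.0, 80.0, 68.0],   # OCC: benign mimic, brisk enhancement
        [54.0, 163.0, 120.0, 77.0], # CCC: strongest corticomedullary peak
    ]
)

_DEFAULT_SD_HU = 15.0


def default_params() -> GenerativeParams:
    """Illustrative default simulator parameters.

    Class means are the four published worked-example patient vectors and
    every per-phase SD is 15 HU, with uniform priors.  These are documented
    stand-ins, not literature population parameters; override them with a
    YAML config to emulate any external parameterization.
    """
    return GenerativeParams(
        mean=_EXAMPLE_MEANS.copy(),
        sd=np.full((N_SUBTYPES, N_PHASES), _DEFAULT_SD_HU),
    )


@dataclasses.dataclass(frozen=True)
class LabeledCohort:
    """A simulated (or loaded) labeled cohort of four-phase vectors.

    Attributes
    ----------
    X : (n, 4) ndarray
        Peak enhancement vectors, HU, phases in acquisition order.
    y : (n,) ndarray of int
        Subtype indices (PPC=0, CPC=1, OCC=2, CCC=3).
    seed : int or None
        Seed used to draw the cohort; None for loaded data.
    params_used : GenerativeParams or None
    """

    X: np.ndarray
    y: np.ndarray
    seed: int | None = None
    params_used: GenerativeParams | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=np.int64)
        if X.ndim != 2 or X.shape[1] != N_PHASES:
            raise ValueError(f"X must be (n, 4), got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X rows")
        if len(y) and (y.min() < 0 or y.max() >= N_SUBTYPES):
            raise ValueError("labels must be subtype indices 0..3")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{p}_hu" for p in PHASES])
        df.insert(0, "subtype", [Subtype(i).name for i in self.y])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledCohort":
        cols = [f"{p}_hu" for p in PHASES]
        y = np.array([parse_subtype(s) for s in df["subtype"]], dtype=np.int64)
        return cls(X=df[cols].to_numpy(dtype=float), y=y)


def sample_cohort(
    params: GenerativeParams,
    n_per_class: int,
    seed: int,
    *,
    weighted: bool = False,
) -> LabeledCohort:
    """Draw a labeled cohort from the Gaussian class-conditional model.

    With ``weighted=False`` (default, matching balanced training) exactly
    ``n_per_class`` records are drawn per subtype, subtype-major, and each
    phase of a record is an independent ``Normal(mean[s, p], sd[s, p])``
    draw.  With ``weighted=True`` the total ``4 * n_per_class`` labels are
    drawn i.i.d. from ``params.priors`` instead, emulating a clinical
    prevalence mix.

    A single seeded generator drives all draws in (subtype, record, phase)
    order, so identical arguments yield bit-identical cohorts.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(seed)
    if weighted:
        n_total = N_SUBTYPES * n_per_class
        y = rng.choice(N_SUBTYPES, size=n_total, p=params.priors)
        X = params.mean[y] + params.sd[y] * rng.standard_normal((n_total, N_PHASES))
    else:
        blocks = []
        for s in range(N_SUBTYPES):
            z = rng.standard_normal((n_per_class, N_PHASES))
            blocks.append(params.mean[s] + params.sd[s] * z)
        X = np.concatenate(blocks, axis=0)
        y = np.repeat(np.arange(N_SUBTYPES), n_per_class)
    return LabeledCohort(X=X, y=y, seed=seed, params_used=params)


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Per-subtype composition and per-phase sample moments of a cohort."""

    counts: pd.Series            # index: subtype code, int counts
    proportions: pd.Series       # percentages, sum to 100
    phase_means: pd.DataFrame    # subtype x phase sample means (HU)
    phase_sds: pd.DataFrame      # subtype x phase unbiased sample SDs (HU)
    sd_undefined: pd.Series      # True where n < 2 (SD reported as 0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        lines = [f"cohort of {self.total} records"]
        for s in SUBTYPES:
            lines.append(
                f"  {s.name}: n={self.counts[s.name]:>6d}  "
                f"({self.proportions[s.name]:.1f}%)"
            )
        return "\n".join(lines)


def summarize_cohort(cohort: LabeledCohort) -> CohortSummary:
    """Composition counts/proportions and per-phase moments of a cohort.

    SDs are the unbiased (ddof=1) sample estimates; a class with a single
    record has an undefined SD, reported as 0 and flagged in
    ``sd_undefined``.  Absent classes have count 0 and NaN moments.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    names = [s.name for s in SUBTYPES]
    counts = pd.Series(
        np.bincount(cohort.y, minlength=N_SUBTYPES), index=names, name="n"
    )
    proportions = 100.0 * counts / counts.sum()
    means = np.full((N_SUBTYPES, N_PHASES), np.nan)
    sds = np.full((N_SUBTYPES, N_PHASES), np.nan)
    undefined = np.zeros(N_SUBTYPES, dtype=bool)
    for s in range(N_SUBTYPES):
        block = cohort.X[cohort.y == s]
        if len(block) == 0:
            continue
        means[s] = block.mean(axis=0)
        if len(block) >= 2:
            sds[s] = block.std(axis=0, ddof=1)
        else:
            sds[s] = 0.0
            undefined[s] = True
    return CohortSummary(
        counts=counts,
        proportions=proportions.rename("percent"),
        phase_means=pd.DataFrame(means, index=names, columns=PHASES),
        phase_sds=pd.DataFrame(sds, index=names, columns=PHASES),
        sd_undefined=pd.Series(undefined, index=names, name="sd_undefined"),
    )
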