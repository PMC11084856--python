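"""Bayes-optimal oracle and evaluation arithmetic.

Under the Gaussian class-conditional simulator the optimal classifier is
available in closed form: with independent per-phase normals the class
posterior is

    P(s | x)  ∝  prior[s] * Π_p  N(x_p; mean[s, p], sd[s, p]),

a diagonal-covariance Gaussian discriminant.  It is computed in log-space
and serves as the information-theoretic accuracy ceiling against which the
trained network is verified.

The module also provides the reporting arithmetic: row-normalized
confusion matrices (rows = actual subtype, columns = predicted), per-class
diagnostic accuracy and the overall concordance of a clinical cohort with
histopathology.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .generative import GenerativeParams, sample_cohort
from .network import FeatureScaler, NetworkParams, predict_labels
from .subtypes import N_SUBTYPES, SUBTYPES, Subtype

__all__ = [
    "BayesPosterior",
    "BayesClassifier",
    "ConfusionMatrix",
    "CohortCounts",
    "CohortMetrics",
    "bayes_posterior",
    "bayes_labels",
    "confusion_matrix",
    "expected_confusion",
    "cohort_metrics",
    "agreement_rate",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclasses.dataclass(frozen=True)
class BayesPosterior:
    """Posterior over the four subtypes for one phase vector."""

    posterior: np.ndarray
    label: Subtype


def _log_posteriors(X: np.ndarray, params: GenerativeParams) -> np.ndarray:
    """Unnormalized log-posteriors, shape (n, 4); -inf where impossible.

    Zero-SD phases degenerate to a point mass: a class contributes -inf
    unless the observation matches its mean exactly on every such phase.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    with np.errstate(divide="ignore"):
        log_priors = np.log(params.priors)
    out = np.tile(log_priors, (n, 1))
    for s in range(N_SUBTYPES):
        sd = params.sd[s]
        mu = params.mean[s]
        ll = np.zeros(n)
        pos = sd > 0
        if pos.any():
            zsc = (X[:, pos] - mu[pos]) / sd[pos]
            ll += np.sum(-0.5 * zsc**2 - np.log(sd[pos]) - _LOG_SQRT_2PI, axis=1)
        if (~pos).any():
            exact = np.all(X[:, ~pos] == mu[~pos], axis=1)
            ll = np.where(exact, ll, -np.inf)
        out[:, s] += ll
    return out


def bayes_posterior(x: np.ndarray, params: GenerativeParams) -> BayesPosterior:
    """Closed-form posterior of the generative model at one phase vector.

    Computed in log-space; ties in the argmax break toward the lowest
    class index.  With zero-SD (degenerate) classes the posterior of any
    non-matching class is exactly 0.
    """
    lp = _log_posteriors(x, params)[0]
    if np.all(np.isinf(lp)):
        raise ValueError("observation has zero density under every class")
    lp = lp - lp.max()
    p = np.exp(lp)
    p /= p.sum()
    return BayesPosterior(posterior=p, label=Subtype(int(np.argmax(p))))


def bayes_labels(X: np.ndarray, params: GenerativeParams) -> np.ndarray:
    """Vectorized Bayes-rule labels for an (n, 4) batch."""
    return _log_posteriors(X, params).argmax(axis=1)


@dataclasses.dataclass(frozen=True)
class BayesClassifier:
    """The Bayes rule of a generative model, wrapped as a classifier."""

    params: GenerativeParams

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return bayes_labels(X, self.params)


@dataclasses.dataclass(frozen=True)
class NetworkClassifier:
    """A trained network (plus optional scaler) wrapped as a classifier."""

    net: NetworkParams
    scaler: FeatureScaler | None = None

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return predict_labels(X, self.net, self.scaler)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts and row-normalized percentages; rows are the actual subtype,
    columns the predicted one."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_SUBTYPES, N_SUBTYPES) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 4x4 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def percent(self) -> np.ndarray:
        """Row percentages at full precision (NaN rows for absent classes)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    @property
    def accuracy(self) -> float:
        """Overall fraction correct, in percent."""
        return 100.0 * float(np.trace(self.counts)) / float(self.counts.sum())

    def to_frame(self, *, rounded: bool = True) -> pd.DataFrame:
        names = [s.name for s in SUBTYPES]
        pct = self.percent
        if rounded:
            pct = np.round(pct, 1)
        return pd.DataFrame(pct, index=names, columns=names)

    def to_text(self) -> str:
        df = self.to_frame()
        header = "confusion matrix (rows = actual, columns = predicted, row %)"
        return header + "\n" + df.to_string(float_format=lambda v: f"{v:6.1f}")


def confusion_matrix(predicted, actual) -> ConfusionMatrix:
    """Tally a 4x4 confusion matrix from label sequences.

    ``counts[a, p]`` counts records with actual class ``a`` predicted as
    ``p``.  Percentages are row-normalized; one-decimal rounding is
    applied only for display, full precision is retained internally.
    """
    predicted = np.asarray(predicted, dtype=np.int64)
    actual = np.asarray(actual, dtype=np.int64)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-D sequences")
    if len(predicted) == 0:
        raise ValueError("cannot build a confusion matrix from empty sequences")
    if (
        predicted.min() < 0
        or predicted.max() >= N_SUBTYPES
        or actual.min() < 0
        or actual.max() >= N_SUBTYPES
    ):
        raise ValueError("labels must be subtype indices 0..3")
    counts = np.zeros((N_SUBTYPES, N_SUBTYPES), dtype=np.int64)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts=counts)


def expected_confusion(
    params: GenerativeParams,
    n_mc: int,
    seed: int,
    classifier: BayesClassifier | NetworkClassifier | Callable[[np.ndarray], np.ndarray],
) -> ConfusionMatrix:
    """Monte-Carlo confusion matrix of a classifier under the simulator.

    Draws ``n_mc`` fresh records per class (an independent stream from any
    training seed), classifies them, and tallies the row-normalized
    matrix.  ``classifier`` is a :class:`BayesClassifier`, a
    :class:`NetworkClassifier`, or any callable mapping an (n, 4) array to
    label indices.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if callable(classifier):
        predict_fn = classifier
    elif hasattr(classifier, "predict_labels"):
        predict_fn = classifier.predict_labels
    else:
        raise ValueError(
            "classifier must expose predict_labels() or be callable on an (n, 4) array"
        )
    cohort = sample_cohort(params, n_mc, seed)
    return confusion_matrix(predict_fn(cohort.X), cohort.y)


@dataclasses.dataclass(frozen=True)
class CohortCounts:
    """Per-subtype case counts of a clinical cohort: total, correctly
    diagnosed, and where the misdiagnoses went."""

    n: Mapping[str, int]
    n_correct: Mapping[str, int]
    misclassified_as: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for s in self.n:
            Subtype[s]  # validates the code
            mis = sum(self.misclassified_as.get(s, {}).values())
            if self.n_correct[s] < 0 or self.n[s] < 0:
                raise ValueError(f"negative count for {s}")
            if self.n_correct[s] + mis != self.n[s]:
                raise ValueError(
                    f"{s}: n_correct ({self.n_correct[s]}) + misclassified ({mis}) "
                    f"!= n ({self.n[s]})"
                )

    @property
    def total(self) -> int:
        return sum(self.n.values())

    @property
    def total_correct(self) -> int:
        return sum(self.n_correct.values())


@dataclasses.dataclass(frozen=True)
class CohortMetrics:
    """Per-class diagnostic accuracy and overall concordance (percent)."""

    per_class_accuracy: Mapping[str, float | None]  # full precision; None if n = 0
    overall_concordance: float
    total_n: int
    total_correct: int

    def rounded(self) -> dict[str, float | None]:
        """Display values at one decimal, as conventionally reported."""
        return {
            s: None if a is None else round(a, 1)
            for s, a in self.per_class_accuracy.items()
        }

    @property
    def overall_rounded(self) -> float:
        return round(self.overall_concordance, 1)

    def to_text(self) -> str:
        lines = ["per-class diagnostic accuracy (%)"]
        for s, a in self.rounded().items():
            lines.append(f"  {s}: " + ("undefined (n=0)" if a is None else f"{a:.1f}"))
        lines.append(
            f"overall concordance: {self.overall_rounded:.1f}% "
            f"({self.total_correct}/{self.total_n})"
        )
        return "\n".join(lines)


def cohort_metrics(counts: CohortCounts) -> CohortMetrics:
    """Diagnostic accuracies of a clinical cohort.

    Per-class accuracy is ``100 * n_correct / n`` (undefined, reported as
    None, for absent classes, which still contribute to the totals);
    overall concordance is ``100 * total_correct / total_n``.  Rounding to
    one decimal happens only in :meth:`CohortMetrics.rounded`.
    """
    per_class: dict[str, float | None] = {}
    for s in counts.n:
        per_class[s] = (
            None if counts.n[s] == 0 else 100.0 * counts.n_correct[s] / counts.n[s]
        )
    if counts.total == 0:
        raise ValueError("cohort has no cases")
    return CohortMetrics(
        per_class_accuracy=per_class,
        overall_concordance=100.0 * counts.total_correct / counts.total,
        total_n=counts.total,
        total_correct=counts.total_correct,
    )


def agreement_rate(
    net: NetworkParams,
    params: GenerativeParams,
    n_per_class: int,
    seed: int,
    scaler: FeatureScaler | None = None,
) -> float:
    """Label agreement (percent) between the network and the Bayes rule
    on a freshly sampled balanced cohort."""
    cohort = sample_cohort(params, n_per_class, seed)
    net_y = predict_labels(cohort.X, net, scaler)
    bayes_y = bayes_labels(cohort.X, params)
    return 100.0 * float(np.mean(net_y == bayes_y))
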