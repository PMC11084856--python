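"""Model/Results interface for the subtype classifier.

:class:`SubtypeClassifier` is the model object: it holds a labeled
training cohort (simulated or loaded) together with the generative
parameters, and :meth:`SubtypeClassifier.fit` runs cross-entropy training
and returns a :class:`SubtypeClassifierResults` carrying the trained
network, the training trace, diagnostic methods (confusion matrix against
fresh draws, agreement with the Bayes oracle) and a ``summary()`` table.

Typical use::

    params = default_params()
    model = SubtypeClassifier.from_generative(params, n_per_class=8000, seed=7)
    res = model.fit(seed=7)
    print(res.summary())
    res.predict([[54, 163, 120, 77]])
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net_mod
from .evaluation import (
    BayesClassifier,
    ConfusionMatrix,
    NetworkClassifier,
    agreement_rate,
    bayes_labels,
    expected_confusion,
)
from .generative import GenerativeParams, LabeledCohort, sample_cohort
from .network import (
    FeatureScaler,
    NetworkParams,
    TrainingConfig,
    TrainingReport,
    predict_labels,
)
from .subtypes import PHASES, SUBTYPES, Subtype

__all__ = ["SubtypeClassifier", "SubtypeClassifierResults"]


class SubtypeClassifier:
    """Four-phase CT renal-tumor subtype classifier (model object).

    Parameters
    ----------
    cohort : LabeledCohort
        Training data: (n, 4) HU vectors with subtype labels.
    params : GenerativeParams, optional
        Generative model the cohort was drawn from; enables the Bayes
        oracle diagnostics on the fitted results.
    """

    def __init__(self, cohort: LabeledCohort, params: GenerativeParams | None = None):
        self.cohort = cohort
        self.params = params if params is not None else cohort.params_used

    @classmethod
    def from_generative(
        cls,
        params: GenerativeParams,
        n_per_class: int,
        seed: int,
        *,
        weighted: bool = False,
    ) -> "SubtypeClassifier":
        """Simulate a training cohort from the generative model."""
        return cls(sample_cohort(params, n_per_class, seed, weighted=weighted), params)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, params: GenerativeParams | None = None
    ) -> "SubtypeClassifier":
        """Build from a cohort DataFrame (``subtype`` + four ``*_hu`` columns)."""
        return cls(LabeledCohort.from_frame(df), params)

    def fit(
        self, config: TrainingConfig | None = None, **kwargs
    ) -> "SubtypeClassifierResults":
        """Train the network; keyword arguments override TrainingConfig
        fields (e.g. ``fit(seed=3, max_epochs=20)``)."""
        if config is None:
            config = TrainingConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a TrainingConfig or keyword overrides, not both")
        net, report, scaler = net_mod.train(self.cohort, config)
        return SubtypeClassifierResults(self, net, report, scaler)


class SubtypeClassifierResults:
    """Fitted classifier: trained parameters, training trace, diagnostics."""

    def __init__(
        self,
        model: SubtypeClassifier,
        net: NetworkParams,
        report: TrainingReport,
        scaler: FeatureScaler | None,
    ):
        self.model = model
        self.net = net
        self.report = report
        self.scaler = scaler

    # -- prediction -------------------------------------------------------

    def predict_one(self, x) -> tuple[Subtype, float, np.ndarray]:
        """Label, confidence (percent) and softmax vector for one record."""
        return net_mod.predict(np.asarray(x, dtype=float), self.net, self.scaler)

    def predict(self, X) -> pd.DataFrame:
        """Batch prediction.

        Returns a DataFrame with the predicted subtype code, the
        confidence ``100 * max(z)`` and the four softmax entries.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = self.scaler.transform(X) if self.scaler is not None else X
        Z = net_mod.forward(Xs, self.net)
        labels = Z.argmax(axis=1)
        out = pd.DataFrame(
            {
                "subtype": [Subtype(i).name for i in labels],
                "confidence_pct": 100.0 * Z.max(axis=1),
            }
        )
        for i, s in enumerate(SUBTYPES):
            out[f"z_{s.name}"] = Z[:, i]
        return out

    # -- diagnostics ------------------------------------------------------

    def confusion_matrix(
        self, n_per_class: int = 5000, seed: int = 0
    ) -> ConfusionMatrix:
        """Row-normalized confusion matrix on fresh simulator draws."""
        self._require_params()
        return expected_confusion(
            self.model.params, n_per_class, seed, NetworkClassifier(self.net, self.scaler)
        )

    def bayes_confusion_matrix(
        self, n_per_class: int = 5000, seed: int = 0
    ) -> ConfusionMatrix:
        """Same fresh-draw matrix for the Bayes-optimal oracle."""
        self._require_params()
        return expected_confusion(
            self.model.params, n_per_class, seed, BayesClassifier(self.model.params)
        )

    def agreement_with_bayes(self, n_per_class: int = 2000, seed: int = 0) -> float:
        """Percent label agreement with the Bayes rule on fresh draws."""
        self._require_params()
        return agreement_rate(
            self.net, self.model.params, n_per_class, seed, self.scaler
        )

    def heldout_accuracy(
        self, n_per_class: int = 2000, seed: int = 0
    ) -> tuple[float, float]:
        """(network, Bayes-oracle) percent accuracy on one fresh sample."""
        self._require_params()
        cohort = sample_cohort(self.model.params, n_per_class, seed)
        net_acc = 100.0 * float(
            np.mean(predict_labels(cohort.X, self.net, self.scaler) == cohort.y)
        )
        bayes_acc = 100.0 * float(
            np.mean(bayes_labels(cohort.X, self.model.params) == cohort.y)
        )
        return net_acc, bayes_acc

    def _require_params(self) -> None:
        if self.model.params is None:
            raise ValueError(
                "generative parameters unknown; construct the model with params "
                "to enable simulator-based diagnostics"
            )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        r = self.report
        lines = [
            "Renal-tumor subtype classifier — fit summary",
            "=" * 52,
            f"architecture          4 -> 50 (ReLU) -> 50 (ReLU) -> 4 (softmax)",
            f"trainable parameters  {self.net.n_parameters}",
            f"training records      {len(self.model.cohort)}",
            f"epochs run            {r.epochs_run} (max {r.config.max_epochs})",
            f"final train loss      {r.train_loss[-1]:.4f}",
            f"final train accuracy  {100 * r.train_accuracy[-1]:.1f}%",
        ]
        if r.val_loss:
            lines.append(f"final val accuracy    {100 * r.val_accuracy[-1]:.1f}%")
        lines.append(
            f"feature scaling       "
            + ("per-phase standardization" if self.scaler else "raw HU")
        )
        if self.model.params is not None:
            lines.append(f"simulator fingerprint {self.model.params.fingerprint()}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        fingerprint = (
            self.model.params.fingerprint() if self.model.params is not None else None
        )
        net_mod.save_model(
            self.net,
            path,
            scaler=self.scaler,
            training_config=self.report.config,
            params_fingerprint=fingerprint,
        )

    # -- plotting (optional, requires matplotlib) -------------------------

    def plot_training(self, ax=None):
        """Training/validation loss trace per epoch."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, self.report.epochs_run + 1)
        ax.plot(epochs, self.report.train_loss, label="train")
        if self.report.val_loss:
            ax.plot(epochs, self.report.val_loss, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        ax.legend()
        return ax

    def plot_confusion(self, n_per_class: int = 2000, seed: int = 0, ax=None):
        """Heatmap of the fresh-draw confusion matrix (row percent)."""
        import matplotlib.pyplot as plt

        cm = self.confusion_matrix(n_per_class, seed)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(cm.percent, vmin=0, vmax=100, cmap="Blues")
        names = [s.name for s in SUBTYPES]
        ax.set_xticks(range(4), names)
        ax.set_yticks(range(4), names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("actual")
        for i in range(4):
            for j in range(4):
                ax.text(j, i, f"{cm.percent[i, j]:.1f}", ha="center", va="center")
        ax.figure.colorbar(im, ax=ax, label="row %")
        return ax
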