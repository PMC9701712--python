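"""Model / Results interface over the promoter-prediction pipeline.

Follows the fitted-model idiom of statistical modelling packages: a
:class:`Sigma70PromoterModel` is constructed from labeled training sequences,
``fit()`` runs cross-validated evaluation plus a final full-data fit, and the
returned :class:`Sigma70PromoterResults` carries the trained artifacts, the
per-fold and mean performance measures, a ``summary()`` table, and the
application modes (predict / scan / design) as methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import apps
from .encoders import EncoderConfig
from .pipeline import (
    FoldResult,
    MetricSet,
    TrainedModel,
    cross_validate,
    fit_chain,
    load_model,
    save_model,
)
from .seqio import NucleotideSequence, read_sequences

METRIC_COLUMNS = ["Sensitivity", "Specificity", "Accuracy", "AUROC", "MCC"]


class Sigma70PromoterModel:
    """Sigma70 promoter classifier over 81-bp sequence windows.

    Parameters
    ----------
    pos, neg:
        Labeled training sequences (promoters / non-promoters), each exactly
        81 bp.
    encoder_config:
        Feature-encoder configuration; defaults cover every family.
    classifier:
        Backend kind: DT, RF, KNN, XGB, GNB or SVM (default).
    """

    def __init__(
        self,
        pos: list[NucleotideSequence],
        neg: list[NucleotideSequence],
        encoder_config: EncoderConfig | None = None,
        classifier: str = "SVM",
    ):
        if not pos or not neg:
            raise ValueError("both classes must be non-empty")
        self.pos = list(pos)
        self.neg = list(neg)
        self.encoder_config = encoder_config or EncoderConfig()
        self.classifier = classifier

    @classmethod
    def from_fasta(
        cls,
        pos_path,
        neg_path,
        encoder_config: EncoderConfig | None = None,
        classifier: str = "SVM",
        dialect: str = "auto",
    ) -> "Sigma70PromoterModel":
        return cls(
            read_sequences(pos_path, dialect),
            read_sequences(neg_path, dialect),
            encoder_config,
            classifier,
        )

    def fit(
        self,
        n_features: int = 200,
        step: int = 10,
        cv: int = 5,
        seed: int = 0,
        threshold: float = 0.5,
        hyperparameters: dict | None = None,
    ) -> "Sigma70PromoterResults":
        """Cross-validate the full chain, then fit it on all training data.

        ``cv``-fold stratified evaluation refits the entire data-dependent
        chain (PSTNP table, scaler, RFE, classifier) inside each fold; the
        shipped model is a separate fit on the complete training set.
        """
        folds, mean = cross_validate(
            self.pos,
            self.neg,
            self.encoder_config,
            kind=self.classifier,
            k=cv,
            seed=seed,
            n_features=n_features,
            step=step,
            threshold=threshold,
            hyperparameters=hyperparameters,
        )
        trained = fit_chain(
            self.pos,
            self.neg,
            self.encoder_config,
            kind=self.classifier,
            n_features=n_features,
            step=step,
            seed=seed,
            threshold=threshold,
            hyperparameters=hyperparameters,
        )
        return Sigma70PromoterResults(self, trained, folds, mean)


@dataclass
class Sigma70PromoterResults:
    """Fitted classifier plus its cross-validated evaluation."""

    model: Sigma70PromoterModel | None
    trained: TrainedModel
    folds: list[FoldResult] = field(default_factory=list)
    mean_metrics: MetricSet | None = None

    # -- reporting ---------------------------------------------------------

    def fold_table(self) -> pd.DataFrame:
        """Per-fold + mean performance (percent columns to 2 decimals, AUROC
        and MCC to 3, matching the usual reporting convention)."""
        if not self.folds:
            raise ValueError("no cross-validation results stored")
        rows = []
        for f in self.folds:
            m = f.metrics
            rows.append([f"fold{f.fold}", m.sensitivity, m.specificity, m.accuracy,
                         m.auroc, m.mcc])
        mm = self.mean_metrics
        rows.append(["mean", mm.sensitivity, mm.specificity, mm.accuracy,
                     mm.auroc, mm.mcc])
        df = pd.DataFrame(rows, columns=["fold"] + METRIC_COLUMNS)
        for c in ("Sensitivity", "Specificity", "Accuracy"):
            df[c] = df[c].round(2)
        for c in ("AUROC", "MCC"):
            df[c] = df[c].round(3)
        return df

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.trained
        lines = [
            "Sigma70 promoter classifier",
            "=" * 60,
            f"classifier:        {t.classifier_kind} {t.hyperparameters}",
            f"training set:      {t.training_metadata.get('n_pos', '?')} promoters / "
            f"{t.training_metadata.get('n_neg', '?')} non-promoters",
            f"selected features: {len(t.selection.selected)} "
            f"(RFE step {t.training_metadata.get('rfe_step', '?')})",
            f"threshold:         {t.default_threshold:g}",
            f"seed:              {t.training_metadata.get('seed', '?')}",
        ]
        if self.folds:
            lines.append("")
            lines.append(f"{len(self.folds)}-fold cross-validation:")
            lines.append(self.fold_table().to_string(index=False))
        return "\n".join(lines)

    def oof_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated out-of-fold (scores, labels) across all folds."""
        scores = np.concatenate([f.scores for f in self.folds])
        labels = np.concatenate([f.labels for f in self.folds])
        return scores, labels

    def plot_roc(self, ax=None):
        """ROC curve of the pooled out-of-fold scores."""
        from sklearn.metrics import roc_curve

        import matplotlib.pyplot as plt

        scores, labels = self.oof_scores()
        fpr, tpr, _ = roc_curve(labels, scores)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr)
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax

    # -- application modes -------------------------------------------------

    def predict(self, seqs, threshold: float | None = None):
        return apps.predict(seqs, self.trained, threshold)

    def scan(self, seq, threshold: float | None = None, revcomp: bool = False):
        return apps.scan(seq, self.trained, threshold, revcomp)

    def design_mutants(self, seq, threshold: float | None = None):
        return apps.design_mutants(seq, self.trained, threshold)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_model(self.trained, path)

    @classmethod
    def load(cls, path) -> "Sigma70PromoterResults":
        return cls(model=None, trained=load_model(path))
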