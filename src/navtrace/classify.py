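"""The two supervised tasks of the analysis.

1. Patient-vs-control classification with a logistic regression trained
   by plain stochastic gradient descent, evaluated leave-one-participant-
   out.  The optimiser is deliberately stochastic — random
   initialisation, sampled gradient steps, a fixed step budget and no
   convergence criterion — and each experiment is repeated (50 runs by
   default) so that the spread of the held-out class probabilities
   quantifies prediction uncertainty.  Sensitivity and specificity
   follow the predicted-class-denominator definitions used with this
   protocol: sensitivity is the fraction of true patients among the
   participants *predicted* as patients, specificity the fraction of
   true controls among those predicted as controls.

2. Alone-vs-accompanied classification of individual patient segments
   with an RBF-kernel support vector machine on raw (standardised)
   segment features, evaluated on repeated random 80/20 splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import ParticipantFeatures, assemble_design

logger = logging.getLogger(__name__)


def sensitivity_specificity(
    y_true: np.ndarray, predicted_control: np.ndarray
) -> tuple[float, float]:
    """Predicted-denominator sensitivity and specificity.

    ``y_true`` is 1 for controls; ``predicted_control`` is boolean.
    Sensitivity = true patients / predicted patients; specificity =
    true controls / predicted controls.  A rate whose denominator is
    empty is undefined and returned as NaN.
    """
    y_true = np.asarray(y_true)
    predicted_control = np.asarray(predicted_control, dtype=bool)
    pred_patient = ~predicted_control
    n_pred_patient = int(pred_patient.sum())
    n_pred_control = int(predicted_control.sum())
    sens = (
        float((pred_patient & (y_true == 0)).sum() / n_pred_patient)
        if n_pred_patient
        else float("nan")
    )
    spec = (
        float((predicted_control & (y_true == 1)).sum() / n_pred_control)
        if n_pred_control
        else float("nan")
    )
    return sens, spec


def _sgd_logistic_probs(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_runs: int,
    n_steps: int,
    learning_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Probabilities of class 1 for ``X_test``, one row per stochastic run.

    Plain logistic loss, no penalty, constant learning rate, standard
    normal random initialisation, single-sample gradient steps with
    indices drawn uniformly with replacement.  All runs are advanced in
    lockstep (vectorised over runs); the randomness per run is
    independent.
    """
    n, p = X_train.shape
    Xa = np.hstack([X_train, np.ones((n, 1))])
    W = rng.standard_normal((n_runs, p + 1))
    idx = rng.integers(0, n, size=(n_steps, n_runs))
    for s in range(n_steps):
        xb = Xa[idx[s]]                      # (runs, p+1)
        z = np.einsum("rj,rj->r", W, xb)
        pr = 1.0 / (1.0 + np.exp(-z))
        W -= learning_rate * ((pr - y_train[idx[s]])[:, None] * xb)
    Xt = np.hstack([X_test, np.ones((len(X_test), 1))])
    return 1.0 / (1.0 + np.exp(-(W @ Xt.T)))


@dataclass
class LooResult:
    """Leave-one-out report over repeated stochastic trainings."""

    participant_ids: list[str]
    y_true: np.ndarray                 # 1 = control
    probabilities: np.ndarray          # (runs, participants) P(control)
    sensitivity: np.ndarray            # per run, NaN when undefined
    specificity: np.ndarray
    median_sensitivity: float = field(init=False)
    median_specificity: float = field(init=False)
    uncertainty: float = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            self.median_sensitivity = float(np.nanmedian(self.sensitivity))
            self.median_specificity = float(np.nanmedian(self.specificity))
        # mean over participants of the SD of their per-run probabilities
        self.uncertainty = float(np.mean(np.std(self.probabilities, axis=0)))


def loo_classify(
    feats: list[ParticipantFeatures],
    feature_subset: list[str],
    runs: int = 50,
    sgd_steps: int = 10000,
    learning_rate: float = 1e-3,
    bins: int = 10,
    seed: int = 0,
) -> LooResult:
    """Leave-one-participant-out logistic-regression classification.

    For every held-out participant the classifier is trained on all
    others and the held-out control-class probability recorded; a
    participant is predicted control when that probability exceeds 0.5.
    The whole procedure runs ``runs`` times with distinct randomness and
    per-run sensitivity/specificity are summarised by their medians.
    """
    if not feature_subset:
        raise ValueError("empty feature subset")
    groups = {f.group for f in feats}
    for g in ("control", "patient"):
        if sum(f.group == g for f in feats) < 2:
            raise ValueError(f"need at least two participants of group {g!r}")
    n = len(feats)
    rng = np.random.default_rng(seed)
    probs = np.empty((runs, n))
    for hold in range(n):
        train_idx = np.array([i for i in range(n) if i != hold])
        X, y = assemble_design(feats, feature_subset, bins, train_idx)
        probs[:, hold] = _sgd_logistic_probs(
            X[train_idx], y[train_idx], X[hold : hold + 1],
            runs, sgd_steps, learning_rate, rng,
        )[:, 0]
    y_true = np.array([1.0 if f.group == "control" else 0.0 for f in feats])
    sens = np.empty(runs)
    spec = np.empty(runs)
    for r in range(runs):
        sens[r], spec[r] = sensitivity_specificity(y_true, probs[r] > 0.5)
    n_bad = int(np.isnan(sens).sum() + np.isnan(spec).sum())
    if n_bad:
        logger.info("%d runs had an empty predicted class; excluded from medians", n_bad)
    return LooResult(
        participant_ids=[f.participant_id for f in feats],
        y_true=y_true,
        probabilities=probs,
        sensitivity=sens,
        specificity=spec,
    )


@dataclass
class SegmentClassResult:
    accuracies: np.ndarray
    median_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.median_accuracy = float(np.median(self.accuracies))


def classify_alone_accompanied(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    repeats: int = 20,
    seed: int = 0,
) -> SegmentClassResult:
    """Alone-vs-accompanied segment classification with an RBF-kernel SVM.

    ``X`` holds raw per-segment features (rows pooled over patients),
    ``y`` the binary companionship label.  Each repeat holds out a
    random ``test_fraction`` of segments, standardises features on the
    training split, fits ``SVC`` with library-default kernel settings
    (C=1, gamma='scale') and records test accuracy.  Splits leaving a
    class absent from training are redrawn (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    for c in range(2):
        if (y_enc == c).sum() < 10:
            raise ValueError("need at least ten segments per class")
    n_test = max(1, int(round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        while True:
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            if len(np.unique(y_enc[train])) == 2:
                break
            logger.info("redrawing split %d: a class was absent from training", r)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(C=1.0, kernel="rbf", gamma="scale")
        clf.fit((X[train] - mu) / sd, y_enc[train])
        accs[r] = float(np.mean(clf.predict((X[test] - mu) / sd) == y_enc[test]))
    return SegmentClassResult(accuracies=accs)


def feature_combination_report(
    feats: list[ParticipantFeatures],
    subsets: list[list[str]],
    **loo_kwargs,
) -> pd.DataFrame:
    """One leave-one-out summary row per feature subset."""
    rows = []
    for subset in subsets:
        res = loo_classify(feats, list(subset), **loo_kwargs)
        rows.append(
            {
                "features": "+".join(subset),
                "median_sensitivity": res.median_sensitivity,
                "median_specificity": res.median_specificity,
                "uncertainty": res.uncertainty,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["features", "median_sensitivity", "median_specificity", "uncertainty"],
    )
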