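"""Two-class Fisher linear discriminant on component loadings, with
confusion-matrix / ROC / AUC evaluation and leave-one-out cross-validation.

Convention: class 2 (the lexicographically larger label) is the ROC
"positive" class; a sample is predicted class 2 iff its discriminant
score is strictly positive (ties go to class 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DiscriminationError
from .io_expression import ExpressionMatrix, SampleAnnotation
from .ufe_core import UFEConfig, UFEResult, discrimination_inputs, run_ufe

logger = logging.getLogger(__name__)


@dataclass
class LDAModel:
    """Fisher discriminant: ``score(x) = w . x - threshold``.

    ``classes`` holds the two labels in lexicographic order; class 2
    (``classes[1]``) is predicted for positive scores.
    """

    weights: np.ndarray
    threshold: float
    classes: tuple[str, str]


@dataclass
class DiscriminationResult:
    """Per-sample scores and labels plus confusion matrix, ROC and AUC.

    ``confusion[p][t]`` counts samples predicted as class ``p+1`` whose
    true class is ``t+1`` (predicted x true layout).  ``roc`` is a list
    of ``(threshold, FPR, TPR)`` triples from sweeping the score
    threshold; ``auc`` is the trapezoidal area.
    """

    scores: np.ndarray
    predicted: list[str]
    true_labels: list[str]
    classes: tuple[str, str]
    confusion: np.ndarray
    roc: list[tuple[float, float, float]]
    auc: float
    mode: str = "in_sample"


def fit_lda(loadings: np.ndarray, annot: SampleAnnotation) -> LDAModel:
    """Fit a two-class Fisher discriminant on a samples-by-components matrix.

    ``w`` solves ``S_w w = mu2 - mu1`` with ``S_w`` the pooled
    within-class covariance (N-denominator, so duplicating every sample
    changes nothing); the threshold sits at the midpoint of the
    projected class means shifted by the empirical log prior ratio.
    A singular ``S_w`` falls back to a small ridge.
    """
    x = np.asarray(loadings, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != annot.n_samples:
        raise DiscriminationError(
            f"{x.shape[0]} loading rows for {annot.n_samples} annotated samples"
        )
    ind = annot.class_indicator()
    x1, x2 = x[ind == 0], x[ind == 1]
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise DiscriminationError("need >= 2 samples per class to fit")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    c1 = x1 - mu1
    c2 = x2 - mu2
    sw = (c1.T @ c1 + c2.T @ c2) / (n1 + n2)
    diff = mu2 - mu1
    try:
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)):
        eps = 1e-8 * np.trace(sw) / sw.shape[0]
        if eps <= 0:
            eps = 1e-8
        warnings.warn(
            "singular pooled within-class covariance; using ridge fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.linalg.solve(sw + eps * np.eye(sw.shape[0]), diff)
    prior1, prior2 = n1 / (n1 + n2), n2 / (n1 + n2)
    threshold = float(w @ (mu1 + mu2) / 2.0 - np.log(prior2 / prior1))
    return LDAModel(weights=w, threshold=threshold, classes=annot.classes)


def predict(model: LDAModel, loadings: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Scores ``w . x - threshold`` and hard labels (positive -> class 2)."""
    x = np.asarray(loadings, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != model.weights.shape[0]:
        raise DiscriminationError(
            f"model expects {model.weights.shape[0]} components, got {x.shape[1]}"
        )
    scores = x @ model.weights - model.threshold
    n_ties = int(np.sum(scores == 0))
    if n_ties:
        logger.info("%d tied score(s) at 0 assigned to class 1", n_ties)
    labels = [model.classes[1] if s > 0 else model.classes[0] for s in scores]
    return scores, labels


def confusion_and_auc(
    scores: np.ndarray,
    true_labels: list[str],
    mode: str = "in_sample",
) -> DiscriminationResult:
    """Confusion matrix at score threshold 0, plus ROC and trapezoidal AUC.

    The ROC sweeps the threshold over every distinct score; the
    trapezoid across tie groups makes the AUC equal to the Mann-Whitney
    statistic with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = [str(t) for t in true_labels]
    if scores.shape[0] != len(labels):
        raise DiscriminationError("scores and labels length mismatch")
    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise DiscriminationError(
            f"evaluation needs both classes present, found {distinct}"
        )
    classes = (distinct[0], distinct[1])
    truth = np.array([1 if t == classes[1] else 0 for t in labels], dtype=int)
    predicted = [classes[1] if s > 0 else classes[0] for s in scores]
    pred = np.array([1 if p == classes[1] else 0 for p in predicted], dtype=int)
    confusion = np.zeros((2, 2), dtype=int)
    for p, t in zip(pred, truth):
        confusion[p, t] += 1

    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    order = np.argsort(-scores, kind="stable")
    roc: list[tuple[float, float, float]] = [(float("inf"), 0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        thr = scores[order[i]]
        while i < len(order) and scores[order[i]] == thr:
            if truth[order[i]] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        roc.append((float(thr), fp / n_neg, tp / n_pos))
    fprs = np.array([r[1] for r in roc])
    tprs = np.array([r[2] for r in roc])
    auc = float(np.trapezoid(tprs, fprs))
    return DiscriminationResult(
        scores=scores,
        predicted=predicted,
        true_labels=labels,
        classes=classes,
        confusion=confusion,
        roc=roc,
        auc=auc,
        mode=mode,
    )


def _project_held_out(result: UFEResult, column: np.ndarray, omega: list[int]) -> np.ndarray:
    """Loading vector of one held-out normalized sample on the model components."""
    if result.stage2 is not None and result.omega2:
        scores = result.stage2.scores
        col = column[result.selected_indices]
    else:
        scores = result.stage1.scores
        col = column
    v = scores.T @ col
    return v[[l - 1 for l in omega]]


def evaluate_in_sample(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    config: UFEConfig | None = None,
    ufe_result: UFEResult | None = None,
) -> tuple[DiscriminationResult, UFEResult]:
    """Fit and evaluate on the same samples (mirrors reported tables).

    ``matrix`` must already be normalized and aligned with ``annot``.
    """
    result = ufe_result or run_ufe(matrix, annot, config)
    x, _ = discrimination_inputs(result)
    model = fit_lda(x, annot)
    scores, _ = predict(model, x)
    disc = confusion_and_auc(scores, annot.class_labels, mode="in_sample")
    return disc, result


def loocv_evaluate(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    config: UFEConfig | None = None,
) -> DiscriminationResult:
    """Leave-one-out cross-validation with selection inside each fold.

    For every held-out sample the full two-stage extraction and the
    discriminant are refit on the remaining samples only, then the
    held-out sample is projected and scored; all held-out scores feed a
    single ROC/AUC.  Folds whose training set loses a class are skipped
    with a warning.  Empty selections inside a fold degrade via the
    ``on_empty="fallback"`` path rather than aborting the whole loop.
    """
    config = config or UFEConfig()
    if matrix.n_samples < 4:
        raise DiscriminationError("LOOCV needs at least 4 samples")
    fold_config = UFEConfig(
        alpha_components=config.alpha_components,
        alpha_features=config.alpha_features,
        omega1=config.omega1,
        omega2=config.omega2,
        renormalize_stage2=config.renormalize_stage2,
        on_empty="fallback",
    )
    held_scores: list[float] = []
    held_labels: list[str] = []
    n_skipped = 0
    for j in range(matrix.n_samples):
        keep = [k for k in range(matrix.n_samples) if k != j]
        train_labels = [annot.class_labels[k] for k in keep]
        if len(set(train_labels)) < 2 or min(
            train_labels.count(c) for c in set(train_labels)
        ) < 2:
            warnings.warn(
                f"fold {j}: training set lacks 2 samples per class; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            n_skipped += 1
            continue
        train_matrix = matrix.subset_samples(keep)
        train_annot = annot.subset(train_matrix.sample_ids)
        result = run_ufe(train_matrix, train_annot, fold_config)
        x, omega = discrimination_inputs(result)
        model = fit_lda(x, train_annot)
        v = _project_held_out(result, matrix.values[:, j], omega)
        score = float(v @ model.weights - model.threshold)
        held_scores.append(score)
        held_labels.append(annot.class_labels[j])
    if not held_scores:
        raise DiscriminationError("all LOOCV folds were skipped")
    if n_skipped:
        logger.warning("LOOCV skipped %d fold(s)", n_skipped)
    return confusion_and_auc(np.array(held_scores), held_labels, mode="loocv")
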