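"""Core unsupervised feature-extraction machinery.

Given a per-sample normalized feature-by-sample matrix ``x`` (N features,
M samples), the procedure is:

1.  PCA on the feature Gram matrix: scores ``u_li`` (unit-norm eigenvectors
    over features) and eigenvalues ``lambda_l``, computed through a thin
    SVD of ``x``.
2.  Loadings ``v_lj = sum_i x_ij u_li`` project each sample onto each
    component.
3.  Each component's loading vector is tested for association with the
    two-class labels; Benjamini-Hochberg correction across components,
    selection at adjusted p < alpha_components (default .05), or an
    explicit override set.
4.  Each feature gets the statistic ``T_i = sum_{l in Omega} (u_li / sigma_l)^2``
    and the upper-tail chi-squared p-value with ``|Omega|`` degrees of
    freedom, where ``sigma_l`` is the population standard deviation of the
    score entries of component ``l``.  BH across features, selection at
    adjusted p < alpha_features (default .01).
5.  PCA and loadings are recomputed on the selected-feature submatrix
    (without re-normalizing, by default), and the component set for
    discrimination is chosen on the recomputed loadings (or overridden).

Component indices are 1-based in every public interface; feature and
sample positions are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DecompositionError, EmptySelectionError
from .io_expression import ExpressionMatrix, SampleAnnotation
from .preprocess import check_normalized, normalize_samples

logger = logging.getLogger(__name__)

_RELATIVE_RANK_TOL = 1e-12


@dataclass
class PCDecomposition:
    """Principal-component scores, eigenvalues, loadings and score dispersions.

    ``scores`` is N x L with unit-norm columns (``scores[i, l-1]`` is
    ``u_li``); ``eigenvalues`` is length L, nonincreasing; ``loadings``
    is L x M (``loadings[l-1, j]`` is ``v_lj``); ``score_sd[l-1]`` is the
    population standard deviation of the entries of score column ``l``.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    score_sd: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ComponentAssociation:
    """Association of one component's loadings with the two-class labels.

    Coefficients are reported under sum-to-zero coding: ``intercept`` is
    the midpoint of the class means and ``effects[s-1]`` is the offset of
    class ``s`` from it (so ``effects[0] + effects[1] == 0``).
    """

    component: int
    intercept: float
    effects: tuple[float, float]
    f_statistic: float
    p_raw: float
    p_adjusted: float = float("nan")


@dataclass
class UFEResult:
    """Complete output of the two-stage feature-extraction run."""

    feature_ids: list[str]
    stage1: PCDecomposition
    stage1_associations: list[ComponentAssociation]
    omega1: list[int]
    omega1_source: str  # "test" or "override" or "fallback"
    feature_statistic: np.ndarray
    feature_p_raw: np.ndarray
    feature_p_adjusted: np.ndarray
    selected_features: list[str]
    selected_indices: list[int]
    stage2: PCDecomposition | None
    stage2_associations: list[ComponentAssociation] | None
    omega2: list[int] | None
    omega2_source: str | None
    fallback: str | None = None


@dataclass
class UFEConfig:
    """Pipeline thresholds and overrides.

    ``omega1`` / ``omega2`` are 1-based component index lists that bypass
    the association test at the corresponding stage.  ``on_empty``
    controls what happens when a selection step comes back empty:
    ``"error"`` raises, ``"fallback"`` degrades gracefully (empty feature
    selection falls back to stage-1 loadings; empty component selection
    falls back to component 1) — the mode used inside cross-validation.
    """

    alpha_components: float = 0.05
    alpha_features: float = 0.01
    omega1: list[int] | None = None
    omega2: list[int] | None = None
    renormalize_stage2: bool = False
    on_empty: str = "error"

    def __post_init__(self) -> None:
        for name in ("alpha_components", "alpha_features"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        for name in ("omega1", "omega2"):
            om = getattr(self, name)
            if om is not None:
                om = sorted(int(l) for l in om)
                if any(l < 1 for l in om):
                    raise ValueError(f"{name} entries must be positive, got {om}")
                setattr(self, name, om)
        if self.on_empty not in ("error", "fallback"):
            raise ValueError(f"on_empty must be 'error' or 'fallback', got {self.on_empty!r}")

    def to_dict(self) -> dict:
        return {
            "alpha_components": self.alpha_components,
            "alpha_features": self.alpha_features,
            "omega1": self.omega1,
            "omega2": self.omega2,
            "renormalize_stage2": self.renormalize_stage2,
            "on_empty": self.on_empty,
        }


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    # Make the largest-magnitude score entry of each component positive
    # (ties broken by lowest feature index); flip loadings to match.
    for l in range(scores.shape[1]):
        col = scores[:, l]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            scores[:, l] = -col
            loadings[l, :] = -loadings[l, :]


def compute_pca(
    matrix: ExpressionMatrix, check_normalization: bool = True
) -> PCDecomposition:
    """PCA of the feature Gram matrix via thin SVD.

    Returns unit-norm per-feature scores, eigenvalues of the Gram
    eigenproblem (squared singular values), the loading matrix obtained
    by contracting scores with the data, and the per-component score
    dispersions.  Components with ``lambda_l / lambda_1 < 1e-12`` are
    discarded.
    """
    x = matrix.values
    n, m = x.shape
    if n < 2 or m < 2:
        raise DecompositionError(f"matrix must be at least 2x2, got {n}x{m}")
    if check_normalization and not check_normalized(x):
        raise DecompositionError(
            "input matrix does not satisfy the per-sample normalization "
            "constraints; run normalize_samples first"
        )
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    lam = s**2
    if lam[0] <= 0:
        raise DecompositionError("matrix is identically zero")
    keep = lam / lam[0] >= _RELATIVE_RANK_TOL
    u = u[:, keep]
    lam = lam[keep]
    loadings = compute_loadings(matrix, u)
    _fix_signs(u, loadings)
    sd = u.std(axis=0, ddof=0)
    return PCDecomposition(scores=u, eigenvalues=lam, loadings=loadings, score_sd=sd)


def compute_loadings(matrix: ExpressionMatrix, scores: np.ndarray) -> np.ndarray:
    """Loading matrix ``v_lj = sum_i x_ij u_li`` (shape L x M).

    Feature order of ``scores`` rows must match the matrix.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != matrix.n_features:
        raise DecompositionError(
            f"scores shape {scores.shape} does not match {matrix.n_features} features"
        )
    return scores.T @ matrix.values


def test_component_association(
    loadings: np.ndarray, annot: SampleAnnotation
) -> list[ComponentAssociation]:
    """Test each component's loadings for a two-class location difference.

    The printed intercept-plus-two-indicators regression is rank
    deficient; its identifiable equivalent is a one-way two-group F-test
    (F equals the square of the equal-variance two-sample t statistic,
    with the same p-value).  BH correction is applied across the L
    components.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[1] != annot.n_samples:
        raise DecompositionError(
            f"loadings have {loadings.shape[1]} samples, annotation has {annot.n_samples}"
        )
    ind = annot.class_indicator()
    g1 = loadings[:, ind == 0]
    g2 = loadings[:, ind == 1]
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise DecompositionError("association test needs >= 2 samples per class")
    out: list[ComponentAssociation] = []
    for l in range(loadings.shape[0]):
        a1, a2 = g1[l], g2[l]
        m1, m2 = a1.mean(), a2.mean()
        pooled_ss = ((a1 - m1) ** 2).sum() + ((a2 - m2) ** 2).sum()
        scale = max(np.abs(loadings[l]).max(), 1.0)
        if pooled_ss <= (1e-15 * scale) ** 2 * (len(a1) + len(a2)):
            if np.isclose(m1, m2, rtol=0, atol=1e-15 * scale):
                f_stat, p = 0.0, 1.0
            else:
                warnings.warn(
                    f"component {l + 1}: zero within-class variance with "
                    "unequal means; p set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                f_stat, p = float("inf"), 0.0
        else:
            # one-way two-group F-test computed explicitly (F = t^2 of the
            # equal-variance two-sample t-test)
            n1, n2 = len(a1), len(a2)
            grand = loadings[l].mean()
            msb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
            msw = pooled_ss / (n1 + n2 - 2)
            f_stat = float(msb / msw)
            p = float(stats.f.sf(f_stat, 1, n1 + n2 - 2))
        intercept = (m1 + m2) / 2.0
        out.append(
            ComponentAssociation(
                component=l + 1,
                intercept=float(intercept),
                effects=(float(m1 - intercept), float(m2 - intercept)),
                f_statistic=f_stat,
                p_raw=p,
            )
        )
    adjusted = benjamini_hochberg(np.array([a.p_raw for a in out]))
    for a, q in zip(out, adjusted):
        a.p_adjusted = float(q)
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment returning adjusted p-values in input order.

    Sort ascending, multiply ``p_(k)`` by ``m/k``, take the cumulative
    minimum from the largest rank down, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


def select_components(
    assocs: Sequence[ComponentAssociation],
    alpha: float = 0.05,
    override: Sequence[int] | None = None,
) -> list[int]:
    """Components with BH-adjusted p strictly below ``alpha`` (ascending, 1-based).

    An ``override`` list bypasses the test entirely (logged as manual).
    Raises :class:`EmptySelectionError` when nothing passes and no
    override was given.
    """
    if override is not None:
        omega = sorted(int(l) for l in override)
        logger.info("component selection overridden manually: %s", omega)
        return omega
    omega = sorted(a.component for a in assocs if a.p_adjusted < alpha)
    if not omega:
        raise EmptySelectionError(
            f"no component has adjusted p < {alpha}; supply an override set "
            "or raise alpha"
        )
    return omega


def score_features(
    scores: np.ndarray, score_sd: np.ndarray, omega: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-squared feature statistics and upper-tail p-values.

    ``T_i = sum_{l in omega} (u_li / sigma_l)^2``; the p-value is the
    chi-squared survival function with ``len(omega)`` degrees of freedom.
    """
    omega = sorted(int(l) for l in omega)
    if not omega:
        raise EmptySelectionError("omega must be nonempty for feature scoring")
    idx = [l - 1 for l in omega]
    if max(idx) >= scores.shape[1]:
        raise DecompositionError(
            f"omega refers to component {max(omega)} but only "
            f"{scores.shape[1]} components exist"
        )
    sd = np.asarray(score_sd, dtype=float)[idx]
    if np.any(sd <= 0):
        raise DecompositionError("score dispersion sigma_l must be positive")
    z = scores[:, idx] / sd
    t = (z**2).sum(axis=1)
    p = stats.chi2.sf(t, df=len(omega))
    return t, p


def select_features(
    p: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """BH-adjust feature p-values and select those strictly below ``alpha``.

    Returns ``(selected_indices, adjusted_p)``.  Raises
    :class:`EmptySelectionError` on an empty selection.
    """
    adjusted = benjamini_hochberg(np.asarray(p, dtype=float))
    selected = np.flatnonzero(adjusted < alpha)
    if selected.size == 0:
        raise EmptySelectionError(
            f"no feature has adjusted p < {alpha}; raise alpha or override "
            "the component set"
        )
    return selected, adjusted


def recompute_stage2(
    matrix: ExpressionMatrix,
    selected_indices: Sequence[int],
    annot: SampleAnnotation | None = None,
    stage2_omega: Sequence[int] | None = None,
    alpha: float = 0.05,
    renormalize: bool = False,
) -> tuple[PCDecomposition, list[ComponentAssociation] | None, list[int], str]:
    """Re-run PCA and loadings on the selected-feature submatrix.

    By default the stage-1 normalized values are reused without
    re-normalizing over the subset (the loadings are recomputed, not the
    data).  The stage-2 component set comes from ``stage2_omega`` if
    given, else from the association test on the new loadings.

    Returns ``(decomposition, associations or None, omega, omega_source)``.
    """
    idx = sorted(int(i) for i in selected_indices)
    if len(idx) < 2:
        raise DecompositionError(
            f"stage-2 recomputation needs >= 2 selected features, got {len(idx)}"
        )
    sub = matrix.subset_features(idx)
    if renormalize:
        sub = normalize_samples(sub)
    pcd = compute_pca(sub, check_normalization=renormalize)
    if stage2_omega is not None:
        omega = sorted(int(l) for l in stage2_omega)
        logger.info("stage-2 component set overridden manually: %s", omega)
        return pcd, None, omega, "override"
    if annot is None:
        raise DecompositionError("annotation required when stage2_omega is not given")
    assocs = test_component_association(pcd.loadings, annot)
    omega = select_components(assocs, alpha=alpha)
    return pcd, assocs, omega, "test"


def run_ufe(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    config: UFEConfig | None = None,
) -> UFEResult:
    """Run the full two-stage procedure on an aligned, normalized matrix.

    Deterministic given inputs and config.  Stage errors carry the stage
    name.  With ``config.on_empty == "fallback"``, an empty feature
    selection degrades to the stage-1 decomposition and component set
    (recorded in ``result.fallback``) instead of raising.
    """
    config = config or UFEConfig()
    if matrix.sample_ids != annot.sample_ids:
        raise DecompositionError(
            "matrix and annotation must be aligned (same sample order); call align()"
        )

    stage1 = compute_pca(matrix)
    assocs = test_component_association(stage1.loadings, annot)

    fallback: str | None = None
    try:
        omega1 = select_components(
            assocs, alpha=config.alpha_components, override=config.omega1
        )
        omega1_source = "override" if config.omega1 is not None else "test"
    except EmptySelectionError:
        if config.on_empty == "error":
            raise EmptySelectionError(
                "stage select_components: no component associated with the classes"
            ) from None
        omega1 = [1]
        omega1_source = "fallback"
        fallback = "component_selection_empty"
        logger.warning("no component selected; falling back to component 1")

    if max(omega1) > stage1.n_components:
        raise DecompositionError(
            f"stage select_components: omega {omega1} exceeds the "
            f"{stage1.n_components} available components"
        )

    t_stat, p_raw = score_features(stage1.scores, stage1.score_sd, omega1)

    stage2 = None
    stage2_assocs: list[ComponentAssociation] | None = None
    omega2: list[int] | None = None
    omega2_source: str | None = None
    try:
        selected_idx, p_adj = select_features(p_raw, alpha=config.alpha_features)
    except EmptySelectionError:
        if config.on_empty == "error":
            raise EmptySelectionError(
                "stage select_features: no feature passed the adjusted threshold"
            ) from None
        p_adj = benjamini_hochberg(p_raw)
        selected_idx = np.array([], dtype=int)
        fallback = "feature_selection_empty"
        logger.warning("no feature selected; discrimination falls back to stage 1")

    if selected_idx.size >= 2:
        stage2, stage2_assocs, omega2, omega2_source = recompute_stage2(
            matrix,
            selected_idx,
            annot=annot,
            stage2_omega=config.omega2,
            alpha=config.alpha_components,
            renormalize=config.renormalize_stage2,
        )
    elif selected_idx.size == 1:
        # a single selected feature cannot support a stage-2 PCA
        fallback = fallback or "single_feature_selection"
        logger.warning("only one feature selected; stage 2 skipped")

    return UFEResult(
        feature_ids=list(matrix.feature_ids),
        stage1=stage1,
        stage1_associations=assocs,
        omega1=omega1,
        omega1_source=omega1_source,
        feature_statistic=t_stat,
        feature_p_raw=p_raw,
        feature_p_adjusted=p_adj,
        selected_features=[matrix.feature_ids[i] for i in selected_idx],
        selected_indices=[int(i) for i in selected_idx],
        stage2=stage2,
        stage2_associations=stage2_assocs,
        omega2=omega2,
        omega2_source=omega2_source,
        fallback=fallback,
    )


def discrimination_inputs(result: UFEResult) -> tuple[np.ndarray, list[int]]:
    """Loadings-by-sample matrix and component set to feed the classifier.

    Uses the stage-2 decomposition and component set when available;
    otherwise falls back to stage 1 (recorded by ``result.fallback``).
    Returns ``(samples x components array, omega)``.
    """
    if result.stage2 is not None and result.omega2:
        pcd, omega = result.stage2, result.omega2
    else:
        pcd, omega = result.stage1, result.omega1
    idx = [l - 1 for l in omega]
    if max(idx) >= pcd.n_components:
        raise DecompositionError(
            f"omega {omega} exceeds the {pcd.n_components} available components"
        )
    return pcd.loadings[idx, :].T, list(omega)
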