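"""Synthetic two-class expression cohorts with known ground truth.

The generator plants a small set of informative features that differ in
location between the two classes on the log2 scale, against log-normal
(multiplicative) noise — the intensity behaviour of a typical microarray.
No correlation structure between features is simulated (documented
limitation; hook: post-process ``SyntheticCohort.matrix.values``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_expression import ExpressionMatrix, SampleAnnotation


@dataclass
class CohortParams:
    """Knobs of the two-class generator (log2-scale effect and noise)."""

    n_features: int = 2000
    n_samples_class1: int = 30
    n_samples_class2: int = 30
    n_informative: int = 20
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (4.0, 14.0)
    class_labels: tuple[str, str] = ("classA", "classB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 0 or self.n_features < self.n_informative:
            raise ValueError(
                f"need n_features >= n_informative >= 0, got "
                f"{self.n_features} / {self.n_informative}"
            )
        if self.n_samples_class1 < 2 or self.n_samples_class2 < 2:
            raise ValueError("both class sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.baseline_range[0] >= self.baseline_range[1]:
            raise ValueError(f"invalid baseline range {self.baseline_range}")
        if len(set(self.class_labels)) != 2:
            raise ValueError("class labels must be two distinct strings")


@dataclass
class SyntheticCohort:
    """Generated cohort plus the identities of the planted features."""

    matrix: ExpressionMatrix
    annot: SampleAnnotation
    truth: set[str]
    params: CohortParams


#: class sizes of the cohort designs used to exercise imbalance regimes
_PRESETS: dict[str, tuple[int, int]] = {
    "v20_hcv_svr": (36, 9),
    "v21_hcv_svr": (68, 22),
    "v21_hcc_btc": (177, 43),
}


def generate_two_class_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Draw one cohort: log2 intensity = baseline + class shift + noise.

    Per feature ``i`` a baseline log2 mean is drawn uniformly from the
    baseline range; planted features get an additional ``+-effect_size``
    shift (random sign) in class 2; Gaussian noise with ``noise_sd`` is
    added and the result exponentiated to the raw intensity scale.
    Identical seed and params reproduce the cohort exactly.
    """
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_features
    m1, m2 = p.n_samples_class1, p.n_samples_class2
    m = m1 + m2

    width = max(len(str(n)), 4)
    feature_ids = [f"feat-{i:0{width}d}" for i in range(1, n + 1)]
    lab1, lab2 = sorted(p.class_labels)
    sample_ids = [f"s{j:03d}" for j in range(1, m + 1)]
    class_labels = [lab1] * m1 + [lab2] * m2

    baseline = rng.uniform(*p.baseline_range, size=n)
    truth_idx = rng.choice(n, size=p.n_informative, replace=False)
    delta = np.zeros(n)
    if p.n_informative:
        signs = rng.choice([-1.0, 1.0], size=p.n_informative)
        delta[truth_idx] = signs * p.effect_size

    log2_vals = baseline[:, None] + rng.normal(0.0, p.noise_sd, size=(n, m))
    log2_vals[:, m1:] += delta[:, None]
    matrix = ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        values=np.exp2(log2_vals),
    )
    annot = SampleAnnotation(sample_ids=sample_ids, class_labels=class_labels)
    truth = {feature_ids[i] for i in truth_idx}
    return SyntheticCohort(matrix=matrix, annot=annot, truth=truth, params=p)


def generate_null_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Same generator with the informative-feature count forced to zero."""
    p = params or CohortParams()
    null_params = CohortParams(
        n_features=p.n_features,
        n_samples_class1=p.n_samples_class1,
        n_samples_class2=p.n_samples_class2,
        n_informative=0,
        effect_size=p.effect_size,
        noise_sd=p.noise_sd,
        baseline_range=p.baseline_range,
        class_labels=p.class_labels,
        seed=p.seed,
    )
    return generate_two_class_cohort(null_params)


def imbalance_preset(name: str, seed: int = 0) -> CohortParams:
    """Parameters matching one of the studied cohort imbalance regimes."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    m1, m2 = _PRESETS[name]
    return CohortParams(n_samples_class1=m1, n_samples_class2=m2, seed=seed)
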