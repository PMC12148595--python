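"""Model evaluation: whitened cosine similarity, noise ceilings, bootstrap
uncertainty and frequentist model comparison.

Candidate model RDMs are compared with subject neural RDMs through the cosine
similarity of their vectorized upper triangles, optionally computed in a
whitened space.  Entries of a squared-Euclidean-distance RDM are correlated
(two distances sharing a condition covary), so the plain cosine over-counts
shared noise; whitening by the inverse of the distance-estimate covariance
under isotropic pattern noise removes that structure.  The identity mode
reduces to the plain cosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rdm import RDM

__all__ = [
    "WhiteningMatrix",
    "whitening_matrix",
    "whitened_cosine",
    "NoiseCeiling",
    "noise_ceiling",
    "ModelEvaluation",
    "score_matrix",
    "bootstrap_evaluate",
    "ComparisonTable",
    "compare_models",
]


@dataclass(frozen=True)
class WhiteningMatrix:
    """Symmetric positive-definite whitening target over vectorized RDM entries.

    ``matrix`` is the covariance-like matrix V; similarities are computed with
    its inverse.  ``mode`` records how it was built.
    """

    matrix: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = np.asarray(self.matrix, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("whitening matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("whitening matrix must be symmetric")
        try:
            np.linalg.cholesky(v)
        except np.linalg.LinAlgError as err:
            raise ValueError("whitening matrix is not positive-definite") from err
        v = (v + v.T) / 2.0
        v.flags.writeable = False
        object.__setattr__(self, "matrix", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def _pair_contrast_matrix(n_conditions: int) -> np.ndarray:
    """Rows e_i - e_j for each unordered condition pair (i < j)."""
    n_pairs = n_conditions * (n_conditions - 1) // 2
    c = np.zeros((n_pairs, n_conditions))
    row = 0
    for i in range(n_conditions):
        for j in range(i + 1, n_conditions):
            c[row, i] = 1.0
            c[row, j] = -1.0
            row += 1
    return c


def whitening_matrix(n_conditions: int = 8, mode: str = "distance-covariance") -> WhiteningMatrix:
    """Build the whitening matrix for vectorized RDM comparison.

    ``identity`` gives V = I (whitened cosine == plain cosine).  The
    ``distance-covariance`` mode uses V proportional to (C C^T) ∘ (C C^T),
    where C is the pairwise-contrast matrix: the covariance structure of
    squared-distance estimates when pattern noise is isotropic.  V is
    normalized to unit trace.
    """
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions")
    n_pairs = n_conditions * (n_conditions - 1) // 2
    if mode == "identity":
        return WhiteningMatrix(np.eye(n_pairs), mode)
    if mode == "distance-covariance":
        c = _pair_contrast_matrix(n_conditions)
        g = c @ c.T
        v = g * g
        v = v / np.trace(v)
        return WhiteningMatrix(v, mode)
    raise ValueError(f"unknown whitening mode {mode!r}")


def _as_vector(x: RDM | np.ndarray) -> np.ndarray:
    if isinstance(x, RDM):
        return x.vector
    return np.asarray(x, dtype=float)


def whitened_cosine(
    d_model: RDM | np.ndarray,
    d_data: RDM | np.ndarray,
    whitening: WhiteningMatrix | None = None,
) -> float:
    """Cosine similarity between two vectorized RDMs in the whitened space.

    s = d1' V^-1 d2 / sqrt((d1' V^-1 d1)(d2' V^-1 d2)); invariant to positive
    rescaling of either argument.  ``whitening=None`` means identity.
    """
    d1 = _as_vector(d_model)
    d2 = _as_vector(d_data)
    if d1.shape != d2.shape:
        raise ValueError("RDM vectors must have equal length")
    if whitening is None or whitening.mode == "identity":
        q11 = d1 @ d1
        q22 = d2 @ d2
        q12 = d1 @ d2
    else:
        vinv = whitening.inverse
        q11 = d1 @ vinv @ d1
        q22 = d2 @ vinv @ d2
        q12 = d1 @ vinv @ d2
    if q11 <= 0 or q22 <= 0:
        raise ValueError("cannot compute cosine of a zero-norm RDM vector")
    return float(q12 / np.sqrt(q11 * q22))


# ---------------------------------------------------------------------------
# Noise ceiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseCeiling:
    """Bracket on the best achievable model score given between-subject noise.

    ``upper``: mean similarity of each subject RDM to the all-subject mean RDM
    (optimistic — the target includes the subject itself).  ``lower``: mean
    leave-one-out similarity (conservative).  ``lower_per_subject`` holds the
    per-subject leave-one-out values used in paired ceiling tests.
    """

    lower: float
    upper: float
    lower_per_subject: np.ndarray = field(repr=False)
    upper_per_subject: np.ndarray = field(repr=False)


def noise_ceiling(
    subject_rdms: list[RDM],
    whitening: WhiteningMatrix | None = None,
) -> NoiseCeiling:
    if len(subject_rdms) < 2:
        raise ValueError("noise ceiling requires at least 2 subjects")
    vecs = np.array([r.vector for r in subject_rdms])
    n = vecs.shape[0]
    total = vecs.sum(axis=0)
    grand_mean = total / n
    upper = np.array([whitened_cosine(v, grand_mean, whitening) for v in vecs])
    loo = (total[None, :] - vecs) / (n - 1)
    lower = np.array(
        [whitened_cosine(v, loo[i], whitening) for i, v in enumerate(vecs)]
    )
    return NoiseCeiling(
        lower=float(lower.mean()),
        upper=float(upper.mean()),
        lower_per_subject=lower,
        upper_per_subject=upper,
    )


# ---------------------------------------------------------------------------
# Scores and bootstrap
# ---------------------------------------------------------------------------

def score_matrix(
    subject_rdms: list[RDM],
    model_rdms: list[RDM],
    whitening: WhiteningMatrix | None = None,
) -> np.ndarray:
    """Per-subject x per-model whitened-cosine scores."""
    return np.array(
        [
            [whitened_cosine(m, s, whitening) for m in model_rdms]
            for s in subject_rdms
        ]
    )


@dataclass(frozen=True)
class ModelEvaluation:
    """Group-level evaluation of candidate models.

    ``scores`` is the (n_subjects, n_models) score matrix; ``mean`` the group
    means; ``sem`` the bootstrap SD of the resampled means; ``ci_low`` /
    ``ci_high`` the percentile 95% bootstrap CI; ``n_boot`` and ``seed`` the
    resampling settings.
    """

    model_names: tuple[str, ...]
    scores: np.ndarray = field(repr=False)
    mean: np.ndarray
    sem: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int | None


def bootstrap_evaluate(
    subject_rdms: list[RDM],
    model_rdms: list[RDM],
    model_names: list[str] | None = None,
    whitening: WhiteningMatrix | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ModelEvaluation:
    """Subject-level bootstrap of mean model scores.

    Subjects are resampled with replacement ``n_boot`` times; per resample the
    mean score of each model is recorded.  Reported are the observed group
    means, the SD of the bootstrap means (as SEM) and percentile 95% CIs.
    """
    if len(subject_rdms) < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if model_names is None:
        model_names = [f"model_{i}" for i in range(len(model_rdms))]
    scores = score_matrix(subject_rdms, model_rdms, whitening)
    n_subj = scores.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot_means = scores[idx].mean(axis=1)  # (n_boot, n_models)
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5], axis=0)
    return ModelEvaluation(
        model_names=tuple(model_names),
        scores=scores,
        mean=scores.mean(axis=0),
        sem=boot_means.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(scores.shape[1]),
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonTable:
    """Pairwise and ceiling/zero comparisons of candidate models.

    Pairwise: paired two-tailed t-tests on per-subject score differences with
    Benjamini-Hochberg FDR control.  Per model: one-sample t against zero, and
    a paired t against the per-subject leave-one-out ceiling values with
    Bonferroni correction over models.
    """

    model_names: tuple[str, ...]
    pair_index: tuple[tuple[int, int], ...]
    pair_t: np.ndarray
    pair_p: np.ndarray
    pair_q: np.ndarray
    pair_significant: np.ndarray
    vs_zero_t: np.ndarray
    vs_zero_p: np.ndarray
    vs_ceiling_t: np.ndarray
    vs_ceiling_p: np.ndarray
    vs_ceiling_p_adjusted: np.ndarray
    below_ceiling: np.ndarray
    fdr_q: float
    alpha: float


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired two-tailed t; an exact tie (zero-variance differences) gives
    t = 0, p = 1 instead of NaN."""
    d = x - y
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0) and np.allclose(
        d.mean(), 0.0
    ):
        return 0.0, 1.0
    t, p = stats.ttest_rel(x, y)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def compare_models(
    evaluation: ModelEvaluation,
    ceiling: NoiseCeiling,
    fdr_q: float = 0.01,
    alpha: float = 0.05,
) -> ComparisonTable:
    scores = evaluation.scores
    n_models = scores.shape[1]
    pairs = [(i, j) for i in range(n_models) for j in range(i + 1, n_models)]
    pair_t = np.empty(len(pairs))
    pair_p = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        pair_t[k], pair_p[k] = _paired_t(scores[:, i], scores[:, j])
    if len(pairs):
        reject, q, _, _ = multipletests(pair_p, alpha=fdr_q, method="fdr_bh")
    else:
        reject, q = np.zeros(0, bool), np.zeros(0)

    vs_zero_t = np.empty(n_models)
    vs_zero_p = np.empty(n_models)
    for m in range(n_models):
        t, p = stats.ttest_1samp(scores[:, m], 0.0)
        vs_zero_t[m], vs_zero_p[m] = float(t), float(p)

    vs_ceiling_t = np.empty(n_models)
    vs_ceiling_p = np.empty(n_models)
    for m in range(n_models):
        vs_ceiling_t[m], vs_ceiling_p[m] = _paired_t(
            scores[:, m], ceiling.lower_per_subject
        )
    vs_ceiling_adj = np.minimum(vs_ceiling_p * n_models, 1.0)
    return ComparisonTable(
        model_names=evaluation.model_names,
        pair_index=tuple(pairs),
        pair_t=pair_t,
        pair_p=pair_p,
        pair_q=np.asarray(q, dtype=float),
        pair_significant=np.asarray(reject, dtype=bool),
        vs_zero_t=vs_zero_t,
        vs_zero_p=vs_zero_p,
        vs_ceiling_t=vs_ceiling_t,
        vs_ceiling_p=vs_ceiling_p,
        vs_ceiling_p_adjusted=vs_ceiling_adj,
        below_ceiling=(vs_ceiling_adj < alpha) & (vs_ceiling_t < 0),
        fdr_q=fdr_q,
        alpha=alpha,
    )
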