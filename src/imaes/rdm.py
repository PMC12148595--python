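"""Representational dissimilarity matrices over the eight task conditions.

The experimental design crosses three binary factors — elicited aesthetic
experience (high/low "moving"), stimulation modality (visual perception /
mental imagery) and stimulus type (artwork/face) — giving eight conditions.
This module builds neural RDMs from condition activity patterns (squared
Euclidean distances between z-scored patterns) and constructs the
theory-derived candidate model RDMs: binary single-factor models, the
all-different "independent" model, and weighted combinations in which one
factor dominates the other two by a factor of 2 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CONDITIONS",
    "N_CONDITIONS",
    "RDM",
    "ModelSpec",
    "condition_attributes",
    "factor_rdm",
    "independent_rdm",
    "combine_weighted",
    "candidate_family",
    "average_rdm",
    "zscore_patterns",
    "compute_neural_rdm",
]

#: Canonical condition order: experience (H/L) x modality (P/I) x type (A/F).
CONDITIONS: tuple[str, ...] = (
    "HPA", "LPA", "HPF", "LPF", "HIA", "LIA", "HIF", "LIF",
)
N_CONDITIONS = len(CONDITIONS)

_FACTORS = ("experience", "modality", "type")


def condition_attributes(label: str) -> dict[str, str]:
    """Decompose a condition label into its three factor levels."""
    if label not in CONDITIONS:
        raise ValueError(f"unknown condition label {label!r}")
    exp, mod, typ = label
    return {
        "experience": "high" if exp == "H" else "low",
        "modality": "perception" if mod == "P" else "imagery",
        "type": "art" if typ == "A" else "face",
    }


def _upper_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


@dataclass(frozen=True)
class RDM:
    """Symmetric, zero-diagonal dissimilarity matrix over labeled conditions.

    Attributes
    ----------
    matrix:
        ``(n, n)`` symmetric nonnegative array with zero diagonal.
    labels:
        Condition labels in row/column order; defaults to :data:`CONDITIONS`.
    """

    matrix: np.ndarray
    labels: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if np.any(m < -1e-10):
            raise ValueError("RDM entries must be nonnegative")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Row-major upper-triangle vectorization (length n(n-1)/2)."""
        i, j = _upper_triangle_indices(self.n)
        return self.matrix[i, j]

    @property
    def pair_labels(self) -> list[tuple[str, str]]:
        i, j = _upper_triangle_indices(self.n)
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    @classmethod
    def from_vector(cls, vec: np.ndarray, labels: tuple[str, ...] = CONDITIONS) -> "RDM":
        vec = np.asarray(vec, dtype=float)
        n = len(labels)
        if vec.shape != (n * (n - 1) // 2,):
            raise ValueError(f"expected {n * (n - 1) // 2} entries, got {vec.shape}")
        m = np.zeros((n, n))
        i, j = _upper_triangle_indices(n)
        m[i, j] = vec
        m[j, i] = vec
        return cls(m, labels)

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, RDM):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.matrix, other.matrix)

    def __hash__(self) -> int:
        return hash((self.labels, self.matrix.tobytes()))

    def allclose(self, other: "RDM", atol: float = 1e-12) -> bool:
        return self.labels == other.labels and np.allclose(
            self.matrix, other.matrix, atol=atol
        )


@dataclass(frozen=True)
class ModelSpec:
    """Named candidate model: factor weights or the all-different model.

    ``weights`` orders the factors as (modality, experience, type).  The
    ``independent`` flag is mutually exclusive with weights.
    """

    name: str
    weights: tuple[float, float, float] | None = None
    independent: bool = False

    def __post_init__(self) -> None:
        if self.independent == (self.weights is not None):
            raise ValueError("exactly one of weights / independent must be given")
        if self.weights is not None:
            if any(w < 0 for w in self.weights):
                raise ValueError("model weights must be nonnegative")
            if all(w == 0 for w in self.weights):
                raise ValueError("at least one model weight must be positive")

    def rdm(self) -> RDM:
        if self.independent:
            return independent_rdm()
        return combine_weighted(self)


def _factor_indicator(factor: str) -> np.ndarray:
    """Binary matrix with 1 where two conditions differ on the factor."""
    if factor not in _FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {_FACTORS}")
    levels = [condition_attributes(c)[factor] for c in CONDITIONS]
    diff = np.array(
        [[1.0 if a != b else 0.0 for b in levels] for a in levels]
    )
    return diff


def factor_rdm(factor: str) -> RDM:
    """Single-factor model: conditions differing on ``factor`` are maximally
    dissimilar (1), all others identical (0)."""
    return RDM(_factor_indicator(factor))


def independent_rdm() -> RDM:
    """Model in which every pair of distinct conditions is maximally dissimilar."""
    m = np.ones((N_CONDITIONS, N_CONDITIONS)) - np.eye(N_CONDITIONS)
    return RDM(m)


def combine_weighted(spec: ModelSpec, normalize: bool = True) -> RDM:
    """Weighted sum of the modality, experience and type indicator RDMs.

    The result is rescaled so its maximum entry is 1 (cosmetic — the cosine
    comparison metrics are scale-invariant).
    """
    if spec.weights is None:
        raise ValueError("combine_weighted requires a weighted ModelSpec")
    w_mod, w_exp, w_type = spec.weights
    m = (
        w_mod * _factor_indicator("modality")
        + w_exp * _factor_indicator("experience")
        + w_type * _factor_indicator("type")
    )
    if normalize:
        m = m / m.max()
    return RDM(m)


def candidate_family(include_partial: bool = False) -> list[ModelSpec]:
    """The nine candidate models (ten with the partial experience-and-type model).

    Weight triples are (modality, experience, type).  The graded models
    down-weight the two non-dominant factors by 2 or 3.
    """
    family = [
        ModelSpec("Independent", independent=True),
        ModelSpec("Modality", weights=(1.0, 0.0, 0.0)),
        ModelSpec("Experience", weights=(0.0, 1.0, 0.0)),
        ModelSpec("Type", weights=(0.0, 0.0, 1.0)),
        ModelSpec("Mod|Exp|Type", weights=(1.0, 1.0, 1.0)),
        ModelSpec("Mod|(Exp|Type)/2", weights=(1.0, 0.5, 0.5)),
        ModelSpec("Mod|(Exp|Type)/3", weights=(1.0, 1.0 / 3.0, 1.0 / 3.0)),
        ModelSpec("Exp|(Mod|Type)/2", weights=(0.5, 1.0, 0.5)),
        ModelSpec("Exp|(Mod|Type)/3", weights=(1.0 / 3.0, 1.0, 1.0 / 3.0)),
    ]
    if include_partial:
        family.append(ModelSpec("Exp|Type", weights=(0.0, 1.0, 1.0)))
    return family


def average_rdm(rdms: list[RDM]) -> RDM:
    """Entrywise mean of RDMs sharing one label order."""
    if not rdms:
        raise ValueError("need at least one RDM to average")
    labels = rdms[0].labels
    for r in rdms:
        if r.labels != labels:
            raise ValueError("cannot average RDMs with mismatched label order")
    return RDM(np.mean([r.matrix for r in rdms], axis=0), labels)


# ---------------------------------------------------------------------------
# Neural RDMs from condition patterns
# ---------------------------------------------------------------------------

def zscore_patterns(patterns: np.ndarray) -> np.ndarray:
    """Standardize each condition pattern to mean 0, SD 1 across channels.

    Parameters
    ----------
    patterns:
        Array of shape ``(..., n_conditions, n_channels)``; standardization is
        along the last axis with the population-SD convention (ddof=0).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[-1] < 2:
        raise ValueError("z-scoring requires at least 2 channels")
    mu = patterns.mean(axis=-1, keepdims=True)
    sd = patterns.std(axis=-1, keepdims=True)
    bad = np.nonzero(sd < 1e-300)
    if bad[0].size:
        idx = tuple(b[0] for b in bad)
        raise ValueError(f"zero-variance pattern at index {idx[:-1]}")
    return (patterns - mu) / sd


def compute_neural_rdm(
    patterns: np.ndarray,
    labels: tuple[str, ...] = CONDITIONS,
    zscore: bool = True,
) -> RDM:
    """Squared-Euclidean-distance RDM between condition patterns of one subject.

    Patterns are z-scored across channels first (disable with ``zscore=False``
    for raw-distance checks).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("expected a (n_conditions, n_channels) pattern array")
    if patterns.shape[0] != len(labels):
        missing = len(labels) - patterns.shape[0]
        raise ValueError(
            f"expected {len(labels)} condition patterns, got {patterns.shape[0]} "
            f"({missing} missing)"
        )
    if zscore:
        patterns = zscore_patterns(patterns)
    sq = np.sum(patterns**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * patterns @ patterns.T
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    return RDM((d2 + d2.T) / 2.0, labels)
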