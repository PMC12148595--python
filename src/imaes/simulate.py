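"""Synthetic behavioral and neural data with known ground truth.

The generator emulates the study design it is built to exercise: 34 subjects
rate 20 artworks and 20 faces on three 7-point scales (pleasure, beauty,
moving) once under visual perception and once under mental imagery, reporting
the vividness of each mental image; neural data are per-subject activity
patterns for the eight conditions crossing experience (high/low), modality
(perception/imagery) and stimulus type (art/face).

Ratings follow the generative structure of a cumulative probit model:
a latent normal variable (subject and stimulus random intercepts plus
modality and type effects) is cut by ordered thresholds.  Imagery trials with
low reported vividness receive extra latent noise, so perception and imagery
responses diverge more when the mental image is faint.

Neural condition means are constructed so that their pairwise squared
Euclidean distances are exactly proportional to a planted weighted
combination of the modality / experience / type indicator RDMs (classical
multidimensional-scaling embedding of the double-centered distance matrix);
independent Gaussian channel noise is added per subject and condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rdm import CONDITIONS, RDM, ModelSpec, combine_weighted, independent_rdm

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "GroundTruthGeometry",
    "PatternSet",
    "RATING_DIMS",
    "generate_ratings",
    "generate_patterns",
    "vividness_noise_scale",
    "write_dataset",
]

RATING_DIMS = ("pleasure", "beauty", "moving")

#: Default vividness distribution over 1..7.  Trained imagery raters report
#: mostly vivid images with a long low tail; not pinned down by any dataset,
#: it is a configuration choice.
DEFAULT_VIVIDNESS_PROBS = (0.02, 0.04, 0.08, 0.16, 0.25, 0.25, 0.20)


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: who rates what, how often, on what scale."""

    n_subjects: int = 34
    n_stimuli_per_type: int = 20
    n_runs: int = 4
    scale_k: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.scale_k < 3:
            raise ValueError("ordinal scale needs at least 3 categories")
        if self.n_stimuli_per_type < 1:
            raise ValueError("need at least 1 stimulus per type")
        if self.n_runs < 1:
            raise ValueError("need at least 1 run")

    @property
    def n_stimuli(self) -> int:
        return 2 * self.n_stimuli_per_type

    @property
    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def stimuli(self) -> pd.DataFrame:
        """Stimulus table with id and type (art stimuli first)."""
        ids = [f"art-{i + 1:02d}" for i in range(self.n_stimuli_per_type)] + [
            f"face-{i + 1:02d}" for i in range(self.n_stimuli_per_type)
        ]
        types = ["art"] * self.n_stimuli_per_type + ["face"] * self.n_stimuli_per_type
        return pd.DataFrame({"stimulus_id": ids, "stimulus_type": types})


@dataclass(frozen=True)
class EffectSpec:
    """Latent-scale effects of the rating generator.

    ``beta_modality`` is the imagery-minus-perception shift and ``beta_type``
    the face-minus-art shift, both on the unit-residual latent probit scale.
    ``thresholds`` are the ordered category cutpoints; ``kappa`` scales the
    vividness-coupled extra noise on imagery trials (0 = perfectly coupled
    modalities up to categorization noise).
    """

    beta_modality: float = -0.29
    beta_type: float = -0.56
    thresholds: tuple[float, ...] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
    sd_subject: float = 0.5
    sd_stimulus: float = 0.3
    vividness_probs: tuple[float, ...] = DEFAULT_VIVIDNESS_PROBS
    kappa: float = 3.6
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        tau = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.sd_subject < 0 or self.sd_stimulus < 0:
            raise ValueError("random-intercept SDs must be nonnegative")
        if self.kappa < 0:
            raise ValueError("vividness coupling kappa must be nonnegative")
        p = np.asarray(self.vividness_probs, dtype=float)
        if len(p) != 7 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("vividness_probs must be 7 nonnegative values summing to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def scale_k_expected(self) -> int:
        return len(self.thresholds) + 1


def vividness_noise_scale(v: np.ndarray | int) -> np.ndarray:
    """Linear coupling map f(v) = (7 - v) / 6: zero extra noise at maximal
    vividness, full strength at v = 1."""
    return (7.0 - np.asarray(v, dtype=float)) / 6.0


def _categorize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map latent values to 1..K through the ordered thresholds."""
    return np.searchsorted(thresholds, latent) + 1


def generate_ratings(design: DesignSpec, effects: EffectSpec) -> pd.DataFrame:
    """Simulate the long-format ratings table.

    One row per (subject, stimulus, modality) with columns for the three
    rating dimensions, the run assignment and — on imagery rows — the trial's
    vividness.  The three dimensions share the trial's vividness draw but have
    independent random intercepts and noise, matching the per-dimension model
    fits downstream.  Fully reproducible from ``design.seed``.
    """
    if effects.scale_k_expected() != design.scale_k:
        raise ValueError(
            f"thresholds imply {effects.scale_k_expected()} categories, "
            f"design says {design.scale_k}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    tau = np.asarray(effects.thresholds, dtype=float)
    stim = design.stimuli
    n_subj, n_stim = design.n_subjects, design.n_stimuli
    is_face = (stim["stimulus_type"] == "face").to_numpy(dtype=float)

    # run assignment: every stimulus appears in exactly one run per subject
    runs = np.empty((n_subj, n_stim), dtype=int)
    base = np.arange(n_stim) % design.n_runs + 1
    for s in range(n_subj):
        runs[s] = base[rng.permutation(n_stim)]

    # vividness per (subject, stimulus) imagery trial, shared across dimensions
    vividness = rng.choice(
        np.arange(1, 8), size=(n_subj, n_stim), p=np.asarray(effects.vividness_probs)
    )

    frames = []
    for dim in RATING_DIMS:
        u_subj = rng.normal(0.0, effects.sd_subject, size=n_subj)
        u_stim = rng.normal(0.0, effects.sd_stimulus, size=n_stim)
        mu = u_subj[:, None] + u_stim[None, :] + effects.beta_type * is_face[None, :]
        lat_per = mu + rng.normal(size=(n_subj, n_stim))
        coupling = effects.kappa * vividness_noise_scale(vividness)
        lat_img = (
            mu
            + effects.beta_modality
            + coupling * rng.normal(size=(n_subj, n_stim))
            + rng.normal(size=(n_subj, n_stim))
        )
        frames.append(
            {
                "perception": _categorize(lat_per, tau),
                "imagery": _categorize(lat_img, tau),
            }
        )

    rows = {
        "subject_id": np.repeat(design.subjects, n_stim * 2),
        "stimulus_id": np.tile(np.repeat(stim["stimulus_id"].to_numpy(), 2), n_subj),
        "stimulus_type": np.tile(
            np.repeat(stim["stimulus_type"].to_numpy(), 2), n_subj
        ),
        "modality": np.tile(["perception", "imagery"], n_subj * n_stim),
        "run": np.repeat(runs.reshape(-1), 2),
    }
    table = pd.DataFrame(rows)
    for dim, lat in zip(RATING_DIMS, frames):
        stacked = np.stack([lat["perception"], lat["imagery"]], axis=-1)  # s,t,2
        table[dim] = stacked.reshape(-1).astype(float)
    viv_col = np.stack(
        [np.full((n_subj, n_stim), np.nan), vividness.astype(float)], axis=-1
    ).reshape(-1)
    table["vividness"] = viv_col

    if effects.missing_rate > 0:
        for dim in RATING_DIMS:
            drop = rng.random(len(table)) < effects.missing_rate
            table.loc[drop, dim] = np.nan
    return table


# ---------------------------------------------------------------------------
# Neural patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthGeometry:
    """Planted representational geometry for pattern simulation.

    The target RDM is ``w_mod * M + w_exp * E + w_type * T`` over the eight
    conditions (``independent=True`` plants the all-different geometry
    instead).  Condition means are scaled so their mean squared channel value
    is 1; ``noise_sd`` is therefore the channel noise SD relative to unit
    signal amplitude.
    """

    w_mod: float = 1.0
    w_exp: float = 0.0
    w_type: float = 0.0
    independent: bool = False
    n_channels: int = 200
    noise_sd: float = 0.4
    subject_sd: float = 0.15
    noise_het: float = 1.0
    embed_dim: int | None = None

    def __post_init__(self) -> None:
        if not self.independent:
            if min(self.w_mod, self.w_exp, self.w_type) < 0:
                raise ValueError("geometry weights must be nonnegative")
            if max(self.w_mod, self.w_exp, self.w_type) <= 0:
                raise ValueError("at least one geometry weight must be positive")
        if self.n_channels < 8:
            raise ValueError("need at least 8 channels")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if self.subject_sd < 0:
            raise ValueError("subject SD must be nonnegative")
        if self.noise_het < 0:
            raise ValueError("noise heterogeneity must be nonnegative")

    @classmethod
    def from_model(cls, spec: ModelSpec, **kwargs) -> "GroundTruthGeometry":
        if spec.independent:
            return cls(independent=True, **kwargs)
        w_mod, w_exp, w_type = spec.weights  # type: ignore[misc]
        return cls(w_mod=w_mod, w_exp=w_exp, w_type=w_type, **kwargs)

    def target_rdm(self) -> RDM:
        if self.independent:
            return independent_rdm()
        return combine_weighted(
            ModelSpec("planted", weights=(self.w_mod, self.w_exp, self.w_type))
        )


@dataclass(frozen=True)
class PatternSet:
    """Per-subject condition activity patterns.

    ``data`` has shape (n_subjects, n_conditions, n_channels); condition order
    is ``labels`` (canonical by default).
    """

    subjects: tuple[str, ...]
    data: np.ndarray = field(repr=False)
    labels: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("pattern data must be (subjects, conditions, channels)")
        if d.shape[0] != len(self.subjects):
            raise ValueError("subject count mismatch")
        if d.shape[1] != len(self.labels):
            raise ValueError("condition count mismatch")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def _cosine_basis(rank: int, n_channels: int) -> np.ndarray:
    """Deterministic orthonormal (rank, n_channels) basis, each vector
    orthogonal to the constant channel, so embedded patterns have zero
    channel mean and z-scoring preserves the planted distances up to scale."""
    if rank > n_channels - 1:
        raise ValueError("embedding rank exceeds available channels")
    p = np.arange(n_channels)
    basis = np.array(
        [np.cos(np.pi * (k + 1) * (p + 0.5) / n_channels) for k in range(rank)]
    )
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    return basis


def _embed_coords(geom: GroundTruthGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Embedding coordinates (8, rank) and channel basis (rank, n_channels)."""
    d_star = geom.target_rdm().matrix
    n = d_star.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d_star @ j
    evals, evecs = np.linalg.eigh(b)
    tol = 1e-10 * max(evals.max(), 1.0)
    if evals.min() < -tol:
        raise ValueError(
            "planted RDM with weights "
            f"({geom.w_mod}, {geom.w_exp}, {geom.w_type}) is not Euclidean-embeddable"
        )
    keep = evals > tol
    rank = int(keep.sum())
    if geom.embed_dim is not None:
        if geom.embed_dim < rank:
            raise ValueError(f"embed_dim {geom.embed_dim} below required rank {rank}")
        rank = min(geom.embed_dim, n - 1)
        keep = np.argsort(evals)[::-1][:rank]
    coords = evecs[:, keep] * np.sqrt(np.maximum(evals[keep], 0.0))
    # unit mean squared channel amplitude across conditions
    scale = np.sqrt(geom.n_channels / np.mean(np.sum(coords**2, axis=1)))
    coords = coords * scale
    basis = _cosine_basis(coords.shape[1], geom.n_channels)
    return coords, basis


def embed_condition_means(geom: GroundTruthGeometry) -> np.ndarray:
    """Classical-MDS embedding of the planted RDM into channel space.

    Returns an (8, n_channels) array of condition means whose pairwise
    squared Euclidean distances are exactly proportional to the planted RDM.
    """
    coords, basis = _embed_coords(geom)
    return coords @ basis


def generate_patterns(design: DesignSpec, geom: GroundTruthGeometry) -> PatternSet:
    """Simulate per-subject condition patterns with the planted geometry.

    Each subject's true condition means are the planted embedding perturbed
    within the signal subspace (displacement SD ``subject_sd`` relative to
    the RMS embedding coordinate), emulating between-subject variability in
    representational geometry; independent N(0, noise_sd^2) channel noise is
    then added per subject and condition.  Reproducible from ``design.seed``.
    """
    coords, basis = _embed_coords(geom)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))
    n_subj = design.n_subjects
    n_cond = len(CONDITIONS)
    if geom.subject_sd > 0:
        rms = np.sqrt(np.mean(coords**2))
        jitter = rng.normal(
            0.0, geom.subject_sd * rms, size=(n_subj, n_cond, coords.shape[1])
        )
        means = (coords[None, :, :] + jitter) @ basis
    else:
        means = np.broadcast_to(
            coords @ basis, (n_subj, n_cond, geom.n_channels)
        ).copy()
    if geom.noise_sd > 0:
        # per-subject noise levels are lognormal around noise_sd: subjects
        # differ substantially in measurement noise (motion, physiology),
        # which is what gives the noise ceiling its between-subject spread
        # normalized so E[sigma_s^2] = noise_sd^2 at any heterogeneity
        sigma_s = geom.noise_sd * np.exp(
            rng.normal(0.0, geom.noise_het, size=n_subj) - geom.noise_het**2
        )
        means = means + sigma_s[:, None, None] * rng.normal(
            size=(n_subj, n_cond, geom.n_channels)
        )
    return PatternSet(subjects=tuple(design.subjects), data=means)


def write_dataset(
    ratings: pd.DataFrame,
    patterns: PatternSet,
    path,
    design: DesignSpec | None = None,
    effects: EffectSpec | None = None,
    geometry: GroundTruthGeometry | None = None,
) -> dict:
    """Write ratings (TSV), patterns (NIfTI + mask + sidecar) and a manifest.

    Returns the manifest dict.  Delegates to :mod:`imaes.io`; the written
    dataset round-trips losslessly through ``read_ratings`` /
    ``read_patterns``.
    """
    from . import io as _io

    subj_ratings = set(ratings["subject_id"].unique())
    if not subj_ratings <= set(patterns.subjects) and not (
        set(patterns.subjects) <= subj_ratings
    ):
        raise ValueError("ratings and patterns disagree on the subject set")
    manifest = {
        "conditions": list(patterns.labels),
        "n_subjects": len(patterns.subjects),
        "n_channels": patterns.n_channels,
    }
    for name, spec in (
        ("design", design),
        ("effects", effects),
        ("geometry", geometry),
    ):
        if spec is not None:
            manifest[name] = dataclasses.asdict(spec)
    return _io.write_dataset_files(ratings, patterns, path, manifest)
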