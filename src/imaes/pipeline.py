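"""End-to-end analysis pipeline: simulate -> behavior -> RDMs -> inference.

`run_pipeline` executes the full study emulation from a single
:class:`RunConfig`: it generates (or loads) a dataset, runs the behavioral
models on the chosen rating dimension, builds per-subject neural RDMs,
evaluates the candidate model family with bootstrap uncertainty and noise
ceilings, and writes tables, figures and a Markdown report plus a JSON run
manifest.  All randomness flows from the explicit seeds in the config; no
stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import behavior, io
from .bayes import McmcConfig, fit_cumulative_probit, fit_vividness_regression, rope_bayes_factor
from .inference import (
    bootstrap_evaluate,
    compare_models,
    noise_ceiling,
    whitening_matrix,
)
from .rdm import RDM, average_rdm, candidate_family, compute_neural_rdm
from .simulate import (
    DesignSpec,
    EffectSpec,
    GroundTruthGeometry,
    PatternSet,
    generate_patterns,
    generate_ratings,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "subject_rdms"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Complete specification of a pipeline run."""

    out_dir: str = "imaes_run"
    design: DesignSpec = field(default_factory=DesignSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    geometry: GroundTruthGeometry = field(default_factory=GroundTruthGeometry)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    dimension: str = "moving"
    n_boot: int = 2000
    whitening: str = "distance-covariance"
    include_partial: bool = False
    subset_high_vividness: bool = False
    fit_behavior: bool = True
    bootstrap_seed: int = 7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = io.load_config(path)
        kwargs = dict(cfg)
        for key, klass in (
            ("design", DesignSpec),
            ("effects", EffectSpec),
            ("geometry", GroundTruthGeometry),
            ("mcmc", McmcConfig),
        ):
            if key in kwargs:
                sub = dict(kwargs[key])
                for tup_key in ("thresholds", "vividness_probs"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Outputs of one pipeline run (also written under ``config.out_dir``)."""

    config: RunConfig
    ratings: pd.DataFrame
    scores: pd.DataFrame
    posterior_summary: pd.DataFrame | None
    rope: dict | None
    evaluation_table: pd.DataFrame
    mean_rdm: RDM
    report_path: Path


def subject_rdms(patterns: PatternSet, zscore: bool = True) -> list[RDM]:
    """Per-subject squared-distance RDMs from a pattern set."""
    return [
        compute_neural_rdm(patterns.data[i], patterns.labels, zscore=zscore)
        for i in range(len(patterns.subjects))
    ]


def _stage(name: str):
    log.info("pipeline stage: %s", name)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    _stage("simulate")
    try:
        ratings = generate_ratings(config.design, config.effects)
        patterns = generate_patterns(config.design, config.geometry)
    except Exception as err:
        raise RuntimeError(f"simulate stage failed: {err}") from err
    io.write_ratings(ratings, out / "ratings.tsv")

    # --- behavior -----------------------------------------------------------
    _stage("behavior")
    try:
        complete = behavior.complete_case_filter(ratings)
        analysed = complete
        subset_label = "all trials"
        if config.subset_high_vividness:
            analysed = behavior.subset_high_vividness(complete)
            subset_label = "high-vividness subset (vividness 6-7)"
        scores = behavior.dissimilarity_score(complete)
        scores.to_csv(out / "dissimilarity_scores.tsv", sep="\t", index=False)
        posterior_summary = None
        rope_info = None
        if config.fit_behavior:
            post = fit_cumulative_probit(
                analysed, dimension=config.dimension, config=config.mcmc
            )
            posterior_summary = post.summary()
            posterior_summary.to_csv(out / "posterior_summary.csv", index=False)
            rope = rope_bayes_factor(post, "beta_modality")
            rope_info = dataclasses.asdict(rope)
            (out / "rope.json").write_text(json.dumps(rope_info, indent=2, default=str))
            viv = fit_vividness_regression(scores, config=config.mcmc)
            viv.summary().to_csv(out / "vividness_summary.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"behavior stage failed: {err}") from err

    # --- rdm ----------------------------------------------------------------
    _stage("rdm")
    try:
        rdms = subject_rdms(patterns)
        mean_rdm = average_rdm(rdms)
        io.write_rdm_csv(mean_rdm, out / "mean_rdm.csv")
        family = candidate_family(include_partial=config.include_partial)
        model_rdms = [m.rdm() for m in family]
        names = [m.name for m in family]
    except Exception as err:
        raise RuntimeError(f"rdm stage failed: {err}") from err

    # --- inference ----------------------------------------------------------
    _stage("inference")
    try:
        wm = whitening_matrix(mode=config.whitening)
        evaluation = bootstrap_evaluate(
            rdms,
            model_rdms,
            model_names=names,
            whitening=wm,
            n_boot=config.n_boot,
            seed=config.bootstrap_seed,
        )
        ceiling = noise_ceiling(rdms, wm)
        comparison = compare_models(evaluation, ceiling)
        table = pd.DataFrame(
            {
                "model": names,
                "mean": evaluation.mean,
                "sem": evaluation.sem,
                "ci_lo": evaluation.ci_low,
                "ci_hi": evaluation.ci_high,
                "above_zero": comparison.vs_zero_p < 0.05,
                "below_ceiling": comparison.below_ceiling,
            }
        )
        table.to_csv(out / "model_evaluation.csv", index=False)
        pd.DataFrame(
            {
                "model_a": [names[i] for i, _ in comparison.pair_index],
                "model_b": [names[j] for _, j in comparison.pair_index],
                "t": comparison.pair_t,
                "p": comparison.pair_p,
                "q": comparison.pair_q,
                "significant": comparison.pair_significant,
            }
        ).to_csv(out / "model_comparisons.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"inference stage failed: {err}") from err

    # --- report -------------------------------------------------------------
    _stage("report")
    fig_rdm = out / "mean_rdm.png"
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(mean_rdm.matrix, cmap="viridis")
    ax.set_xticks(range(8), mean_rdm.labels, rotation=90)
    ax.set_yticks(range(8), mean_rdm.labels)
    fig.colorbar(im, ax=ax, label="squared distance")
    fig.tight_layout()
    fig.savefig(fig_rdm, dpi=120)
    plt.close(fig)

    fig_bar = out / "model_scores.png"
    fig, ax = plt.subplots(figsize=(6.4, 3.6))
    xs = np.arange(len(names))
    ax.bar(xs, evaluation.mean, color="#4878a8")
    ax.errorbar(
        xs,
        evaluation.mean,
        yerr=[evaluation.mean - evaluation.ci_low, evaluation.ci_high - evaluation.mean],
        fmt="none",
        ecolor="black",
        capsize=2,
    )
    ax.axhspan(ceiling.lower, ceiling.upper, color="gray", alpha=0.3, label="noise ceiling")
    ax.set_xticks(xs, names, rotation=60, ha="right")
    ax.set_ylabel("whitened cosine similarity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(fig_bar, dpi=120)
    plt.close(fig)

    report = out / "report.md"
    lines = [
        "# Pipeline report",
        "",
        f"Behavioral analysis subset: {subset_label}.",
        f"Whitening mode: {config.whitening}; bootstrap resamples: {config.n_boot}.",
        "",
        "## Neural model evaluation",
        "",
        table.to_markdown(index=False, floatfmt=".3f"),
        "",
        f"Noise ceiling: lower {ceiling.lower:.3f}, upper {ceiling.upper:.3f}.",
        "",
        f"![mean RDM]({fig_rdm.name})",
        f"![model scores]({fig_bar.name})",
    ]
    if posterior_summary is not None:
        keep = posterior_summary[
            posterior_summary["parameter"].str.startswith(("beta", "sigma"))
        ]
        lines += ["", "## Behavioral posterior", "", keep.to_markdown(index=False, floatfmt=".3f")]
    if rope_info is not None:
        lines += [
            "",
            f"ROPE {rope_info['rope']} BF01 for beta_modality: {rope_info['bf01']:.2f}",
        ]
    report.write_text("\n".join(lines) + "\n")

    manifest = {
        "config": dataclasses.asdict(config),
        "n_subjects": config.design.n_subjects,
        "n_complete_rows": int(len(complete)),
        "n_analysed_rows": int(len(analysed)),
        "noise_ceiling": {"lower": ceiling.lower, "upper": ceiling.upper},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        config=config,
        ratings=ratings,
        scores=scores,
        posterior_summary=posterior_summary,
        rope=rope_info,
        evaluation_table=table,
        mean_rdm=mean_rdm,
        report_path=report,
    )
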