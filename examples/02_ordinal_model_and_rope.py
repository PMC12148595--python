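"""Fit the hierarchical cumulative probit model and test for equivalence.

Asks whether being "moved" differs between perception and imagery, and then
quantifies evidence that any difference is negligible via a ROPE Bayes
factor on the standardized modality effect.
"""

from imaes import (
    DesignSpec,
    EffectSpec,
    McmcConfig,
    fit_cumulative_probit,
    generate_ratings,
    rope_bayes_factor,
)

design = DesignSpec(n_subjects=34, n_stimuli_per_type=20, seed=2)
ratings = generate_ratings(design, EffectSpec())

fit = fit_cumulative_probit(
    ratings, dimension="moving", config=McmcConfig(chains=2, warmup=800, draws=800, seed=0)
)
summary = fit.summary()
print(summary[summary.parameter.str.startswith(("beta", "sigma"))].round(3).to_string(index=False))
print(f"\nconverged: {fit.converged}")

rope = rope_bayes_factor(fit, "beta_modality")
print(
    f"\nROPE {rope.rope}: posterior mass {rope.posterior_mass:.3f}, "
    f"prior mass {rope.prior_mass:.3f}, BF01 = {rope.bf01:.2f}"
)
print(
    "BF01 > 1 favours practical equivalence of imagery and perception;"
    " here the generator plants a small negative modality effect, so the"
    " posterior sits mostly outside the ROPE."
)
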