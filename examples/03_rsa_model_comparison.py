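"""Representational similarity analysis with a planted geometry.

Plants a modality-dominated 8-condition geometry in synthetic voxel
patterns, scores the nine candidate condition models with the whitened
cosine, and brackets the best achievable score with a noise ceiling.
"""

import numpy as np

from imaes import (
    DesignSpec,
    GroundTruthGeometry,
    bootstrap_evaluate,
    candidate_family,
    compare_models,
    generate_patterns,
    noise_ceiling,
    subject_rdms,
    whitening_matrix,
)

design = DesignSpec(n_subjects=30, seed=3)
geometry = GroundTruthGeometry(w_mod=1.0, w_exp=1 / 3.0, w_type=1 / 3.0)
patterns = generate_patterns(design, geometry)
rdms = subject_rdms(patterns)

family = candidate_family()
whitener = whitening_matrix(8)
evaluation = bootstrap_evaluate(
    rdms,
    [m.rdm() for m in family],
    [m.name for m in family],
    whitening=whitener,
    seed=0,
)
ceiling = noise_ceiling(rdms, whitener)
table = compare_models(evaluation, ceiling)

for name, mean, lo, hi in zip(
    evaluation.model_names, evaluation.mean, evaluation.ci_low, evaluation.ci_high
):
    print(f"{name:>18}: {mean:.3f}  [{lo:.3f}, {hi:.3f}]")
print(f"\nnoise ceiling: [{ceiling.lower:.3f}, {ceiling.upper:.3f}]")

best = int(np.argmax(evaluation.mean))
print(f"best model: {evaluation.model_names[best]}")
print(f"below lower ceiling after correction: {bool(table.below_ceiling[best])}")
print(
    "\nThe graded Mod|(Exp|Type)/3 model wins and reaches the ceiling,"
    " matching the geometry that was planted."
)
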