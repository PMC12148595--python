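"""Simulate a rating study and compute cross-modality dissimilarity scores.

Generates ordinal aesthetic ratings for 34 subjects who judge 40 stimuli
(art and faces) under both visual perception and mental imagery, then sums
the squared perception-minus-imagery differences over the three rating
dimensions per stimulus.
"""

from imaes import DesignSpec, EffectSpec, dissimilarity_score, generate_ratings

design = DesignSpec(n_subjects=34, n_stimuli_per_type=20, seed=1)
ratings = generate_ratings(design, EffectSpec())
scores = dissimilarity_score(ratings)

print(ratings.head(4).to_string(index=False))
print(f"\n{len(scores)} perception/imagery pairs scored")
print(scores["score"].describe().round(2).to_string())
by_viv = scores.groupby("vividness")["score"].mean().round(2)
print("\nmean score by imagery vividness:")
print(by_viv.to_string())
print(
    "\nScores shrink as vividness rises: vivid imagery reproduces the"
    " perceptual aesthetic judgment more faithfully."
)
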