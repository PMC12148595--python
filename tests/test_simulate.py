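"""Synthetic-data generator: determinism, planted effects, planted geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imaes import (
    DesignSpec,
    EffectSpec,
    GroundTruthGeometry,
    candidate_family,
    generate_patterns,
    generate_ratings,
)
from imaes.behavior import dissimilarity_score
from imaes.rdm import compute_neural_rdm
from imaes.simulate import embed_condition_means, vividness_noise_scale


class TestDesignValidation:
    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            DesignSpec(n_subjects=1)
        with pytest.raises(ValueError):
            DesignSpec(scale_k=2)
        with pytest.raises(ValueError):
            EffectSpec(thresholds=(0.0, -1.0, 1.0, 2.0, 3.0, 4.0))
        with pytest.raises(ValueError):
            EffectSpec(vividness_probs=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.5))
        with pytest.raises(ValueError):
            GroundTruthGeometry(w_mod=0.0, w_exp=0.0, w_type=0.0)

    def test_threshold_count_must_match_scale(self):
        d = DesignSpec(n_subjects=3, n_stimuli_per_type=2, scale_k=5)
        with pytest.raises(ValueError, match="categories"):
            generate_ratings(d, EffectSpec())


class TestRatings:
    def test_structure_and_run_assignment(self, small_design, small_ratings):
        r = small_ratings
        n = small_design.n_subjects * small_design.n_stimuli * 2
        assert len(r) == n
        # vividness present exactly on imagery rows
        assert r.loc[r.modality == "imagery", "vividness"].notna().all()
        assert r.loc[r.modality == "perception", "vividness"].isna().all()
        # every stimulus appears in exactly one run per subject
        runs = r.groupby(["subject_id", "stimulus_id"])["run"].nunique()
        assert (runs == 1).all()
        for dim in ("pleasure", "beauty", "moving"):
            assert r[dim].between(1, 7).all()

    def test_seed_determinism(self, small_design):
        a = generate_ratings(small_design, EffectSpec())
        b = generate_ratings(small_design, EffectSpec())
        pd.testing.assert_frame_equal(a, b)
        c = generate_ratings(
            DesignSpec(**{**small_design.__dict__, "seed": 99}), EffectSpec()
        )
        assert not a[["pleasure", "beauty", "moving"]].equals(
            c[["pleasure", "beauty", "moving"]]
        )

    def test_null_generator_score_independent_of_vividness(self):
        # with no effects and no coupling, the dissimilarity score has the
        # same distribution in high- and low-vividness trials
        d = DesignSpec(n_subjects=50, n_stimuli_per_type=50, seed=7)
        eff = EffectSpec(
            beta_modality=0.0,
            beta_type=0.0,
            sd_subject=0.0,
            sd_stimulus=0.0,
            kappa=0.0,
            vividness_probs=(1 / 7.0,) * 7,
        )
        scores = dissimilarity_score(generate_ratings(d, eff))
        assert len(scores) == 5000
        low = scores.loc[scores.vividness <= 3, "score"]
        high = scores.loc[scores.vividness >= 5, "score"]
        table = pd.crosstab(
            scores["vividness"] >= 4, pd.cut(scores["score"], [-1, 0, 2, 5, 10, 200])
        )
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01
        assert abs(low.mean() - high.mean()) < 0.5

    def test_coupling_makes_score_grow_as_vividness_drops(self):
        d = DesignSpec(n_subjects=100, n_stimuli_per_type=50, seed=13)
        eff = EffectSpec(
            beta_modality=0.0,
            beta_type=0.0,
            sd_subject=0.0,
            sd_stimulus=0.0,
            kappa=3.6,
            vividness_probs=(1 / 7.0,) * 7,
        )
        scores = dissimilarity_score(generate_ratings(d, eff))
        means = scores.groupby("vividness")["score"].mean()
        # about 1400 trials per vividness level; means strictly decrease in v
        assert (np.diff(means.to_numpy()) < 0).all()

    def test_coupling_scale_map(self):
        assert vividness_noise_scale(7) == 0.0
        assert vividness_noise_scale(1) == 1.0
        v = np.arange(1, 8)
        assert (np.diff(vividness_noise_scale(v)) < 0).all()

    def test_mcar_missingness_rate(self):
        d = DesignSpec(n_subjects=30, n_stimuli_per_type=20, seed=5)
        r = generate_ratings(d, EffectSpec(missing_rate=0.1))
        rate = r[["pleasure", "beauty", "moving"]].isna().to_numpy().mean()
        assert 0.08 < rate < 0.12


class TestPatterns:
    def test_noiseless_rdm_proportional_to_planted(self, noiseless_geometry):
        d = DesignSpec(n_subjects=3, seed=2)
        pats = generate_patterns(d, noiseless_geometry)
        target = noiseless_geometry.target_rdm().matrix
        got = compute_neural_rdm(pats.data[0], zscore=False).matrix
        ratio = got[0, 4] / target[0, 4]
        assert ratio > 0
        assert np.allclose(got, ratio * target, rtol=1e-10, atol=1e-8)

    def test_modality_only_geometry_structure(self):
        geom = GroundTruthGeometry(
            w_mod=1.0, w_exp=0.0, w_type=0.0, noise_sd=0.0, subject_sd=0.0
        )
        means = embed_condition_means(geom)
        r = compute_neural_rdm(means, zscore=False).matrix
        # within-modality distances vanish; cross-modality all equal
        perception = slice(0, 4)
        imagery = slice(4, 8)
        assert np.allclose(r[perception, perception], 0.0, atol=1e-10)
        assert np.allclose(r[imagery, imagery], 0.0, atol=1e-10)
        cross = r[perception, imagery]
        assert np.allclose(cross, cross.flat[0], rtol=1e-10)
        assert cross.flat[0] > 0

    def test_equal_weights_rank_correlation(self):
        d = DesignSpec(n_subjects=30, seed=21)
        geom = GroundTruthGeometry(
            w_mod=1.0, w_exp=1.0, w_type=1.0, noise_sd=0.05, subject_sd=0.0,
            noise_het=0.0,
        )
        pats = generate_patterns(d, geom)
        mean_rdm = np.mean(
            [compute_neural_rdm(pats.data[i]).matrix for i in range(30)], axis=0
        )
        model = geom.target_rdm()
        iu = np.triu_indices(8, 1)
        # noise adds a near-constant offset to every squared distance, so the
        # mean RDM is approximately an affine map of the planted model
        rho, _ = stats.pearsonr(mean_rdm[iu], model.matrix[iu])
        assert rho > 0.99

    def test_pattern_determinism(self):
        d = DesignSpec(n_subjects=4, seed=8)
        g = GroundTruthGeometry()
        assert np.array_equal(
            generate_patterns(d, g).data, generate_patterns(d, g).data
        )

    def test_zscoring_preserves_planted_geometry_exactly(self, noiseless_geometry):
        # embedded means have zero channel-mean and equal norms, so the
        # z-scored RDM stays proportional to the planted one
        d = DesignSpec(n_subjects=2, seed=4)
        pats = generate_patterns(d, noiseless_geometry)
        target = noiseless_geometry.target_rdm().matrix
        got = compute_neural_rdm(pats.data[0], zscore=True).matrix
        ratio = got[0, 4] / target[0, 4]
        assert np.allclose(got, ratio * target, rtol=1e-10, atol=1e-8)

    def test_every_family_geometry_is_embeddable(self):
        for spec in candidate_family(include_partial=True):
            geom = GroundTruthGeometry.from_model(spec, noise_sd=0.0, subject_sd=0.0)
            means = embed_condition_means(geom)
            assert means.shape == (8, geom.n_channels)
            # channel means vanish by construction
            assert np.allclose(means.mean(axis=1), 0.0, atol=1e-10)
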