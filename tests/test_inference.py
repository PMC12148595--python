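"""Whitened cosine, noise ceiling, bootstrap and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imaes import (
    DesignSpec,
    GroundTruthGeometry,
    bootstrap_evaluate,
    candidate_family,
    compare_models,
    generate_patterns,
    noise_ceiling,
    whitened_cosine,
    whitening_matrix,
)
from imaes.inference import _pair_contrast_matrix, score_matrix
from imaes.pipeline import subject_rdms
from imaes.rdm import RDM


def random_rdms(n_subjects, seed):
    rng = np.random.default_rng(seed)
    return [RDM.from_vector(rng.random(28)) for _ in range(n_subjects)]


class TestWhitening:
    def test_contrast_matrix_diagonal(self):
        c = _pair_contrast_matrix(8)
        assert c.shape == (28, 8)
        assert np.allclose(np.diag(c @ c.T), 2.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_distance_covariance_is_spd_unit_trace(self, n):
        w = whitening_matrix(n, mode="distance-covariance")
        v = w.matrix
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) > 0)
        assert np.trace(v) == pytest.approx(1.0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            whitening_matrix(8, mode="mahalanobis")

    def test_identity_mode_matches_plain_cosine(self):
        # independently coded cosine, no whitening machinery
        rng = np.random.default_rng(17)
        w = whitening_matrix(8, mode="identity")
        for _ in range(20):
            a, b = rng.random(28), rng.random(28)
            plain = float(a @ b / np.sqrt((a @ a) * (b @ b)))
            assert abs(whitened_cosine(a, b, w) - plain) < 1e-12
            assert abs(whitened_cosine(a, b, None) - plain) < 1e-12


class TestWhitenedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(2)
        w = whitening_matrix(8)
        for _ in range(5):
            v = rng.random(28)
            assert whitened_cosine(v, v, w) == pytest.approx(1.0)

    def test_scale_invariance_and_symmetry(self):
        rng = np.random.default_rng(3)
        w = whitening_matrix(8)
        a, b = rng.random(28), rng.random(28)
        s = whitened_cosine(a, b, w)
        assert whitened_cosine(3.5 * a, 0.2 * b, w) == pytest.approx(s)
        assert whitened_cosine(b, a, w) == pytest.approx(s)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=28), rng.normal(size=28)
        w = whitening_matrix(8)
        assert abs(whitened_cosine(a, b, w)) <= 1.0 + 1e-10

    def test_accepts_rdm_objects(self):
        fam = candidate_family()
        s = whitened_cosine(fam[1].rdm(), fam[1].rdm().vector)
        assert s == pytest.approx(1.0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            whitened_cosine(np.zeros(28), np.ones(28))


class TestNoiseCeiling:
    def test_identical_subjects_hit_one(self):
        r = RDM.from_vector(np.linspace(0.1, 1.0, 28))
        c = noise_ceiling([r, r, r, r])
        assert c.lower == pytest.approx(1.0)
        assert c.upper == pytest.approx(1.0)

    def test_lower_never_exceeds_upper(self):
        w = whitening_matrix(8)
        for seed in range(100):
            rdms = random_rdms(5, seed)
            for whitener in (None, w):
                c = noise_ceiling(rdms, whitener)
                assert c.lower <= c.upper + 1e-12

    def test_three_subject_hand_oracle(self):
        vecs = [np.eye(28)[0] + 0.5, np.eye(28)[1] + 0.5, np.eye(28)[2] + 0.5]
        rdms = [RDM.from_vector(v) for v in vecs]
        c = noise_ceiling(rdms)

        def cos(a, b):
            return a @ b / np.sqrt((a @ a) * (b @ b))

        gm = np.mean(vecs, axis=0)
        upper = np.mean([cos(v, gm) for v in vecs])
        lower = np.mean(
            [cos(vecs[i], (3 * gm - vecs[i]) / 2) for i in range(3)]
        )
        assert c.upper == pytest.approx(upper, abs=1e-12)
        assert c.lower == pytest.approx(lower, abs=1e-12)

    def test_single_subject_errors(self):
        with pytest.raises(ValueError):
            noise_ceiling(random_rdms(1, 0))


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rdms = random_rdms(10, 5)
        models = [m.rdm() for m in candidate_family()]
        a = bootstrap_evaluate(rdms, models, seed=3)
        b = bootstrap_evaluate(rdms, models, seed=3)
        assert np.array_equal(a.ci_low, b.ci_low)
        assert np.array_equal(a.sem, b.sem)

    def test_identical_subjects_zero_width(self):
        r = RDM.from_vector(np.linspace(0.1, 1.0, 28))
        models = [m.rdm() for m in candidate_family()]
        ev = bootstrap_evaluate([r] * 6, models, seed=1)
        assert np.allclose(ev.ci_high - ev.ci_low, 0.0, atol=1e-12)
        assert np.allclose(ev.sem, 0.0, atol=1e-12)

    def test_sem_shrinks_like_root_n(self):
        models = [candidate_family()[1].rdm()]
        sems = []
        for n in (10, 40, 160):
            rng = np.random.default_rng(9)
            rdms = [RDM.from_vector(rng.random(28)) for _ in range(n)]
            sems.append(bootstrap_evaluate(rdms, models, seed=2).sem[0])
        # quadrupling n should roughly halve the SEM
        assert sems[1] < 0.75 * sems[0]
        assert sems[2] < 0.75 * sems[1]

    def test_mean_matches_score_matrix(self):
        rdms = random_rdms(8, 11)
        models = [m.rdm() for m in candidate_family()]
        ev = bootstrap_evaluate(rdms, models, seed=0)
        assert np.allclose(ev.mean, score_matrix(rdms, models).mean(axis=0))


class TestCompareModels:
    def test_exact_tie_gives_null_result(self):
        r = random_rdms(6, 21)
        models = [candidate_family()[1].rdm()] * 2
        ev = bootstrap_evaluate(r, models, seed=0)
        table = compare_models(ev, noise_ceiling(r))
        assert table.pair_t[0] == 0.0
        assert table.pair_p[0] == 1.0
        assert not table.pair_significant[0]

    def test_bh_against_reference_implementation(self):
        rng = np.random.default_rng(7)
        rdms = [RDM.from_vector(rng.random(28) + 0.01) for _ in range(12)]
        models = [m.rdm() for m in candidate_family()]
        ev = bootstrap_evaluate(rdms, models, seed=0)
        table = compare_models(ev, noise_ceiling(rdms), fdr_q=0.01)
        # hand-rolled Benjamini-Hochberg on the reported raw p-values
        p = table.pair_p
        m = len(p)
        order = np.argsort(p)
        thresh = 0.01 * (np.arange(1, m + 1)) / m
        passed = p[order] <= thresh
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        expect = np.zeros(m, bool)
        expect[order[:k]] = True
        assert np.array_equal(table.pair_significant, expect)

    def test_planted_modality_geometry_recovered(self):
        d = DesignSpec(n_subjects=20, seed=77)
        geom = GroundTruthGeometry(w_mod=1.0, w_exp=0.0, w_type=0.0, noise_sd=0.3)
        rdms = subject_rdms(generate_patterns(d, geom))
        fam = candidate_family()
        w = whitening_matrix(8)
        ev = bootstrap_evaluate(rdms, [m.rdm() for m in fam], [m.name for m in fam],
                                whitening=w, seed=0)
        table = compare_models(ev, noise_ceiling(rdms, w))
        best = int(np.argmax(ev.mean))
        assert fam[best].weights == (1.0, 0.0, 0.0)
        # the winner beats every rival significantly after FDR control
        for k, (i, j) in enumerate(table.pair_index):
            if best in (i, j):
                assert table.pair_significant[k]
        # and is not significantly below the lower noise ceiling
        assert not table.below_ceiling[best]
        # while scoring above zero
        assert table.vs_zero_p[best] < 1e-6

    def test_subject_order_invariance(self):
        rdms = random_rdms(9, 33)
        models = [m.rdm() for m in candidate_family()]
        ev1 = bootstrap_evaluate(rdms, models, seed=0)
        ev2 = bootstrap_evaluate(list(reversed(rdms)), models, seed=0)
        assert np.allclose(ev1.mean, ev2.mean)
        t1 = compare_models(ev1, noise_ceiling(rdms))
        t2 = compare_models(ev2, noise_ceiling(list(reversed(rdms))))
        assert np.allclose(t1.pair_t, t2.pair_t)
        assert np.allclose(t1.vs_ceiling_p, t2.vs_ceiling_p)
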