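"""GMM-EM fitting, hard segmentation and HMRF/ICM refinement."""

import numpy as np
import pytest

from mammoseg.gmm_hmrf import (
    GMMParams,
    HMRFConfig,
    em_e_step,
    em_m_step,
    gmm_em_fit,
    gmm_pdf,
    gmm_segment,
    hmrf_energy,
    hmrf_refine,
    kmeans_init,
    log_likelihood,
)


def two_component(mu=(0.0, 10.0), sd=(1.0, 1.0), w=(0.5, 0.5)):
    return GMMParams(weights=np.array(w), means=np.array(mu), stds=np.array(sd))


class TestKMeans:
    def test_separated_groups_exact(self):
        x = np.array([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        labels, means = kmeans_init(x, 2, rng_seed=0)
        np.testing.assert_allclose(sorted(means), [1.0, 9.0])
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_k1_global_mean(self):
        x = np.array([2.0, 4.0, 9.0])
        _, means = kmeans_init(x, 1, rng_seed=0)
        np.testing.assert_allclose(means, [5.0])

    def test_wcss_non_increasing_in_iterations(self, rng):
        x = rng.uniform(0, 255, 300)

        def wcss(iters):
            labels, means = kmeans_init(x, 4, rng_seed=3, iters=iters)
            return float(((x - means[labels]) ** 2).sum())

        vals = [wcss(i) for i in (1, 2, 4, 8, 16)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_too_many_clusters(self):
        with pytest.raises(ValueError):
            kmeans_init(np.array([1.0, 1.0]), 2)


class TestPdf:
    def test_standard_normal_mode(self):
        p = GMMParams(weights=np.array([1.0]), means=np.array([0.0]),
                      stds=np.array([1.0]))
        np.testing.assert_allclose(gmm_pdf(np.array(0.0), p),
                                   1 / np.sqrt(2 * np.pi), atol=1e-9)

    def test_symmetric_pair_at_origin(self):
        a = 3.0
        p = two_component(mu=(-a, a))
        expected = 2 * 0.5 / np.sqrt(2 * np.pi) * np.exp(-a**2 / 2)
        np.testing.assert_allclose(gmm_pdf(np.array(0.0), p), expected,
                                   rtol=1e-12)

    def test_integrates_to_one(self):
        p = two_component(mu=(30.0, 200.0), sd=(5.0, 20.0), w=(0.3, 0.7))
        grid = np.linspace(-200, 500, 200001)
        total = np.trapezoid(gmm_pdf(grid, p), grid)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)


class TestESteps:
    def test_k1_all_ones(self):
        p = GMMParams(weights=np.array([1.0]), means=np.array([5.0]),
                      stds=np.array([2.0]))
        resp = em_e_step([1.0, 5.0, 9.0], p)
        np.testing.assert_allclose(resp, 1.0)

    def test_equidistant_split(self):
        resp = em_e_step([5.0], two_component())
        np.testing.assert_allclose(resp[0], [0.5, 0.5])

    def test_far_point_saturates(self):
        resp = em_e_step([0.0], two_component())
        np.testing.assert_allclose(resp[0, 0], 1.0 / (1.0 + np.exp(-50)),
                                   rtol=1e-12)

    def test_unweighted_mode_is_exponent_only(self):
        # exponent-only responsibilities: no weights, no 1/sigma factor
        p = two_component(mu=(0.0, 4.0), sd=(1.0, 2.0), w=(0.9, 0.1))
        x = 2.0
        e1 = np.exp(-0.5 * (x - 0.0) ** 2 / 1.0**2)
        e2 = np.exp(-0.5 * (x - 4.0) ** 2 / 2.0**2)
        resp = em_e_step([x], p, mode="unweighted")
        np.testing.assert_allclose(resp[0], [e1 / (e1 + e2), e2 / (e1 + e2)],
                                   rtol=1e-12)

    def test_rows_always_sum_to_one(self, rng):
        p = two_component(mu=(10.0, 240.0), sd=(0.01, 5.0), w=(0.99, 0.01))
        for mode in ("unweighted", "full"):
            resp = em_e_step(rng.uniform(0, 255, 100), p, mode)
            np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)


class TestMStep:
    def test_crisp_responsibilities(self):
        x = np.array([0.0, 2.0, 10.0, 14.0])
        resp = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        p = em_m_step(x, resp, mode="full")
        np.testing.assert_allclose(sorted(p.means), [1.0, 12.0])
        np.testing.assert_allclose(sorted(p.stds), [1.0, 2.0])
        np.testing.assert_allclose(p.weights, [0.5, 0.5])

    def test_uniform_responsibilities_collapse_to_mean(self, rng):
        x = rng.uniform(0, 10, 20)
        resp = np.full((20, 2), 0.5)
        p = em_m_step(x, resp, mode="full")
        np.testing.assert_allclose(p.means, x.mean())

    def test_matches_scalar_oracle(self, rng):
        x = rng.uniform(0, 255, 20)
        resp = rng.dirichlet(np.ones(3), size=20)
        p = em_m_step(x, resp, mode="full")
        for j in range(3):
            tot = sum(resp[i, j] for i in range(20))
            mu = sum(resp[i, j] * x[i] for i in range(20)) / tot
            var = sum(resp[i, j] * (x[i] - mu) ** 2 for i in range(20)) / tot
            np.testing.assert_allclose(p.means[j], mu, atol=1e-12)
            np.testing.assert_allclose(p.stds[j], np.sqrt(var), atol=1e-12)
            np.testing.assert_allclose(p.weights[j], tot / 20, atol=1e-12)

    def test_unweighted_mode_keeps_sigma_and_weights(self):
        prior = two_component(sd=(2.0, 3.0), w=(0.3, 0.7))
        p = em_m_step([1.0, 9.0], np.array([[1, 0], [0, 1.0]]),
                      mode="unweighted", params=prior)
        np.testing.assert_allclose(p.stds, prior.stds)
        np.testing.assert_allclose(p.weights, prior.weights)


class TestEMFit:
    def test_loglik_monotone_and_recovery(self, rng):
        x = np.concatenate([rng.normal(60, 10, 5000),
                            rng.normal(180, 10, 5000)])
        params, hist = gmm_em_fit(x, k=2, iters=100, rng_seed=0)
        assert all(b >= a - 1e-7 for a, b in zip(hist, hist[1:]))
        order = np.argsort(params.means)
        np.testing.assert_allclose(params.means[order], [60, 180], atol=2)
        np.testing.assert_allclose(params.stds[order], [10, 10], atol=1)
        np.testing.assert_allclose(params.weights, [0.5, 0.5], atol=0.03)

    def test_k1_closed_form(self, rng):
        x = rng.uniform(0, 100, 500)
        params, _ = gmm_em_fit(x, k=1, iters=50, rng_seed=0)
        np.testing.assert_allclose(params.means, [x.mean()], atol=1e-6)
        np.testing.assert_allclose(params.stds, [x.std()], atol=1e-6)


class TestSegment:
    def test_pixel_at_mean_gets_that_component(self):
        p = two_component(mu=(50.0, 200.0))
        labels = gmm_segment(np.array([[50.0, 200.0]]), p)
        np.testing.assert_array_equal(labels, [[0, 1]])

    def test_decision_boundary_at_midpoint(self):
        p = two_component(mu=(0.0, 10.0))
        labels = gmm_segment(np.array([[4.9, 5.1]]), p)
        np.testing.assert_array_equal(labels, [[0, 1]])
        # exact midpoint ties to the lower index
        assert gmm_segment(np.array([[5.0]]), p)[0, 0] == 0

    def test_two_level_phantom_recovered(self):
        img = np.full((20, 20), 60, dtype=np.uint8)
        img[5:15, 5:15] = 180
        params, _ = gmm_em_fit(img.ravel().astype(float), k=2, rng_seed=1)
        labels = gmm_segment(img, params)
        bright = int(np.argmax(params.means))
        np.testing.assert_array_equal(labels == bright, img == 180)


class TestHMRF:
    def make_two_region(self, rng, h=40, w=40):
        img = np.full((h, w), 60.0)
        img[:, w // 2:] = 180.0
        img += rng.normal(0, 5, (h, w))
        truth = np.zeros((h, w), dtype=np.int32)
        truth[:, w // 2:] = 1
        params = two_component(mu=(60.0, 180.0), sd=(5.0, 5.0))
        return img, truth, params

    def test_beta_zero_is_ml_relabel(self, rng):
        img, _, params = self.make_two_region(rng)
        start = np.zeros(img.shape, dtype=np.int32)
        out = hmrf_refine(img, start, params,
                          HMRFConfig(beta=0.0, icm_sweeps=1, em_rounds=1))
        ml = gmm_segment(img, params)
        np.testing.assert_array_equal(out, ml)

    def test_single_flip_restored(self):
        img = np.full((9, 9), 60.0)
        params = two_component(mu=(60.0, 180.0), sd=(5.0, 5.0))
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[4, 4] = 1
        out = hmrf_refine(img, labels, params,
                          HMRFConfig(beta=1.0, icm_sweeps=1, em_rounds=1))
        assert out[4, 4] == 0

    def test_label_noise_mostly_corrected(self, rng):
        img, truth, params = self.make_two_region(rng)
        noisy = truth.copy()
        flip = rng.random(truth.shape) < 0.05
        noisy[flip] = 1 - noisy[flip]
        out = hmrf_refine(img, noisy, params, HMRFConfig(beta=1.0))
        corrected = (out[flip] == truth[flip]).mean()
        assert corrected >= 0.95

    def test_energy_non_increasing(self, rng):
        img, truth, params = self.make_two_region(rng)
        noisy = truth.copy()
        flip = rng.random(truth.shape) < 0.2
        noisy[flip] = 1 - noisy[flip]
        cfg = HMRFConfig(beta=1.0, icm_sweeps=3, em_rounds=1)
        before = hmrf_energy(img, noisy, params, cfg)
        out = hmrf_refine(img, noisy, params, cfg)
        after = hmrf_energy(img, out, params, cfg)
        assert after <= before

    def test_loglik_helper_matches_pdf(self, rng):
        p = two_component(mu=(30.0, 80.0), sd=(4.0, 9.0), w=(0.4, 0.6))
        x = rng.uniform(0, 120, 50)
        np.testing.assert_allclose(
            log_likelihood(x, p), np.log(gmm_pdf(x, p)).sum(), rtol=1e-10
        )
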