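import itertools
import math

import numpy as np
import pytest

from veinseg import RunConfig
from veinseg.segmentation import (LabelGMM, LPPProjection, build_graph,
                                  compute_eta, fit_label_gmm, init_clusters,
                                  kl_divergence, lpp_distance, min_cut,
                                  region_energies, region_term, segment,
                                  smoothness_term)

from conftest import brute_force_min_energy, random_seg_graph


def single_gaussian(mean, var):
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    var = np.atleast_1d(np.asarray(var, dtype=float))
    return LabelGMM(weights=np.array([1.0]), means=mean[None],
                    variances=var[None]).validate()


class TestInitClusters:
    def test_single_cluster_is_global_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 3))
        centers, weights = init_clusters(x, 1, seed=0)
        np.testing.assert_allclose(centers[0], x.mean(axis=0))
        assert weights[0] == 1.0

    def test_two_separated_clouds_match_exhaustive_two_means(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(6, 2))
        b = rng.normal(8.0, 0.1, size=(6, 2)) + [0, 5]
        x = np.vstack([a, b])
        centers, weights = init_clusters(x, 2, seed=3)
        # oracle: enumerate every 2-partition, minimize the WCSS objective
        best, best_centers = np.inf, None
        for assign in itertools.product((0, 1), repeat=len(x)):
            assign = np.asarray(assign)
            if assign.min() == assign.max():
                continue
            cs = [x[assign == k].mean(axis=0) for k in (0, 1)]
            j = sum(((x[assign == k] - cs[k]) ** 2).sum() for k in (0, 1))
            if j < best:
                best, best_centers = j, cs
        found = sorted(map(tuple, centers))
        expected = sorted(map(tuple, best_centers))
        np.testing.assert_allclose(found, expected, atol=1e-8)
        np.testing.assert_allclose(sorted(weights), [0.5, 0.5])

    def test_kmeans_objective_no_worse_than_random_assignments(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 2))
        centers, _ = init_clusters(x, 3, seed=1)
        d2 = ((x[:, None] - centers[None]) ** 2).sum(axis=-1)
        j_fit = d2.min(axis=1).sum()
        for _ in range(20):
            assign = rng.integers(3, size=len(x))
            cs = np.array([
                x[assign == k].mean(axis=0) if (assign == k).any() else [0, 0]
                for k in range(3)])
            j_rand = ((x - cs[assign]) ** 2).sum()
            assert j_fit <= j_rand + 1e-9

    @pytest.mark.parametrize("k", [0, 13])
    def test_invalid_component_count_raises(self, k):
        with pytest.raises(ValueError, match="cluster count"):
            init_clusters(np.zeros((12, 2)), k, seed=0)


class TestFitLabelGmm:
    def test_recovers_known_gaussians_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        n = 2000
        fg_mean, bg_mean = np.array([10.0, -4.0]), np.array([-3.0, 6.0])
        sigma = 1.5
        x = np.vstack([
            rng.normal(fg_mean, sigma, size=(n, 2)),
            rng.normal(bg_mean, sigma, size=(n, 2)),
        ])
        labels = np.repeat([1, 0], n)
        fg, bg = fit_label_gmm(x, labels, k=1, seed=0)
        se = 3 * sigma / math.sqrt(n)
        assert np.all(np.abs(fg.means[0] - fg_mean) < se)
        assert np.all(np.abs(bg.means[0] - bg_mean) < se)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(500, 3))
        labels = rng.integers(2, size=500)
        fg, bg = fit_label_gmm(x, labels, k=4, seed=0)
        assert fg.weights.sum() == pytest.approx(1.0)
        assert bg.weights.sum() == pytest.approx(1.0)

    def test_invariant_to_pixel_order(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(300, 2))
        labels = rng.integers(2, size=300)
        fg1, _ = fit_label_gmm(x, labels, k=3, seed=5)
        perm = rng.permutation(300)
        fg2, _ = fit_label_gmm(x[perm], labels[perm], k=3, seed=5)
        np.testing.assert_allclose(sorted(map(tuple, fg1.means)),
                                   sorted(map(tuple, fg2.means)), atol=1e-9)

    def test_small_class_reduces_component_count(self):
        rng = np.random.default_rng(20)
        x = np.vstack([np.zeros((3, 2)), rng.normal(size=(100, 2))])
        labels = np.repeat([1, 0], [3, 100])
        fg, bg = fit_label_gmm(x, labels, k=5, seed=0)
        assert fg.n_components <= 3
        assert bg.n_components == 5

    def test_single_class_labeling_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            fit_label_gmm(np.zeros((10, 2)), np.ones(10), k=2, seed=0)


class TestRegionTerm:
    def test_closed_form_at_single_component_mean(self):
        var = np.array([0.5, 2.0, 1.0, 4.0, 0.25])
        model = single_gaussian(np.arange(5.0), var)
        # at the mean tau=1 for every feature, so L = (prod delta)^(1/N)
        expected = -np.log(np.prod(2 * np.pi * var) ** -0.5) / 5
        assert region_term(np.arange(5.0), model) == pytest.approx(expected)

    def test_minimized_at_the_mean(self):
        model = single_gaussian([2.0, -1.0], [1.0, 3.0])
        e_mean = region_term(np.array([2.0, -1.0]), model)
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = rng.normal([2.0, -1.0], 2.0)
            assert region_term(p, model) >= e_mean - 1e-12

    def test_doubling_sigma_adds_log_two_at_the_mean(self):
        mean, var = np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, 2.0])
        e1 = region_term(mean, single_gaussian(mean, var))
        e2 = region_term(mean, single_gaussian(mean, 4.0 * var))
        assert e2 - e1 == pytest.approx(math.log(2.0))

    def test_floor_keeps_energy_finite_far_from_mean(self):
        model = single_gaussian([0.0], [1e-3])
        e = region_term(np.array([1e6]), model)
        assert np.isfinite(e) and e == pytest.approx(-math.log(1e-12))


class TestLppAndEta:
    def test_identity_projection_gives_euclidean_distance(self):
        rng = np.random.default_rng(4)
        feats = rng.uniform(0, 255, (6, 6, 5))
        proj = LPPProjection(identity=True).fit(feats.reshape(-1, 5))
        d = lpp_distance(proj, feats, (0, 0), (3, 4))
        assert d == pytest.approx(np.linalg.norm(feats[0, 0] - feats[3, 4]))
        assert lpp_distance(proj, feats, (2, 2), (2, 2)) == 0.0
        assert d == pytest.approx(lpp_distance(proj, feats, (3, 4), (0, 0)))

    def test_unfitted_projection_raises(self):
        with pytest.raises(RuntimeError, match="not been fitted"):
            lpp_distance(LPPProjection(), np.zeros((2, 2, 5)), (0, 0), (0, 1))

    def test_fitted_projection_is_deterministic_and_shaped(self):
        rng = np.random.default_rng(5)
        feats = rng.uniform(0, 255, (500, 5))
        p1 = LPPProjection(n_components=4).fit(feats, seed=11)
        p2 = LPPProjection(n_components=4).fit(feats, seed=11)
        np.testing.assert_allclose(p1.components_, p2.components_)
        assert p1.transform(feats).shape == (500, 4)

    def test_eta_two_pixel_unit_distance(self):
        proj = np.zeros((1, 2, 1))
        proj[0, 1, 0] = 1.0
        assert compute_eta(proj, neighborhood=4) == pytest.approx(1.0)

    def test_eta_degenerate_features_fall_back_to_maximum(self):
        assert compute_eta(np.zeros((4, 4, 2)), eta_max=123.0) == 123.0

    def test_eta_scales_inverse_quadratically(self):
        rng = np.random.default_rng(6)
        proj = rng.normal(size=(8, 8, 3))
        assert compute_eta(3.0 * proj) == pytest.approx(compute_eta(proj) / 9)


class TestSmoothnessTerm:
    def test_identical_features_axial_weight(self):
        proj = np.zeros((2, 2, 3))
        w = smoothness_term((0, 0), (0, 1), proj, eta=1.0, c_noise=math.pi)
        assert w == pytest.approx(1.0 + math.pi)

    def test_dissimilar_features_floor_at_noise_constant(self):
        proj = np.zeros((1, 2, 1))
        proj[0, 1, 0] = 1e4
        w = smoothness_term((0, 0), (0, 1), proj, eta=1.0, c_noise=0.2)
        assert w == pytest.approx(0.2)

    def test_diagonal_neighbors_downweighted_by_sqrt_two(self):
        proj = np.zeros((2, 2, 3))
        ax = smoothness_term((0, 0), (0, 1), proj, eta=1.0)
        di = smoothness_term((0, 0), (1, 1), proj, eta=1.0)
        assert di == pytest.approx(ax / math.sqrt(2))

    def test_same_pixel_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            smoothness_term((1, 1), (1, 1), np.zeros((2, 2, 1)), eta=1.0)


class TestBuildGraphAndMinCut:
    def test_unary_dominated_graph_labels_all_foreground(self):
        rng = np.random.default_rng(10)
        feats = rng.normal(5.0, 0.1, size=(4, 4, 2))
        fg = single_gaussian([5.0, 5.0], [1.0, 1.0])
        bg = single_gaussian([-5.0, -5.0], [1.0, 1.0])
        g = build_graph(feats, fg, bg, beta=0.0, eta=1.0)
        assert np.all(min_cut(g) == 1)

    def test_capacities_are_non_negative(self):
        rng = np.random.default_rng(11)
        feats = rng.uniform(0, 255, (5, 5, 3))
        fg = single_gaussian([10.0, 10.0, 10.0], [1e-3, 1e-3, 1e-3])
        bg = single_gaussian([200.0, 200.0, 200.0], [5.0, 5.0, 5.0])
        g = build_graph(feats, fg, bg, beta=0.5, eta=0.01)
        assert g.source_caps.min() >= 0 and g.sink_caps.min() >= 0
        assert g.pair_caps.min() >= 0

    def test_cut_energy_matches_independent_recomputation(self):
        rng = np.random.default_rng(12)
        feats = rng.uniform(0, 10, (6, 6, 2))
        labels = rng.integers(2, size=36)
        fg, bg = fit_label_gmm(feats.reshape(-1, 2), labels, k=2, seed=0)
        g = build_graph(feats, fg, bg, beta=0.3, eta=0.05)
        lab = min_cut(g)
        # independent energy: unary -log L + beta-scaled boundary weights
        e_fg = region_energies(feats.reshape(-1, 2), fg)
        e_bg = region_energies(feats.reshape(-1, 2), bg)
        flat = lab.ravel().astype(bool)
        unary = e_fg[flat].sum() + e_bg[~flat].sum()
        pair = sum(
            0.3 * smoothness_term(
                (a // 6, a % 6), (b // 6, b % 6),
                feats, eta=0.05)
            for a, b in zip(g.pair_a, g.pair_b)
            if flat[a] != flat[b])
        assert g.energy(lab) == pytest.approx(unary + pair)

    def test_min_cut_matches_brute_force_on_tiny_images(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            h, w = int(rng.integers(1, 4)), int(rng.integers(1, 5))
            g = random_seg_graph(rng, h, w,
                                 neighborhood=8 if rng.random() < 0.5 else 4)
            assert g.energy(min_cut(g)) == pytest.approx(
                brute_force_min_energy(g), abs=1e-9)

    def test_one_by_two_hand_set_capacities(self):
        from veinseg.segmentation import SegGraph

        g = SegGraph(shape=(1, 2),
                     source_caps=np.array([[4.0, 0.5]]),
                     sink_caps=np.array([[0.5, 4.0]]),
                     pair_a=np.array([0]), pair_b=np.array([1]),
                     pair_caps=np.array([1.0]))
        lab = min_cut(g)
        # enumerate: (1,0) costs 0.5+0.5+1=2, the unique minimum
        assert lab.tolist() == [[1, 0]]
        assert g.energy(lab) == pytest.approx(2.0)

    def test_swapping_terminals_flips_the_labeling(self):
        rng = np.random.default_rng(14)
        g = random_seg_graph(rng, 3, 3)
        # perturb to avoid ties between complementary optima
        g.source_caps += rng.uniform(0, 0.01, g.source_caps.shape)
        from veinseg.segmentation import SegGraph

        flipped = SegGraph(shape=g.shape, source_caps=g.sink_caps,
                           sink_caps=g.source_caps, pair_a=g.pair_a,
                           pair_b=g.pair_b, pair_caps=g.pair_caps)
        np.testing.assert_array_equal(min_cut(flipped), 1 - min_cut(g))

    def test_non_finite_capacity_rejected(self):
        rng = np.random.default_rng(15)
        g = random_seg_graph(rng, 2, 2)
        g.source_caps[0, 0] = np.inf
        with pytest.raises(ValueError, match="source_caps"):
            g.validate()


class TestKlDivergence:
    def test_self_divergence_is_zero_within_mc_tolerance(self):
        m = LabelGMM(weights=np.array([0.4, 0.6]),
                     means=np.array([[0.0, 1.0], [3.0, -2.0]]),
                     variances=np.array([[1.0, 0.5], [2.0, 1.0]]))
        assert abs(kl_divergence(m, m, n_samples=4000, seed=0)) < 1e-9

    @pytest.mark.parametrize("mu", [1.0, 2.0])
    def test_unit_variance_gaussians_match_closed_form(self, mu):
        p = single_gaussian([0.0], [1.0])
        q = single_gaussian([mu], [1.0])
        est = kl_divergence(p, q, n_samples=20000, seed=1)
        assert est == pytest.approx(mu * mu / 2, rel=0.1)

    def test_estimate_non_negative_within_tolerance(self):
        rng = np.random.default_rng(16)
        for seed in range(5):
            p = single_gaussian(rng.normal(size=2), rng.uniform(0.5, 2, 2))
            q = single_gaussian(rng.normal(size=2), rng.uniform(0.5, 2, 2))
            assert kl_divergence(p, q, n_samples=5000, seed=seed) > -0.05


@pytest.fixture(scope="module")
def two_region_image():
    """Two textured regions with well-separated fused features."""
    xx, yy = np.meshgrid(np.arange(128), np.arange(128))
    img = np.where(xx < 64,
                   110 + 40 * np.cos(2 * np.pi * xx / 10.0),
                   190 + 40 * np.cos(2 * np.pi * yy / 10.0))
    truth = (xx < 64)          # the darker textured region is foreground
    return img.astype(float), truth


@pytest.fixture(scope="module")
def two_region_config():
    cfg = RunConfig()
    cfg.gabor.target_size = 128
    cfg.segmentation.init_method = "intensity_otsu"
    return cfg


class TestSegment:
    def test_two_region_agreement_above_99_percent(self, two_region_image,
                                                   two_region_config):
        img, truth = two_region_image
        res = segment(img, two_region_config, seed=0)
        agreement = (res.labels.astype(bool) == truth).mean()
        assert agreement >= 0.99

    def test_energy_trace_is_non_increasing(self, two_region_image,
                                            two_region_config):
        img, _ = two_region_image
        res = segment(img, two_region_config, seed=0)
        trace = res.energy_trace
        assert len(trace) >= 1
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
        assert all(k >= 0 for k in res.kl_trace)

    def test_same_seed_reproduces_bitwise(self, two_region_image,
                                          two_region_config):
        img, _ = two_region_image
        a = segment(img, two_region_config, seed=7)
        b = segment(img, two_region_config, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.energy_trace == b.energy_trace
        assert a.kl_trace == b.kl_trace

    def test_constant_image_degenerate_seeding_raises(self):
        cfg = RunConfig()
        cfg.gabor.target_size = 64
        with pytest.raises(ValueError, match="degenerate initial labeling"):
            segment(np.full((64, 64), 128.0), cfg, seed=0)

    def test_labels_map_back_to_original_frame(self, default_config):
        from veinseg import generate

        s = generate(seed=21, shape=(480, 640), finger_frame=True,
                     noise_sigma=2.0, n_veins=2, margin=30)
        res = segment(s.image, default_config, seed=0)
        assert res.labels.shape == (480, 640)
        # anything outside the cropped ROI stays background
        r0, r1, c0, c1 = res.pad_record.crop
        outside = res.labels.copy()
        outside[r0:r1, c0:c1] = 0
        assert outside.sum() == 0
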