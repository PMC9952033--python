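import numpy as np
import pytest

from lungnlb import imageprep, nlbayes
from lungnlb.nlbayes import (
    NLBParams,
    Patch,
    PatchGroup,
    aggregate_patches,
    bayes_shrink_step1,
    bayes_shrink_step2,
    denoise,
    extract_patches,
    find_similar,
    group_stats,
    mmse_patch_estimate,
    patch_distance,
    patches_at,
    select_params,
)


def brute_force_group_anchors(image, ref_anchor, e, lam, n_group, tau0):
    """Independent exhaustive window scan used as the grouping oracle.

    Enumerates every candidate anchor in the clipped search window, computes
    mean squared patch distances one by one, sorts by (distance, row, col),
    applies the threshold with the nearest-N fallback, and forces the
    reference into the group.
    """
    h, w = image.shape
    rr, rc = ref_anchor
    ref = image[rr : rr + e, rc : rc + e]
    scored = []
    for r in range(max(rr - lam, 0), min(rr + lam, h - e) + 1):
        for c in range(max(rc - lam, 0), min(rc + lam, w - e) + 1):
            cand = image[r : r + e, c : c + e]
            d = float(np.mean((cand - ref) ** 2))
            scored.append((d, r, c))
    scored.sort()
    n_take = min(n_group, len(scored))
    passing = [s for s in scored if s[0] <= tau0]
    pool = passing if len(passing) >= n_take else scored
    sel = [(r, c) for _, r, c in pool[:n_take]]
    if ref_anchor not in sel:
        sel[-1] = ref_anchor
    return sel


class TestSelectParams:
    @pytest.mark.parametrize(
        "sigma, e1, e2",
        [(10, 3, 3), (20, 3, 3), (21, 5, 3), (30, 5, 3), (50, 5, 3),
         (51, 7, 5), (60, 7, 5), (70, 7, 5), (71, 7, 7), (100, 7, 7)],
    )
    def test_breakpoints(self, sigma, e1, e2):
        p = select_params(sigma)
        assert (p.e1, p.e2) == (e1, e2)

    def test_derived_quantities(self):
        p30 = select_params(30)
        assert (p30.N1, p30.N2, p30.tau0) == (75, 27, 144.0)
        p60 = select_params(60)
        assert (p60.N1, p60.N2, p60.lambda1, p60.tau0) == (147, 75, 74, 400.0)

    def test_rules_hold_for_all_sigma(self):
        import math

        for sigma in np.linspace(0.5, 120, 57):
            p = select_params(float(sigma))
            assert p.N1 == 3 * p.e1**2 and p.N2 == 3 * p.e2**2
            assert p.lambda1 == math.ceil(p.N1 / 2) and p.lambda2 == math.ceil(p.N2 / 2)
            assert p.tau0 == 16 * p.e2**2

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            select_params(0)

    def test_inconsistent_params_rejected(self):
        with pytest.raises(ValueError, match="N = 3"):
            NLBParams(e1=3, e2=3, N1=28, N2=27, lambda1=14, lambda2=14, tau0=144.0, sigma=10)


class TestPatchOps:
    def test_patch_counts(self, rng):
        img8 = rng.normal(size=(8, 8))
        assert len(extract_patches(img8, 3, 1)) == 36
        only = extract_patches(img8, 8, 1)
        assert len(only) == 1 and np.array_equal(only[0].values, img8.ravel())

    def test_stride_grid_covers_all_pixels(self, rng):
        img = rng.normal(size=(9, 9))
        patches = extract_patches(img, 3, 3)
        assert sorted(p.anchor for p in patches) == [(r, c) for r in (0, 3, 6) for c in (0, 3, 6)]
        covered = np.zeros((9, 9), dtype=bool)
        for p in patches:
            covered[p.anchor[0] : p.anchor[0] + 3, p.anchor[1] : p.anchor[1] + 3] = True
        assert covered.all()

    def test_distance_examples(self, rng):
        p = Patch(rng.normal(size=9), (0, 0))
        q = Patch(p.values + 2.0, (1, 1))
        assert patch_distance(p, p) == 0.0
        assert patch_distance(p, q) == pytest.approx(4.0)
        r = Patch(rng.normal(size=9), (2, 2))
        assert patch_distance(p, r) == patch_distance(r, p)
        with pytest.raises(ValueError):
            patch_distance(p, Patch(np.zeros(25), (0, 0)))


class TestGrouping:
    def test_constant_image_takes_scan_order_with_reference(self):
        img = np.full((32, 32), 5.0)
        params = select_params(10)
        ref = patches_at(img, [(15, 15)], 3)[0]
        group = find_similar(ref, img, params, iteration=1)
        assert len(group.members) == params.N1
        assert ref.anchor in group.anchors()

    def test_matches_brute_force_oracle(self, rng):
        img = rng.normal(100, 30, (32, 32))
        params = select_params(20)
        e, n, lam = params.e1, params.N1, params.lambda1
        for anchor in [(0, 0), (5, 17), (15, 15), (29, 2), (29, 29)]:
            ref = patches_at(img, [anchor], e)[0]
            group = find_similar(ref, img, params, iteration=1)
            assert group.anchors() == brute_force_group_anchors(img, anchor, e, lam, n, params.tau0)

    def test_zero_threshold_falls_back_to_nearest(self, rng):
        img = rng.normal(size=(32, 32))
        params = NLBParams(e1=3, e2=3, N1=27, N2=27, lambda1=14, lambda2=14,
                           tau0=144.0, sigma=20.0)
        object.__setattr__(params, "tau0", 0.0)  # unique patches: nothing passes
        ref = patches_at(img, [(10, 10)], 3)[0]
        group = find_similar(ref, img, params, iteration=1)
        assert len(group.members) == 27

    def test_iteration2_distances_use_guide(self, rng):
        noisy = rng.normal(100, 20, (32, 32))
        guide = np.full((32, 32), 1.0)
        guide[:, 16:] = 200.0  # two flat halves: groups stay within a half
        params = select_params(20)
        ref = patches_at(noisy, [(10, 2)], params.e2)[0]
        group = find_similar(ref, noisy, params, iteration=2, guide=guide)
        assert all(c <= 16 - params.e2 for _, c in group.anchors())


class TestGroupStats:
    def test_identical_members(self):
        p = Patch(np.arange(9.0), (0, 0))
        group = PatchGroup(p, [p, Patch(p.values.copy(), (0, 1))])
        mean, cov = group_stats(group)
        assert np.array_equal(mean, p.values) and np.all(cov == 0)

    def test_two_scalar_patches(self):
        group = PatchGroup(Patch([8.0], (0, 0)), [Patch([8.0], (0, 0)), Patch([12.0], (0, 1))])
        mean, cov = group_stats(group)
        assert mean[0] == 10.0 and cov[0, 0] == 8.0

    def test_against_double_loop_oracle(self, rng):
        mat = rng.normal(size=(5, 9))
        group = PatchGroup(Patch(mat[0], (0, 0)), [Patch(v, (0, i)) for i, v in enumerate(mat)])
        mean, cov = group_stats(group)
        mu = mat.mean(axis=0)
        expected = np.zeros((9, 9))
        for i in range(9):
            for j in range(9):
                expected[i, j] = sum((m[i] - mu[i]) * (m[j] - mu[j]) for m in mat) / 4
        assert np.allclose(cov, expected)
        assert np.allclose(mean, mu)

    def test_single_member_rejected(self):
        group = PatchGroup(Patch([1.0], (0, 0)), [Patch([1.0], (0, 0))])
        with pytest.raises(ValueError, match=">= 2"):
            group_stats(group)


def _scalar_group(members, mean=None, cov=None):
    patches = [Patch([float(v)], (0, i)) for i, v in enumerate(members)]
    g = PatchGroup(patches[0], patches)
    if mean is not None:
        g.mean, g.cov = np.array([mean]), np.array([[cov]])
    return g


class TestShrinkage:
    @pytest.mark.parametrize("variant", ["printed", "classic"])
    def test_zero_noise_is_identity(self, rng, variant):
        mat = rng.normal(size=(12, 9))
        group = PatchGroup(Patch(mat[0], (0, 0)), [Patch(v, (0, i)) for i, v in enumerate(mat)])
        out = bayes_shrink_step1(group, sigma=0.0, variant=variant)
        for est, orig in zip(out, mat):
            assert np.allclose(est.values, orig, atol=1e-9)

    def test_zero_covariance_gives_total_shrinkage(self):
        vals = np.full(4, 7.0)
        group = PatchGroup(Patch([7.0], (0, 0)), [Patch([v], (0, i)) for i, v in enumerate(vals)])
        out = bayes_shrink_step1(group, sigma=3.0)
        assert all(est.values[0] == pytest.approx(7.0) for est in out)

    def test_scalar_closed_form_step1(self):
        # P_bar = 10, C = 4, sigma^2 = 4, P = 14 -> 10 + (4/8) * 4 = 12
        group = _scalar_group([14.0], mean=10.0, cov=4.0)
        out = bayes_shrink_step1(group, sigma=2.0)
        assert out[0].values[0] == pytest.approx(12.0, abs=1e-10)

    def test_scalar_closed_form_step2(self):
        # P1_bar = 9, C1 = 3, sigma^2 = 1, Pn = 13, Pn_bar = 10 -> 9 + (3/4) * 3 = 11.25
        noisy = _scalar_group([13.0, 7.0])  # mean 10
        basic = _scalar_group([0.0, 0.0], mean=9.0, cov=3.0)
        basic.members = [Patch([9.0], (0, 0)), Patch([9.0], (0, 1))]
        out = bayes_shrink_step2(noisy, basic, sigma=1.0)
        assert out[0].values[0] == pytest.approx(11.25, abs=1e-10)

    def test_step2_zero_oracle_covariance_returns_basic_mean(self, rng):
        noisy = _scalar_group(rng.normal(10, 5, size=4))
        basic_vals = np.full(4, 42.0)
        basic = _scalar_group(basic_vals)
        out = bayes_shrink_step2(noisy, basic, sigma=2.0)
        assert all(est.values[0] == pytest.approx(42.0) for est in out)

    def test_step2_anchor_mismatch_rejected(self):
        noisy = _scalar_group([1.0, 2.0])
        basic = PatchGroup(Patch([1.0], (5, 5)), [Patch([1.0], (5, 5)), Patch([2.0], (5, 6))])
        with pytest.raises(ValueError, match="anchors"):
            bayes_shrink_step2(noisy, basic, sigma=1.0)

    @pytest.mark.parametrize("variant", ["printed", "classic"])
    def test_shrinkage_contracts_toward_mean(self, rng, variant):
        # the filter is symmetric with eigenvalues in [0, 1], so the
        # Euclidean deviation from the group mean can only shrink
        mat = rng.normal(50, 12, size=(30, 9))
        group = PatchGroup(Patch(mat[0], (0, 0)), [Patch(v, (0, i)) for i, v in enumerate(mat)])
        mean, _ = group_stats(group)
        out = bayes_shrink_step1(group, sigma=8.0, variant=variant)
        for est, orig in zip(out, mat):
            assert np.linalg.norm(est.values - mean) <= np.linalg.norm(orig - mean) + 1e-9


class TestAggregate:
    def test_nonoverlapping_tiling_places_values(self, rng):
        img = rng.normal(size=(9, 9))
        patches = extract_patches(img, 3, 3)
        out, cov = aggregate_patches(patches, (9, 9))
        assert np.allclose(out, img) and np.all(cov == 1)

    def test_overlap_averages(self):
        a = Patch(np.full(9, 10.0), (0, 0))
        b = Patch(np.full(9, 20.0), (0, 0))
        out, cov = aggregate_patches([a, b], (3, 3))
        assert np.allclose(out, 15.0) and np.all(cov == 2)

    def test_consistent_estimates_reproduce_source(self, rng):
        img = rng.normal(size=(12, 12))
        out, _ = aggregate_patches(extract_patches(img, 3, 1), (12, 12))
        assert np.allclose(out, img)

    def test_uncovered_pixel_rejected(self):
        with pytest.raises(ValueError, match="covered"):
            aggregate_patches([Patch(np.zeros(9), (0, 0))], (8, 8))


class TestDenoise:
    def test_small_noise_near_identity(self, benign_phantom):
        res = denoise(benign_phantom.clean, 0.5, stride=2)
        assert np.abs(res.final - benign_phantom.clean).max() < 1.0

    def test_improves_psnr_on_phantom(self, malignant_phantom):
        ph = malignant_phantom
        res = denoise(ph.noisy, ph.spec.sigma, stride=2)
        assert imageprep.psnr(ph.clean, res.final) > imageprep.psnr(ph.clean, ph.noisy)

    def test_coverage_everywhere(self, benign_phantom):
        res = denoise(benign_phantom.noisy, 20, stride=3)
        assert res.coverage.min() >= 1

    def test_deterministic(self, rng):
        img = rng.normal(100, 20, (32, 32))
        a = denoise(img, 15, stride=2)
        b = denoise(img, 15, stride=2)
        assert np.array_equal(a.final, b.final) and np.array_equal(a.basic, b.basic)

    def test_classic_variant_runs(self, rng):
        img = rng.normal(100, 20, (32, 32))
        res = denoise(img, 15, stride=2, step1_filter="classic")
        assert np.isfinite(res.final).all()


class TestMMSE:
    def test_degenerate_average_returns_target(self, rng):
        t = Patch(rng.normal(size=9), (0, 0))
        out = mmse_patch_estimate(t, [Patch(t.values.copy(), (0, i)) for i in range(3)], sigma=5)
        assert np.allclose(out.values, t.values)

    def test_convex_combination_bound(self, rng):
        cands = [Patch(rng.normal(size=9), (0, i)) for i in range(8)]
        t = Patch(rng.normal(size=9), (0, 0))
        out = mmse_patch_estimate(t, cands, sigma=2.0)
        mat = np.stack([c.values for c in cands])
        assert np.all(out.values >= mat.min(axis=0) - 1e-12)
        assert np.all(out.values <= mat.max(axis=0) + 1e-12)

    def test_two_candidate_hand_value(self):
        # sigma = 5 makes w2/w1 = exp(-100/50) = e^-2
        t = Patch([0.0], (0, 0))
        cands = [Patch([0.0], (0, 1)), Patch([10.0], (0, 2))]
        out = mmse_patch_estimate(t, cands, sigma=5.0)
        expected = 10 * np.exp(-2) / (1 + np.exp(-2))
        assert out.values[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.192, abs=5e-4)
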