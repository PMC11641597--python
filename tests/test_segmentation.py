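import numpy as np
import pytest

from fins.segmentation import (
    DegenerateImageError,
    FittingTerm,
    IndicatorField,
    SolverParams,
    binarize_solution,
    build_fitting_term,
    energy,
    initialize_indicator,
    label_nuclei,
    minimize_energy,
    otsu_threshold,
    segment_nuclei,
)


def brute_force_otsu(z, nbins=256):
    """Exhaustive scan of all histogram cut points minimising the weighted
    intra-class variance; independent of the implementation under test.
    Cuts falling in an empty inter-mode gap are exactly tied, so ties are
    resolved to the middle of the optimal plateau (the same convention the
    implementation uses, reached via the between-class shortcut instead)."""
    counts, edges = np.histogram(z, bins=nbins, range=(z.min(), z.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    intra = np.full(nbins + 1, np.inf)
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        v0 = (counts[:k] * (centers[:k] - m0) ** 2).sum() / w0
        v1 = (counts[k:] * (centers[k:] - m1) ** 2).sum() / w1
        intra[k] = (w0 * v0 + w1 * v1) / (w0 + w1)
    best = intra.min()
    ties = np.flatnonzero(intra <= best * (1 + 1e-12))
    return edges[int(round((ties[0] + ties[-1]) / 2.0))]


class TestOtsu:
    def test_bimodal_split_between_modes(self):
        z = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)]).reshape(20, 50)
        t = otsu_threshold(z)
        assert 0.2 < t < 0.8

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 0.5))

    def test_gaussian_mixture_matches_brute_force(self):
        rng = np.random.default_rng(42)
        z = np.clip(
            np.concatenate([rng.normal(0.15, 0.05, 5000), rng.normal(0.75, 0.05, 5000)]),
            0.0,
            1.0,
        ).reshape(100, 100)
        assert abs(otsu_threshold(z) - brute_force_otsu(z)) <= 0.05

    def test_strictly_interior(self):
        rng = np.random.default_rng(0)
        z = rng.random((40, 40))
        t = otsu_threshold(z)
        assert z.min() < t < z.max()


class TestFittingTerm:
    def test_constant_zero_image(self):
        fit = build_fitting_term(np.zeros((4, 4)), 0.3)
        np.testing.assert_allclose(fit.f, 0.3)

    def test_zero_crossing_at_threshold(self):
        z = np.array([[0.5, 0.2]])
        fit = build_fitting_term(z, 0.5)
        assert fit.f[0, 0] == 0.0

    def test_binary_image(self):
        z = np.array([[0.0, 1.0]])
        np.testing.assert_allclose(build_fitting_term(z, 0.5).f, [[0.5, -0.5]])

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2])
    def test_threshold_must_be_interior(self, t):
        with pytest.raises(ValueError):
            build_fitting_term(np.zeros((2, 2)), t)


class TestInitialization:
    @pytest.mark.parametrize(
        "f, expected",
        [
            (np.full((3, 3), 0.2), 0.0),  # all positive -> u0 = 0
            (np.full((3, 3), -0.2), 1.0),  # all negative -> u0 = 1
        ],
    )
    def test_uniform_fields(self, f, expected):
        u0 = initialize_indicator(FittingTerm(f, 0.5))
        np.testing.assert_array_equal(u0.u, np.full((3, 3), expected))
        assert u0.iterations == 0

    def test_disk_indicator(self, disk_field):
        f, disk = disk_field
        u0 = initialize_indicator(FittingTerm(f, 0.5))
        np.testing.assert_array_equal(u0.u.astype(bool), disk)


class TestMinimizeEnergy:
    def test_no_foreground_evidence_gives_empty(self):
        u = minimize_energy(FittingTerm(np.full((16, 16), 0.3), 0.5))
        np.testing.assert_allclose(u.u, 0.0)
        assert u.final_energy == 0.0

    def test_all_foreground_evidence_gives_full(self):
        u = minimize_energy(FittingTerm(np.full((16, 16), -0.3), 0.5))
        np.testing.assert_allclose(u.u, 1.0)

    def test_disk_beats_all_binary_candidates(self, disk_field):
        """Fidelity dominates perimeter at this scale: the solution is the disk,
        and its energy matches or beats the best binary candidate within 1%."""
        f, disk = disk_field
        fit = FittingTerm(f, 0.5)
        u = minimize_energy(fit)
        candidates = [np.zeros_like(f), disk.astype(float), np.ones_like(f)]
        best = min(energy(c, fit, 20.0) for c in candidates)
        assert u.final_energy <= best + 0.01 * abs(best)
        np.testing.assert_array_equal(binarize_solution(u), disk)

    def test_energy_never_increases_from_start(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            f = rng.normal(0, 0.3, (32, 32))
            fit = FittingTerm(f, 0.5)
            e0 = energy(initialize_indicator(fit).u, fit, 20.0)
            u = minimize_energy(fit)
            assert u.final_energy <= e0 + 1e-9 * max(abs(e0), 1.0)

    def test_nonfinite_fitting_term_rejected(self):
        f = np.zeros((4, 4))
        f[0, 0] = np.nan
        with pytest.raises(ValueError):
            FittingTerm(f, 0.5)

    def test_initialization_independence(self, small_fixture):
        channels, _ = small_fixture
        t = otsu_threshold(channels[0])
        fit = build_fitting_term(channels[0], t)
        from_eq4 = minimize_energy(fit)
        from_zero = minimize_energy(fit, u0=IndicatorField(np.zeros_like(fit.f)))
        np.testing.assert_array_equal(binarize_solution(from_eq4), binarize_solution(from_zero))

    def test_max_iter_reported_not_fatal(self):
        rng = np.random.default_rng(17)
        f = rng.normal(0, 0.3, (32, 32))
        u = minimize_energy(FittingTerm(f, 0.5), SolverParams(max_iter=2, tol=1e-12))
        assert not u.converged
        assert u.iterations == 2


class TestBinarize:
    def test_extremes(self):
        assert not binarize_solution(IndicatorField(np.zeros((3, 3)))).any()
        assert binarize_solution(IndicatorField(np.ones((3, 3)))).all()

    def test_beta_invariance_on_near_binary_disk(self, disk_field):
        f, _ = disk_field
        u = minimize_energy(FittingTerm(f, 0.5))
        masks = [binarize_solution(u, b) for b in (0.25, 0.5, 0.75)]
        assert np.array_equal(masks[0], masks[1]) and np.array_equal(masks[1], masks[2])

    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_beta_interior(self, beta):
        with pytest.raises(ValueError):
            binarize_solution(np.zeros((2, 2)), beta)


def flood_fill_count(mask, connectivity=8):
    """Brute-force component count by BFS; the oracle for label_nuclei."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    n = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                n += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                            if mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return n


class TestLabelNuclei:
    def test_empty_mask(self):
        assert label_nuclei(np.zeros((8, 8), dtype=bool)).n == 0

    def test_two_disjoint_disks(self):
        mask = np.zeros((32, 32), dtype=bool)
        rr, cc = np.mgrid[:32, :32]
        mask[(rr - 8) ** 2 + (cc - 8) ** 2 <= 9] = True
        mask[(rr - 24) ** 2 + (cc - 24) ** 2 <= 9] = True
        assert label_nuclei(mask).n == 2

    def test_corner_touch_merges_under_8_connectivity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # touches at corner (4,4)-(5,5)
        labels = label_nuclei(mask, connectivity=8)
        assert labels.n == 1 == flood_fill_count(mask, 8)
        assert label_nuclei(mask, connectivity=4).n == 2 == flood_fill_count(mask, 4)

    def test_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = rng.random((20, 20)) < 0.35
            assert label_nuclei(mask).n == flood_fill_count(mask)

    def test_labels_gapless_and_raster_ordered(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1, 1], mask[5, 5], mask[9, 2] = True, True, True
        labels = label_nuclei(mask)
        assert labels.n == 3
        assert labels.label_map[1, 1] == 1
        assert labels.label_map[5, 5] == 2
        assert labels.label_map[9, 2] == 3

    def test_min_area_filter_relabels(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:5, 1:5] = True  # 16 px
        mask[8, 8] = True  # 1 px
        labels = label_nuclei(mask, min_area=4)
        assert labels.n == 1
        assert set(np.unique(labels.label_map)) == {0, 1}


class TestSegmentNuclei:
    def test_noiseless_oracle_equivalence(self, small_fixture):
        """Piecewise-constant field: Omega_D equals the plain threshold set."""
        channels, truth = small_fixture
        labels, u_star, t = segment_nuclei(channels[0])
        np.testing.assert_array_equal(labels.foreground, channels[0].z > t)
        assert labels.n == truth.n_nuclei

    def test_degenerate_channel_raises(self):
        with pytest.raises(DegenerateImageError):
            segment_nuclei(np.full((16, 16), 0.4))
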