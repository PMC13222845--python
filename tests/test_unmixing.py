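"""Endmember extraction and NNLS unmixing, checked against independent oracles."""

import itertools

import numpy as np
import pytest

import kernelpheno as kp
from kernelpheno.cube_io import SpectralCube
from kernelpheno.segmentation import ForegroundMask, background_mask
from kernelpheno.unmixing import (EndmemberSet, extract_endmembers,
                                  extract_endmembers_nfindr, nnls_unmix,
                                  pca_reduce, reconstruction_rrmse,
                                  spectral_angle, two_pass_unmix)

from conftest import match_endmembers


def grid_search_nnls(E, r, resolution=1e-3, upper=None):
    """Exhaustive non-negative grid search oracle at the given resolution.

    All but the last coefficient are enumerated over the full lattice
    [0, upper] at *resolution*; for each combination the last coefficient is
    a 1-D convex quadratic whose lattice minimum is the nearest grid point
    to its continuous minimum (clipped to the bounds), so the result is
    exactly the full-enumeration optimum without materializing the cube.
    The box bound defaults to twice the unconstrained least-squares solution
    (which always brackets the constrained optimum's active coordinates).
    """
    E = np.asarray(E, dtype=float)
    r = np.asarray(r, dtype=float)
    n_em = E.shape[1]
    if upper is None:
        a_ls, *_ = np.linalg.lstsq(E, r, rcond=None)
        upper = float(np.clip(2.0 * np.abs(a_ls).max(), 1.5, 20.0))
    vals = np.arange(0.0, upper + resolution / 2, resolution)
    e_last = E[:, -1]
    denom = float(e_last @ e_last)
    best_obj, best_a = np.inf, None
    lead_axes = [vals] * max(0, n_em - 2)
    for chunk in np.array_split(vals, max(1, len(vals) // 64)):
        if n_em == 1:
            lead = np.zeros((1, 0))
        else:
            grids = np.meshgrid(chunk, *lead_axes, indexing="ij")
            lead = np.stack([g.ravel() for g in grids], axis=1)
        resid = r - lead @ E[:, :-1].T                # (m, bands)
        a_star = (resid @ e_last) / denom             # continuous 1-D optimum
        a_last = np.clip(np.round(a_star / resolution) * resolution, 0.0, upper)
        obj = ((resid - a_last[:, None] * e_last) ** 2).sum(axis=1)
        k = int(np.argmin(obj))
        if obj[k] < best_obj:
            best_obj = float(obj[k])
            best_a = np.append(lead[k], a_last[k])
        if n_em == 1:
            break
    return best_a, best_obj


class TestPcaReduce:
    def test_planar_data_recovers_rank(self, rng):
        basis = rng.normal(size=(2, 10))
        pts = rng.normal(size=(200, 2)) @ basis
        scores, _ = pca_reduce(pts, var_target=0.999)
        assert scores.shape[1] == 2

    def test_scores_are_centered(self, rng):
        pts = rng.normal(loc=5.0, size=(100, 6))
        scores, _ = pca_reduce(pts)
        np.testing.assert_allclose(scores.mean(axis=0), 0, atol=1e-10)

    def test_repeated_point_degenerates_to_one_dim(self):
        pts = np.tile(np.array([1.0, 2.0, 3.0]), (50, 1))
        scores, _ = pca_reduce(pts)
        assert scores.shape[1] == 1

    def test_explained_variance_matches_direct_eigendecomposition(self, rng):
        pts = rng.normal(size=(300, 8))
        _, pca = pca_reduce(pts, var_target=0.999)
        cov = np.cov(pts, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pca.explained_variance_[:8], eig, rtol=1e-8)


class TestEndmemberExtraction:
    @pytest.mark.parametrize("method", ["ppi", "nfindr", "fippi"])
    def test_planted_simplex_recovered(self, pure_scene, method):
        mask = background_mask(pure_scene.cube)
        em = extract_endmembers(pure_scene.cube, mask, 3, method=method,
                                seed=1, **({"n_skewers": 3000} if method == "ppi" else {}))
        assert em.n_em == 3
        for t in pure_scene.true_endmembers.spectra:
            assert min(spectral_angle(e, t) for e in em.spectra) < 1e-6

    @pytest.mark.parametrize("method", ["ppi", "nfindr", "fippi"])
    def test_same_seed_is_bit_identical(self, pure_scene, method):
        mask = background_mask(pure_scene.cube)
        a = extract_endmembers(pure_scene.cube, mask, 3, method=method, seed=7)
        b = extract_endmembers(pure_scene.cube, mask, 3, method=method, seed=7)
        assert np.array_equal(a.spectra, b.spectra)

    def test_two_distinct_points_both_returned(self):
        wl = np.linspace(425, 974, 6)
        data = np.zeros((1, 2, 6))
        data[0, 0] = 0.8
        data[0, 1] = np.linspace(0.1, 0.4, 6)
        cube = SpectralCube(data, wl)
        mask = ForegroundMask(np.ones((1, 2), dtype=bool))
        em = extract_endmembers(cube, mask, 2, method="ppi", seed=0, n_skewers=50)
        assert em.n_em == 2
        got = {tuple(np.round(s, 10)) for s in em.spectra}
        want = {tuple(np.round(data[0, 0], 10)), tuple(np.round(data[0, 1], 10))}
        assert got == want

    def test_nfindr_matches_brute_force_triangle(self, rng):
        # 2-D point cloud with three planted extreme vertices + interior points
        verts = np.array([[0.0, 0.0], [4.0, 0.5], [1.0, 3.0]])
        w = rng.dirichlet((2, 2, 2), size=60)
        pts2d = np.vstack([verts, w @ verts])
        # lift into spectra so raw_pixels are well-defined
        lift = np.abs(rng.normal(size=(2, 8))) + 0.1
        raw = 0.2 + pts2d @ lift * 0.05
        scores = pts2d - pts2d.mean(axis=0)
        em = extract_endmembers_nfindr(scores, raw, 3, np.arange(8.0), seed=0)

        def tri_area(idx):
            a, b, c = pts2d[list(idx)]
            ab, ac = b - a, c - a
            return abs(ab[0] * ac[1] - ab[1] * ac[0]) / 2

        best = max(itertools.combinations(range(len(pts2d)), 3), key=tri_area)
        best_spectra = {tuple(np.round(raw[i], 9)) for i in best}
        got = {tuple(np.round(s, 9)) for s in em.spectra}
        assert got == best_spectra

    def test_nfindr_identical_points_warns_zero_volume(self, caplog):
        raw = np.tile(np.array([0.5, 0.5, 0.5, 0.5]), (20, 1))
        scores = np.zeros((20, 2))
        em = extract_endmembers_nfindr(scores, raw, 3, np.arange(4.0), seed=0)
        assert em.n_em == 3  # initial set returned

    def test_nfindr_dimension_shortfall_is_hard_error(self):
        scores = np.zeros((10, 1))
        raw = np.random.default_rng(0).uniform(size=(10, 5))
        with pytest.raises(ValueError, match="volume"):
            extract_endmembers_nfindr(scores, raw, 4, np.arange(5.0), seed=0)

    def test_fippi_agrees_with_ppi_on_phantom(self, pure_scene):
        mask = background_mask(pure_scene.cube)
        ppi = extract_endmembers(pure_scene.cube, mask, 3, method="ppi", seed=1)
        fippi = extract_endmembers(pure_scene.cube, mask, 3, method="fippi", seed=1)
        for a, b in zip(ppi.spectra, fippi.spectra):
            # arccos of a unit dot product floors at ~sqrt(2*eps) ~ 2e-8
            assert spectral_angle(a, b) < 1e-6

    def test_fippi_converges_quickly(self, pure_scene):
        mask = background_mask(pure_scene.cube)
        em = extract_endmembers(pure_scene.cube, mask, 3, method="fippi", seed=1)
        assert em.n_iterations <= 20

    def test_endmember_csv_round_trip(self, tmp_path, pure_scene):
        mask = background_mask(pure_scene.cube)
        em = extract_endmembers(pure_scene.cube, mask, 3, seed=1)
        em.to_csv(tmp_path / "em.csv")
        back = EndmemberSet.from_csv(tmp_path / "em.csv")
        np.testing.assert_allclose(back.spectra, em.spectra, atol=1e-12)


class TestNnlsUnmix:
    def setup_method(self):
        self.wl = np.linspace(425, 974, 4)
        self.e1 = np.array([0.8, 0.7, 0.6, 0.5])
        self.e2 = np.array([0.1, 0.3, 0.2, 0.4])
        self.em = EndmemberSet(np.vstack([self.e1, self.e2]), self.wl, "manual")

    def unmix_single(self, pixel):
        cube = SpectralCube(pixel.reshape(1, 1, 4), self.wl)
        mask = ForegroundMask(np.ones((1, 1), dtype=bool))
        return nnls_unmix(cube, mask, self.em)

    def test_exact_mixture_recovered(self):
        ab, diag = self.unmix_single(0.3 * self.e1 + 0.7 * self.e2)
        np.testing.assert_allclose(ab.fractions[0, 0], [0.3, 0.7], atol=1e-10)
        assert diag.rrmse < 1e-12

    def test_pure_pixel(self):
        ab, _ = self.unmix_single(self.e1.copy())
        np.testing.assert_allclose(ab.fractions[0, 0], [1.0, 0.0], atol=1e-10)

    def test_supersaturated_pixel_normalized(self):
        ab, diag = self.unmix_single(self.e1 + self.e2)
        np.testing.assert_allclose(diag.raw_abundances[0], [1.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(ab.fractions[0, 0], [0.5, 0.5], atol=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            E = rng.uniform(0.05, 1.0, size=(4, 3))
            r = rng.uniform(0.0, 1.0, size=4)
            em = EndmemberSet(E.T, self.wl, "manual")
            cube = SpectralCube(r.reshape(1, 1, 4), self.wl)
            mask = ForegroundMask(np.ones((1, 1), dtype=bool))
            _, diag = nnls_unmix(cube, mask, em)
            a = diag.raw_abundances[0]
            f_nnls = float(((E @ a - r) ** 2).sum())
            _, f_grid = grid_search_nnls(E, r)
            assert f_nnls <= f_grid + 1e-9
            assert f_grid - f_nnls <= 1e-6

    @pytest.mark.parametrize("pattern", ["pure_zones", "radial_gradient", "dirichlet"])
    def test_sum_to_one_and_nonnegativity(self, pattern):
        ph = kp.make_kernel_scene(layout=(2, 2), image_shape=(60, 60), bands=30,
                                  abundance_pattern=pattern, snr_db=25, seed=5)
        mask = background_mask(ph.cube)
        em = extract_endmembers(ph.cube, mask, 3, seed=5, n_skewers=2000)
        ab, _ = nnls_unmix(ph.cube, mask, em)
        frac = ab.pixel_matrix()
        classified = ~ab.unclassifiable[mask.valid]
        assert (frac >= 0).all()
        np.testing.assert_allclose(frac[classified].sum(axis=1), 1.0, atol=1e-9)

    def test_noisy_abundance_recovery(self, noisy_scene):
        mask = background_mask(noisy_scene.cube)
        em = extract_endmembers(noisy_scene.cube, mask, 3, seed=1, n_skewers=5000)
        ab, _ = nnls_unmix(noisy_scene.cube, mask, em)
        order = match_endmembers(em, noisy_scene.true_endmembers)
        est = ab.fractions[..., order][noisy_scene.true_abundance.valid.valid]
        true = noisy_scene.true_abundance.pixel_matrix()
        assert np.sqrt(np.mean((est - true) ** 2)) < 0.05


class TestRrmse:
    def test_exact_reconstruction_is_zero(self, pure_scene):
        mask = background_mask(pure_scene.cube)
        em = pure_scene.true_endmembers
        _, diag = nnls_unmix(pure_scene.cube, mask, em)
        assert diag.rrmse < 1e-12

    def test_zero_model_closed_form(self):
        wl = np.linspace(425, 974, 3)
        data = np.array([[[0.2, 0.4, 0.6]]])
        cube = SpectralCube(data, wl)
        mask = ForegroundMask(np.ones((1, 1), dtype=bool))
        em = EndmemberSet(np.zeros((2, 3)), wl, "manual")
        rr = reconstruction_rrmse(cube, mask, em, np.zeros((1, 2)))
        r = data.ravel()
        assert rr == pytest.approx(np.sqrt(np.mean(r**2)) / np.mean(r))

    def test_zero_mean_reflectance_is_hard_error(self):
        wl = np.linspace(425, 974, 3)
        cube = SpectralCube(np.zeros((1, 1, 3)), wl)
        mask = ForegroundMask(np.ones((1, 1), dtype=bool))
        em = EndmemberSet(np.ones((2, 3)), wl, "manual")
        with pytest.raises(ValueError):
            reconstruction_rrmse(cube, mask, em, np.zeros((1, 2)))

    def test_monotone_in_endmember_count(self, noisy_scene):
        mask = background_mask(noisy_scene.cube)
        true = noisy_scene.true_endmembers
        extra = true.spectra.mean(axis=0) * 0.5
        nested = [true.spectra[:2], true.spectra,
                  np.vstack([true.spectra, extra])]
        rrmses = []
        for spectra in nested:
            em = EndmemberSet(spectra, true.wavelengths, "manual")
            _, diag = nnls_unmix(noisy_scene.cube, mask, em)
            rrmses.append(diag.rrmse)
        assert rrmses[1] <= rrmses[0] + 1e-9
        assert rrmses[2] <= rrmses[1] + 1e-9

    def test_noisy_rrmse_near_planted_noise_floor(self, noisy_scene):
        # analytic floor: rRMSE -> sigma / mean(R) when the model is exact
        mask = ForegroundMask(noisy_scene.true_abundance.valid.valid)
        _, diag = nnls_unmix(noisy_scene.cube, mask, noisy_scene.true_endmembers)
        pixels = noisy_scene.cube.reflectance[mask.valid]
        floor = noisy_scene.noise_sigma / pixels.mean()
        assert diag.rrmse == pytest.approx(floor, rel=0.05)


class TestTwoPass:
    def test_dark_flat_background_removed_exactly(self, darkflat_scene):
        mask = background_mask(darkflat_scene.cube)
        res = two_pass_unmix(darkflat_scene.cube, mask, n_em_global=4,
                             n_em_kernel=3, seed=2, n_skewers=3000)
        assert res.background_em_ids
        np.testing.assert_array_equal(res.kernel_mask.valid,
                                      darkflat_scene.true_abundance.valid.valid)

    def test_no_background_keeps_mask(self, pure_scene, caplog):
        mask = background_mask(pure_scene.cube)
        res = two_pass_unmix(pure_scene.cube, mask, n_em_global=3,
                             n_em_kernel=3, seed=1, n_skewers=2000)
        assert res.background_em_ids == []
        np.testing.assert_array_equal(res.kernel_mask.valid, mask.valid)

    def test_second_pass_not_worse_on_kernel_pixels(self, darkflat_scene):
        mask = background_mask(darkflat_scene.cube)
        res = two_pass_unmix(darkflat_scene.cube, mask, n_em_global=4,
                             n_em_kernel=3, seed=2, n_skewers=3000)
        # recompute pass-1 reconstruction error on the pass-2 pixel set
        _, diag1 = nnls_unmix(darkflat_scene.cube, res.kernel_mask, res.em_global)
        assert res.diag_kernel.rrmse <= diag1.rrmse + 1e-9
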