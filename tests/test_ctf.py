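"""CTF model, power spectra, three-step fitting, anisotropic field."""

import numpy as np
import pytest
from scipy.optimize import brentq

from streamspa import ctf, poly, synthetic


BASE = ctf.CtfParams(dfx=1.8, dfy=1.8, ang_ast=0.0, amp_contrast=0.0,
                     phshift=0.0, pixel_size=1.0)


class TestCtfModel:
    def test_zero_frequency_zero_contrast(self):
        p = ctf.CtfParams(amp_contrast=0.0, phshift=0.0)
        assert ctf.ctf_eval(p, 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_astigmatic_defocus_extremes(self):
        """Along the astigmatism axis the effective defocus is dfx; at 90
        degrees it is dfy."""
        p = ctf.CtfParams(dfx=2.1, dfy=1.5, ang_ast=35.0, pixel_size=1.0)
        ang = np.radians(35.0)
        px = ctf.CtfParams(dfx=2.1, dfy=2.1, ang_ast=0.0, pixel_size=1.0)
        py = ctf.CtfParams(dfx=1.5, dfy=1.5, ang_ast=0.0, pixel_size=1.0)
        g = np.linspace(0.01, 0.4, 50)
        assert np.allclose(ctf.ctf_eval(p, g, ang), ctf.ctf_eval(px, g, 0.0))
        assert np.allclose(ctf.ctf_eval(p, g, ang + np.pi / 2),
                           ctf.ctf_eval(py, g, 0.0))

    def test_first_zero_matches_chi_root(self):
        """First CTF zero coincides with the numerically solved chi = pi."""
        p = ctf.CtfParams(dfx=2.0, dfy=2.0, amp_contrast=0.0, phshift=0.0,
                          pixel_size=1.0)
        # locate the first sign change by dense scan, refine with brentq
        gs = np.arange(1e-4, 0.1, 1e-4)
        vals = ctf.ctf_eval(p, gs)
        i = int(np.argmax(vals[:-1] * vals[1:] < 0))
        root_ctf = brentq(lambda g: ctf.ctf_eval(p, g), gs[i], gs[i + 1])
        root_chi = brentq(lambda g: ctf._chi(p, np.asarray(g), 0.0) - np.pi,
                          1e-4, 0.1)
        assert root_ctf == pytest.approx(root_chi, abs=1e-10)

    def test_amplitude_contrast_phase(self):
        # A = atan(w / sqrt(1 - w^2)) = asin(w)
        p = ctf.CtfParams(amp_contrast=0.1)
        assert ctf._chi(p, np.asarray(0.0), 0.0) == pytest.approx(
            np.arcsin(0.1))

    def test_canonicalization_degeneracy(self):
        a = ctf.CtfParams(dfx=1.5, dfy=1.9, ang_ast=120.0, pixel_size=1.0)
        c = ctf.canonical_astigmatism(a)
        assert (c.dfx, c.dfy) == (1.9, 1.5)
        assert c.ang_ast == pytest.approx(30.0)
        g, th = np.meshgrid(np.linspace(0.01, 0.3, 20),
                            np.linspace(0, np.pi, 20))
        assert np.allclose(ctf.ctf_eval(a, g, th), ctf.ctf_eval(c, g, th))


class TestSpectrum:
    def test_tiling_count(self):
        mic = np.random.default_rng(0).normal(size=(2048, 2048))
        spec = ctf.compute_spectrum(mic, 1.0, tile_size=512, overlap=0.5)
        assert spec.n_tiles == 49

    def test_white_noise_flat_after_background_subtraction(self):
        mic = np.random.default_rng(1).normal(size=(2048, 2048))
        spec = ctf.compute_spectrum(mic, 1.0, tile_size=512)
        g, prof = spec.radial_average()
        sel = (g > 1.0 / 30) & (g < 0.45)
        vals = prof[sel]
        assert np.abs(vals.mean()) < 3 * vals.std()

    def test_constant_image_zero_off_origin(self):
        mic = np.full((1024, 1024), 7.0)
        spec = ctf.compute_spectrum(mic, 1.0, tile_size=256)
        c = 128
        off = spec.values.copy()
        off[c - 2:c + 3, c - 2:c + 3] = 0.0
        assert np.abs(off).max() < 1e-12

    def test_too_small_micrograph_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            ctf.compute_spectrum(np.zeros((256, 256)), 1.0, tile_size=512)


class TestScore:
    def _synthetic_spectrum(self, params, scale=3.0):
        """Spectrum whose values are exactly scale * CTF^2."""
        n = 512
        spec = ctf.PowerSpectrum2d(values=np.zeros((n, n)), pixel_size=1.0,
                                   tile_size=n, n_tiles=1)
        g, theta = spec.freq_grids()
        spec.values = scale * ctf.ctf_eval(params, g, theta) ** 2
        return spec

    def test_self_correlation_is_one(self):
        spec = self._synthetic_spectrum(BASE)
        assert ctf.score_cc(spec, BASE) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self):
        a = self._synthetic_spectrum(BASE, scale=1.0)
        b = self._synthetic_spectrum(BASE, scale=250.0)
        other = ctf.CtfParams(dfx=2.4, dfy=2.4, pixel_size=1.0)
        assert ctf.score_cc(a, other) == pytest.approx(
            ctf.score_cc(b, other), abs=1e-12)

    def test_noise_spectrum_low_correlation(self):
        n = 512
        spec = ctf.PowerSpectrum2d(
            values=np.random.default_rng(2).normal(size=(n, n)),
            pixel_size=1.0, tile_size=n, n_tiles=1)
        assert abs(ctf.score_cc(spec, BASE)) < 0.1

    def test_empty_annulus_rejected(self):
        spec = self._synthetic_spectrum(BASE)
        with pytest.raises(ValueError):
            ctf.score_cc(spec, BASE, res_range=(1.9, 1.5))

    def test_penalty_closed_forms(self):
        spec = self._synthetic_spectrum(BASE)
        mask, g, theta = ctf._annulus_mask(spec, (30.0, 5.0))
        F = spec.values[mask]
        N = F.size
        # zero astigmatism: f = cc exactly
        f, _, cc, fpen = ctf._score_f_and_grad(F, g, theta, BASE, 0.05)
        assert fpen == 0.0
        assert f == cc
        # |dfx - dfy| = dftol: fpen = -1/(2N)
        p = ctf.CtfParams(dfx=1.85, dfy=1.80, pixel_size=1.0)
        _, _, _, fpen = ctf._score_f_and_grad(F, g, theta, p, 0.05)
        assert fpen == pytest.approx(-0.5 / N, rel=1e-12)

    def test_penalty_monotone_and_score_bounded_by_cc(self):
        spec = self._synthetic_spectrum(BASE)
        mask, g, theta = ctf._annulus_mask(spec, (30.0, 5.0))
        F = spec.values[mask]
        pens = []
        for d in (0.0, 0.02, 0.05, 0.1):
            p = ctf.CtfParams(dfx=1.8 + d, dfy=1.8, pixel_size=1.0)
            f, _, cc, fpen = ctf._score_f_and_grad(F, g, theta, p, 0.05)
            assert f <= cc
            pens.append(fpen)
        assert all(a > b for a, b in zip(pens, pens[1:]))

    def test_analytic_gradient_matches_finite_differences(self):
        spec = self._synthetic_spectrum(
            ctf.CtfParams(dfx=1.9, dfy=1.7, ang_ast=20.0, pixel_size=1.0))
        mask, g, theta = ctf._annulus_mask(spec, (30.0, 5.0))
        F = spec.values[mask]
        p = ctf.CtfParams(dfx=1.85, dfy=1.75, ang_ast=20.0, pixel_size=1.0)
        _, grad, _, _ = ctf._score_f_and_grad(F, g, theta, p, 0.05)
        eps = 1e-6
        for i, key in enumerate(("dfx", "dfy")):
            from dataclasses import replace
            fp, _, _, _ = ctf._score_f_and_grad(
                F, g, theta, replace(p, **{key: getattr(p, key) + eps}), 0.05)
            fm, _, _, _ = ctf._score_f_and_grad(
                F, g, theta, replace(p, **{key: getattr(p, key) - eps}), 0.05)
            assert grad[i] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4)


class TestThreeStepFit:
    def test_1d_search_distinguishes_defoci(self):
        for df in (0.8, 3.0):
            base = ctf.CtfParams(dfx=df, dfy=df, pixel_size=1.0)
            mic = synthetic.make_ctf_micrograph(
                synthetic.CtfGroundTruth(base=base), dims=(1024, 1024),
                snr=None, seed=int(df * 10))
            spec = ctf.compute_spectrum(mic, 1.0, tile_size=512)
            est, _, flag = ctf.search_defocus_1d(
                spec, ctf.CtfParams(pixel_size=1.0))
            assert not flag
            assert est == pytest.approx(df, abs=0.02)

    def test_flat_spectrum_flagged(self):
        spec = ctf.PowerSpectrum2d(values=np.zeros((256, 256)),
                                   pixel_size=1.0, tile_size=256, n_tiles=1)
        _, _, flag = ctf.search_defocus_1d(spec, ctf.CtfParams(pixel_size=1.0))
        assert flag

    def test_full_fit_recovers_planted_parameters(self, ctf_fixture):
        _, spectrum, truth = ctf_fixture
        fit = ctf.estimate_ctf(spectrum, ctf.CtfParams(pixel_size=1.0),
                               seed=1)
        got = ctf.canonical_astigmatism(fit.params)
        want = ctf.canonical_astigmatism(truth)
        assert got.dfx == pytest.approx(want.dfx, abs=0.01)
        assert got.dfy == pytest.approx(want.dfy, abs=0.01)
        d = abs(got.ang_ast - want.ang_ast) % 180
        assert min(d, 180 - d) < 3.0

    def test_astigmatism_search_deterministic_under_seed(self, ctf_fixture):
        _, spectrum, _ = ctf_fixture
        a = ctf.refine_astigmatism(spectrum, ctf.CtfParams(pixel_size=1.0),
                                   1.8, seed=9)
        b = ctf.refine_astigmatism(spectrum, ctf.CtfParams(pixel_size=1.0),
                                   1.8, seed=9)
        assert (a.dfx, a.dfy, a.ang_ast) == (b.dfx, b.dfy, b.ang_ast)

    def test_phase_plate_mode_recovers_phase_shift(self):
        base = ctf.CtfParams(dfx=1.2, dfy=1.2, phshift=np.pi / 2,
                             pixel_size=1.0)
        mic = synthetic.make_ctf_micrograph(
            synthetic.CtfGroundTruth(base=base), dims=(2048, 2048),
            snr=None, seed=12)
        spec = ctf.compute_spectrum(mic, 1.0)
        fit = ctf.estimate_ctf(spec, ctf.CtfParams(pixel_size=1.0),
                               phase_plate=True, seed=12)
        assert abs(fit.params.phshift - np.pi / 2) < 0.2
        # searching without phase-plate mode scores worse
        fit_off = ctf.estimate_ctf(spec, ctf.CtfParams(pixel_size=1.0),
                                   phase_plate=False, seed=12)
        assert fit.cc > fit_off.cc

    def test_fit_resolution_noiseless_beyond_scoring_limit(self):
        base = ctf.CtfParams(dfx=2.2, dfy=2.2, pixel_size=1.0)
        mic = synthetic.make_ctf_micrograph(
            synthetic.CtfGroundTruth(base=base), dims=(2048, 2048),
            snr=None, seed=13)
        spec = ctf.compute_spectrum(mic, 1.0)
        res, flagged = ctf.fit_resolution(spec, base)
        assert not flagged
        assert res <= 5.0

    def test_fit_resolution_pure_noise_flagged(self):
        spec = ctf.PowerSpectrum2d(
            values=np.random.default_rng(3).normal(size=(512, 512)),
            pixel_size=1.0, tile_size=512, n_tiles=1)
        res, flagged = ctf.fit_resolution(spec, BASE)
        assert flagged
        assert res == 30.0


class TestPatchGrid:
    def test_worked_example_49_points(self):
        points, _, _ = ctf.build_patch_grid((4000, 4000), spacing=512)
        assert len(points) == 49

    def test_weights_normalized_and_monotone(self):
        points, centers, table = ctf.build_patch_grid((2048, 2048),
                                                      spacing=512)
        for p, (idx, w) in zip(points, table):
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w > 0).all()
            d = np.hypot(*(centers[idx] - p).T)
            order = np.argsort(d)
            assert (np.diff(w[order]) <= 1e-12).all()

    def test_nearest_tile_has_max_weight(self):
        points, centers, table = ctf.build_patch_grid((2048, 2048),
                                                      spacing=512)
        for p, (idx, w) in zip(points, table):
            d = np.hypot(*(centers[idx] - p).T)
            assert w[np.argmin(d)] == w.max()

    def test_small_micrograph_single_point(self):
        with pytest.warns(UserWarning, match="single central point"):
            points, _, _ = ctf.build_patch_grid((256, 256), spacing=512,
                                                tile_size=256)
        assert len(points) == 1


class TestAnisoField:
    def test_polynomial_exactly_interpolates_own_basis(self):
        rng = np.random.default_rng(4)
        exps = poly.BIVARIATE_EXPONENTS
        coeffs = rng.normal(0, 0.1, len(exps))
        pts = np.array([(x, y) for x in np.linspace(-1, 1, 5)
                        for y in np.linspace(-1, 1, 5)])
        vals = poly.eval_poly(coeffs, pts, exps)
        refit, rms = poly.fit_least_squares(pts, vals, exps)
        assert np.abs(refit - coeffs).max() < 1e-8
        assert rms < 1e-8

    def test_constant_field_recovered_flat(self):
        base = ctf.CtfParams(dfx=1.8, dfy=1.8, pixel_size=1.0)
        mic = synthetic.make_ctf_micrograph(
            synthetic.CtfGroundTruth(base=base), dims=(2048, 2048),
            snr=None, seed=14)
        spec = ctf.compute_spectrum(mic, 1.0)
        gfit = ctf.estimate_ctf(spec, ctf.CtfParams(pixel_size=1.0), seed=14)
        model = ctf.fit_patch_ctf(mic, gfit)
        vals = [ctf.evaluate_local_ctf(model, x, y).dfx
                for x in (50, 1024, 2000) for y in (50, 1024, 2000)]
        assert max(vals) - min(vals) < 0.03

    def test_planted_tilt_recovered(self):
        field = synthetic.linear_defocus_field(1.5, edge_to_edge_x=0.4)
        truth = synthetic.CtfGroundTruth(
            base=ctf.CtfParams(dfx=1.5, dfy=1.5, pixel_size=1.0),
            field_dfx=field, field_dfy=field)
        mic = synthetic.make_ctf_micrograph(truth, dims=(2048, 2048),
                                            snr=None, seed=15)
        spec = ctf.compute_spectrum(mic, 1.0)
        gfit = ctf.estimate_ctf(spec, ctf.CtfParams(pixel_size=1.0), seed=15)
        model = ctf.fit_patch_ctf(mic, gfit)
        rng = np.random.default_rng(5)
        errs = []
        for x, y in zip(rng.uniform(100, 1900, 25),
                        rng.uniform(100, 1900, 25)):
            p = ctf.evaluate_local_ctf(model, x, y)
            tx, ty = truth.local_defocus(poly.normalize_coords(x, 2047),
                                         poly.normalize_coords(y, 2047))
            errs += [p.dfx - tx, p.dfy - ty]
        assert np.sqrt(np.mean(np.square(errs))) < 0.05

    def test_local_evaluation_continuity(self):
        """Neighbouring pixels differ by less than the polynomial gradient
        bound."""
        field = synthetic.linear_defocus_field(1.5, edge_to_edge_x=0.4,
                                               edge_to_edge_y=0.2)
        model = ctf.AnisoCtfModel(
            poly_dfx=field, poly_dfy=field, ang_ast=0.0, phshift=0.0,
            base=ctf.CtfParams(pixel_size=1.0), dims=(2048, 2048))
        exps = poly.BIVARIATE_EXPONENTS
        bound = sum(abs(c) * max(e) for c, e in zip(field, exps)) * 2 / 2047
        vals = [ctf.evaluate_local_ctf(model, x, 300.0).dfx
                for x in range(500, 510)]
        assert np.abs(np.diff(vals)).max() <= bound + 1e-12
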