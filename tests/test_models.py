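import numpy as np
import pytest

import nchroma as nc
from nchroma.exceptions import ModelConfigError


class TestModelConfig:
    def test_named_model_conventions(self):
        ch = nc.ModelConfig.ch()
        assert (ch.transform, ch.scale_value, ch.use_noise) == ("hyperbolic", 1.0, False)
        em = nc.ModelConfig.em()
        assert (em.transform, em.relative_outputs, em.scale_value) == ("ln", True, 0.75)
        rnl = nc.ModelConfig.rnl_log((0.13, 0.06, 0.12))
        assert rnl.transform == "ln" and rnl.use_noise

    def test_noise_model_without_noise_rejected(self):
        with pytest.raises(ModelConfigError, match="noise"):
            nc.ModelConfig(kind="RNL_linear", transform="identity", use_noise=True)

    def test_noise_on_noiseless_model_rejected(self):
        with pytest.raises(ModelConfigError):
            nc.ModelConfig(kind="CH", transform="hyperbolic", noise=(0.1, 0.1, 0.1))

    def test_scalar_noise_broadcasts_to_receptor_count(self):
        cfg = nc.ModelConfig.rnl_log(0.1)
        assert cfg.resolved_noise(5) == (0.1,) * 5


class TestClosedFormRnl:
    def test_trichromat_reference_value(self):
        # equal 0.1 noise, single-receptor contrast: sqrt(0.02/0.0003)
        ds = nc.rnl_delta_s_closed([0, 0, 1], [0, 0, 0], [0.1, 0.1, 0.1])
        assert ds == pytest.approx(8.1650, abs=1e-4)

    def test_dichromat_reference_value(self):
        ds = nc.rnl_delta_s_closed([0, 1], [0, 0], [0.1, 0.1])
        assert ds == pytest.approx(7.0711, abs=1e-4)

    def test_uniform_output_shift_is_invisible(self, rng):
        for i in (2, 3, 4):
            c = rng.normal()
            e = rng.uniform(0.05, 0.3, size=i)
            assert nc.rnl_delta_s_closed(np.full(i, c), np.zeros(i), e) == pytest.approx(0.0)

    def test_noise_scaling_homogeneity(self, rng):
        Ea, Eb = rng.normal(size=3), rng.normal(size=3)
        e = rng.uniform(0.05, 0.3, size=3)
        base = nc.rnl_delta_s_closed(Ea, Eb, e)
        assert nc.rnl_delta_s_closed(Ea, Eb, 2.0 * e) == pytest.approx(base / 2.0)

    def test_unsupported_receptor_count_points_to_generic(self):
        with pytest.raises(ValueError, match="generic"):
            nc.rnl_delta_s_closed(np.zeros(5), np.zeros(5), np.full(5, 0.1))


class TestNoiseSpace:
    def test_equal_noise_trichromat_is_pure_rescaling(self):
        # V R Vt = e^2 (3/2) I for unit 120-degree columns, so the noise
        # space divides loci by e*sqrt(3/2)
        b = nc.chromaticity_basis(3)
        e = np.full(3, 0.1)
        x = nc.color_locus(b, [0.0, 0.0, 1.0])
        s = nc.rnl_noise_space(b, e, x)
        np.testing.assert_allclose(s, x / (0.1 * np.sqrt(1.5)), atol=1e-12)
        assert np.linalg.norm(s) == pytest.approx(8.1650, abs=1e-4)

    def test_origin_maps_to_origin(self):
        b = nc.chromaticity_basis(4)
        s = nc.rnl_noise_space(b, np.full(4, 0.1), np.zeros(3))
        np.testing.assert_allclose(s, 0.0)

    @pytest.mark.parametrize("i", [2, 3, 4])
    def test_oracle_equivalence_with_closed_forms(self, i):
        """|s| from the noise-space transform equals the closed-form RNL
        distance on 200 randomized inputs per receptor count."""
        rng = np.random.default_rng(1234 + i)
        basis = nc.chromaticity_basis(i)
        for _ in range(200):
            Ea = rng.normal(scale=2.0, size=i)
            Eb = rng.normal(scale=2.0, size=i)
            e = rng.uniform(0.02, 0.4, size=i)
            closed = nc.rnl_delta_s_closed(Ea, Eb, e)
            s = nc.rnl_noise_space(basis, e, basis.V @ (Ea - Eb))
            assert abs(np.linalg.norm(s) - closed) < 1e-9

    def test_basis_scale_cancels(self, rng):
        Ea, Eb = rng.normal(size=3), rng.normal(size=3)
        e = rng.uniform(0.05, 0.3, size=3)
        unit = nc.chromaticity_basis(3)
        scaled = nc.chromaticity_basis(3, "vertex_distance", 3.0)
        d_unit = np.linalg.norm(nc.rnl_noise_space(unit, e, unit.V @ (Ea - Eb)))
        d_scaled = np.linalg.norm(nc.rnl_noise_space(scaled, e, scaled.V @ (Ea - Eb)))
        assert d_unit == pytest.approx(d_scaled, abs=1e-12)


class TestGenericRnl:
    def test_pentachromat_zero_contrast(self):
        assert nc.rnl_delta_s_generic(np.ones(5), np.ones(5), np.full(5, 0.1)) == 0.0

    def test_pentachromat_distance_is_finite_and_positive(self, rng):
        Ea = rng.normal(size=5)
        ds = nc.rnl_delta_s_generic(Ea, np.zeros(5), np.full(5, 0.1))
        assert np.isfinite(ds) and ds > 0

    def test_noise_scaling_inverse(self, rng):
        Ea, Eb = rng.normal(size=4), rng.normal(size=4)
        e = rng.uniform(0.05, 0.3, size=4)
        assert nc.rnl_delta_s_generic(Ea, Eb, 3.0 * e) == pytest.approx(
            nc.rnl_delta_s_generic(Ea, Eb, e) / 3.0
        )


class TestRunModel:
    @pytest.fixture()
    def scene(self, grid, trichromat, flat_illuminant, background_7pct):
        return dict(
            background=background_7pct,
            illuminant=flat_illuminant,
            receptors=trichromat,
        )

    @pytest.mark.parametrize(
        "config",
        [
            nc.ModelConfig.ch(),
            nc.ModelConfig.em(),
            nc.ModelConfig.rnl_linear((0.13, 0.06, 0.12)),
            nc.ModelConfig.rnl_log((0.13, 0.06, 0.12)),
        ],
        ids=["CH", "EM", "linear-RNL", "log-RNL"],
    )
    def test_stimulus_equal_to_background_sits_at_origin(self, scene, config):
        res = nc.run_model(scene["background"], scene["background"],
                           scene["illuminant"], scene["receptors"], config)
        np.testing.assert_allclose(res.locus, 0.0, atol=1e-12)
        assert res.delta_s_background == pytest.approx(0.0, abs=1e-12)

    def test_em_simplex_corner_reaches_exactly_075(self):
        """A stimulus monopolizing one receptor sits a distance of exactly
        0.75 from the background in the Endler-Mielke space."""
        basis = nc.chromaticity_basis(4, "vector_length", 0.75)
        corner = nc.color_locus(basis, [1.0, 0.0, 0.0, 0.0])
        assert nc.euclidean_delta_s(corner) == pytest.approx(0.75, abs=1e-12)

    def test_ch_loci_stay_inside_unit_circumradius(self, scene, grid):
        cfg = nc.ModelConfig.ch()
        for mp in (350, 450, 550, 650):
            stim = nc.logistic_reflectance(mp, grid=grid)
            res = nc.run_model(stim, scene["background"], scene["illuminant"],
                               scene["receptors"], cfg)
            assert np.linalg.norm(res.locus) < 1.0

    def test_em_spurious_regime_flagged(self, scene, grid):
        # stimulus catches below background: ln outputs go negative, the
        # output sum crosses zero, relative outputs explode past 0.75
        found = False
        for mp in np.arange(420.0, 560.0, 5.0):
            stim = nc.shift_reflectance(nc.logistic_reflectance(mp, grid=grid), -10.0)
            res = nc.run_model(stim, scene["background"], scene["illuminant"],
                               scene["receptors"], nc.ModelConfig.em())
            if res.delta_s_background > 0.75:
                assert res.warnings
                found = True
        assert found, "no spurious EM distance found in the shifted sweep"

    def test_log_rnl_invariant_to_stimulus_intensity(self, grid, trichromat, d65, leaf):
        cfg = nc.ModelConfig.rnl_log((0.13, 0.06, 0.12))
        base = nc.flat_reflectance(0.10, grid)
        ds = []
        for k in (1.0, 2.0, 5.0):
            stim = nc.Spectrum(grid, k * base.values)
            res = nc.run_model(stim, leaf, d65, trichromat, cfg)
            ds.append(res.delta_s_background)
        np.testing.assert_allclose(ds, ds[0], atol=1e-9)

    def test_linear_rnl_grows_with_achromatic_level(self, grid, trichromat, d65, leaf):
        cfg = nc.ModelConfig.rnl_linear((0.13, 0.06, 0.12))
        ds = [
            nc.run_model(nc.flat_reflectance(lv, grid), leaf, d65, trichromat, cfg
                         ).delta_s_background
            for lv in (0.1, 0.3, 0.5, 0.7)
        ]
        assert np.all(np.diff(ds) > 0)

    def test_negative_ln_outputs_recorded_as_warning(self, scene, grid):
        stim = nc.flat_reflectance(0.03, grid)  # darker than the 7% background
        res = nc.run_model(stim, scene["background"], scene["illuminant"],
                           scene["receptors"], nc.ModelConfig.rnl_log(0.1))
        assert any("negative" in w for w in res.warnings)

    def test_rnl_delta_s_matches_standalone_computation(self, scene, grid):
        cfg = nc.ModelConfig.rnl_log((0.13, 0.06, 0.12))
        stim = nc.logistic_reflectance(480.0, grid=grid)
        res = nc.run_model(stim, scene["background"], scene["illuminant"],
                           scene["receptors"], cfg)
        expected = nc.rnl_delta_s_generic(res.catch.E, np.zeros(3), (0.13, 0.06, 0.12))
        assert res.delta_s_background == pytest.approx(expected, abs=1e-12)
        assert np.linalg.norm(res.noise_locus) == pytest.approx(expected, abs=1e-12)

    def test_custom_hyperbolic_generic_model_matches_ch(self, scene, grid):
        """A user-defined model with transform q/(q+1) reproduces the hexagon."""
        stim = nc.logistic_reflectance(520.0, grid=grid)
        ch = nc.run_model(stim, scene["background"], scene["illuminant"],
                          scene["receptors"], nc.ModelConfig.ch())
        gen = nc.run_model(
            stim, scene["background"], scene["illuminant"], scene["receptors"],
            nc.ModelConfig.generic(transform="custom",
                                   custom_transform=lambda q: q / (q + 1.0)),
        )
        np.testing.assert_allclose(gen.locus, ch.locus, atol=1e-12)
        assert gen.delta_s_background == pytest.approx(ch.delta_s_background)

    def test_missing_noise_for_rnl_kind_is_config_error(self):
        with pytest.raises(ModelConfigError):
            nc.ModelConfig(kind="RNL_log", transform="ln", use_noise=True, noise=None)
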