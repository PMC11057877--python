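import numpy as np
import pytest
from hypothesis import given, strategies as hst

from anemonevision.rnl import (
    QuantumCatchVector,
    VisualModelError,
    classify_non_spectral,
    complementary_pairs,
    hue_angles_from_xyz,
    noise_corrected_xyz,
    quantum_catch,
    receptor_noise,
    rnl_delta_s,
    _delta_s_from_df,
)
from anemonevision.spectra import DEFAULT_GRID, Spectrum


def _catch(q):
    return QuantumCatchVector(np.asarray(q, dtype=float))


class TestReceptorNoise:
    @pytest.mark.parametrize(
        "sigma,ratio,expected",
        [
            ((0.05,), (1.0,), (0.05,)),
            ((0.05,), (2.0,), (0.035355,)),
            ((0.11, 0.14, 0.14, 0.14), (1, 2, 1, 1), (0.11, 0.098995, 0.14, 0.14)),
        ],
    )
    def test_weber_over_sqrt_abundance(self, sigma, ratio, expected):
        np.testing.assert_allclose(receptor_noise(sigma, ratio), expected, atol=1e-5)

    def test_nonpositive_rejected(self):
        with pytest.raises(VisualModelError):
            receptor_noise((0.0,), (1.0,))


class TestQuantumCatch:
    def test_background_maps_to_unit_catches(self, display, visual_system):
        c = quantum_catch(display.background, display.background, visual_system)
        np.testing.assert_allclose(c.q, 1.0)
        np.testing.assert_allclose(c.f, 0.0)

    def test_doubling_radiance_doubles_catches(self, display, visual_system):
        doubled = display.background.with_values(display.background.values * 2.0)
        c = quantum_catch(doubled, display.background, visual_system)
        np.testing.assert_allclose(c.q, 2.0)

    def test_uv_stimulus_maximally_drives_uv_cone(self, display, visual_system):
        wl = DEFAULT_GRID.wavelengths
        uv = Spectrum(wl, 1.0 + 100.0 * np.exp(-0.5 * ((wl - 380.0) / 10.0) ** 2))
        c = quantum_catch(uv, display.background, visual_system)
        assert np.argmax(c.q) == 0

    def test_zero_stimulus_catch_names_receptor(self, display):
        # boxcar receptors with disjoint support expose the undefined-log case
        from anemonevision.rnl import VisualSystem

        wl = DEFAULT_GRID.wavelengths
        blue_rec = Spectrum(wl, np.where((wl > 400) & (wl < 450), 1.0, 0.0), "absorbance")
        red_rec = Spectrum(wl, np.where((wl > 600) & (wl < 650), 1.0, 0.0), "absorbance")
        vs = VisualSystem((blue_rec, red_rec), (0.1, 0.1), (1.0, 1.0), ("B", "R"))
        blue_only = Spectrum(wl, np.where(wl < 500.0, 1.0, 0.0))
        with pytest.raises(VisualModelError, match="R"):
            quantum_catch(blue_only, display.background, vs)


class TestDeltaS:
    def test_identity_and_symmetry(self, visual_system):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = _catch(np.exp(rng.normal(0, 0.3, 4)))
            b = _catch(np.exp(rng.normal(0, 0.3, 4)))
            assert rnl_delta_s(a, a, visual_system) == 0.0
            assert rnl_delta_s(a, b, visual_system) == pytest.approx(
                rnl_delta_s(b, a, visual_system)
            )

    def test_dichromat_closed_form(self):
        # |df1-df2| / sqrt(e1^2+e2^2)
        df = np.array([0.1, 0.0])
        e = np.array([0.05, 0.05])
        assert _delta_s_from_df(df, e) == pytest.approx(0.1 / np.sqrt(0.005), abs=1e-12)

    def test_general_matches_dichromat_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            df = rng.normal(size=2)
            e = rng.uniform(0.01, 0.3, 2)
            closed = abs(df[0] - df[1]) / np.hypot(e[0], e[1])
            assert _delta_s_from_df(df, e) == pytest.approx(closed, abs=1e-12)

    def test_uniform_intensity_shift_is_achromatic(self, visual_system):
        a = _catch([1.0, 1.0, 1.0, 1.0])
        b = _catch([3.7, 3.7, 3.7, 3.7])
        assert rnl_delta_s(a, b, visual_system) == pytest.approx(0.0, abs=1e-12)

    def test_trichromat_closed_form_agrees(self):
        # published 3-receptor form as an independent oracle
        rng = np.random.default_rng(2)
        for _ in range(200):
            df = rng.normal(size=3)
            e = rng.uniform(0.02, 0.3, 3)
            num = (
                e[2] ** 2 * (df[0] - df[1]) ** 2
                + e[1] ** 2 * (df[0] - df[2]) ** 2
                + e[0] ** 2 * (df[1] - df[2]) ** 2
            )
            den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
            assert _delta_s_from_df(df, e) == pytest.approx(np.sqrt(num / den), abs=1e-10)

    def test_tetrachromat_closed_form_agrees(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            df = rng.normal(size=4)
            e = rng.uniform(0.02, 0.3, 4)
            num = 0.0
            idx = range(4)
            for i in idx:
                for j in idx:
                    if i < j:
                        others = [k for k in idx if k not in (i, j)]
                        num += (e[others[0]] * e[others[1]] * (df[i] - df[j])) ** 2
            den = sum(
                (e[i] * e[j] * e[k]) ** 2
                for i in idx
                for j in idx
                for k in idx
                if i < j < k
            )
            assert _delta_s_from_df(df, e) == pytest.approx(np.sqrt(num / den), abs=1e-10)

    def test_scaling_stimulus_and_background_invariance(self, display, visual_system):
        wl = DEFAULT_GRID.wavelengths
        stim = Spectrum(wl, 1.0 + np.exp(-0.5 * ((wl - 450.0) / 30.0) ** 2))
        a1 = quantum_catch(stim, display.background, visual_system)
        stim2 = stim.with_values(stim.values * 7.0)
        bg2 = display.background.with_values(display.background.values * 7.0)
        a2 = quantum_catch(stim2, bg2, visual_system)
        ref = _catch([1.0, 1.0, 1.0, 1.0])
        assert rnl_delta_s(a1, ref, visual_system) == pytest.approx(
            rnl_delta_s(a2, ref, visual_system), rel=1e-12
        )


class TestNoiseCorrectedXyz:
    def test_reference_maps_to_origin(self, visual_system):
        v = noise_corrected_xyz(_catch([1, 1, 1, 1]), vs=visual_system)
        np.testing.assert_allclose(v.xyz, 0.0, atol=1e-12)

    def test_isometry_on_random_pairs(self, visual_system):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            a = _catch(np.exp(rng.normal(0, 0.4, 4)))
            b = _catch(np.exp(rng.normal(0, 0.4, 4)))
            va = noise_corrected_xyz(a, vs=visual_system)
            vb = noise_corrected_xyz(b, vs=visual_system)
            d_embed = np.linalg.norm(va.xyz - vb.xyz)
            assert d_embed == pytest.approx(rnl_delta_s(a, b, visual_system), abs=1e-9)

    def test_norm_equals_delta_s_from_grey(self, visual_system):
        c = _catch([1.5, 1.1, 0.9, 1.2])
        v = noise_corrected_xyz(c, vs=visual_system)
        assert v.magnitude == pytest.approx(
            rnl_delta_s(c, _catch([1, 1, 1, 1]), visual_system), abs=1e-9
        )

    def test_axis_sign_conventions(self, visual_system):
        z = noise_corrected_xyz(_catch([1.3, 1, 1, 1]), vs=visual_system).xyz
        assert z[2] > 0  # UV opponent -> +z
        x = noise_corrected_xyz(_catch([1, 1, 1, 1.3]), vs=visual_system).xyz
        assert x[0] > 0  # L opponent -> +x
        y = noise_corrected_xyz(_catch([1, 1.3, 1, 1]), vs=visual_system).xyz
        assert y[1] > 0  # M1 opponent -> +y

    def test_triangle_inequality(self, visual_system):
        rng = np.random.default_rng(6)
        for _ in range(200):
            a, b, c = (_catch(np.exp(rng.normal(0, 0.4, 4))) for _ in range(3))
            ab = rnl_delta_s(a, b, visual_system)
            bc = rnl_delta_s(b, c, visual_system)
            ac = rnl_delta_s(a, c, visual_system)
            assert ac <= ab + bc + 1e-12

    def test_requires_tetrachromat(self, visual_system):
        from anemonevision.model_selection import build_variant

        tri = build_variant(visual_system, "M2", 0.11, 0.14)
        with pytest.raises(VisualModelError):
            noise_corrected_xyz(QuantumCatchVector(np.ones(3), tri.labels), vs=tri)


class TestVisualSystemIO:
    def test_yaml_round_trip(self, visual_system, tmp_path):
        from anemonevision.rnl import load_visual_system
        from anemonevision.spectra import write_spectrum

        files = []
        for lab, rec in zip(visual_system.labels, visual_system.receptors):
            name = f"receptor_{lab}.csv"
            write_spectrum(rec, tmp_path / name)
            files.append(name)
        visual_system.to_yaml(tmp_path / "vs.yaml", files)
        loaded = load_visual_system(tmp_path / "vs.yaml")
        assert loaded.labels == visual_system.labels
        assert loaded.sigma == visual_system.sigma
        np.testing.assert_allclose(loaded.noise, visual_system.noise)
        for a, b in zip(loaded.receptors, visual_system.receptors):
            np.testing.assert_allclose(a.values, b.values, atol=1e-9)


class TestHueAngles:
    @pytest.mark.parametrize(
        "xyz,theta,phi",
        [
            ((0, 0, 1), 90.0, None),
            ((1, 1, 0), 0.0, 45.0),
            ((1, 0, 1), 45.0, 0.0),
            ((1, -1, 0), 0.0, 315.0),
            ((0, 0, -1), -90.0, None),
        ],
    )
    def test_axis_aligned_vectors(self, xyz, theta, phi):
        th, ph = hue_angles_from_xyz(np.array(xyz, dtype=float))
        assert th == pytest.approx(theta, abs=1e-9)
        if phi is None:
            assert np.isnan(ph)
        else:
            assert ph == pytest.approx(phi, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(VisualModelError):
            hue_angles_from_xyz(np.zeros(3))

    @given(
        hst.floats(-89.0, 89.0),
        hst.floats(0.0, 359.0),
        hst.floats(0.1, 5.0),
    )
    def test_round_trip_from_spherical(self, theta, phi, r):
        from anemonevision.synth import direction_from_angles

        th, ph = hue_angles_from_xyz(r * direction_from_angles(theta, phi))
        assert th == pytest.approx(theta, abs=1e-6)
        assert min(abs(ph - phi), 360 - abs(ph - phi)) < 1e-6


class TestComplementaryPairs:
    def test_exact_polarity(self):
        assert complementary_pairs([("A", 0.0), ("B", 180.0)], 15.0)[0][:2] == ("A", "B")

    def test_orthogonal_not_paired(self):
        assert complementary_pairs([("A", 0.0), ("B", 90.0)], 15.0) == []

    def test_reported_set_azimuths_give_two_pairs(self):
        # azimuths and elevations of the four sets involved; same-side sets
        # (UV & violet-green are both UV-positive) must not pair up
        sets = [
            ("green", 297.0, -78.0),
            ("UV", 127.0, 81.0),
            ("purple", 128.0, -58.0),
            ("violet-green", 298.0, 53.0),
        ]
        pairs = complementary_pairs(sets, 15.0)
        found = {frozenset(p[:2]) for p in pairs}
        assert found == {
            frozenset({"green", "UV"}),
            frozenset({"purple", "violet-green"}),
        }
        for _, _, dev in pairs:
            assert dev == pytest.approx(10.0)

    def test_tolerance_bounds(self):
        with pytest.raises(VisualModelError):
            complementary_pairs([("A", 0.0)], 95.0)


class TestNonSpectral:
    @pytest.mark.parametrize(
        "q,expected",
        [
            ((2, 1, 1, 2), True),
            ((1, 2, 2, 1), False),
            ((1, 1, 1, 1), False),
            ((1.0, 0.8, 1.5, 1.2), True),
        ],
    )
    def test_classification(self, q, expected):
        assert classify_non_spectral(_catch(q)) is expected

    def test_needs_three_receptors(self):
        with pytest.raises(VisualModelError):
            classify_non_spectral(_catch([1.0, 2.0]))
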