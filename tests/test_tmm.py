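"""Optics engine checks against closed forms and the independent oracle."""

import math

import numpy as np
import pytest

from omlit.materials import MaterialLibrary
from omlit.tmm import (
    DegenerateGeometryError,
    Illumination,
    IlluminationError,
    Layer,
    LayerStack,
    UnsupportedInputError,
    admittance,
    characteristic_matrix,
    incoherent_combine,
    reflectance_recursive,
    refraction_angle,
    spectral_angular_average,
    stack_reflectance,
)

from conftest import flat_material


def random_coherent_stack(rng, materials=("glass", "arc", "metal", "absorber", "highindex")):
    n_layers = int(rng.integers(1, 7))
    layers = tuple(
        Layer(str(rng.choice(materials)), float(rng.uniform(0.0, 400.0)))
        for _ in range(n_layers)
    )
    substrate = str(rng.choice(materials))
    illum = Illumination(
        wavelength_nm=float(rng.uniform(390.0, 630.0)),
        angle_deg=float(rng.uniform(0.0, 80.0)),
        polarization="unpolarized",
    )
    return LayerStack("air", layers, substrate), illum


# -- elementary operations ---------------------------------------------------

def test_refraction_angle_normal_incidence_and_index_match():
    assert refraction_angle(1.0, 0.0, 2.0 + 0.5j) == pytest.approx(0.0)
    assert math.degrees(refraction_angle(1.0, 30.0, 1.0).real) == pytest.approx(30.0)


def test_refraction_angle_snell_closed_form():
    theta = refraction_angle(1.0, 30.0, 1.5)
    assert complex(1.5 * np.sin(theta)).real == pytest.approx(0.5, abs=1e-12)
    assert math.degrees(theta.real) == pytest.approx(19.4712, abs=1e-3)


def test_refraction_angle_decaying_branch_in_absorber():
    theta = refraction_angle(1.0, 45.0, 2.0 + 3.0j)
    n_cos = (2.0 + 3.0j) * np.cos(theta)
    assert n_cos.imag >= 0  # wave decays into the absorbing layer


@pytest.mark.parametrize(
    "n, theta_deg, pol, expected",
    [(1.5, 0.0, "s", 1.5), (1.5, 0.0, "p", 1.5), (1.0, 60.0, "s", 0.5)],
)
def test_admittance_closed_forms(n, theta_deg, pol, expected):
    assert admittance(n, math.radians(theta_deg), pol) == pytest.approx(expected)


def test_admittance_degenerate_grazing():
    with pytest.raises(DegenerateGeometryError):
        admittance(1.5, math.radians(90.0), "p")


def test_characteristic_matrix_zero_thickness_is_identity():
    M = characteristic_matrix(1.5, 0.0, 500.0, 0.0, "s")
    assert np.allclose(M, np.eye(2), atol=1e-15)


def test_characteristic_matrix_quarter_wave_closed_form():
    n = 1.5
    d = 500.0 / (4 * n)  # delta = pi/2
    M = characteristic_matrix(n, d, 500.0, 0.0, "s")
    expected = np.array([[0.0, 1j / n], [1j * n, 0.0]])
    assert np.allclose(M, expected, atol=1e-12)


def test_characteristic_matrix_group_property_and_determinant():
    n, lam = 1.8 + 0.2j, 470.0
    theta = refraction_angle(1.0, 25.0, n)
    full = characteristic_matrix(n, 200.0, lam, theta, "p")
    half = characteristic_matrix(n, 100.0, lam, theta, "p")
    assert np.allclose(half @ half, full, atol=1e-12)
    assert np.linalg.det(full) == pytest.approx(1.0, abs=1e-12)


# -- stack reflectance -------------------------------------------------------

def test_bare_interface_fresnel(synthetic_lib):
    st = LayerStack("air", (), "glass")
    res = stack_reflectance(st, Illumination(470.0), synthetic_lib)
    assert res.R == pytest.approx(0.04, abs=1e-12)
    assert res.T == pytest.approx(0.96, abs=1e-12)
    assert res.A == pytest.approx(0.0, abs=1e-12)


def test_quarter_wave_antireflection(synthetic_lib):
    lam = 470.0
    d = lam / (4 * 1.5**0.5)
    st = LayerStack("air", (Layer("arc", d),), "glass")
    assert stack_reflectance(st, Illumination(lam), synthetic_lib).R <= 1e-10


def test_s_equals_p_at_normal_incidence(synthetic_lib):
    st = LayerStack("air", (Layer("metal", 80.0), Layer("glass", 120.0)), "absorber")
    res = stack_reflectance(st, Illumination(500.0), synthetic_lib)
    assert abs(res.R_s - res.R_p) <= 1e-10


def test_zero_thickness_layer_insertion_is_noop(synthetic_lib):
    illum = Illumination(520.0, angle_deg=30.0)
    base = LayerStack("air", (Layer("glass", 150.0), Layer("metal", 60.0)), "glass")
    R0 = stack_reflectance(base, illum, synthetic_lib).R
    for pos in range(3):
        for coherence in ("coherent", "incoherent"):
            layers = list(base.layers)
            layers.insert(pos, Layer("absorber", 0.0, coherence))
            R = stack_reflectance(LayerStack("air", tuple(layers), "glass"), illum, synthetic_lib).R
            assert abs(R - R0) <= 1e-12


def test_layer_subdivision_invariance(synthetic_lib):
    illum = Illumination(470.0, angle_deg=40.0)
    whole = LayerStack("air", (Layer("absorber", 240.0),), "glass")
    split = LayerStack("air", (Layer("absorber", 120.0), Layer("absorber", 120.0)), "glass")
    Rw = stack_reflectance(whole, illum, synthetic_lib).R
    Rs = stack_reflectance(split, illum, synthetic_lib).R
    assert abs(Rw - Rs) <= 1e-12


def test_energy_conservation_on_random_stacks(synthetic_lib):
    rng = np.random.default_rng(1234)
    for _ in range(100):
        stack, illum = random_coherent_stack(rng)
        res = stack_reflectance(stack, illum, synthetic_lib)
        for value in (res.R, res.T, res.A, res.R_s, res.R_p, res.T_s, res.T_p):
            assert -1e-12 <= value <= 1 + 1e-12
        assert res.R + res.T + res.A == pytest.approx(1.0, abs=1e-9)


def test_absorptance_zero_for_lossless_stacks(synthetic_lib):
    rng = np.random.default_rng(99)
    for _ in range(100):
        stack, illum = random_coherent_stack(rng, materials=("glass", "arc", "highindex"))
        res = stack_reflectance(stack, illum, synthetic_lib)
        assert abs(res.A) <= 1e-9


def test_matrix_engine_matches_recursive_oracle(synthetic_lib):
    rng = np.random.default_rng(20240917)
    worst = 0.0
    for _ in range(100):
        stack, illum = random_coherent_stack(rng)
        R_matrix = stack_reflectance(stack, illum, synthetic_lib).R
        R_recursive = reflectance_recursive(stack, illum, synthetic_lib)
        worst = max(worst, abs(R_matrix - R_recursive))
    assert worst <= 1e-9


def test_recursive_oracle_matches_airy_closed_form(synthetic_lib):
    # single lossless film: two-beam Airy summation
    lam, d, n1, n2 = 550.0, 180.0, 1.5, 2.3
    r01 = (1 - n1) / (1 + n1)
    r12 = (n1 - n2) / (n1 + n2)
    beta = 2 * np.pi * n1 * d / lam
    r = (r01 + r12 * np.exp(2j * beta)) / (1 + r01 * r12 * np.exp(2j * beta))
    st = LayerStack("air", (Layer("glass", d),), "highindex")
    for func in (reflectance_recursive, lambda s, i, l: stack_reflectance(s, i, l).R):
        assert func(st, Illumination(lam), synthetic_lib) == pytest.approx(abs(r) ** 2, abs=1e-10)


def test_recursive_oracle_rejects_incoherent_layers(synthetic_lib):
    st = LayerStack("air", (Layer("glass", 50000.0, "incoherent"),), "glass")
    with pytest.raises(UnsupportedInputError):
        reflectance_recursive(st, Illumination(470.0), synthetic_lib)


# -- incoherent handling -----------------------------------------------------

def test_incoherent_combine_noop_without_incoherent_layer(synthetic_lib):
    st = LayerStack("air", (Layer("glass", 140.0), Layer("metal", 40.0)), "glass")
    illum = Illumination(470.0, angle_deg=15.0)
    a = stack_reflectance(st, illum, synthetic_lib)
    b = incoherent_combine(st, illum, synthetic_lib)
    assert a.R == pytest.approx(b.R, abs=1e-15)


def test_incoherent_slab_between_matched_media(synthetic_lib):
    st = LayerStack("glass", (Layer("glass", 60000.0, "incoherent"),), "glass")
    assert stack_reflectance(st, Illumination(470.0), synthetic_lib).R == pytest.approx(0.0, abs=1e-12)


def test_incoherent_slab_matches_summation_closed_form(synthetic_lib):
    # lossless slab in air: R = (R1 + R2 - 2 R1 R2) / (1 - R1 R2)
    st = LayerStack("air", (Layer("glass", 50000.0, "incoherent"),), "air")
    R1 = R2 = 0.04
    expected = (R1 + R2 - 2 * R1 * R2) / (1 - R1 * R2)
    got = stack_reflectance(st, Illumination(470.0), synthetic_lib).R
    assert got == pytest.approx(expected, abs=1e-6)


def test_incoherent_tape_over_absorber_conserves_energy(synthetic_lib):
    st = LayerStack(
        "air",
        (Layer("glass", 120.0), Layer("highindex", 50000.0, "incoherent"), Layer("metal", 500.0)),
        "glass",
    )
    res = stack_reflectance(st, Illumination(555.0, angle_deg=10.0), synthetic_lib)
    assert 0 <= res.R <= 1 and 0 <= res.T <= 1
    assert res.R + res.T + res.A == pytest.approx(1.0, abs=1e-9)
    assert res.T == pytest.approx(0.0, abs=1e-12)  # 500 nm of metal is opaque


# -- band / aperture averaging ----------------------------------------------

def test_degenerate_averaging_equals_single_point(synthetic_lib):
    st = LayerStack("air", (Layer("glass", 140.0),), "highindex")
    illum = Illumination(470.0)
    a = stack_reflectance(st, illum, synthetic_lib).R
    b = spectral_angular_average(st, illum, synthetic_lib).R
    assert a == pytest.approx(b, abs=1e-15)


def test_band_average_of_constant_reflectance_is_unchanged(synthetic_lib):
    st = LayerStack("air", (), "glass")  # dispersionless bare interface
    base = stack_reflectance(st, Illumination(470.0), synthetic_lib).R
    banded = stack_reflectance(
        st, Illumination(470.0, spectral_fwhm_nm=30.0), synthetic_lib
    ).R
    assert banded == pytest.approx(base, abs=1e-12)


def test_small_aperture_average_close_to_normal_incidence(synthetic_lib):
    st = LayerStack("air", (), "glass")
    base = stack_reflectance(st, Illumination(470.0), synthetic_lib).R
    cone = stack_reflectance(
        st, Illumination(470.0, numerical_aperture=0.06), synthetic_lib
    ).R
    assert abs(cone - base) / base < 0.01  # 2x objective barely perturbs R


def test_invalid_numerical_aperture_rejected():
    with pytest.raises(IlluminationError):
        Illumination(470.0, numerical_aperture=1.0)


def test_lossy_incident_medium_rejected(synthetic_lib):
    st = LayerStack("metal", (), "glass")
    with pytest.raises(IlluminationError):
        stack_reflectance(st, Illumination(470.0), synthetic_lib)


# -- interference periodicity ------------------------------------------------

def test_film_reflectance_period_is_half_wavelength_over_index(synthetic_lib):
    from omlit.contrast_model import estimate_period

    lam, n = 470.0, 1.5
    thicknesses = np.arange(10.0, 900.0, 2.0)
    lib = MaterialLibrary(
        [flat_material("air", 1.0), flat_material("film", n), flat_material("mirror", 2.0, 3.5)]
    )
    R = np.array(
        [
            stack_reflectance(
                LayerStack("air", (Layer("film", float(d)),), "mirror"), Illumination(lam), lib
            ).R
            for d in thicknesses
        ]
    )
    est = estimate_period(thicknesses, R)
    assert est.period_nm == pytest.approx(lam / (2 * n), abs=2.0)  # one grid step
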