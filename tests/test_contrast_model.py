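"""Stack building, contrast, sweeps and the optimum report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omlit.materials import MaterialLibrary, OpticalConstants
from omlit.tmm import Illumination
from omlit.contrast_model import (
    Coating,
    DegenerateContrastError,
    InsufficientDataError,
    OmlitConfig,
    contrast,
    contrast_from_reflectances,
    estimate_period,
    format_report_text,
    optimum_report,
    sweep,
)

from conftest import flat_material


@pytest.fixture(scope="module")
def section_lib() -> MaterialLibrary:
    """Dispersionless stack library where cell and surround differ only in k."""
    return MaterialLibrary(
        [
            flat_material("air", 1.0),
            flat_material("cell", 1.5, 0.05),
            flat_material("surround", 1.5, 0.0),
            flat_material("polycarbonate_tape", 1.58, 0.0),
            flat_material("carbon_tape", 2.0, 0.8),
            flat_material("silicon", 4.2, 0.05),
            flat_material("silver", 0.05, 3.0),
        ]
    )


def synth_config(**kw) -> OmlitConfig:
    kw.setdefault("cell_material", "cell")
    kw.setdefault("surround_material", "surround")
    return OmlitConfig(**kw)


# -- stack construction ------------------------------------------------------

def test_build_stacks_structure_without_coating():
    from omlit.contrast_model import build_stacks

    cell, surround = build_stacks(synth_config())
    assert len(cell.layers) == 3 and len(surround.layers) == 3
    assert [l.material for l in cell.layers] == ["cell", "polycarbonate_tape", "carbon_tape"]
    assert cell.incident_medium == "air" and cell.substrate == "silicon"


def test_build_stacks_with_silver_coating():
    from omlit.contrast_model import build_stacks

    cell, surround = build_stacks(synth_config(coating=Coating("silver", 70.0)))
    assert len(cell.layers) == 4
    assert cell.layers[1].material == "silver"
    assert cell.layers[1].thickness_nm == 70.0
    # identical except the section layer material
    assert cell.layers[1:] == surround.layers[1:]
    assert cell.layers[0].material == "cell" and surround.layers[0].material == "surround"


def test_identical_materials_give_identical_stacks_and_unit_contrast(section_lib):
    cfg = synth_config(cell_material="cell", surround_material="cell")
    from omlit.contrast_model import build_stacks

    cell, surround = build_stacks(cfg)
    assert cell == surround
    assert contrast(cfg, Illumination(470.0), section_lib).contrast == pytest.approx(1.0)


# -- contrast definition -----------------------------------------------------

def test_contrast_is_ratio_of_brighter_to_darker():
    assert contrast_from_reflectances(0.20, 0.05) == pytest.approx(4.0)
    assert contrast_from_reflectances(0.05, 0.20) == pytest.approx(4.0)
    assert contrast_from_reflectances(0.20, 0.05, "michelson") == pytest.approx(0.6)
    with pytest.raises(DegenerateContrastError):
        contrast_from_reflectances(0.2, 0.0)


def test_contrast_symmetric_under_role_swap(section_lib):
    cfg = synth_config(section_thickness_nm=80.0, coating=Coating("silver", 40.0))
    swapped = synth_config(
        section_thickness_nm=80.0, coating=Coating("silver", 40.0),
        cell_material="surround", surround_material="cell",
    )
    illum = Illumination(470.0)
    a = contrast(cfg, illum, section_lib)
    b = contrast(swapped, illum, section_lib)
    assert a.contrast == pytest.approx(b.contrast, abs=1e-12)
    assert a.contrast >= 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(min_value=10.0, max_value=300.0),
    st.floats(min_value=400.0, max_value=620.0),
)
def test_contrast_at_least_one_over_parameter_space(section_thickness, wavelength):
    lib = MaterialLibrary(
        [
            flat_material("air", 1.0),
            flat_material("cell", 1.55, 0.1),
            flat_material("surround", 1.5, 0.02),
            flat_material("polycarbonate_tape", 1.58, 0.0),
            flat_material("carbon_tape", 2.0, 0.8),
            flat_material("silicon", 4.2, 0.05),
        ]
    )
    cfg = synth_config(section_thickness_nm=section_thickness)
    cv = contrast(cfg, Illumination(wavelength), lib)
    assert cv.contrast >= 1.0


# -- sweeps ------------------------------------------------------------------

def test_single_point_sweep_reduces_to_contrast_call(section_lib):
    cfg = synth_config(coating=Coating("silver", 0.0))
    illum = Illumination(470.0)
    res = sweep(cfg, [60.0], [70.0], [470.0], illum, section_lib)
    assert res.contrast.shape == (1, 1, 1)
    direct = contrast(
        synth_config(section_thickness_nm=60.0, coating=Coating("silver", 70.0)),
        illum, section_lib,
    )
    assert res.contrast[0, 0, 0] == pytest.approx(direct.contrast, abs=1e-12)
    assert res.argmax[3] == pytest.approx(direct.contrast, abs=1e-12)
    assert res.fraction_thickness_nm == 70.0


def test_sweep_argmax_equals_grid_maximum(section_lib):
    cfg = synth_config(coating=Coating("silver", 0.0))
    res = sweep(
        cfg, np.arange(30.0, 100.0, 10.0), np.arange(10.0, 80.0, 10.0),
        [470.0, 555.0], Illumination(470.0), section_lib,
    )
    assert res.argmax[3] == res.contrast.max()
    wl, sec, coat, _ = res.argmax
    wi = list(res.wavelengths_nm).index(wl)
    si = list(res.section_nm).index(sec)
    ci = list(res.coating_nm).index(coat)
    assert res.contrast[wi, si, ci] == res.contrast.max()
    assert res.fraction_thickness_nm <= coat


def test_coating_free_sweep_collapses_coating_axis(section_lib):
    res = sweep(synth_config(), [40.0, 60.0], [10.0, 20.0], [470.0],
                Illumination(470.0), section_lib)
    assert res.coating_nm.tolist() == [0.0]
    assert res.contrast.shape == (1, 2, 1)


def test_period_ratio_across_wavelengths_matches_wavelength_ratio(section_lib):
    # lossless-surround section over an opaque substrate: no tape/carbon layers
    cfg = synth_config(
        tape_thickness_nm=0.0, carbon_tape_thickness_nm=0.0, substrate="silver"
    )
    step = 5.0
    grid = np.arange(10.0, 900.0, step)
    periods = {}
    for wl in (390.0, 630.0):
        res = sweep(cfg, grid, [0.0], [wl], Illumination(wl), section_lib)
        trace = res.contrast[0, :, 0]
        periods[wl] = estimate_period(grid, trace).period_nm
        assert periods[wl] == pytest.approx(wl / (2 * 1.5), abs=step)
    assert periods[630.0] / periods[390.0] == pytest.approx(630.0 / 390.0, rel=0.10)


# -- period estimation -------------------------------------------------------

def test_estimate_period_pure_cosine():
    t = np.arange(0.0, 500.0, 1.0)
    est = estimate_period(t, np.cos(2 * np.pi * t / 100.0))
    assert est.period_nm == pytest.approx(100.0, abs=1.0)


def test_estimate_period_noisy_cosine():
    rng = np.random.default_rng(5)
    t = np.arange(0.0, 500.0, 1.0)
    y = np.cos(2 * np.pi * t / 100.0) + rng.normal(0, 0.01, t.size)
    assert estimate_period(t, y).period_nm == pytest.approx(100.0, abs=2.0)


def test_estimate_period_rejects_constant_and_single_peak():
    t = np.arange(0.0, 100.0, 1.0)
    with pytest.raises(InsufficientDataError):
        estimate_period(t, np.ones_like(t))
    with pytest.raises(InsufficientDataError):
        estimate_period(t, np.exp(-((t - 50) ** 2) / 50.0))


# -- optimum report ----------------------------------------------------------

def saturating_sweep_result():
    """Sweep whose contrast rises monotonically with coating thickness and
    saturates, capped by the grid end (the "400 (80) *" pattern)."""
    from omlit.contrast_model import SweepResult

    coating = np.arange(10.0, 401.0, 10.0)
    curve = 1.0 + 10.0 * np.tanh(coating / 60.0)  # saturates near 11
    contrast_grid = curve[None, None, :]
    return SweepResult(
        coating_material="silver",
        wavelengths_nm=np.array([470.0]),
        section_nm=np.array([60.0]),
        coating_nm=coating,
        contrast=contrast_grid,
        R_cell=0.1 * np.ones_like(contrast_grid),
        R_surround=0.1 * curve[None, None, :],
    )


def test_report_saturating_coating_marks_95pct_thickness():
    res = saturating_sweep_result()
    # monotone saturating curve: optimum sits at the grid boundary...
    assert res.argmax[2] == res.coating_nm[-1]
    rep = optimum_report({"silver": res})
    row = rep.iloc[0]
    assert row.coating_thickness_nm == res.coating_nm[-1]
    # ...and the 95%-of-optimum thickness is strictly smaller
    assert row.fraction_thickness_nm < row.coating_thickness_nm
    expected = res.coating_nm[
        np.nonzero(res.contrast[0, 0, :] >= 0.95 * res.contrast.max())[0][0]
    ]
    assert row.fraction_thickness_nm == expected
    text = format_report_text(rep)
    assert "(" in text and "*" in text  # parenthetical convention present


def test_report_rows_sorted_by_material_then_wavelength(section_lib):
    sweeps = {}
    for m in ("silver", "carbon_tape"):
        cfg = synth_config(coating=Coating(m, 0.0))
        sweeps[m] = sweep(cfg, [60.0, 80.0], [20.0, 40.0], [555.0, 470.0],
                          Illumination(470.0), section_lib)
    rep = optimum_report(sweeps)
    assert rep.coating_material.tolist() == ["carbon_tape", "carbon_tape", "silver", "silver"]
    assert rep.wavelength_nm.tolist() == [470.0, 555.0, 470.0, 555.0]
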