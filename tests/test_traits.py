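import numpy as np
import pandas as pd
import pytest

from twigwood import (
    TissueLabel,
    composite_fractions,
    ellipse_area,
    leaf_area_sapwood_ratio,
    modulus_of_elasticity,
    nfold_variation,
    species_means,
    specific_leaf_area,
    wall_material_density,
    wood_density,
)


# --- wood density ---------------------------------------------------------


@pytest.mark.parametrize(
    "dry, displaced, expected",
    [(0.53, 1.00, 0.53), (1.0, 1.0, 1.0), (0.38, 1.00, 0.38)],
)
def test_wood_density_is_mass_over_displaced_volume(dry, displaced, expected):
    assert wood_density(dry, displaced) == pytest.approx(expected)


def test_wood_density_rejects_nonpositive():
    with pytest.raises(ValueError):
        wood_density(0.0, 1.0)


# --- geometry -------------------------------------------------------------


def test_ellipse_area_circle_and_symmetry():
    assert ellipse_area(2, 2) == pytest.approx(np.pi)
    assert ellipse_area(2, 4) == pytest.approx(2 * np.pi)
    assert ellipse_area(3, 7) == ellipse_area(7, 3)
    with pytest.raises(ValueError):
        ellipse_area(0, 2)


# --- composites -----------------------------------------------------------


def test_composite_fractions_sum_components():
    fr = {
        TissueLabel.AXIAL_PARENCHYMA: 0.14,
        TissueLabel.RAY_PARENCHYMA: 0.21,
        TissueLabel.FIBRE_LUMEN: 0.13,
        TissueLabel.FIBRE_WALL: 0.32,
        TissueLabel.VESSEL_LUMEN: 0.13,
        TissueLabel.VESSEL_WALL: 0.04,
    }
    comp = composite_fractions(fr)
    assert comp["TPF"] == pytest.approx(0.35)
    assert comp["TFF"] == pytest.approx(0.45)
    assert comp["TVF"] == pytest.approx(0.17)
    assert comp["WF"] == pytest.approx(0.36)


def test_composites_of_empty_fractions_are_zero():
    assert all(v == 0.0 for v in composite_fractions({}).values())


# --- leaf traits ----------------------------------------------------------


def test_sla_orientation_and_lma_roundtrip():
    sla = specific_leaf_area(100.0, 1.0)
    assert sla == pytest.approx(100.0)
    assert specific_leaf_area(200.0, 1.0) == pytest.approx(2 * sla)
    assert (1.0 / sla) * sla == pytest.approx(1.0)


def test_leaf_area_sapwood_ratio_worked_example():
    lasa = leaf_area_sapwood_ratio(
        sla_cm2_per_g=100.0,
        sla_subset_area_cm2=200.0,
        remaining_leaf_mass_g=3.0,
        wood_diameters_mm=(5.0, 5.0),
    )
    # total leaf area 500 cm2 over an ellipse of 0.19635 cm2
    assert lasa == pytest.approx(500.0 / 0.19635, rel=1e-4)


def test_leaf_area_sapwood_ratio_zero_remaining_and_linearity():
    base = leaf_area_sapwood_ratio(100.0, 200.0, 0.0, (5.0, 5.0))
    assert base == pytest.approx(200.0 / 0.19635, rel=1e-4)
    doubled = leaf_area_sapwood_ratio(100.0, 400.0, 0.0, (5.0, 5.0))
    assert doubled == pytest.approx(2 * base)


# --- mechanics ------------------------------------------------------------


def test_moe_circular_section_closed_form():
    # I = pi 5^4 / 64 = 30.68 mm^4; slope 10 N/mm over a 100 mm span
    moe = modulus_of_elasticity(10.0, 100.0, (5.0, 5.0))
    assert moe == pytest.approx(10.0 * 100.0**3 / (48 * np.pi * 5**4 / 64), rel=1e-12)
    assert moe == pytest.approx(6790, rel=1e-3)


def test_moe_linear_in_slope():
    a = modulus_of_elasticity(10.0, 120.0, (5.0, 5.0))
    b = modulus_of_elasticity(20.0, 120.0, (5.0, 5.0))
    assert b == pytest.approx(2 * a)


def test_moe_realistic_inputs_fall_in_observed_envelope():
    # twig-like specimens: 4-8 mm diameter, span 20-30x diameter
    cases = [(2.0, 120.0, (5.0, 5.5)), (14.0, 160.0, (7.0, 7.0)),
             (1.2, 90.0, (4.2, 4.0))]
    for slope, span, d in cases:
        assert 1000 < modulus_of_elasticity(slope, span, d) < 13000


def test_moe_span_rule_warns_or_raises():
    with pytest.warns(UserWarning, match="20 times"):
        modulus_of_elasticity(10.0, 50.0, (5.0, 5.0))
    with pytest.raises(ValueError, match="20 times"):
        modulus_of_elasticity(10.0, 50.0, (5.0, 5.0), strict=True)


# --- wall material density ------------------------------------------------


def test_wall_material_density_ratio_and_monotonicity():
    assert wall_material_density(0.53, 0.36) == pytest.approx(1.472, abs=1e-3)
    assert wall_material_density(0.5, 1.0) == pytest.approx(0.5)
    assert wall_material_density(0.5, 0.3) > wall_material_density(0.5, 0.4)
    with pytest.raises(ValueError):
        wall_material_density(0.5, 0.0)


# --- aggregation ----------------------------------------------------------


def test_species_means_are_arithmetic():
    df = pd.DataFrame({
        "species": ["a"] * 3 + ["b"],
        "site": ["s1"] * 3 + ["s1"],
        "replicate": [1, 2, 3, 1],
        "WD": [0.1, 0.2, 0.3, 0.5],
    })
    out = species_means(df)
    assert out.loc[out.species == "a", "WD"].item() == pytest.approx(0.2)
    # single replicate species keeps its value
    assert out.loc[out.species == "b", "WD"].item() == pytest.approx(0.5)


def test_species_at_two_sites_kept_separate():
    df = pd.DataFrame({
        "species": ["dup", "dup"],
        "site": ["s1", "s2"],
        "replicate": [1, 1],
        "WD": [0.4, 0.6],
    })
    assert len(species_means(df)) == 2


def test_species_means_warn_on_all_missing_trait():
    df = pd.DataFrame({
        "species": ["a", "a"],
        "site": ["s1", "s1"],
        "replicate": [1, 2],
        "WD": [np.nan, np.nan],
    })
    with pytest.warns(UserWarning, match="a"):
        out = species_means(df)
    assert np.isnan(out["WD"]).all()


def test_derive_specimen_traits_from_measurement_table():
    from twigwood import derive_specimen_traits

    df = pd.DataFrame([{
        "species": "a", "replicate": 1,
        "dry_mass_g": 0.53, "displaced_water_mass_g": 1.0,
        "pith_d1_mm": 2.0, "pith_d2_mm": 4.0,
        "wood_d1_mm": 5.0, "wood_d2_mm": 5.0,
        "sla_leaf_area_cm2": 200.0, "sla_leaf_mass_g": 2.0,
        "remaining_leaf_mass_g": 3.0,
        "bending_slope_N_per_mm": 10.0, "span_mm": 120.0,
        "specimen_d1_mm": 5.0, "specimen_d2_mm": 5.0,
        "height_m": 8.0, "max_height_m": 20.0,
    }])
    out = derive_specimen_traits(df)
    assert out.loc[0, "WD"] == pytest.approx(0.53)
    assert out.loc[0, "PA"] == pytest.approx(2 * np.pi)
    assert out.loc[0, "SLA"] == pytest.approx(100.0)
    assert out.loc[0, "LASA"] == pytest.approx(500.0 / 0.19635, rel=1e-4)
    assert out.loc[0, "MOE"] == pytest.approx(
        10.0 * 120.0**3 / (48 * np.pi * 5**4 / 64)
    )
    assert out.loc[0, "species"] == "a"
    with pytest.raises(ValueError, match="lacks columns"):
        derive_specimen_traits(df.drop(columns=["span_mm"]))


# --- n-fold variation -----------------------------------------------------


def test_nfold_zero_exclusion_rule():
    assert nfold_variation([0.0, 0.01, 0.64]) == pytest.approx(64.0)


def test_nfold_constant_vector_is_one():
    assert nfold_variation([0.3, 0.3, 0.3]) == pytest.approx(1.0)


def test_nfold_of_density_selection_band():
    assert round(nfold_variation([0.38, 0.5, 0.62]), 1) == 1.6


def test_nfold_all_zero_is_error():
    with pytest.raises(ValueError):
        nfold_variation([0.0, 0.0])
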