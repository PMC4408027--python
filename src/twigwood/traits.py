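"""Derived physical, composite, leaf and mechanical traits.

Units follow field convention: wood density in g cm^-3 (oven-dry mass over
water-saturated volume by Archimedes displacement), modulus of elasticity
in MPa from a three-point bending test, specific leaf area in cm^2 g^-1,
leaf area to sapwood area in cm^2 cm^-2, pith and sapwood areas as
ellipses from two perpendicular caliper diameters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import reference as ref
from .stereology import FractionVector
from .section import TissueLabel

__all__ = [
    "wood_density",
    "ellipse_area",
    "composite_fractions",
    "specific_leaf_area",
    "leaf_area_sapwood_ratio",
    "modulus_of_elasticity",
    "wall_material_density",
    "species_means",
    "nfold_variation",
    "trait_record_from_fractions",
]

#: Span must be at least this many times the specimen diameter for the
#: three-point bending test to be dominated by bending (not shear).
SPAN_TO_DIAMETER = 20.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive (got {value!r})")


def wood_density(dry_mass_g: float, displaced_water_mass_g: float) -> float:
    """Oven-dry mass over saturated volume, g cm^-3.

    The displaced-water mass equals the saturated volume in cm^3 at the
    standard water density of 1.0 g cm^-3.
    """
    _require_positive(dry_mass_g=dry_mass_g,
                      displaced_water_mass_g=displaced_water_mass_g)
    return dry_mass_g / displaced_water_mass_g


def ellipse_area(d1: float, d2: float) -> float:
    """Area of an ellipse from two perpendicular diameters (pi d1 d2 / 4)."""
    _require_positive(d1=d1, d2=d2)
    return np.pi * d1 * d2 / 4.0


def composite_fractions(fractions: FractionVector | dict) -> dict[str, float]:
    """Composite tissue fractions: TPF = APF+RPF, TFF = FLF+FWF,
    TVF = VLF+VWF, WF = FWF+VWF."""
    if isinstance(fractions, FractionVector):
        fr = fractions.fractions
    else:
        fr = {TissueLabel(k): v for k, v in fractions.items()}
    g = lambda lab: fr.get(lab, 0.0)
    return {
        "TPF": g(TissueLabel.AXIAL_PARENCHYMA) + g(TissueLabel.RAY_PARENCHYMA),
        "TFF": g(TissueLabel.FIBRE_LUMEN) + g(TissueLabel.FIBRE_WALL),
        "TVF": g(TissueLabel.VESSEL_LUMEN) + g(TissueLabel.VESSEL_WALL),
        "WF": g(TissueLabel.FIBRE_WALL) + g(TissueLabel.VESSEL_WALL),
    }


def trait_record_from_fractions(fractions: FractionVector | dict) -> dict[str, float]:
    """Map a fraction vector to the canonical trait abbreviations plus the
    composites (APF, RPF, TPF, FLF, FWF, TFF, VLF, VWF, TVF, CF, MCF, WF)."""
    if isinstance(fractions, FractionVector):
        fr = fractions.fractions
    else:
        fr = {TissueLabel(k): v for k, v in fractions.items()}
    g = lambda lab: fr.get(lab, 0.0)
    rec = {
        "APF": g(TissueLabel.AXIAL_PARENCHYMA),
        "RPF": g(TissueLabel.RAY_PARENCHYMA),
        "FLF": g(TissueLabel.FIBRE_LUMEN),
        "FWF": g(TissueLabel.FIBRE_WALL),
        "VLF": g(TissueLabel.VESSEL_LUMEN),
        "VWF": g(TissueLabel.VESSEL_WALL),
        "CF": g(TissueLabel.CONDUIT15),
        "MCF": g(TissueLabel.MUCILAGE_CANAL),
    }
    rec.update(composite_fractions(fractions))
    return rec


def specific_leaf_area(leaf_area_cm2: float, leaf_dry_mass_g: float) -> float:
    """SLA = leaf area / dry mass (cm^2 g^-1); LMA is its reciprocal."""
    _require_positive(leaf_area_cm2=leaf_area_cm2, leaf_dry_mass_g=leaf_dry_mass_g)
    return leaf_area_cm2 / leaf_dry_mass_g


def leaf_area_sapwood_ratio(
    sla_cm2_per_g: float,
    sla_subset_area_cm2: float,
    remaining_leaf_mass_g: float,
    wood_diameters_mm: tuple[float, float],
) -> float:
    """Total leaf area over sapwood cross-sectional area (cm^2 cm^-2).

    The total leaf area on the shoot is the directly measured SLA-subset
    area plus SLA times the dry mass of the remaining leaves.  Sapwood
    area is the ellipse of the two wood diameters measured under bark and
    excluding pith.
    """
    _require_positive(sla_cm2_per_g=sla_cm2_per_g,
                      sla_subset_area_cm2=sla_subset_area_cm2)
    if remaining_leaf_mass_g < 0:
        raise ValueError("remaining leaf mass cannot be negative")
    d1_cm, d2_cm = (d / 10.0 for d in wood_diameters_mm)
    sa_cm2 = ellipse_area(d1_cm, d2_cm)
    total_leaf_cm2 = sla_subset_area_cm2 + sla_cm2_per_g * remaining_leaf_mass_g
    return total_leaf_cm2 / sa_cm2


def modulus_of_elasticity(
    bending_slope_N_per_mm: float,
    span_mm: float,
    diameters_mm: tuple[float, float],
    strict: bool = False,
) -> float:
    """Modulus of elasticity (MPa) from a three-point bending test.

    Standard beam theory for a centrally loaded simply supported beam:
    MOE = m L^3 / (48 I) with m the load-deflection slope and, for an
    elliptical section (diameters a across, b in the loading direction),
    I = pi a b^3 / 64.  The specimen includes bark and pith, as tested.
    The span should be at least 20x the diameter so shear is negligible;
    shorter spans warn (or raise with ``strict``).
    """
    _require_positive(bending_slope_N_per_mm=bending_slope_N_per_mm, span_mm=span_mm)
    a, b = diameters_mm
    _require_positive(diameter_a_mm=a, diameter_b_mm=b)
    if span_mm < SPAN_TO_DIAMETER * max(a, b):
        msg = (
            f"span {span_mm} mm is below {SPAN_TO_DIAMETER:g}x the specimen "
            f"diameter {max(a, b)} mm; the bending test requires a span at "
            f"least 20 times longer than diameter"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    second_moment = np.pi * a * b ** 3 / 64.0  # mm^4
    return bending_slope_N_per_mm * span_mm ** 3 / (48.0 * second_moment)  # N/mm^2 = MPa


def wall_material_density(wood_density_g_cm3: float, wall_fraction: float) -> float:
    """Approximate cell wall material density (g cm^-3).

    A first-order ratio: wood density divided by the wall_F+V fraction.
    It ignores parenchyma and small-conduit walls and bound water, so it
    is an approximation, not a measured wall density; plausible values
    fall near the ~1.5 g cm^-3 cited for cell wall material.
    """
    _require_positive(wood_density_g_cm3=wood_density_g_cm3)
    if not 0 < wall_fraction <= 1:
        raise ValueError("wall fraction must be in (0, 1]")
    return wood_density_g_cm3 / wall_fraction


#: Expected columns of a specimen measurement table.
MEASUREMENT_COLUMNS = (
    "dry_mass_g", "displaced_water_mass_g",
    "pith_d1_mm", "pith_d2_mm",
    "wood_d1_mm", "wood_d2_mm",
    "sla_leaf_area_cm2", "sla_leaf_mass_g", "remaining_leaf_mass_g",
    "bending_slope_N_per_mm", "span_mm",
    "specimen_d1_mm", "specimen_d2_mm",
    "height_m", "max_height_m",
)


def derive_specimen_traits(measurements: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Per-replicate physical, leaf and mechanical traits from raw specimen
    measurements.

    Expects the columns of :data:`MEASUREMENT_COLUMNS` (plus any identifier
    columns such as species/site/replicate, which are carried through) and
    returns WD, PA (pith area, mm^2), SLA, LASA, MOE, H and MH.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {', '.join(missing)}")
    rows = []
    for _, m in measurements.iterrows():
        sla = specific_leaf_area(m["sla_leaf_area_cm2"], m["sla_leaf_mass_g"])
        rows.append({
            "WD": wood_density(m["dry_mass_g"], m["displaced_water_mass_g"]),
            "PA": ellipse_area(m["pith_d1_mm"], m["pith_d2_mm"]),
            "SLA": sla,
            "LASA": leaf_area_sapwood_ratio(
                sla, m["sla_leaf_area_cm2"], m["remaining_leaf_mass_g"],
                (m["wood_d1_mm"], m["wood_d2_mm"]),
            ),
            "MOE": modulus_of_elasticity(
                m["bending_slope_N_per_mm"], m["span_mm"],
                (m["specimen_d1_mm"], m["specimen_d2_mm"]), strict=strict,
            ),
            "H": m["height_m"],
            "MH": m["max_height_m"],
        })
    derived = pd.DataFrame(rows, index=measurements.index)
    carried = measurements.drop(columns=list(MEASUREMENT_COLUMNS))
    return pd.concat([carried, derived], axis=1)


def species_means(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic trait means per species-at-site.

    A species occurring at two sites is kept as two separate entities.
    Traits missing for all replicates of a species propagate as missing
    (with a warning naming the species).
    """
    if "species" not in table.columns:
        raise ValueError("table must have a 'species' column")
    keys = ["species"] + (["site"] if "site" in table.columns else [])
    numeric = table.select_dtypes("number").columns.difference(["replicate"])
    out = table.groupby(keys, sort=False)[list(numeric)].mean().reset_index()
    missing = out[numeric].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            "missing trait values for species: "
            + ", ".join(out.loc[missing, "species"].astype(str)),
            stacklevel=2,
        )
    cols = keys + [t for t in ref.TRAIT_ORDER if t in out.columns]
    cols += [c for c in out.columns if c not in cols]
    return out[cols]


def nfold_variation(values) -> float:
    """Max over min *positive* value: the n-fold variation of a trait.

    Zeros mark absence of the tissue and are excluded, so the ratio uses
    the lowest value different from zero.  All-zero input is an error.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("n-fold variation needs at least one positive value")
    if (v < 0).any():
        raise ValueError("trait values must be non-negative")
    return float(v.max() / pos.min())
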