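"""Default calibration of the synthetic study cohort.

The synthetic trait-table generator emulates a species-level survey of
twig wood across angiosperm trees and shrubs whose wood density falls in
a deliberately narrow band (0.38-0.62 g cm^-3), sampled at three
climatically contrasting sites (tropical rainforest, tropical woodland,
temperate forest).  The constants below fix that cohort: the 22 traits
with their units and species-level ranges and averages, which traits are
treated as normally distributed on the species level, the site sizes,
and the latent correlation structure among the trait drivers.

All fractions are of the wood cross-section excluding pith and bark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# Trait registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitInfo:
    abbrev: str
    name: str
    unit: str
    low: float          # species-level minimum (smallest nonzero where zeros occur)
    high: float         # species-level maximum
    average: float      # species-level mean (over species where present)
    normal: bool        # species means treated as normally distributed
    zero_possible: bool = False  # trait absent (exactly zero) in some species


#: The 22 traits in canonical column order.
TRAITS: tuple[TraitInfo, ...] = (
    TraitInfo("APF", "axial parenchyma fraction", "unitless", 0.01, 0.33, 0.14, False),
    TraitInfo("RPF", "ray parenchyma fraction", "unitless", 0.06, 0.41, 0.21, True),
    TraitInfo("TPF", "total parenchyma fraction (axial + ray)", "unitless", 0.12, 0.66, 0.35, True),
    TraitInfo("FLF", "fibre lumen fraction", "unitless", 0.02, 0.32, 0.13, True),
    TraitInfo("FWF", "fibre wall fraction", "unitless", 0.15, 0.52, 0.32, True),
    TraitInfo("TFF", "total fibre fraction (lumen + wall)", "unitless", 0.20, 0.74, 0.45, True),
    TraitInfo("VLF", "vessel lumen fraction", "unitless", 0.06, 0.23, 0.13, True),
    TraitInfo("VWF", "vessel wall fraction", "unitless", 0.02, 0.09, 0.04, False),
    TraitInfo("TVF", "total vessel fraction (lumen + wall)", "unitless", 0.09, 0.30, 0.18, True),
    TraitInfo("CF", "conduits below 15 um fraction", "unitless", 0.002, 0.15, 0.06, False, True),
    TraitInfo("MCF", "mucilage canal fraction", "unitless", 0.01, 0.02, 0.014, False, True),
    TraitInfo("WF", "wall fraction (fibre wall + vessel wall)", "unitless", 0.18, 0.56, 0.36, True),
    TraitInfo("A", "vessel area", "mm^2", 0.0002, 0.0036, 0.0014, False),
    TraitInfo("N", "vessel number per area", "mm^-2", 34.0, 730.7, 148.7, False),
    TraitInfo("S", "vessel area to number ratio", "mm^4", 4e-7, 1.1e-4, 2e-5, False),
    TraitInfo("Dh", "hydraulically weighted diameter", "mm", 0.02, 0.08, 0.05, False),
    TraitInfo("PA", "pith area", "mm^2", 0.13, 72.6, 5.6, False, True),
    TraitInfo("WD", "wood density", "g cm^-3", 0.38, 0.62, 0.53, False),
    TraitInfo("H", "height", "m", 0.7, 33.6, 12.2, False),
    TraitInfo("MH", "maximum height", "m", 1.0, 40.0, 18.1, False),
    TraitInfo("MOE", "modulus of elasticity", "MPa", 1555.0, 11778.0, 5200.0, False),
    TraitInfo("LASA", "leaf area / sapwood area", "cm^2 cm^-2", 838.0, 24904.0, 7884.0, False),
)

TRAIT_BY_ABBREV: dict[str, TraitInfo] = {t.abbrev: t for t in TRAITS}
TRAIT_ORDER: tuple[str, ...] = tuple(t.abbrev for t in TRAITS)

#: Traits whose species means are treated as approximately normal (the
#: Shapiro-Wilk gate then selects Pearson for pairs of these).
NORMAL_TRAITS: frozenset[str] = frozenset(t.abbrev for t in TRAITS if t.normal)

#: Base tissue fractions that must close to 1 on every wood cross-section.
BASE_FRACTIONS: tuple[str, ...] = (
    "APF", "RPF", "FLF", "FWF", "VLF", "VWF", "CF", "MCF",
)

#: Composite fraction identities (composite -> components).
COMPOSITES: dict[str, tuple[str, str]] = {
    "TPF": ("APF", "RPF"),
    "TFF": ("FLF", "FWF"),
    "TVF": ("VLF", "VWF"),
    "WF": ("FWF", "VWF"),
}

# ---------------------------------------------------------------------------
# Cohort design: sites, presence patterns
# ---------------------------------------------------------------------------

#: Species-at-sites per site (total 69).
SITE_SPECIES: dict[str, int] = {
    "rainforest": 41,
    "woodland": 11,
    "temperate": 17,
}

#: Number of species per site bearing conduits below 15 um (total 26).
CONDUIT_SPECIES_PER_SITE: dict[str, int] = {
    "rainforest": 2,
    "woodland": 10,
    "temperate": 14,
}

#: Number of species with mucilage canals, all at the rainforest site.
MUCILAGE_SPECIES: int = 3

# ---------------------------------------------------------------------------
# Latent correlation of the cohort drivers
# ---------------------------------------------------------------------------

#: Latent drivers: composite totals, minor fractions, vessel size, and the
#: ecological traits, plus the two split shares (fibre-wall share of total
#: fibre; axial share of total parenchyma).
DRIVER_NAMES: tuple[str, ...] = (
    "TPF", "TFF", "VLF", "VWF", "CF", "A",
    "PA", "WD", "H", "MH", "MOE", "LASA",
    "SHARE_FW", "SHARE_AX",
)

# Pairwise latent targets among the 12 trait drivers: the published
# species-level coefficients (the method-gated values: Pearson for pairs of
# normal traits, Spearman otherwise).  The two shares carry a handful of
# structural correlations: denser wood and stiffer twigs have wallier
# fibres; larger vessels go with a larger axial share of parenchyma.
_DRIVER_PAIRS: dict[tuple[str, str], float] = {
    ("TPF", "TFF"): -0.86, ("TPF", "VLF"): -0.11, ("TPF", "VWF"): -0.23,
    ("TPF", "CF"): -0.46, ("TPF", "A"): 0.30, ("TPF", "PA"): 0.35,
    ("TPF", "WD"): -0.16, ("TPF", "H"): 0.41, ("TPF", "MH"): 0.25,
    ("TPF", "MOE"): -0.41, ("TPF", "LASA"): 0.34,
    ("TFF", "VLF"): -0.27, ("TFF", "VWF"): -0.13, ("TFF", "CF"): 0.19,
    ("TFF", "A"): -0.16, ("TFF", "PA"): -0.19, ("TFF", "WD"): 0.14,
    ("TFF", "H"): -0.33, ("TFF", "MH"): -0.18, ("TFF", "MOE"): 0.38,
    ("TFF", "LASA"): -0.15,
    ("VLF", "VWF"): 0.48, ("VLF", "CF"): -0.03, ("VLF", "A"): 0.19,
    ("VLF", "PA"): 0.06, ("VLF", "WD"): -0.27, ("VLF", "H"): 0.31,
    ("VLF", "MH"): 0.31, ("VLF", "MOE"): -0.25, ("VLF", "LASA"): 0.24,
    ("VWF", "CF"): 0.22, ("VWF", "A"): -0.42, ("VWF", "PA"): -0.18,
    ("VWF", "WD"): 0.10, ("VWF", "H"): -0.06, ("VWF", "MH"): -0.15,
    ("VWF", "MOE"): 0.10, ("VWF", "LASA"): -0.22,
    ("CF", "A"): -0.49, ("CF", "PA"): -0.54, ("CF", "WD"): 0.40,
    ("CF", "H"): -0.66, ("CF", "MH"): -0.52, ("CF", "MOE"): 0.16,
    ("CF", "LASA"): -0.67,
    ("A", "PA"): 0.45, ("A", "WD"): -0.47, ("A", "H"): 0.64,
    ("A", "MH"): 0.65, ("A", "MOE"): -0.44, ("A", "LASA"): 0.58,
    ("PA", "WD"): -0.52, ("PA", "H"): 0.48, ("PA", "MH"): 0.23,
    ("PA", "MOE"): -0.17, ("PA", "LASA"): 0.66,
    ("WD", "H"): -0.36, ("WD", "MH"): -0.31, ("WD", "MOE"): 0.27,
    ("WD", "LASA"): -0.39,
    ("H", "MH"): 0.83, ("H", "MOE"): -0.47, ("H", "LASA"): 0.58,
    ("MH", "MOE"): -0.40, ("MH", "LASA"): 0.46,
    ("MOE", "LASA"): -0.22,
    ("SHARE_FW", "WD"): 0.55, ("SHARE_FW", "MOE"): 0.30,
    ("SHARE_AX", "A"): 0.30,
}


def default_latent_correlation() -> np.ndarray:
    """Latent driver correlation matrix, projected to the nearest valid
    correlation matrix (the empirical pairwise targets are mildly
    indefinite when assembled jointly)."""
    from .copula import nearest_correlation

    d = len(DRIVER_NAMES)
    idx = {name: i for i, name in enumerate(DRIVER_NAMES)}
    mat = np.eye(d)
    for (a, b), r in _DRIVER_PAIRS.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    return nearest_correlation(mat)
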