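"""Vessel morphometrics: per-vessel records and the A, N, S, D_H statistics.

Vessel lumens are taken as 4-connected components of the vessel-lumen
label.  "Diameter" means the circle-equivalent diameter computed from the
lumen area (exact for the synthetic disc geometry); the small-conduit
cutoff uses the maximum Feret diameter with a strict "below 15 um" rule.

The derived statistics follow the standard identities:

* ``A``   — arithmetic mean vessel lumen area (mm^2),
* ``N``   — vessels per area = vessel lumen fraction / A (mm^-2),
* ``S``   — vessel area to number ratio = A / N = A^2 / VLF (mm^4),
* ``D_H`` — hydraulically weighted diameter = sum(d^5) / sum(d^4) (mm),

so N*A = VLF and S*N = A hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .section import LabeledSection, TissueLabel

__all__ = [
    "VesselRecord",
    "VesselStats",
    "extract_vessels",
    "partition_conduits15",
    "hydraulic_diameter",
    "vessel_stats",
]


@dataclass(frozen=True)
class VesselRecord:
    """One vessel lumen component, in physical units."""

    lumen_area_mm2: float
    equivalent_diameter_mm: float
    max_feret_diameter_mm: float
    centroid_px: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        if self.lumen_area_mm2 <= 0:
            raise ValueError("lumen area must be positive")


@dataclass(frozen=True)
class VesselStats:
    A: float      # mean lumen area, mm^2
    N: float      # vessels per area, mm^-2
    S: float      # area-to-number ratio, mm^4
    D_H: float    # hydraulically weighted diameter, mm
    VLF: float    # vessel lumen fraction used for N
    n_vessels: int


def extract_vessels(section: LabeledSection) -> list[VesselRecord]:
    """One record per 4-connected vessel-lumen component whose centroid
    lies inside the sector.  Returns an empty list when there are no
    vessel pixels."""
    mask = section.label_map == TissueLabel.VESSEL_LUMEN
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=1)
    mm = section.scale_mm_per_px
    records: list[VesselRecord] = []
    for prop in measure.regionprops(labeled):
        r, c = prop.centroid
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), section.shape[0] - 1)
        ci = min(max(ci, 0), section.shape[1] - 1)
        if not section.sector_mask[ri, ci]:
            continue
        area = prop.area * mm * mm
        records.append(
            VesselRecord(
                lumen_area_mm2=float(area),
                equivalent_diameter_mm=float(2.0 * np.sqrt(area / np.pi)),
                max_feret_diameter_mm=float(prop.feret_diameter_max * mm),
                centroid_px=(float(r), float(c)),
            )
        )
    return records


def partition_conduits15(
    records: list[VesselRecord], threshold_um: float = 15.0
) -> tuple[list[VesselRecord], list[VesselRecord]]:
    """Split records into (vessels, conduits): strict maximum-Feret-below-
    threshold components are conduits; the rest are vessels."""
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    thr_mm = threshold_um * 1e-3
    conduits = [r for r in records if r.max_feret_diameter_mm < thr_mm]
    vessels = [r for r in records if r.max_feret_diameter_mm >= thr_mm]
    return vessels, conduits


def hydraulic_diameter(diameters) -> float:
    """Hydraulically weighted diameter sum(d^5)/sum(d^4), in input units.

    Weighting each conduit by its hydraulic contribution makes D_H at
    least the arithmetic mean diameter, with equality only when all
    diameters are equal.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one diameter")
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    return float((d ** 5).sum() / (d ** 4).sum())


def vessel_stats(records: list[VesselRecord], vlf: float) -> VesselStats:
    """Compute A, N, S and D_H from vessel records and a vessel lumen
    fraction (typically the grid estimate for the same section)."""
    if not records:
        raise ValueError("no vessel records")
    if not 0 < vlf <= 1:
        raise ValueError("vessel lumen fraction must be in (0, 1]")
    areas = np.array([r.lumen_area_mm2 for r in records])
    diams = np.array([r.equivalent_diameter_mm for r in records])
    a = float(areas.mean())
    n = vlf / a
    return VesselStats(
        A=a, N=n, S=a / n, D_H=hydraulic_diameter(diams),
        VLF=vlf, n_vessels=len(records),
    )
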