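"""Labeled wood cross-sections.

The measurement substrate of the whole package is a per-pixel tissue label
map of a twig cross-section sector together with a physical scale.  The
sector is the wedge of wood actually analysed (bounded by pith, rays and
bark in real material); pith and anything outside the sector never enter
fraction denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class TissueLabel(IntEnum):
    """Mutually exclusive per-pixel tissue classes of angiosperm twig wood.

    ``CONDUIT15`` pools small conduits (tracheids or small vessels) whose
    maximum lumen diameter is below 15 um; their wall and lumen are not
    separated.  ``PITH`` and ``OUTSIDE`` are excluded from all fraction
    denominators.
    """

    VESSEL_LUMEN = 1
    VESSEL_WALL = 2
    AXIAL_PARENCHYMA = 3
    RAY_PARENCHYMA = 4
    FIBRE_LUMEN = 5
    FIBRE_WALL = 6
    CONDUIT15 = 7
    MUCILAGE_CANAL = 8
    PITH = 9
    OUTSIDE = 10


#: Labels that count toward tissue fractions (everything except pith/outside).
WOOD_LABELS: tuple[TissueLabel, ...] = (
    TissueLabel.VESSEL_LUMEN,
    TissueLabel.VESSEL_WALL,
    TissueLabel.AXIAL_PARENCHYMA,
    TissueLabel.RAY_PARENCHYMA,
    TissueLabel.FIBRE_LUMEN,
    TissueLabel.FIBRE_WALL,
    TissueLabel.CONDUIT15,
    TissueLabel.MUCILAGE_CANAL,
)


class EmptySectorError(ValueError):
    """Raised when a section has no analysable in-sector pixels."""


@dataclass
class LabeledSection:
    """A labeled cross-section sector with physical scale.

    Parameters
    ----------
    label_map : ndarray of uint8, shape (H, W)
        Per-pixel :class:`TissueLabel` values.
    scale_um_per_px : float
        Physical side length of one pixel in micrometres.
    sector_mask : ndarray of bool, shape (H, W), optional
        True where the pixel belongs to the analysed sector.  Defaults to
        every pixel.  In-sector pixels must not be labeled ``OUTSIDE``.
    """

    label_map: np.ndarray
    scale_um_per_px: float
    sector_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.uint8)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D")
        if not np.isfinite(self.scale_um_per_px) or self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be a positive length")
        if self.sector_mask is None:
            self.sector_mask = np.ones(self.label_map.shape, dtype=bool)
        else:
            self.sector_mask = np.asarray(self.sector_mask, dtype=bool)
        if self.sector_mask.shape != self.label_map.shape:
            raise ValueError("label_map and sector_mask must have the same shape")
        in_sector = self.label_map[self.sector_mask]
        if in_sector.size and (in_sector == TissueLabel.OUTSIDE).any():
            raise ValueError("in-sector pixels must not carry the OUTSIDE label")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def scale_mm_per_px(self) -> float:
        return self.scale_um_per_px * 1e-3

    def n_in_sector(self) -> int:
        """Number of in-sector pixels with a wood (non-pith) label."""
        labels = self.label_map[self.sector_mask]
        return int((labels != TissueLabel.PITH).sum())


def realized_fractions(section: LabeledSection) -> dict[TissueLabel, float]:
    """Pixel-exact area fractions of each wood tissue in the sector.

    This is the exhaustive-counting oracle against which the grid-point
    estimator is checked: fraction(label) = in-sector pixel count of the
    label divided by the total in-sector wood pixel count.  The returned
    fractions sum to 1 to machine precision.

    Raises
    ------
    EmptySectorError
        If the sector contains no wood pixels.
    """
    labels = section.label_map[section.sector_mask]
    labels = labels[labels != TissueLabel.PITH]
    total = labels.size
    if total == 0:
        raise EmptySectorError("sector mask selects no wood pixels")
    counts = np.bincount(labels, minlength=int(TissueLabel.OUTSIDE) + 1)
    return {lab: counts[int(lab)] / total for lab in WOOD_LABELS}
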