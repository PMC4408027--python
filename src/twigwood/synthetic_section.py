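"""Synthetic labeled wood cross-sections with known ground truth.

The generator renders a stylized but geometrically explicit wood mosaic:

* vessels as non-overlapping discs (lumen) with a concentric wall annulus,
  placed by dart throwing; conduits below 15 um and mucilage canals as
  smaller/larger plain discs;
* rays as vertical bands and axial parenchyma as horizontal bands, both
  sized by exact pixel accounting against the remaining unpainted area;
* fibres as a hexagonal tessellation of the remainder, split into wall
  and lumen by thresholding the distance to the nearest cell boundary at
  the exact quantile that realizes the requested wall:lumen split.

Every pixel gets exactly one label, so :func:`~twigwood.section.realized_fractions`
is a pixel-exact oracle for the grid-point estimator, and the generator's
metadata records the true vessel and conduit geometry for the
morphometrics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .section import LabeledSection, TissueLabel, WOOD_LABELS

__all__ = ["SectionSpec", "InfeasibleSectionError", "generate_section", "section_from_discs"]


class InfeasibleSectionError(ValueError):
    """Target fractions cannot be realized by the mosaic geometry."""

    def __init__(self, label: TissueLabel, message: str):
        super().__init__(f"{label.name}: {message}")
        self.label = label


@dataclass
class SectionSpec:
    """Specification of a synthetic labeled section.

    ``target_fractions`` maps in-sector tissue labels to area fractions
    summing to 1.  Diameter distributions are lognormal ``(median_um,
    sigma_log)``; vessel draws are truncated to >= 15 um and conduit draws
    to < 15 um so the two populations respect the small-conduit cutoff.
    """

    target_fractions: dict[TissueLabel, float]
    image_size_px: tuple[int, int] = (800, 800)   # (width, height)
    scale_um_per_px: float = 1.0
    vessel_diameter_um: tuple[float, float] = (45.0, 0.30)
    conduit_diameter_um: tuple[float, float] = (10.0, 0.25)
    mucilage_diameter_um: float = 100.0
    ray_width_um: float = 30.0
    axial_band_width_um: float = 40.0
    fibre_cell_diameter_um: float = 20.0
    rng_seed: int = 0
    max_dart_attempts: int = 200

    def __post_init__(self) -> None:
        fr = {TissueLabel(k): float(v) for k, v in self.target_fractions.items()}
        for lab, v in fr.items():
            if lab not in WOOD_LABELS:
                raise ValueError(f"{lab.name} cannot carry a target fraction")
            if v < 0:
                raise ValueError(f"negative target fraction for {lab.name}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target fractions must sum to 1 (got {total!r})")
        self.target_fractions = fr
        w, h = self.image_size_px
        if w < 8 or h < 8:
            raise ValueError("image must be at least 8x8 px")
        for name in ("scale_um_per_px", "mucilage_diameter_um", "ray_width_um",
                     "axial_band_width_um", "fibre_cell_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vessel_diameter_um[0] < 15:
            raise ValueError("vessel diameter median must be >= 15 um")
        if not 0 < self.conduit_diameter_um[0] < 15:
            raise ValueError("conduit diameter median must be in (0, 15) um")
        # image must hold a reasonable number of fibre cells
        cell_area = (self.fibre_cell_diameter_um / self.scale_um_per_px) ** 2
        if w * h / cell_area < 50:
            raise ValueError("image too small: must hold at least 50 fibre cells")

    def target(self, label: TissueLabel) -> float:
        return self.target_fractions.get(label, 0.0)


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------


def _paint_disc(canvas: np.ndarray, cx: float, cy: float, r: float, value: int) -> int:
    """Rasterize a disc onto unassigned (0) pixels; returns pixels painted."""
    h, w = canvas.shape
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    patch = canvas[y0:y1, x0:x1]
    sel = inside & (patch == 0)
    patch[sel] = value
    return int(sel.sum())


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float,
    low: float | None, high: float | None,
) -> float:
    for _ in range(1000):
        d = median * np.exp(sigma * rng.standard_normal())
        if (low is None or d >= low) and (high is None or d < high):
            return d
    raise RuntimeError("diameter distribution truncation failed to converge")


def _place_discs(
    canvas: np.ndarray,
    placed: list[tuple[float, float, float]],
    rng: np.random.Generator,
    label: TissueLabel,
    body_target_px: float,
    diameter_px,                    # callable -> lumen/body diameter in px
    wall_ratio: float,
    wall_label: TissueLabel | None,
    max_attempts: int,
) -> tuple[int, int, list[float]]:
    """Dart-throw non-overlapping discs until the body target is best met.

    Returns (body pixels painted, wall pixels painted, body diameters px).
    The stopping rule adds a disc only while it brings the realized body
    area closer to the target, so the residual is at most half a disc.
    """
    h, w = canvas.shape
    body_px = 0
    wall_px = 0
    diams: list[float] = []
    while True:
        d = diameter_px()
        r = d / 2.0
        t = r * (np.sqrt(1.0 + wall_ratio) - 1.0) if wall_ratio > 0 else 0.0
        est = np.pi * r * r
        if abs(body_px - body_target_px) <= abs(body_px + est - body_target_px):
            break
        router = r + t
        for _ in range(max_attempts):
            cx = rng.uniform(router + 1, w - router - 2)
            cy = rng.uniform(router + 1, h - router - 2)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (router + pr + 1.0) ** 2
                   for px, py, pr in placed):
                break
        else:
            raise InfeasibleSectionError(
                label,
                f"could not place a disc after {max_attempts} darts "
                f"(target fraction too high for non-overlapping packing)",
            )
        if wall_label is not None and t > 0:
            wall_px += _paint_disc(canvas, cx, cy, router, int(wall_label))
        # lumen/body painted second, overwriting the wall disc's interior
        patch_r = r
        yy0, yy1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        xx0, xx1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.mgrid[yy0:yy1, xx0:xx1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= patch_r * patch_r
        patch = canvas[yy0:yy1, xx0:xx1]
        sel = inside & ((patch == 0) | (patch == int(wall_label or 0)))
        if wall_label is not None:
            wall_px -= int((inside & (patch == int(wall_label))).sum())
        patch[sel] = int(label)
        body_px += int(sel.sum())
        placed.append((cx, cy, router))
        diams.append(2.0 * r)
    return body_px, wall_px, diams


def _paint_bands(
    canvas: np.ndarray,
    rng: np.random.Generator,
    label: TissueLabel,
    target_px: int,
    band_width: int,
    vertical: bool,
    wiggle_amp: float,
    wiggle_period: float,
) -> int:
    """Paint wiggly parallel bands onto unassigned pixels until ``target_px``
    is reached (to within about one band column).

    Bands meander sinusoidally across their long axis — like rays bending
    around vessels — which also keeps band membership from being constant
    along any straight line.  Band positions are evenly spaced; they are
    visited in golden-ratio stride order so that stopping early still
    leaves the bands spread across the section.
    """
    if target_px <= 0:
        return 0
    h, w = canvas.shape
    length = w if vertical else h          # axis across the bands
    span = h if vertical else w            # axis along each band
    n_max = max(1, length // (band_width + 2))
    starts = np.linspace(0, length - band_width, n_max)
    order = np.argsort((np.arange(n_max) * 0.61803398875) % 1.0)
    t = np.arange(span)
    painted = 0
    for idx in order:
        s = int(round(starts[idx]))
        phase = rng.uniform(0, 2 * np.pi)
        shift = np.round(wiggle_amp * np.sin(2 * np.pi * t / wiggle_period + phase))
        shift = shift.astype(int)
        for c in range(band_width):
            lines = (s + c + shift) % length
            if vertical:
                sel = canvas[t, lines] == 0
                canvas[t[sel], lines[sel]] = int(label)
            else:
                sel = canvas[lines, t] == 0
                canvas[lines[sel], t[sel]] = int(label)
            painted += int(sel.sum())
            if painted >= target_px:
                return painted
    raise InfeasibleSectionError(
        label, "not enough unassigned area left for the requested fraction"
    )


def _hex_centers(h: int, w: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    dy = spacing * np.sqrt(3.0) / 2.0
    phase = rng.uniform(0, spacing, size=2)
    rows = np.arange(-1, int(h / dy) + 2)
    pts = []
    for i in rows:
        y = i * dy + phase[1]
        xoff = (spacing / 2.0 if i % 2 else 0.0) + phase[0]
        xs = np.arange(-1, int(w / spacing) + 2) * spacing + xoff
        pts.append(np.column_stack([np.full_like(xs, y), xs]))
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def generate_section(spec: SectionSpec) -> LabeledSection:
    """Render a labeled section whose pixel-exact fractions match the spec
    targets to within +/-0.02 per tissue.

    Deterministic given ``spec.rng_seed``.  Raises
    :class:`InfeasibleSectionError` naming the violated tissue when a
    target cannot be realized (e.g. vessel packing beyond the
    non-overlapping disc limit).
    """
    rng = np.random.default_rng(spec.rng_seed)
    w, h = spec.image_size_px
    canvas = np.zeros((h, w), dtype=np.uint8)
    total = float(h * w)
    scale = spec.scale_um_per_px
    placed: list[tuple[float, float, float]] = []
    meta: dict = {"rng_seed": spec.rng_seed, "scale_um_per_px": scale}

    vl_t = spec.target(TissueLabel.VESSEL_LUMEN)
    vw_t = spec.target(TissueLabel.VESSEL_WALL)
    if vl_t == 0 and vw_t > 0:
        raise InfeasibleSectionError(
            TissueLabel.VESSEL_WALL, "vessel wall requires a nonzero vessel lumen target"
        )

    # mucilage canals (largest discs first: easiest to pack early)
    mc_t = spec.target(TissueLabel.MUCILAGE_CANAL)
    if mc_t > 0:
        _place_discs(
            canvas, placed, rng, TissueLabel.MUCILAGE_CANAL, mc_t * total,
            lambda: spec.mucilage_diameter_um / scale, 0.0, None,
            spec.max_dart_attempts,
        )

    # vessels: lumen disc + wall annulus sized by the wall:lumen area ratio
    vessel_diams_px: list[float] = []
    if vl_t > 0:
        ratio = vw_t / vl_t
        med, sig = spec.vessel_diameter_um
        _, _, vessel_diams_px = _place_discs(
            canvas, placed, rng, TissueLabel.VESSEL_LUMEN, vl_t * total,
            lambda: _truncated_lognormal(rng, med, sig, 15.0, None) / scale,
            ratio, TissueLabel.VESSEL_WALL, spec.max_dart_attempts,
        )
    meta["vessel_diameters_um"] = [d * scale for d in vessel_diams_px]
    meta["n_vessels"] = len(vessel_diams_px)

    # small conduits (pooled wall+lumen label)
    cf_t = spec.target(TissueLabel.CONDUIT15)
    conduit_diams_px: list[float] = []
    if cf_t > 0:
        cmed, csig = spec.conduit_diameter_um
        _, _, conduit_diams_px = _place_discs(
            canvas, placed, rng, TissueLabel.CONDUIT15, cf_t * total,
            lambda: _truncated_lognormal(rng, cmed, csig, None, 15.0) / scale,
            0.0, None, spec.max_dart_attempts,
        )
    meta["conduit_diameters_um"] = [d * scale for d in conduit_diams_px]
    meta["n_conduits"] = len(conduit_diams_px)

    # rays: vertical meandering bands, pixel accounting on the unpainted area
    ray_t = spec.target(TissueLabel.RAY_PARENCHYMA)
    if ray_t > 0:
        rw = max(1, round(spec.ray_width_um / scale))
        _paint_bands(
            canvas, rng, TissueLabel.RAY_PARENCHYMA,
            target_px=int(round(ray_t * total)),
            band_width=rw, vertical=True,
            wiggle_amp=1.5 * rw, wiggle_period=max(8.0 * rw, h / 4.0),
        )

    # axial parenchyma: horizontal bands on what is still unpainted
    ax_t = spec.target(TissueLabel.AXIAL_PARENCHYMA)
    if ax_t > 0:
        aw = max(1, round(spec.axial_band_width_um / scale))
        _paint_bands(
            canvas, rng, TissueLabel.AXIAL_PARENCHYMA,
            target_px=int(round(ax_t * total)),
            band_width=aw, vertical=False,
            wiggle_amp=1.5 * aw, wiggle_period=max(8.0 * aw, w / 4.0),
        )

    # fibres fill the remainder; wall vs lumen split at the exact quantile
    # of the distance to the nearest hexagonal cell boundary
    rem_idx = np.flatnonzero(canvas.ravel() == 0)
    fw_t = spec.target(TissueLabel.FIBRE_WALL)
    fl_t = spec.target(TissueLabel.FIBRE_LUMEN)
    if rem_idx.size:
        if fw_t + fl_t <= 0:
            # degenerate spec without fibres: hand the residue to the most
            # abundant requested tissue so labels stay exhaustive
            fallback = max(spec.target_fractions, key=spec.target_fractions.get)
            canvas.ravel()[rem_idx] = int(fallback)
        else:
            wall_share = fw_t / (fw_t + fl_t)
            if wall_share >= 1.0 - 1e-12:
                canvas.ravel()[rem_idx] = int(TissueLabel.FIBRE_WALL)
            elif wall_share <= 1e-12:
                canvas.ravel()[rem_idx] = int(TissueLabel.FIBRE_LUMEN)
            else:
                yy, xx = np.unravel_index(rem_idx, canvas.shape)
                centers = _hex_centers(h, w, spec.fibre_cell_diameter_um / scale, rng)
                dist, _ = cKDTree(centers).query(
                    np.column_stack([yy, xx]).astype(float), k=2
                )
                edge = (dist[:, 1] - dist[:, 0]) / 2.0  # distance to cell boundary
                thr = np.quantile(edge, wall_share)
                lab = np.where(edge <= thr, int(TissueLabel.FIBRE_WALL),
                               int(TissueLabel.FIBRE_LUMEN))
                canvas.ravel()[rem_idx] = lab

    section = LabeledSection(canvas, scale, meta=meta)
    from .section import realized_fractions

    meta["realized_fractions"] = {
        lab.name: v for lab, v in realized_fractions(section).items()
    }
    meta["target_fractions"] = {
        lab.name: v for lab, v in spec.target_fractions.items()
    }
    return section


def section_from_discs(
    diameters_um,
    scale_um_per_px: float = 1.0,
    image_size_px: tuple[int, int] = (400, 400),
    background: TissueLabel = TissueLabel.FIBRE_WALL,
    label: TissueLabel = TissueLabel.VESSEL_LUMEN,
    rng_seed: int = 0,
) -> LabeledSection:
    """Paint discs of the given lumen diameters on a uniform background.

    A small ground-truth builder for the vessel morphometrics stage: the
    resulting section has exactly ``len(diameters_um)`` disjoint disc
    components of ``label`` with known diameters.
    """
    rng = np.random.default_rng(rng_seed)
    w, h = image_size_px
    canvas = np.full((h, w), int(background), dtype=np.uint8)
    placed: list[tuple[float, float, float]] = []
    for d_um in diameters_um:
        r = d_um / scale_um_per_px / 2.0
        if r < 0.5:
            raise ValueError("disc diameter below one pixel")
        for _ in range(10000):
            cx = rng.uniform(r + 1, w - r - 2)
            cy = rng.uniform(r + 1, h - r - 2)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (r + pr + 2.0) ** 2
                   for px, py, pr in placed):
                break
        else:
            raise InfeasibleSectionError(label, "could not pack the requested discs")
        yy, xx = np.mgrid[0:h, 0:w]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        canvas[inside] = int(label)
        placed.append((cx, cy, r))
    return LabeledSection(
        canvas, scale_um_per_px,
        meta={"disc_diameters_um": list(diameters_um), "rng_seed": rng_seed},
    )
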