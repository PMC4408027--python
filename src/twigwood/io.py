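"""File formats: label maps (indexed PNG + JSON sidecar), trait tables
(CSV/XLSX), fraction and vessel CSVs, and the pipeline configuration.

A label map is written as an 8-bit indexed PNG whose palette indices are
the tissue codes, accompanied by ``<name>.json`` recording the index ->
tissue mapping, the physical scale and the generating seed; an optional
mask PNG stores the analysed-sector mask.  The sidecar makes foreign
label maps usable: any indexed PNG plus a complete sidecar is accepted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .section import LabeledSection, TissueLabel
from .stereology import FractionVector, PointCounts
from .vessels import VesselRecord, VesselStats

__all__ = [
    "write_label_map",
    "read_label_map",
    "write_fractions_csv",
    "write_vessels_csv",
    "write_vessel_stats_csv",
    "load_trait_table",
    "load_species_dataset",
    "PipelineConfig",
]

#: Display palette (RGB) per tissue, loosely following the conventional
#: colour coding of annotated cross-sections.
LABEL_COLORS: dict[TissueLabel, tuple[int, int, int]] = {
    TissueLabel.VESSEL_LUMEN: (120, 190, 255),
    TissueLabel.VESSEL_WALL: (128, 0, 160),
    TissueLabel.AXIAL_PARENCHYMA: (220, 40, 40),
    TissueLabel.RAY_PARENCHYMA: (40, 160, 60),
    TissueLabel.FIBRE_LUMEN: (255, 230, 90),
    TissueLabel.FIBRE_WALL: (90, 60, 20),
    TissueLabel.CONDUIT15: (255, 140, 0),
    TissueLabel.MUCILAGE_CANAL: (0, 200, 200),
    TissueLabel.PITH: (230, 230, 230),
    TissueLabel.OUTSIDE: (0, 0, 0),
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_map(section: LabeledSection, path) -> Path:
    """Write an indexed PNG + JSON sidecar (+ mask PNG when non-trivial)."""
    path = Path(path)
    img = Image.fromarray(section.label_map, mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for lab, rgb in LABEL_COLORS.items():
        palette[int(lab)] = rgb
    img.putpalette(palette.ravel().tolist())
    img.save(path)
    sidecar = {
        "format": "twigwood-label-map",
        "palette": {str(int(lab)): lab.name for lab in TissueLabel},
        "scale_um_per_px": section.scale_um_per_px,
        "seed": section.meta.get("rng_seed"),
    }
    if not section.sector_mask.all():
        mask_path = path.with_name(path.stem + ".mask.png")
        Image.fromarray(section.sector_mask.astype(np.uint8) * 255, mode="L").save(mask_path)
        sidecar["sector_mask_file"] = mask_path.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_label_map(path) -> LabeledSection:
    """Read a label map written by :func:`write_label_map` (or any indexed
    PNG with a complete sidecar).

    Raises on a missing scale or on palette indices present in the image
    but absent from the sidecar mapping (the offending index is named).
    """
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    if "scale_um_per_px" not in sidecar:
        raise ValueError("sidecar lacks scale_um_per_px")
    mapping = sidecar.get("palette", {})
    arr = np.asarray(Image.open(path))
    remap = np.full(256, -1, dtype=np.int16)
    for idx_str, name in mapping.items():
        remap[int(idx_str)] = int(TissueLabel[name])
    present = np.unique(arr)
    unknown = [int(i) for i in present if remap[i] < 0]
    if unknown:
        raise ValueError(f"palette index {unknown[0]} has no tissue mapping in the sidecar")
    labels = remap[arr].astype(np.uint8)
    mask = None
    if "sector_mask_file" in sidecar:
        mask_arr = np.asarray(Image.open(path.with_name(sidecar["sector_mask_file"])))
        mask = mask_arr > 0
    return LabeledSection(
        labels, float(sidecar["scale_um_per_px"]), sector_mask=mask,
        meta={"rng_seed": sidecar.get("seed"), "source": str(path)},
    )


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------


def write_fractions_csv(
    fractions: FractionVector, path, counts: PointCounts | None = None
) -> Path:
    path = Path(path)
    rows = []
    for lab, frac in fractions.fractions.items():
        rows.append({
            "label": lab.name,
            "count": counts.counts.get(lab, "") if counts else "",
            "fraction": frac,
            "se": fractions.standard_errors.get(lab, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_vessels_csv(
    vessels: list[VesselRecord], conduits: list[VesselRecord], path
) -> Path:
    path = Path(path)
    rows = []
    for cls, recs in (("vessel", vessels), ("conduit15", conduits)):
        for i, r in enumerate(recs):
            rows.append({
                "id": f"{cls[0]}{i + 1}", "class": cls,
                "area_mm2": r.lumen_area_mm2,
                "eq_diam_mm": r.equivalent_diameter_mm,
                "feret_mm": r.max_feret_diameter_mm,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_vessel_stats_csv(stats: VesselStats, path) -> Path:
    path = Path(path)
    pd.DataFrame([{
        "A_mm2": stats.A, "N_per_mm2": stats.N, "S_mm4": stats.S,
        "Dh_mm": stats.D_H, "VLF": stats.VLF, "n_vessels": stats.n_vessels,
    }]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


def load_trait_table(path) -> pd.DataFrame:
    """Read a replicate- or species-level trait table CSV."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    return df


def load_species_dataset(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Ingest a deposited species-level dataset (CSV or XLSX).

    ``column_map`` maps the file's column headers to the canonical trait
    abbreviations (APF, RPF, ..., LASA) plus 'species' and optionally
    'site'; identity for already-canonical headers.  Unmapped columns are
    kept untouched.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "species" not in df.columns:
        raise ValueError(
            "dataset lacks a 'species' column after mapping; provide a column_map"
        )
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through JSON."""

    output_dir: str = "twigwood_out"
    sections_dir: str | None = None       # measure existing label maps
    trait_table: str | None = None        # analyse an existing table
    n_species: int = 69
    n_replicates: int = 3
    replicate_cv: float = 0.1
    grid_spacing_px: int = 300
    min_points: int = 300
    conduit_threshold_um: float = 15.0
    alpha: float = 0.05
    strict: bool = False
    n_demo_sections: int = 1
    section_size_px: int = 1200
    scale_um_per_px: float = 1.0
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        for name in ("grid_spacing_px", "min_points", "conduit_threshold_um", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            source = Path(source).read_text()
        return cls(**json.loads(source))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
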