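"""End-to-end orchestration: simulate -> measure -> derive -> aggregate ->
correlate -> summarize, with CSV/plot outputs and a JSON report.

Each stage is a thin call into the library; a stage failure aborts the
run with the stage name.  All randomness flows from the single seed in
the config, and the report records the config digest so reruns are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference as ref
from .io import PipelineConfig, write_fractions_csv, write_label_map, \
    write_vessel_stats_csv, write_vessels_csv, load_trait_table
from .section import TissueLabel, realized_fractions
from .stereology import GridSpec, count_points, fractions_from_counts, overlay_grid
from .stats import correlation_matrix, normality_screen, summarize_traits
from .synthetic_section import SectionSpec, generate_section
from .synthetic_traits import study_cohort_table
from .traits import species_means, trait_record_from_fractions
from .vessels import extract_vessels, partition_conduits15, vessel_stats

__all__ = ["run_pipeline", "measure_section"]

#: Demonstration section targets: the cohort's average tissue composition.
AVERAGE_FRACTIONS: dict[TissueLabel, float] = {
    TissueLabel.FIBRE_WALL: 0.32,
    TissueLabel.FIBRE_LUMEN: 0.13,
    TissueLabel.AXIAL_PARENCHYMA: 0.14,
    TissueLabel.RAY_PARENCHYMA: 0.21,
    TissueLabel.VESSEL_LUMEN: 0.13,
    TissueLabel.VESSEL_WALL: 0.04,
    TissueLabel.CONDUIT15: 0.02,
    TissueLabel.MUCILAGE_CANAL: 0.01,
}


def measure_section(section, config: PipelineConfig) -> dict:
    """Measure one labeled section: grid fractions, vessel statistics."""
    grid = GridSpec(spacing_px=config.grid_spacing_px)
    pts = overlay_grid(section, grid)
    counts = count_points(section, pts)
    fractions = fractions_from_counts(counts, config.min_points, config.strict)
    records = extract_vessels(section)
    vessels, conduits = partition_conduits15(records, config.conduit_threshold_um)
    result: dict = {
        "fractions": fractions,
        "counts": counts,
        "traits": trait_record_from_fractions(fractions),
        "vessel_records": vessels,
        "conduit_records": conduits,
    }
    vlf = fractions[TissueLabel.VESSEL_LUMEN]
    if vessels and vlf > 0:
        result["vessel_stats"] = vessel_stats(vessels, vlf)
    return result


def _fail(stage: str, exc: Exception) -> RuntimeError:
    err = RuntimeError(f"pipeline stage '{stage}' failed: {exc}")
    err.__cause__ = exc
    return err


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write outputs under ``config.output_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "seed": config.seed,
                    "outputs": {}}

    # --- simulate (or load) the cohort trait table -------------------------
    try:
        if config.trait_table:
            table = load_trait_table(config.trait_table)
        else:
            table = study_cohort_table(
                n_species=config.n_species,
                n_replicates=config.n_replicates,
                replicate_cv=config.replicate_cv,
                rng_seed=config.seed,
            )
        table_path = out / "cohort_replicates.csv"
        table.to_csv(table_path, index=False)
        report["outputs"]["cohort_replicates"] = table_path.name
    except Exception as exc:  # noqa: BLE001
        raise _fail("simulate", exc)

    # --- demonstration sections: simulate, measure, compare to oracle -----
    try:
        demos = []
        for k in range(config.n_demo_sections):
            spec = SectionSpec(
                target_fractions=AVERAGE_FRACTIONS,
                image_size_px=(config.section_size_px, config.section_size_px),
                scale_um_per_px=config.scale_um_per_px,
                rng_seed=config.seed + k,
            )
            section = generate_section(spec)
            png = write_label_map(section, out / f"section_{k:02d}.png")
            measured = measure_section(section, config)
            oracle = realized_fractions(section)
            write_fractions_csv(
                measured["fractions"], out / f"section_{k:02d}_fractions.csv",
                measured["counts"],
            )
            write_vessels_csv(
                measured["vessel_records"], measured["conduit_records"],
                out / f"section_{k:02d}_vessels.csv",
            )
            if "vessel_stats" in measured:
                write_vessel_stats_csv(
                    measured["vessel_stats"], out / f"section_{k:02d}_vessel_stats.csv"
                )
            max_err = max(
                abs(measured["fractions"][lab] - oracle[lab])
                for lab in oracle
            )
            demos.append({
                "file": png.name,
                "n_points": measured["fractions"].n,
                "max_abs_error_vs_oracle": max_err,
            })
        report["sections"] = demos
    except Exception as exc:  # noqa: BLE001
        raise _fail("measure", exc)

    # --- aggregate, summarize, correlate -----------------------------------
    try:
        means = species_means(table)
        means_path = out / "species_means.csv"
        means.to_csv(means_path, index=False)
        summary = summarize_traits(means)
        summary_path = out / "trait_summary.csv"
        summary.to_csv(summary_path, index=False)
        report["outputs"]["species_means"] = means_path.name
        report["outputs"]["trait_summary"] = summary_path.name
    except Exception as exc:  # noqa: BLE001
        raise _fail("aggregate", exc)

    try:
        screen = normality_screen(means, alpha=config.alpha)
        normality = {t: r.is_normal for t, r in screen.items()}
        corr = correlation_matrix(means, normality=normality, alpha=config.alpha)
        corr.headline.to_csv(out / "correlations_headline.csv")
        corr.pearson.to_csv(out / "correlations_pearson.csv")
        corr.spearman.to_csv(out / "correlations_spearman.csv")
        corr.to_long().to_csv(out / "correlations_long.csv", index=False)
        report["outputs"]["correlations"] = "correlations_headline.csv"
        report["n_normal_traits"] = int(sum(normality.values()))
        report["fibre_parenchyma_r"] = float(corr.headline.loc["TFF", "TPF"])
    except Exception as exc:  # noqa: BLE001
        raise _fail("correlate", exc)

    # --- plots --------------------------------------------------------------
    if config.make_plots:
        try:
            _make_plots(means, out)
            report["outputs"]["plots"] = ["tissue_fractions.png", "trait_scatter.png"]
        except Exception as exc:  # noqa: BLE001
            raise _fail("plot", exc)

    # deterministic digest over the CSV outputs
    sha = hashlib.sha256()
    for f in sorted(out.glob("*.csv")):
        sha.update(f.read_bytes())
    report["csv_digest"] = sha.hexdigest()[:16]
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _make_plots(means: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # stacked tissue fractions, species sorted by total parenchyma
    order = means.sort_values("TPF", ascending=False)
    parts = ["APF", "RPF", "FLF", "FWF", "VLF", "VWF", "CF", "MCF"]
    colors = ["#dc2828", "#28a03c", "#ffe65a", "#5a3c14",
              "#78beff", "#8000a0", "#ff8c00", "#00c8c8"]
    fig, ax = plt.subplots(figsize=(7, 9))
    left = np.zeros(len(order))
    y = np.arange(len(order))
    for part, color in zip(parts, colors):
        vals = order[part].to_numpy()
        ax.barh(y, vals, left=left, color=color, label=part, height=0.85)
        left += vals
    ax.set_yticks([])
    ax.set_xlabel("tissue fraction of wood cross-section")
    ax.legend(ncols=4, fontsize=7, loc="upper center", bbox_to_anchor=(0.5, 1.06))
    fig.savefig(out / "tissue_fractions.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    site_colors = {"rainforest": "green", "woodland": "red", "temperate": "blue"}
    c = [site_colors.get(s, "gray") for s in means.get("site", ["?"] * len(means))]
    axes[0].scatter(means["TPF"], means["TFF"], c=c, s=18)
    axes[0].set_xlabel("total parenchyma fraction")
    axes[0].set_ylabel("total fibre fraction")
    axes[1].scatter(means["WF"], means["MOE"], c=c, s=18)
    axes[1].set_xlabel("wall fraction (fibre+vessel)")
    axes[1].set_ylabel("modulus of elasticity (MPa)")
    axes[2].scatter(means["A"], means["N"], c=c, s=18)
    axes[2].set_xscale("log")
    axes[2].set_yscale("log")
    axes[2].set_xlabel("vessel area (mm$^2$)")
    axes[2].set_ylabel("vessels per area (mm$^{-2}$)")
    fig.tight_layout()
    fig.savefig(out / "trait_scatter.png", dpi=120)
    plt.close(fig)
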