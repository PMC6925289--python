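"""Pipeline orchestration: simulate → analyze → quantify in one place.

These functions bind the stages together for the CLI and for end-to-end
studies; each stage remains individually usable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .configio import config_hash, save_simulation_config
from .imaging import (ChannelThreshold, PartitionGrid,
                      PolynomialIlluminationField, call_partitions,
                      derive_threshold_ntc, estimate_illumination,
                      extract_partition_intensities, locate_grid, qc_filter_rox)
from .quantify import allele_fraction, estimate_from_table
from .simulate import (ROX, ImageSet, SimulationConfig, make_ntc_imageset,
                       render_array_images, simulate_occupancy)
from .table import PartitionTable


@dataclass
class RunAnalysis:
    """Everything the analysis stage produced for one sample run."""

    table: PartitionTable
    thresholds: dict[str, ChannelThreshold]
    measurements: pd.DataFrame
    ntc_measurements: pd.DataFrame
    grid: PartitionGrid
    field: PolynomialIlluminationField


def analyze_imageset(images: ImageSet, *,
                     rox_threshold: float | None = None) -> tuple[
                         pd.DataFrame, PartitionGrid, PolynomialIlluminationField]:
    """Grid location, illumination fit, extraction and ROX QC for one image set."""
    cfg = images.config
    rox_post = images.images[ROX]["post"]
    grid = locate_grid(rox_post, cfg.geometry, pixel_pitch=cfg.pixel_pitch,
                       margin_px=cfg.margin_px)
    field = estimate_illumination(rox_post, grid)
    meas = extract_partition_intensities(images, grid, field)
    meas = qc_filter_rox(meas, rox_threshold=rox_threshold)
    return meas, grid, field


def analyze_run(images: ImageSet, ntc_images: ImageSet, *,
                n_sd: float = 5.0, min_ntc_valid: int = 1000) -> RunAnalysis:
    """Analyze a sample run with NTC-derived thresholds; produce the call table."""
    ntc_meas, _, _ = analyze_imageset(ntc_images)
    thresholds = {ch: derive_threshold_ntc(ntc_meas, ch, n_sd=n_sd,
                                           min_valid=min_ntc_valid)
                  for ch in images.config.probe_channels}
    meas, grid, field = analyze_imageset(images)
    table = call_partitions(meas, thresholds)
    return RunAnalysis(table, thresholds, meas, ntc_meas, grid, field)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    simulation: SimulationConfig
    outdir: Path
    target: str = "FAM"
    reference: str | None = "HEX"
    n_sd: float = 5.0


def simulate_run(config: SimulationConfig, outdir: str | Path, *,
                 ntc: bool = False) -> ImageSet:
    """Generate an image set (+ truth and provenance) and write it to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ntc:
        images, truth = make_ntc_imageset(config)
    else:
        truth = simulate_occupancy(config)
        images = render_array_images(truth, config)
    images.save(outdir)
    truth.to_frame().to_csv(outdir / "truth.csv", index=False)
    save_simulation_config(config, outdir / "config.yaml")
    _write_provenance(outdir, config)
    return images


def _write_provenance(outdir: Path, config: SimulationConfig) -> None:
    prov = {"seed": config.seed, "config_hash": config_hash(config),
            "package": "arraydpcr", "version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")


def run_end_to_end(run: RunConfig) -> dict[str, Path]:
    """simulate (NTC + sample) → analyze → quantify; write all artifacts.

    Writes images, truth, partition table, thresholds, a results CSV with one
    row per probe channel (plus the target:reference fraction when a
    reference with nonzero concentration is configured) and a provenance log.
    """
    outdir = Path(run.outdir)
    sample_dir, ntc_dir = outdir / "sample", outdir / "ntc"
    ntc_cfg = dataclasses.replace(run.simulation, seed=run.simulation.seed + 1)
    images = simulate_run(run.simulation, sample_dir)
    ntc_images = simulate_run(ntc_cfg, ntc_dir, ntc=True)

    analysis = analyze_run(images, ntc_images, n_sd=run.n_sd)
    table_path = outdir / "partition_table.csv"
    analysis.table.write_csv(table_path)
    thr_rows = [{"channel": t.channel, "threshold": t.threshold,
                 "source": t.source, "ntc_mean": t.ntc_mean, "ntc_sd": t.ntc_sd,
                 "ntc_max": t.ntc_max, "ntc_n": t.ntc_n}
                for t in analysis.thresholds.values()]
    pd.DataFrame(thr_rows).to_csv(outdir / "thresholds.csv", index=False)

    v_ul = run.simulation.geometry.nominal_volume_pl / 1e6
    rows = []
    estimates = {}
    for ch in images.config.probe_channels:
        est = estimate_from_table(analysis.table, ch, v_ul)
        estimates[ch] = est
        rows.append({"channel": ch, "k_positive": est.k_positive,
                     "n_valid": est.n_valid, "conc_cp_ul": est.conc,
                     "ci_low_cp_ul": est.ci_low, "ci_high_cp_ul": est.ci_high,
                     "fraction_pct": ""})
    if run.reference and run.reference in estimates \
            and estimates[run.reference].conc > 0 and run.target in estimates:
        frac = allele_fraction(estimates[run.target], estimates[run.reference])
        for r in rows:
            if r["channel"] == run.target:
                r["fraction_pct"] = frac.fraction_pct
    results_path = outdir / "results.csv"
    pd.DataFrame(rows).to_csv(results_path, index=False)
    _write_provenance(outdir, run.simulation)
    return {"sample": sample_dir, "ntc": ntc_dir, "table": table_path,
            "results": results_path}
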