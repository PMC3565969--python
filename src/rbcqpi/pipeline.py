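"""End-to-end orchestration: interferogram(s) in, cell table + summary out.

The stages run in the order the instrument would: demodulate -> unwrap ->
background subtraction -> global threshold -> connected-component labeling
-> volume/border filtering -> per-cell morphology -> population statistics.
File plumbing (TIFF in/out, CSV, key-value summary and manifest) lives here
so the science modules stay array-in/array-out.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import phantom, population, reconstruct, segment
from .exceptions import GridMismatchError, RbcQpiError
from .morphology import CellRecord, measure_cell
from .optics import OpticalConfig, phase_to_height
from .phantom import CellSpec, InterferogramModel, Scene
from .population import PopulationStats

log = logging.getLogger(__name__)


@dataclass
class AnalysisSettings:
    """Tunable knobs of the analysis pipeline."""

    tau_rad: float = 0.3              # global phase threshold
    connectivity: int = 8
    min_volume_fl: float = 20.0       # platelet exclusion
    filter_radius_frac: float = 0.7   # Hilbert window radius / carrier magnitude
    carrier: Optional[tuple[float, float]] = None  # None = auto-estimate
    min_object_px: int = 10           # 0 disables the speck pre-filter
    exclude_border: bool = True


@dataclass
class FrameResult:
    """Everything computed from one interferogram frame."""

    phase: reconstruct.PhaseMap
    labelmap: segment.LabelMap
    cells: list[segment.SegmentedCell]
    records: list[CellRecord]
    n_components: int
    carrier: tuple[float, float]


def analyze_frame(
    sample_img: np.ndarray,
    background_img: Optional[np.ndarray],
    config: OpticalConfig,
    settings: AnalysisSettings = AnalysisSettings(),
) -> FrameResult:
    """Run the full pipeline on one frame (arrays in, records out)."""
    pitch = config.pixel_pitch_um
    carrier = settings.carrier or reconstruct.estimate_carrier(sample_img)
    radius = settings.filter_radius_frac * float(np.hypot(*carrier))

    def _reconstruct(img: np.ndarray) -> reconstruct.PhaseMap:
        wrapped = reconstruct.demodulate(img, carrier, radius, pitch)
        return reconstruct.unwrap(wrapped)

    sample_phase = _reconstruct(sample_img)
    if background_img is not None:
        if np.shape(background_img) != np.shape(sample_img):
            raise GridMismatchError("sample and background dimensions differ")
        bg_phase = _reconstruct(background_img)
    else:
        log.warning("no background frame supplied; proceeding with a zero background")
        bg_phase = reconstruct.PhaseMap(
            np.zeros_like(sample_phase.values), pitch, wrapped=False
        )
    corrected = reconstruct.subtract_background(sample_phase, bg_phase)

    mask = segment.threshold_mask(corrected.values, settings.tau_rad)
    if settings.min_object_px > 0:
        mask = segment.remove_small_objects(
            mask, settings.min_object_px, settings.connectivity
        )
    labelmap = segment.label_components(mask, settings.connectivity)
    labelmap.threshold_rad = settings.tau_rad

    height = phase_to_height(corrected.values, config)
    cells = segment.extract_cells(
        labelmap,
        height,
        corrected.values,
        pitch,
        min_volume_fl=settings.min_volume_fl,
        exclude_border=settings.exclude_border,
    )
    records = [
        measure_cell(
            c.label, c.height_um, c.mask, c.phase, pitch, centroid_px=c.centroid_px
        )
        for c in cells
    ]
    return FrameResult(
        phase=corrected,
        labelmap=labelmap,
        cells=cells,
        records=records,
        n_components=labelmap.n_components,
        carrier=carrier,
    )


def analyze_frames(
    frames: Sequence[np.ndarray],
    background_img: Optional[np.ndarray],
    config: OpticalConfig,
    settings: AnalysisSettings = AnalysisSettings(),
) -> tuple[list[CellRecord], PopulationStats]:
    """Analyze a frame sequence; records are concatenated across frames."""
    records: list[CellRecord] = []
    for i, img in enumerate(frames):
        res = analyze_frame(img, background_img, config, settings)
        for r in res.records:
            r.id = len(records) + 1
            records.append(r)
        log.info("frame %d: %d cells kept", i, len(res.records))
    stats = population.summarize(records) if records else None
    return records, stats


# ---------------------------------------------------------------------------
# phantom convenience: population -> frames


def simulate_population_frames(
    specs: Sequence[CellSpec],
    shape_px: tuple[int, int],
    config: OpticalConfig,
    model: InterferogramModel,
    seed: int = 0,
    aberration_peak_rad: float = 0.5,
    n_dirt: int = 10,
    dirt_peak_rad: float = 1.0,
    max_frames: int = 200,
) -> list[tuple[Scene, np.ndarray, np.ndarray]]:
    """Distribute a cell population over as many frames as needed.

    Returns a list of ``(scene, sample_interferogram, background_interferogram)``
    triples; every spec is placed on exactly one frame.
    """
    rng = np.random.default_rng(seed)
    remaining = list(specs)
    out = []
    frame = 0
    while remaining:
        if frame >= max_frames:
            raise RbcQpiError(f"could not place all cells within {max_frames} frames")
        placed, remaining = phantom.place_cells(
            remaining, shape_px, config.pixel_pitch_um, rng
        )
        if not placed:
            raise RbcQpiError("no cell could be placed on an empty frame")
        scene = phantom.build_scene(
            specs=placed,
            shape_px=shape_px,
            config=config,
            aberration_peak_rad=aberration_peak_rad,
            n_dirt=n_dirt,
            dirt_peak_rad=dirt_peak_rad,
            seed=int(rng.integers(2**31 - 1)),
        )
        sample = phantom.synthesize_interferogram(
            scene, model, seed=int(rng.integers(2**31 - 1))
        )
        bg = phantom.make_background_frame(
            scene, model, seed=int(rng.integers(2**31 - 1))
        )
        out.append((scene, sample, bg))
        frame += 1
    return out


# ---------------------------------------------------------------------------
# file commands (used by the CLI)


def truths_to_frame(scenes: Sequence[Scene]) -> pd.DataFrame:
    rows = []
    for fi, scene in enumerate(scenes):
        for t in scene.truths:
            rows.append(
                {
                    "frame": fi,
                    "cell_id": t.id,
                    "shape": t.shape,
                    "true_volume_fl": t.volume_fl,
                    "true_surface_area_um2": t.surface_area_um2,
                    "centroid_row_px": t.centroid_row_px,
                    "centroid_col_px": t.centroid_col_px,
                    "is_platelet": t.is_platelet,
                }
            )
    return pd.DataFrame(rows)


def cmd_simulate(
    out_dir,
    config: OpticalConfig,
    n_cells: int = 20,
    mean_volume_fl: float = 90.0,
    rdw_percent: float = 15.0,
    platelet_fraction: float = 0.0,
    shape: str = "biconcave",
    shape_px: tuple[int, int] = (512, 512),
    model: InterferogramModel = InterferogramModel(),
    seed: int = 0,
) -> dict:
    """Generate a phantom dataset on disk: TIFF frames, truth CSV, configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mix = {shape: 1.0 - platelet_fraction}
    if platelet_fraction > 0:
        mix["platelet"] = platelet_fraction
    if n_cells > 0:
        specs = phantom.sample_population(
            n_cells, mean_volume_fl, rdw_percent, shape_mix=mix, seed=seed
        )
    else:
        specs = []
    if specs:
        triples = simulate_population_frames(
            specs, shape_px, config, model, seed=seed
        )
    else:  # background-only pair
        scene = phantom.build_scene([], shape_px, config, seed=seed)
        triples = [
            (
                scene,
                phantom.synthesize_interferogram(scene, model, seed=seed + 1),
                phantom.make_background_frame(scene, model, seed=seed + 2),
            )
        ]
    sample_paths = []
    for i, (_, sample, bg) in enumerate(triples):
        p = out / f"sample_{i:03d}.tif"
        tifffile.imwrite(p, sample)
        sample_paths.append(str(p))
        if i == 0:
            tifffile.imwrite(out / "background.tif", bg)
    truth = truths_to_frame([s for s, _, _ in triples])
    truth.to_csv(out / "truth.csv", index=False)
    config.to_file(out / "optics.yaml")
    scene_cfg = {
        "n_cells": n_cells,
        "mean_volume_fl": mean_volume_fl,
        "rdw_percent": rdw_percent,
        "platelet_fraction": platelet_fraction,
        "shape": shape,
        "shape_px": list(shape_px),
        "carrier_cpp": model.carrier_cpp,
        "fringe_contrast": model.fringe_contrast,
        "mean_intensity": model.mean_intensity,
        "noise_sd": model.noise_sd,
        "seed": seed,
        "n_frames": len(triples),
    }
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(scene_cfg, fh, sort_keys=False)
    return {
        "samples": sample_paths,
        "background": str(out / "background.tif"),
        "truth": str(out / "truth.csv"),
        "n_frames": len(triples),
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def cmd_analyze(
    sample_paths: Sequence,
    background_path,
    config: OpticalConfig,
    out_dir,
    settings: AnalysisSettings = AnalysisSettings(),
) -> dict:
    """Analyze interferogram files; write cells.csv, summary.txt and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        frames = [np.asarray(tifffile.imread(p)) for p in sample_paths]
        background = (
            np.asarray(tifffile.imread(background_path)) if background_path else None
        )
    except (OSError, ValueError) as exc:
        raise RbcQpiError(f"could not read input TIFF: {exc}") from exc

    records: list[CellRecord] = []
    record_frames: list[int] = []
    frame_rows = []
    timings = {}
    for i, img in enumerate(frames):
        t1 = time.perf_counter()
        res = analyze_frame(img, background, config, settings)
        timings[f"frame_{i:03d}_s"] = round(time.perf_counter() - t1, 4)
        for r in res.records:
            r.id = len(records) + 1
            records.append(r)
            record_frames.append(i)
        frame_rows.append((i, res.n_components, len(res.records)))

    cells_csv = out / "cells.csv"
    df = population.records_to_frame(records)
    df.insert(0, "frame", record_frames)
    with open(cells_csv, "w") as fh:
        fh.write(_CELL_CSV_HEADER)
        df.to_csv(fh, index=False)

    summary_path = out / "summary.txt"
    if records:
        stats = population.summarize(records)
        summary_path.write_text(population.format_summary(stats))
    else:
        stats = None
        summary_path.write_text("n_cells: 0\n")

    manifest = {
        "inputs": {
            "samples": [str(p) for p in sample_paths],
            "background": str(background_path) if background_path else None,
        },
        "config": {k: v for k, v in asdict(config).items() if v is not None},
        "settings": asdict(settings),
        "frames": [
            {"index": i, "components": nc, "cells_kept": nk}
            for i, nc, nk in frame_rows
        ],
        "n_cells_total": len(records),
        "timings_s": timings,
        "elapsed_s": round(time.perf_counter() - t0, 4),
        "outputs": {
            "cells_csv": str(cells_csv),
            "summary": str(summary_path),
            "cells_csv_sha256": _sha256(cells_csv),
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {"records": records, "stats": stats, "manifest": manifest}


_CELL_CSV_HEADER = (
    "# per-cell morphological parameters; units: um (lengths), um^2 (areas), "
    "fL (volumes), rad*px (integrated density)\n"
)


def cmd_recover(
    cells_csv,
    truth_csv,
    pixel_pitch_um: float,
    match_radius_um: float = 3.0,
) -> pd.DataFrame:
    """Match measured cells to phantom ground truth by nearest centroid.

    One row per truth cell: matched flag, measured vs true volume/SA and
    relative errors.  Unmatched truths (or platelets filtered out) simply
    carry ``matched=False``.
    """
    cells = pd.read_csv(cells_csv, comment="#")
    truth = pd.read_csv(truth_csv)
    per_frame = "frame" in cells.columns and "frame" in truth.columns
    rows = []
    used: set[int] = set()
    for _, t in truth.iterrows():
        best, best_d = None, np.inf
        for j, c in cells.iterrows():
            if j in used:
                continue
            if per_frame and c["frame"] != t["frame"]:
                continue
            d = (
                np.hypot(
                    c["centroid_row_px"] - t["centroid_row_px"],
                    c["centroid_col_px"] - t["centroid_col_px"],
                )
                * pixel_pitch_um
            )
            if d < best_d:
                best, best_d = j, d
        matched = best is not None and best_d <= match_radius_um
        row = {
            "truth_id": t.get("cell_id", None),
            "shape": t.get("shape", None),
            "is_platelet": bool(t.get("is_platelet", False)),
            "matched": matched,
            "match_distance_um": best_d if matched else np.nan,
            "true_volume_fl": t["true_volume_fl"],
        }
        if matched:
            used.add(best)
            c = cells.loc[best]
            row.update(
                measured_volume_fl=c["volume_fl"],
                volume_rel_err=(c["volume_fl"] - t["true_volume_fl"])
                / t["true_volume_fl"],
                measured_sa_um2=c["surface_area_um2"],
                sa_rel_err=(c["surface_area_um2"] - t["true_surface_area_um2"])
                / t["true_surface_area_um2"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
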