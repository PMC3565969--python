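"""Sample-level hematology indices and distributions from per-cell records.

MCV (mean corpuscular volume) is the arithmetic mean of the per-cell
volumes; RDW (red cell distribution width) is the coefficient of variation
of volume, ``100 * sd(V) / mean(V)``, using the sample (n-1) standard
deviation.  Distributions are reported as fixed-width histograms plus a
five-number-style summary (mean, sd, median, quartiles by linear
interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, NoCellsError, ParameterError
from .morphology import CellRecord

#: default histogram bin widths per parameter (same units as the parameter)
DEFAULT_BIN_WIDTHS = {
    "volume_fl": 1.0,
    "surface_area_um2": 5.0,
    "projected_area_um2": 2.0,
    "sphericity": 0.02,
    "mcd_um": 0.1,
    "equivalent_diameter_um": 0.2,
    "mean_thickness_um": 0.1,
}


def _volumes(records: Sequence[CellRecord]) -> np.ndarray:
    return np.array([r.volume_fl for r in records], dtype=float)


def mcv(records: Sequence[CellRecord]) -> float:
    """Mean corpuscular volume (fL): arithmetic mean of per-cell volumes."""
    if len(records) == 0:
        raise NoCellsError("MCV needs at least one cell")
    return float(_volumes(records).mean())


def rdw(records: Sequence[CellRecord]) -> float:
    """Red cell distribution width (%): 100 * sample-sd(volume) / mean(volume)."""
    if len(records) < 2:
        raise InsufficientDataError("RDW needs at least two cells")
    v = _volumes(records)
    return float(100.0 * v.std(ddof=1) / v.mean())


@dataclass
class Distribution:
    """Histogram + summary statistics of one per-cell parameter."""

    parameter: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


def distributions(
    records: Sequence[CellRecord],
    parameter: str,
    bin_width: float | None = None,
) -> Distribution:
    """Binned distribution and quartile summary of one CellRecord field."""
    if len(records) == 0:
        raise NoCellsError("distribution needs at least one cell")
    if parameter not in CellRecord.__dataclass_fields__:
        raise ParameterError(f"unknown parameter {parameter!r}")
    vals = np.array([getattr(r, parameter) for r in records], dtype=float)
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(parameter)
    if bin_width is None:
        bin_width = max(np.ptp(vals), 1e-12) / 20.0
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return Distribution(
        parameter=parameter,
        bin_edges=edges,
        counts=counts,
        n=len(vals),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


@dataclass
class PopulationStats:
    """Filtered per-sample aggregates: the compact numeric output of a run."""

    n_cells: int
    mcv_fl: float
    rdw_percent: float
    msa_um2: float
    mean_sphericity: float
    mean_mcd_um: float
    distributions: dict[str, Distribution] = field(default_factory=dict)


def summarize(
    records: Sequence[CellRecord],
    histogram_parameters: Iterable[str] = (
        "volume_fl",
        "surface_area_um2",
        "sphericity",
        "mcd_um",
        "equivalent_diameter_um",
    ),
) -> PopulationStats:
    """Aggregate CellRecords (already volume-filtered) into sample statistics."""
    if len(records) == 0:
        raise NoCellsError("cannot summarize an empty record set")
    dists = {p: distributions(records, p) for p in histogram_parameters}
    return PopulationStats(
        n_cells=len(records),
        mcv_fl=mcv(records),
        rdw_percent=rdw(records) if len(records) >= 2 else 0.0,
        msa_um2=float(np.mean([r.surface_area_um2 for r in records])),
        mean_sphericity=float(np.mean([r.sphericity for r in records])),
        mean_mcd_um=float(np.mean([r.mcd_um for r in records])),
        distributions=dists,
    )


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Per-cell records as a DataFrame with a stable column order."""
    cols = list(CellRecord.__dataclass_fields__)
    return pd.DataFrame([r.to_dict() for r in records], columns=cols)


def format_summary(stats: PopulationStats) -> str:
    """Key-value + histogram-table text rendering of the sample summary.

    This is the kilobyte-scale artifact of a run: numbers, not images.
    """
    lines = [
        f"n_cells: {stats.n_cells}",
        f"mcv_fl: {stats.mcv_fl:.3f}",
        f"rdw_percent: {stats.rdw_percent:.3f}",
        f"msa_um2: {stats.msa_um2:.3f}",
        f"mean_sphericity: {stats.mean_sphericity:.4f}",
        f"mean_mcd_um: {stats.mean_mcd_um:.4f}",
    ]
    for name, d in stats.distributions.items():
        lines.append("")
        lines.append(f"[histogram {name}]")
        lines.append(
            f"n: {d.n}  mean: {d.mean:.4f}  sd: {d.sd:.4f}  "
            f"q1: {d.q1:.4f}  median: {d.median:.4f}  q3: {d.q3:.4f}"
        )
        lines.append("bin_lo\tbin_hi\tcount")
        for lo, hi, c in zip(d.bin_edges[:-1], d.bin_edges[1:], d.counts):
            if c:
                lines.append(f"{lo:.4f}\t{hi:.4f}\t{int(c)}")
    return "\n".join(lines) + "\n"
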