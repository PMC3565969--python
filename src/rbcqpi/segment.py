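"""Cell segmentation: global threshold + label-equivalence connected components.

Segmentation is deliberately simple, matching a dilute blood smear in which
cells are well separated: a single global phase threshold separates cells
from background, and connected-component labeling assigns one id per cell.

The labeler is the data-parallel "label equivalence" scheme: each foreground
pixel starts with its own linear index as a provisional label, and the
algorithm alternates a *scanning* pass (every pixel adopts the minimum label
in its neighborhood, recording the discovered equivalence) with an
*analysis* pass (each label is resolved to the root of its equivalence
chain) until nothing changes.  The final partition is identical, up to
relabeling, to classic flood fill.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateCellError

log = logging.getLogger(__name__)


@dataclass
class LabelMap:
    """Integer label image: 0 = background, 1..K = connected objects."""

    labels: np.ndarray
    connectivity: int
    threshold_rad: float | None = None

    @property
    def n_components(self) -> int:
        return int(self.labels.max(initial=0))


def threshold_mask(phase_values: np.ndarray, tau: float) -> np.ndarray:
    """Foreground mask: pixels with phase >= tau (rad).

    Expects an unwrapped, background-subtracted phase image, where the empty
    field sits at zero and cells rise above it.
    """
    return np.asarray(phase_values, dtype=float) >= tau


def _neighbor_shifts(connectivity: int) -> list[tuple[int, int]]:
    if connectivity == 4:
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        return [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _shifted(arr: np.ndarray, dy: int, dx: int, fill: int) -> np.ndarray:
    """arr translated by (dy, dx) with constant fill — neighbor view per pixel."""
    out = np.full_like(arr, fill)
    src_y = slice(max(-dy, 0), arr.shape[0] - max(dy, 0))
    src_x = slice(max(-dx, 0), arr.shape[1] - max(dx, 0))
    dst_y = slice(max(dy, 0), arr.shape[0] - max(-dy, 0))
    dst_x = slice(max(dx, 0), arr.shape[1] - max(-dx, 0))
    out[dst_y, dst_x] = arr[src_y, src_x]
    return out


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Label-equivalence connected-component labeling of a binary mask.

    Raises
    ------
    TypeError
        if the input is not binary (bool, or integer 0/1).
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise TypeError("label_components expects a binary mask")
        mask = mask.astype(bool)
    shifts = _neighbor_shifts(connectivity)

    n = mask.size
    sentinel = n  # larger than any pixel index
    idx = np.arange(n, dtype=np.int64).reshape(mask.shape)
    labels = np.where(mask, idx, sentinel)
    # equivalence table over provisional labels (pixel indices)
    ref = np.arange(n + 1, dtype=np.int64)

    while True:
        # -- scanning: minimum label over self + foreground neighbors
        m = labels.copy()
        for dy, dx in shifts:
            np.minimum(m, _shifted(labels, dy, dx, sentinel), out=m)
        m = np.where(mask, m, sentinel)
        changed_px = m < labels
        if not changed_px.any():
            break
        # record equivalences: the old label's root now points at the new minimum
        np.minimum.at(ref, labels[changed_px], m[changed_px])
        # -- analysis: resolve each label to the root of its equivalence chain
        while True:
            ref2 = ref[ref]
            if np.array_equal(ref2, ref):
                break
            ref = ref2
        labels = np.where(mask, ref[labels], sentinel)

    # compact to 1..K
    out = np.zeros(mask.shape, dtype=np.int32)
    fg = labels[mask]
    if fg.size:
        roots, inv = np.unique(fg, return_inverse=True)
        out[mask] = inv.astype(np.int32) + 1
    return LabelMap(out, connectivity=connectivity)


def flood_fill_labels(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Independent flood-fill labeling (scipy), used as the reference partition."""
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    lab, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    return lab


def remove_small_objects(mask: np.ndarray, min_px: int = 10, connectivity: int = 8) -> np.ndarray:
    """Optional pre-filter killing noise specks below ``min_px`` pixels."""
    lab = flood_fill_labels(mask, connectivity)
    if lab.max() == 0:
        return np.asarray(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    removed = int((~keep[1:]).sum())
    if removed:
        log.info("removed %d objects smaller than %d px", removed, min_px)
    return keep[lab]


@dataclass
class SegmentedCell:
    """One labeled object: its mask and height crop, plus bookkeeping."""

    label: int
    mask: np.ndarray          # boolean crop
    height_um: np.ndarray     # height crop (um), same shape as mask
    phase: np.ndarray         # phase crop (rad)
    offset_px: tuple[int, int]  # (row, col) of crop origin in the full image
    centroid_px: tuple[float, float]  # (row, col) in full-image coordinates
    volume_fl: float


def extract_cells(
    labelmap: LabelMap,
    height_um: np.ndarray,
    phase_values: np.ndarray,
    pixel_pitch_um: float,
    min_volume_fl: float = 20.0,
    exclude_border: bool = True,
) -> list[SegmentedCell]:
    """Crop each labeled object and apply the volume / border filters.

    Objects with integrated volume below ``min_volume_fl`` (default 20 fL,
    the platelet-exclusion threshold) are dropped, as are objects touching
    the image border, whose volume would be truncated.
    """
    lab = labelmap.labels
    if lab.shape != np.shape(height_um):
        raise DegenerateCellError("label map and height map grids differ")
    cells: list[SegmentedCell] = []
    objects = ndimage.find_objects(lab)
    area = pixel_pitch_um**2
    ny, nx = lab.shape
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = lab[sl] == k
        if exclude_border and (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == ny or sl[1].stop == nx
        ):
            continue
        h = np.where(sub, np.maximum(np.asarray(height_um)[sl], 0.0), 0.0)
        vol = float(h.sum() * area)
        if vol < min_volume_fl:
            continue
        cy, cx = ndimage.center_of_mass(sub)
        cells.append(
            SegmentedCell(
                label=k,
                mask=sub,
                height_um=np.asarray(height_um)[sl].copy(),
                phase=np.asarray(phase_values)[sl].copy(),
                offset_px=(sl[0].start, sl[1].start),
                centroid_px=(cy + sl[0].start, cx + sl[1].start),
                volume_fl=vol,
            )
        )
    return cells
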