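"""Quantitative phase reconstruction from off-axis interferograms.

The two-step procedure: (i) Fourier/Hilbert demodulation — isolate the
first-order spectral lobe of the fringe pattern, shift it to baseband and
take the argument of the analytic signal, yielding the phase wrapped to
[-pi, pi); (ii) 2D phase unwrapping to restore the continuous field.  A
background frame (same optical path, no cells) is then subtracted to remove
static dirt and aberrations, and a global offset is fixed so the cell-free
background sits at zero phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_reliability

from .exceptions import GridMismatchError, LobeOverlapError, NoFringeError

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: pixels at each image edge excluded from accuracy guarantees
BORDER_MARGIN_PX = 16


def wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into [-pi, pi)."""
    return np.mod(np.asarray(phase, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass
class PhaseMap:
    """A 2D quantitative phase field (radians) on a pixel grid.

    ``wrapped`` marks values confined to [-pi, pi);
    ``background_subtracted`` marks maps ready for segmentation.
    """

    values: np.ndarray
    pixel_pitch_um: float
    wrapped: bool = False
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PhaseMap values must be 2D")
        if self.wrapped:
            v = self.values
            if v.size and (v.min() < -np.pi or v.max() >= np.pi):
                raise ValueError("wrapped PhaseMap must lie in [-pi, pi)")

    @property
    def shape(self):
        return self.values.shape


def estimate_carrier(interferogram: np.ndarray, dc_block_bins: int = 4) -> tuple[float, float]:
    """Locate the carrier (first-order lobe) frequency of an interferogram.

    Returns ``(u, v)`` in cycles/pixel along (columns, rows), taken from the
    dominant non-DC peak of the power spectrum restricted to the half-plane
    ``u > 0`` (or ``u == 0, v > 0``), which resolves the conjugate ambiguity.

    Raises
    ------
    NoFringeError
        if no peak rises at least 3x above the spectral noise floor
        (median non-DC magnitude).
    """
    img = np.asarray(interferogram, dtype=float)
    ny, nx = img.shape
    spec = np.fft.fft2(img - img.mean())
    mag = np.abs(spec)

    u = np.fft.fftfreq(nx)[None, :] * np.ones((ny, 1))
    v = np.fft.fftfreq(ny)[:, None] * np.ones((1, nx))

    # exclude the DC neighborhood and the conjugate half-plane
    near_dc = (np.abs(u) * nx <= dc_block_bins) & (np.abs(v) * ny <= dc_block_bins)
    half = (u > 0) | ((u == 0) & (v > 0))
    search = half & ~near_dc
    if not search.any():
        raise NoFringeError("image too small to search for a carrier")

    floor = np.median(mag[~near_dc]) if (~near_dc).any() else 0.0
    idx = np.argmax(np.where(search, mag, -np.inf))
    iy, ix = np.unravel_index(idx, mag.shape)
    peak = mag[iy, ix]
    if peak <= 3.0 * floor or peak <= 0:
        raise NoFringeError(
            f"no first-order lobe above noise floor (peak {peak:.3g}, floor {floor:.3g})"
        )
    return float(u[iy, ix]), float(v[iy, ix])


def demodulate(
    interferogram: np.ndarray,
    carrier: tuple[float, float],
    filter_radius: float | None = None,
    pixel_pitch_um: float = 1.0,
) -> PhaseMap:
    """Fourier demodulation of an off-axis interferogram.

    Isolates the first-order lobe with a circular hard window of
    ``filter_radius`` (cycles/pixel; default half the carrier magnitude),
    shifts it to baseband by an integer-bin spectral roll, inverse
    transforms, and returns the per-pixel argument wrapped to [-pi, pi).
    """
    img = np.asarray(interferogram, dtype=float)
    ny, nx = img.shape
    cu, cv = carrier
    cmag = float(np.hypot(cu, cv))
    if cmag <= 0:
        raise NoFringeError("carrier magnitude must be > 0")
    if filter_radius is None:
        filter_radius = cmag / 2.0
    if filter_radius >= cmag:
        raise LobeOverlapError(
            f"filter radius {filter_radius:.4g} must be < carrier magnitude {cmag:.4g}"
        )

    spec = np.fft.fft2(img)
    u = np.fft.fftfreq(nx)[None, :]
    v = np.fft.fftfreq(ny)[:, None]
    window = (u - cu) ** 2 + (v - cv) ** 2 <= filter_radius**2
    lobe = spec * window

    # shift lobe to baseband: integer-bin roll (exact when the carrier sits
    # on an FFT bin; any sub-bin residual tilt cancels in background subtraction)
    shift_x = int(np.round(cu * nx))
    shift_y = int(np.round(cv * ny))
    lobe = np.roll(lobe, (-shift_y, -shift_x), axis=(0, 1))
    analytic = np.fft.ifft2(lobe)
    return PhaseMap(wrap(np.angle(analytic)), pixel_pitch_um, wrapped=True)


def _count_residues(wrapped: np.ndarray) -> int:
    """Count phase residues (non-zero curl of the wrapped gradient)."""
    dx = wrap(np.diff(wrapped, axis=1))
    dy = wrap(np.diff(wrapped, axis=0))
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    charges = np.round(loop / TWO_PI)
    return int(np.count_nonzero(charges))


def unwrap(wrapped: PhaseMap) -> PhaseMap:
    """Unwrap a wrapped phase map.

    Uses reliability-ordered (quality-guided) unwrapping, then snaps the
    result back onto the congruence contract: output equals input plus an
    exact integer multiple of 2*pi at every pixel.  Residue-laden inputs are
    unwrapped best-effort; the residue count is logged.
    """
    if not wrapped.wrapped:
        raise ValueError("unwrap expects a wrapped PhaseMap")
    w = wrapped.values
    n_res = _count_residues(w)
    if n_res:
        log.warning("phase field contains %d residues; unwrapping best-effort", n_res)
    est = np.asarray(_unwrap_reliability(w))
    k = np.round((est - w) / TWO_PI)
    out = w + TWO_PI * k
    return replace(wrapped, values=out, wrapped=False)


def subtract_background(sample: PhaseMap, background: PhaseMap, nbins: int = 128) -> PhaseMap:
    """Pixel-wise sample-minus-background phase with the global offset removed.

    The offset is fixed by the mode of a coarse histogram of the difference:
    in a dilute smear the cell-free background dominates, so the modal phase
    is the empty-field level and is mapped to zero.
    """
    if sample.shape != background.shape:
        raise GridMismatchError(f"grid mismatch: {sample.shape} vs {background.shape}")
    if sample.wrapped or background.wrapped:
        raise ValueError("subtract_background expects unwrapped inputs")
    diff = sample.values - background.values
    offset = _modal_level(diff, nbins)
    return PhaseMap(
        diff - offset,
        sample.pixel_pitch_um,
        wrapped=False,
        background_subtracted=True,
    )


def _modal_level(values: np.ndarray, nbins: int) -> float:
    """Modal value of a field, refined as the median inside the modal bin +/- 1."""
    flat = values.ravel()
    counts, edges = np.histogram(flat, bins=nbins)
    i = int(np.argmax(counts))
    lo, hi = edges[max(i - 1, 0)], edges[min(i + 2, nbins)]
    inside = flat[(flat >= lo) & (flat <= hi)]
    return float(np.median(inside)) if inside.size else float(np.median(flat))
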