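"""Per-cell morphological parameters from a segmented height patch.

The measured quantities, per cell:

* projected area ``PA`` (um^2) — pixel count times pixel area;
* equivalent circular diameter ``2*sqrt(PA/pi)`` (um);
* volume ``V`` (fL) — height integrated over the projected area;
* surface area ``SA`` (um^2) — Monge quadrature of the top surface,
  ``dA = sqrt(1 + h_x^2 + h_y^2) dx dy``, plus PA for the flat bottom
  (the cell lies on the coverslip);
* sphericity ``psi = pi^(1/3) (6V)^(2/3) / SA`` — 1 for a sphere;
* minimum cylindrical diameter ``MCD`` — diameter of the sphero-cylinder
  (cylinder with hemispherical caps) with the cell's SA and V, the smallest
  capillary the cell can traverse without changing SA or V; smallest
  positive root of ``pi D^3 - 3 SA D + 12 V = 0``;
* and the extended set: perimeter, eccentricity, thickness extrema/mean,
  circularity, integrated (phase) density, and variance/skewness/kurtosis of
  the height distribution.

Negative heights inside a mask (reconstruction noise) are clamped to zero;
the per-cell clamp count is retained on the record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import optimize
from skimage.measure import perimeter as _perimeter_contour
from skimage.measure import perimeter_crofton as _perimeter_crofton

from .exceptions import DegenerateCellError, InfeasibleShapeError

log = logging.getLogger(__name__)


@dataclass
class CellRecord:
    """The full morphological parameter vector of one segmented cell."""

    id: int
    projected_area_um2: float
    equivalent_diameter_um: float
    volume_fl: float
    surface_area_um2: float
    sphericity: float
    mcd_um: float
    perimeter_um: float
    eccentricity: float
    min_thickness_um: float
    max_thickness_um: float
    mean_thickness_um: float
    circularity: float
    integrated_density_rad_px: float
    height_variance_um2: float
    height_skewness: float
    height_kurtosis: float
    centroid_row_px: float
    centroid_col_px: float
    height_moments_degenerate: bool = False
    clamped_px: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# elementary measures


def projected_area(mask: np.ndarray, pixel_pitch_um: float) -> float:
    """Projected area: foreground pixel count times pixel area (um^2)."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise DegenerateCellError("empty mask has no projected area")
    return n * pixel_pitch_um**2


def equivalent_diameter(pa_um2: float) -> float:
    """Diameter of the circular disk with the cell's projected area (um)."""
    if pa_um2 <= 0:
        raise DegenerateCellError("projected area must be > 0")
    return 2.0 * np.sqrt(pa_um2 / np.pi)


def cell_volume(height_um: np.ndarray, mask: np.ndarray, pixel_pitch_um: float) -> float:
    """Volume (fL = um^3): height integrated over the projected area.

    Negative heights inside the mask are clamped to zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateCellError("empty mask has no volume")
    h = np.asarray(height_um, dtype=float)[mask]
    n_neg = int(np.count_nonzero(h < 0))
    if n_neg:
        log.debug("clamped %d negative height pixels to 0", n_neg)
    return float(np.clip(h, 0.0, None).sum() * pixel_pitch_um**2)


def cell_surface_area(height_um: np.ndarray, mask: np.ndarray, pixel_pitch_um: float) -> float:
    """Monge-parameterization surface area (um^2): top quadrature + PA bottom.

    Gradients use central differences inside the mask and one-sided
    differences at mask edges (height outside the mask treated as 0, the
    coverslip level).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateCellError("empty mask has no surface area")
    h = np.where(mask, np.clip(np.asarray(height_um, dtype=float), 0.0, None), 0.0)
    hx, hy = _masked_gradients(h, mask, pixel_pitch_um)
    da = np.sqrt(1.0 + hx**2 + hy**2) * pixel_pitch_um**2
    top = float(da[mask].sum())
    return top + projected_area(mask, pixel_pitch_um)


def _masked_gradients(h: np.ndarray, mask: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Central differences where both neighbors are in the mask, one-sided at edges."""
    grads = []
    for axis in (1, 0):  # x (cols), y (rows)
        fwd = np.roll(h, -1, axis=axis)
        bwd = np.roll(h, 1, axis=axis)
        m_fwd = np.roll(mask, -1, axis=axis)
        m_bwd = np.roll(mask, 1, axis=axis)
        # np.roll wraps around; edge rows/cols get one-sided treatment below,
        # so mark wrapped neighbors as outside
        edge_f = np.zeros_like(mask)
        edge_b = np.zeros_like(mask)
        if axis == 1:
            edge_f[:, -1] = True
            edge_b[:, 0] = True
        else:
            edge_f[-1, :] = True
            edge_b[0, :] = True
        m_fwd = m_fwd & ~edge_f
        m_bwd = m_bwd & ~edge_b
        central = m_fwd & m_bwd
        g = np.zeros_like(h)
        g[central] = (fwd[central] - bwd[central]) / (2.0 * pitch)
        only_f = m_fwd & ~m_bwd
        g[only_f] = (fwd[only_f] - h[only_f]) / pitch
        only_b = m_bwd & ~m_fwd
        g[only_b] = (h[only_b] - bwd[only_b]) / pitch
        # isolated in this axis: gradient taken as the drop to the coverslip
        lone = ~m_fwd & ~m_bwd
        g[lone] = h[lone] / pitch
        grads.append(g)
    hx, hy = grads
    return hx, hy


# ---------------------------------------------------------------------------
# shape indices from SA and V


def sphericity(volume_fl: float, surface_area_um2: float) -> float:
    """Sphericity index: surface area of the equal-volume sphere over SA."""
    if volume_fl <= 0 or surface_area_um2 <= 0:
        raise DegenerateCellError("sphericity needs V > 0 and SA > 0")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_fl) ** (2.0 / 3.0) / surface_area_um2)


def minimum_cylindrical_diameter(volume_fl: float, surface_area_um2: float) -> float:
    """Smallest positive root D of ``pi D^3 - 3 SA D + 12 V = 0`` (um).

    D is the diameter of the sphero-cylinder with the cell's surface area
    and volume — the narrowest capillary the cell can squeeze through at
    fixed SA and V.  Inputs with sphericity > 1 admit no real deformation.
    """
    if volume_fl <= 0 or surface_area_um2 <= 0:
        raise DegenerateCellError("MCD needs V > 0 and SA > 0")
    psi = sphericity(volume_fl, surface_area_um2)
    coeffs = [np.pi, 0.0, -3.0 * surface_area_um2, 12.0 * volume_fl]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    pos = real[real > 0]
    if pos.size == 0:
        # sphericity a hair above 1 happens on discretized near-spheres;
        # the limiting sphero-cylinder is the equal-volume sphere
        if psi <= 1.0 + 1e-3:
            return float((6.0 * volume_fl / np.pi) ** (1.0 / 3.0))
        raise InfeasibleShapeError(
            f"no sphero-cylinder exists for V={volume_fl:.4g} fL, "
            f"SA={surface_area_um2:.4g} um^2 (sphericity {psi:.4g} > 1)"
        )
    return float(pos.min())


# ---------------------------------------------------------------------------
# extended parameters

_PERIMETER_METHODS = {
    "contour": lambda m: _perimeter_contour(m, neighborhood=4),
    "crofton": lambda m: _perimeter_crofton(m, directions=4),
    "crack": lambda m: _crack_length(m),
}


def _crack_length(mask: np.ndarray) -> float:
    """Pixel-edge (crack) boundary length in pixel units."""
    m = np.asarray(mask, dtype=bool)
    p = np.pad(m, 1)
    exposed = 0
    for axis in (0, 1):
        d = np.diff(p.astype(np.int8), axis=axis)
        exposed += int(np.abs(d).sum())
    return float(exposed)


def mask_perimeter(mask: np.ndarray, pixel_pitch_um: float, method: str = "crofton") -> float:
    """Boundary length of the mask (um).

    ``crofton`` (default, 4-direction Crofton formula) is essentially
    unbiased on smooth convex shapes; ``contour`` (weighted contour length)
    and ``crack`` (pixel-edge length) are alternatives with different
    discretization behavior.
    """
    try:
        fn = _PERIMETER_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown perimeter method {method!r}") from None
    return float(fn(np.asarray(mask, dtype=bool))) * pixel_pitch_um


def mask_eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the ellipse with the mask's second central moments."""
    ys, xs = np.nonzero(mask)
    if ys.size < 4:
        raise DegenerateCellError("eccentricity needs at least 4 pixels")
    x = xs - xs.mean()
    y = ys - ys.mean()
    # +1/12 per axis: moments of a unit square pixel
    mxx = np.mean(x * x) + 1.0 / 12.0
    myy = np.mean(y * y) + 1.0 / 12.0
    mxy = np.mean(x * y)
    common = np.sqrt((mxx - myy) ** 2 + 4.0 * mxy**2)
    lam_max = (mxx + myy + common) / 2.0
    lam_min = (mxx + myy - common) / 2.0
    if lam_max <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - lam_min / lam_max)))


def extended_parameters(
    height_um: np.ndarray,
    mask: np.ndarray,
    phase_rad: np.ndarray,
    pixel_pitch_um: float,
    perimeter_method: str = "crofton",
) -> dict:
    """The remaining CellRecord fields (perimeter, moments, thickness, ...).

    Height-distribution moments use the population (n) normalization and
    raw (non-excess) kurtosis.  A constant height field has undefined
    skewness/kurtosis; both are reported as 0 with the degenerate flag set.
    """
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx < 4:
        raise DegenerateCellError("extended parameters need a mask of >= 4 px")
    h = np.clip(np.asarray(height_um, dtype=float)[mask], 0.0, None)
    pa = projected_area(mask, pixel_pitch_um)
    per = mask_perimeter(mask, pixel_pitch_um, perimeter_method)
    var = float(np.var(h))  # population normalization
    degenerate = var <= 1e-300
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (h - h.mean()) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    return {
        "perimeter_um": per,
        "eccentricity": mask_eccentricity(mask),
        "min_thickness_um": float(h.min()),
        "max_thickness_um": float(h.max()),
        "mean_thickness_um": float(h.mean()),
        "circularity": float(4.0 * np.pi * pa / per**2),
        "integrated_density_rad_px": float(np.asarray(phase_rad, dtype=float)[mask].sum()),
        "height_variance_um2": var,
        "height_skewness": skew,
        "height_kurtosis": kurt,
        "height_moments_degenerate": degenerate,
    }


def measure_cell(
    cell_id: int,
    height_um: np.ndarray,
    mask: np.ndarray,
    phase_rad: np.ndarray,
    pixel_pitch_um: float,
    centroid_px: tuple[float, float] = (np.nan, np.nan),
    perimeter_method: str = "crofton",
) -> CellRecord:
    """Assemble the full CellRecord for one segmented cell."""
    mask = np.asarray(mask, dtype=bool)
    h_raw = np.asarray(height_um, dtype=float)
    clamped = int(np.count_nonzero(h_raw[mask] < 0))
    pa = projected_area(mask, pixel_pitch_um)
    vol = cell_volume(h_raw, mask, pixel_pitch_um)
    sa = cell_surface_area(h_raw, mask, pixel_pitch_um)
    ext = extended_parameters(h_raw, mask, phase_rad, pixel_pitch_um, perimeter_method)
    try:
        mcd = minimum_cylindrical_diameter(vol, sa)
    except InfeasibleShapeError:
        # wall-dominated shapes whose quadrature SA falls below the sphere
        # bound have no sphero-cylinder; keep the record, flag the MCD
        log.warning("cell %d: sphericity above 1, MCD undefined (NaN)", cell_id)
        mcd = float("nan")
    return CellRecord(
        id=cell_id,
        projected_area_um2=pa,
        equivalent_diameter_um=equivalent_diameter(pa),
        volume_fl=vol,
        surface_area_um2=sa,
        sphericity=sphericity(vol, sa),
        mcd_um=mcd,
        centroid_row_px=float(centroid_px[0]),
        centroid_col_px=float(centroid_px[1]),
        clamped_px=clamped,
        **ext,
    )
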