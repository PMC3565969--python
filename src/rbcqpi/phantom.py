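"""Ground-truthed synthetic scenes: RBC phase objects and their off-axis
interferograms.

This module stands in for the interferometric microscope.  A *scene* is a
set of non-overlapping cell thickness profiles (biconcave disc, spherocyte,
flat disc, platelet) on a pixel grid, plus a smooth aberration field and
static dirt blobs shared between the sample frame and a cell-free background
frame.  The interferogram is the classic off-axis fringe pattern

    I(x, y) = A * (1 + m * cos(2*pi*u0*x + phi(x, y))) + noise,

quantized to the camera bit depth.  Each scene carries per-cell ground truth
(volume, surface area from fine-grid quadrature, centroid) so that recovery
error of the full pipeline is measurable cell by cell.

The biconcave profile is the Evans-Fung parametric normal-RBC shape
``h(r) = sqrt(1-(r/R)^2) * (C0 + C2 (r/R)^2 + C4 (r/R)^4)`` with the height
rescaled to hit the requested volume exactly on the discrete grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import FringeSamplingError, ParameterError, PlacementError
from .optics import OpticalConfig, height_to_phase

# Evans-Fung normal-RBC biconcave profile coefficients (um), for R0 = 3.91 um
EVANS_FUNG_C0 = 0.81
EVANS_FUNG_C2 = 7.83
EVANS_FUNG_C4 = -4.39

#: platelet-exclusion volume threshold (fL)
PLATELET_VOLUME_LIMIT_FL = 20.0

RBC_SHAPES = ("biconcave", "spherocyte", "flat_disc")
ALL_SHAPES = RBC_SHAPES + ("platelet",)


@dataclass
class CellSpec:
    """One phantom cell: where it sits, what shape, and its intended volume."""

    shape: str
    target_volume_fl: float
    radius_um: float
    center_xy_um: Optional[tuple[float, float]] = None  # (x, y); None = unplaced
    rotation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ALL_SHAPES:
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.target_volume_fl <= 0:
            raise ParameterError("target_volume_fl must be > 0")
        if self.radius_um <= 0:
            raise ParameterError("radius_um must be > 0")
        if self.shape == "platelet" and self.target_volume_fl >= PLATELET_VOLUME_LIMIT_FL:
            raise ParameterError(
                f"platelet volume must be < {PLATELET_VOLUME_LIMIT_FL} fL, "
                f"got {self.target_volume_fl}"
            )


@dataclass
class CellTruth:
    """Ground truth for one placed cell, from the analytic height field."""

    id: int
    shape: str
    volume_fl: float
    surface_area_um2: float
    centroid_row_px: float
    centroid_col_px: float
    radius_um: float
    is_platelet: bool


@dataclass
class Scene:
    """A full synthetic field of view with per-cell ground truth."""

    shape_px: tuple[int, int]
    config: OpticalConfig
    cells: list[CellSpec]
    truths: list[CellTruth]
    cell_phase: np.ndarray        # sum of all cell phase patches (rad)
    background_phase: np.ndarray  # aberration + dirt (rad), shared with background frame

    @property
    def true_phase(self) -> np.ndarray:
        return self.cell_phase + self.background_phase


@dataclass
class InterferogramModel:
    """Carrier, contrast, intensity and noise of the simulated camera frame."""

    carrier_cpp: float = 0.25        # cycles/pixel along x; >= 3 px per fringe
    fringe_contrast: float = 0.8
    mean_intensity: float = 2000.0   # counts
    noise_sd: float = 20.0           # additive Gaussian sd (counts)
    bit_depth: int = 16
    poisson: bool = False            # optional shot-noise flag

    def __post_init__(self) -> None:
        if self.carrier_cpp <= 0 or self.carrier_cpp > 1.0 / 3.0 + 1e-12:
            raise FringeSamplingError(
                f"carrier {self.carrier_cpp} cycles/px violates the "
                "3-pixels-per-fringe minimum"
            )
        if not (0.0 < self.fringe_contrast <= 1.0):
            raise ParameterError("fringe_contrast must be in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# analytic thickness profiles


def _profile(spec: CellSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Unit-scale thickness profile h(r) in um for r in um (0 outside radius)."""
    R = spec.radius_um
    if spec.shape == "biconcave":

        def h(r):
            rho2 = np.clip((r / R) ** 2, 0.0, 1.0)
            inside = r < R
            prof = np.sqrt(1.0 - rho2) * (
                EVANS_FUNG_C0 + EVANS_FUNG_C2 * rho2 + EVANS_FUNG_C4 * rho2**2
            )
            return np.where(inside, prof, 0.0)

    elif spec.shape == "spherocyte":
        # compact high-sphericity dome with bounded rim slope; a literal
        # sphere's chord profile has a singular rim that neither the finite
        # fringe bandwidth nor the Monge quadrature can represent
        def h(r):
            rho2 = np.clip((r / R) ** 2, 0.0, 1.0)
            return np.where(r < R, (1.0 - rho2) ** 1.5, 0.0)

    elif spec.shape == "flat_disc":

        def h(r):
            return np.where(r < R, 1.0, 0.0)

    else:  # platelet: low parabolic dome
        def h(r):
            rho2 = np.clip((r / R) ** 2, 0.0, 1.0)
            return np.where(r < R, 1.0 - rho2, 0.0)

    return h


def make_rbc_height(
    spec: CellSpec, shape_px: tuple[int, int], pixel_pitch_um: float
) -> np.ndarray:
    """Rasterize one cell's thickness profile onto the full grid (um).

    The height is rescaled so the *discrete* integral equals
    ``target_volume_fl`` exactly; the rotation parameter is applied to the
    sampling coordinates (a no-op for these circularly symmetric shapes).
    """
    if spec.center_xy_um is None:
        raise PlacementError("cell has no center; place it first")
    ny, nx = shape_px
    R = spec.radius_um
    if 2.0 * R / pixel_pitch_um < 10.0:
        raise PlacementError(
            f"cell spans {2*R/pixel_pitch_um:.1f} px; need >= 10 px across"
        )
    cx, cy = spec.center_xy_um
    if not (R <= cx <= nx * pixel_pitch_um - R and R <= cy <= ny * pixel_pitch_um - R):
        raise PlacementError(f"cell at ({cx:.1f}, {cy:.1f}) um extends outside the grid")

    # rasterize only the bounding box
    x = (np.arange(nx) + 0.5) * pixel_pitch_um - cx
    y = (np.arange(ny) + 0.5) * pixel_pitch_um - cy
    jx = np.nonzero(np.abs(x) <= R + pixel_pitch_um)[0]
    jy = np.nonzero(np.abs(y) <= R + pixel_pitch_um)[0]
    xv, yv = np.meshgrid(x[jx], y[jy])
    c, s = np.cos(spec.rotation_rad), np.sin(spec.rotation_rad)
    xr = c * xv + s * yv
    yr = -s * xv + c * yv
    r = np.hypot(xr, yr)
    patch = _profile(spec)(r)
    total = patch.sum() * pixel_pitch_um**2
    if total <= 0:
        raise PlacementError("cell rasterized to zero volume")
    patch *= spec.target_volume_fl / total

    out = np.zeros(shape_px)
    out[np.ix_(jy, jx)] = patch
    return out


def make_rbc_phase(
    spec: CellSpec, shape_px: tuple[int, int], config: OpticalConfig
) -> np.ndarray:
    """Phase patch (rad) induced by one cell on the full grid."""
    h = make_rbc_height(spec, shape_px, config.pixel_pitch_um)
    return height_to_phase(h, config)


def _fine_grid_truth(
    spec: CellSpec, pixel_pitch_um: float, fine_factor: int = 4
) -> tuple[float, float]:
    """(volume fL, surface area um^2) of the analytic profile by fine quadrature.

    The height scale matches the coarse rasterization (discrete-volume
    normalization), so truth volume equals the target by construction; the
    surface area integrates the Monge area element of the oversampled
    profile plus the flat base.
    """
    R = spec.radius_um
    pitch = pixel_pitch_um / fine_factor
    n = int(np.ceil(2 * (R + pitch) / pitch))
    ax = (np.arange(n) - (n - 1) / 2) * pitch
    xv, yv = np.meshgrid(ax, ax)
    r = np.hypot(xv, yv)
    h = _profile(spec)(r)
    vol = h.sum() * pitch**2
    h *= spec.target_volume_fl / vol
    hy, hx = np.gradient(h, pitch)
    support = h > 0
    top = (np.sqrt(1.0 + hx**2 + hy**2) * pitch**2)[support].sum()
    base = support.sum() * pitch**2
    return spec.target_volume_fl, float(top + base)


# ---------------------------------------------------------------------------
# scene assembly


def place_cells(
    specs: Sequence[CellSpec],
    shape_px: tuple[int, int],
    pixel_pitch_um: float,
    rng: np.random.Generator,
    margin_um: float = 1.0,
    border_um: float = 3.0,
    max_tries: int = 300,
) -> tuple[list[CellSpec], list[CellSpec]]:
    """Assign random non-overlapping centers to as many specs as fit.

    Returns ``(placed, unplaced)``; the unplaced remainder can go on the
    next frame.  Cells are kept ``margin_um`` apart edge-to-edge and
    ``border_um`` clear of the image border.
    """
    ny, nx = shape_px
    W, H = nx * pixel_pitch_um, ny * pixel_pitch_um
    placed: list[CellSpec] = []
    unplaced: list[CellSpec] = []
    taken: list[tuple[float, float, float]] = []  # (x, y, exclusion radius)
    for spec in specs:
        R = spec.radius_um
        lo_x, hi_x = R + border_um, W - R - border_um
        lo_y, hi_y = R + border_um, H - R - border_um
        if lo_x >= hi_x or lo_y >= hi_y:
            raise PlacementError("cell too large for the grid")
        ok = False
        for _ in range(max_tries):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if all(
                np.hypot(cx - tx, cy - ty) > R + tr + margin_um for tx, ty, tr in taken
            ):
                ok = True
                break
        if ok:
            placed.append(
                CellSpec(
                    shape=spec.shape,
                    target_volume_fl=spec.target_volume_fl,
                    radius_um=spec.radius_um,
                    center_xy_um=(cx, cy),
                    rotation_rad=float(rng.uniform(0, 2 * np.pi)),
                )
            )
            taken.append((cx, cy, R))
        else:
            unplaced.append(spec)
    return placed, unplaced


def _aberration_field(shape_px, peak_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order background phase: random quadratic + gentle sinusoid."""
    ny, nx = shape_px
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    c = rng.standard_normal(6)
    f = c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y
    f = f + 0.5 * np.sin(2 * np.pi * (0.4 * x + 0.3 * y) + rng.uniform(0, 2 * np.pi))
    span = np.ptp(f)
    if span > 0 and peak_rad > 0:
        f = (f - f.min()) / span * peak_rad
    else:
        f = np.zeros(shape_px)
    return f


def _dirt_field(
    shape_px, n_dirt: int, peak_rad: float, rng: np.random.Generator
) -> np.ndarray:
    """Static dirt: small Gaussian phase blobs, identical in both frames."""
    ny, nx = shape_px
    out = np.zeros(shape_px)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _ in range(n_dirt):
        cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
        sigma = rng.uniform(1.5, 5.0)
        amp = rng.uniform(0.2, 1.0) * peak_rad
        out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return out


def build_scene(
    specs: Sequence[CellSpec],
    shape_px: tuple[int, int],
    config: OpticalConfig,
    aberration_peak_rad: float = 0.5,
    n_dirt: int = 10,
    dirt_peak_rad: float = 1.0,
    seed: int = 0,
) -> Scene:
    """Render placed cell specs into a Scene with ground-truth bookkeeping."""
    rng = np.random.default_rng(seed)
    pitch = config.pixel_pitch_um
    cell_phase = np.zeros(shape_px)
    truths: list[CellTruth] = []
    for i, spec in enumerate(specs, start=1):
        h = make_rbc_height(spec, shape_px, pitch)
        cell_phase += height_to_phase(h, config)
        vol, sa = _fine_grid_truth(spec, pitch)
        cx, cy = spec.center_xy_um
        truths.append(
            CellTruth(
                id=i,
                shape=spec.shape,
                volume_fl=vol,
                surface_area_um2=sa,
                centroid_row_px=cy / pitch - 0.5,
                centroid_col_px=cx / pitch - 0.5,
                radius_um=spec.radius_um,
                is_platelet=spec.shape == "platelet",
            )
        )
    background = _aberration_field(shape_px, aberration_peak_rad, rng) + _dirt_field(
        shape_px, n_dirt, dirt_peak_rad, rng
    )
    return Scene(
        shape_px=tuple(shape_px),
        config=config,
        cells=list(specs),
        truths=truths,
        cell_phase=cell_phase,
        background_phase=background,
    )


# ---------------------------------------------------------------------------
# interferogram synthesis


def _render(phase: np.ndarray, model: InterferogramModel, seed: int) -> np.ndarray:
    ny, nx = phase.shape
    x = np.arange(nx)[None, :]
    carrier = 2.0 * np.pi * model.carrier_cpp * x
    ideal = model.mean_intensity * (
        1.0 + model.fringe_contrast * np.cos(carrier + phase)
    )
    rng = np.random.default_rng(seed)
    if model.poisson:
        img = rng.poisson(np.clip(ideal, 0, None)).astype(float)
    else:
        img = ideal.copy()
    if model.noise_sd > 0:
        img = img + rng.normal(0.0, model.noise_sd, size=ideal.shape)
    full = 2**model.bit_depth - 1
    return np.clip(np.round(img), 0, full).astype(np.uint16)


def synthesize_interferogram(
    scene: Scene, model: InterferogramModel, seed: int = 0
) -> np.ndarray:
    """Off-axis interferogram of the full scene (cells + background), uint16."""
    return _render(scene.true_phase, model, seed)


def make_background_frame(
    scene: Scene, model: InterferogramModel, seed: int = 1
) -> np.ndarray:
    """Cell-free reference frame: same aberration and dirt, no cells."""
    return _render(scene.background_phase, model, seed)


# ---------------------------------------------------------------------------
# population sampling


def sample_population(
    n: int,
    mean_volume_fl: float = 90.0,
    rdw_percent: float = 15.0,
    shape_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    rbc_radius_um: float = 3.91,
    rbc_radius_sd_um: float = 0.15,
    platelet_volume_fl: float = 9.0,
    platelet_volume_sd_fl: float = 2.0,
    platelet_radius_um: float = 1.8,
) -> list[CellSpec]:
    """Draw a cell population with a target mean volume and RDW.

    RBC volumes follow a normal law with ``sd = rdw_percent/100 * mean``,
    truncated above the 20 fL platelet limit; platelet volumes stay below
    it.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if rdw_percent < 0:
        raise ParameterError("rdw_percent must be >= 0")
    shape_mix = dict(shape_mix or {"biconcave": 1.0})
    bad = set(shape_mix) - set(ALL_SHAPES)
    if bad:
        raise ParameterError(f"unknown shapes in mix: {sorted(bad)}")
    probs = np.array(list(shape_mix.values()), dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ParameterError("shape_mix fractions must be non-negative and sum > 0")
    probs = probs / probs.sum()

    sd = rdw_percent / 100.0 * mean_volume_fl
    if sd > 0:
        frac_ok = stats.norm.sf(PLATELET_VOLUME_LIMIT_FL, loc=mean_volume_fl, scale=sd)
    else:
        frac_ok = 1.0 if mean_volume_fl > PLATELET_VOLUME_LIMIT_FL else 0.0
    if frac_ok < 0.01:
        raise ParameterError(
            f"mean {mean_volume_fl} fL with RDW {rdw_percent}% leaves "
            f"essentially no mass above the {PLATELET_VOLUME_LIMIT_FL} fL cut"
        )

    rng = np.random.default_rng(seed)
    shapes = rng.choice(list(shape_mix.keys()), size=n, p=probs)
    specs: list[CellSpec] = []
    for shape in shapes:
        if shape == "platelet":
            v = float(
                np.clip(
                    rng.normal(platelet_volume_fl, platelet_volume_sd_fl),
                    2.0,
                    PLATELET_VOLUME_LIMIT_FL - 0.5,
                )
            )
            radius = float(np.clip(rng.normal(platelet_radius_um, 0.15), 1.2, 2.5))
        else:
            while True:  # truncate at the platelet limit
                v = float(rng.normal(mean_volume_fl, sd)) if sd > 0 else mean_volume_fl
                if v > PLATELET_VOLUME_LIMIT_FL:
                    break
            if shape == "spherocyte":
                # dome aspect H = 1.4 R: V = (2/5) pi R^2 H = 0.56 pi R^3
                radius = float((5.0 * v / (2.8 * np.pi)) ** (1.0 / 3.0))
            else:
                radius = float(
                    np.clip(rng.normal(rbc_radius_um, rbc_radius_sd_um), 3.0, 4.8)
                )
        specs.append(CellSpec(shape=str(shape), target_volume_fl=v, radius_um=radius))
    return specs
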