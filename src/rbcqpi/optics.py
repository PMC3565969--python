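"""Optical constants and the physics linking hemoglobin, refractive index,
phase and cell height.

A quantitative phase microscope measures the optical pathlength delay
``phi(x, y) = (2*pi/lambda) * dn * h(x, y)`` that a cell of thickness ``h``
and refractive-index contrast ``dn = n_cell - n_medium`` imposes on the
illumination.  The cell index itself follows the linear law
``n_cell = n_water + beta * C`` where ``C`` is the hemoglobin concentration
(MCHC, g/dL) and ``beta`` the refractive increment (dL/g).  Everything in
this module is a pure, side-effect-free map; clamping of unphysical
(negative) heights is deliberately left to the morphology stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .exceptions import ConfigError, ParameterError

#: refractive index of water at visible wavelengths (dimensionless)
DEFAULT_N_WATER = 1.334
#: refractive increment of hemoglobin (dL/g), standard for visible light
DEFAULT_BETA_DL_PER_G = 0.00196
#: PBS + 0.1% albumin suspension medium (dimensionless)
DEFAULT_N_MEDIUM = 1.337


@dataclass(frozen=True)
class OpticalConfig:
    """Optical configuration of the (real or simulated) instrument.

    Parameters
    ----------
    wavelength_nm:
        Effective center wavelength of the illumination, nm.
    pixel_pitch_um:
        Physical size of one image pixel at the sample plane
        (camera pitch divided by magnification), micrometres.
    n_medium:
        Refractive index of the suspension buffer.
    n_water, beta_dl_per_g:
        Constants of the linear index law ``n = n_water + beta * C``.
    mchc_g_dl:
        Mean cell hemoglobin concentration (g/dL), as reported by an
        impedance analyzer.  Sets the cell index through the linear law.
    n_cell_override:
        Explicit cell refractive index; mutually exclusive with
        ``mchc_g_dl``.
    """

    wavelength_nm: float = 550.0
    pixel_pitch_um: float = 0.125
    n_medium: float = DEFAULT_N_MEDIUM
    n_water: float = DEFAULT_N_WATER
    beta_dl_per_g: float = DEFAULT_BETA_DL_PER_G
    mchc_g_dl: Optional[float] = 33.0
    n_cell_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ConfigError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if self.pixel_pitch_um <= 0:
            raise ConfigError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if (self.mchc_g_dl is None) == (self.n_cell_override is None):
            raise ConfigError(
                "exactly one of mchc_g_dl and n_cell_override must be set "
                f"(got mchc_g_dl={self.mchc_g_dl}, n_cell_override={self.n_cell_override})"
            )
        if self.delta_n <= 0:
            raise ConfigError(
                f"refractive contrast dn = n_cell - n_medium = {self.delta_n:.6g} "
                "must be > 0; heights would be undefined"
            )

    @property
    def n_cell(self) -> float:
        """Cell refractive index, from the override or the linear MCHC law."""
        if self.n_cell_override is not None:
            return self.n_cell_override
        return refractive_index_from_mchc(self.mchc_g_dl, self)

    @property
    def delta_n(self) -> float:
        """Refractive-index contrast dn = n_cell - n_medium."""
        if self.n_cell_override is not None:
            n_cell = self.n_cell_override
        else:
            if self.mchc_g_dl is None or self.mchc_g_dl < 0:
                raise ConfigError("mchc_g_dl must be a non-negative number")
            n_cell = self.n_water + self.beta_dl_per_g * self.mchc_g_dl
        return n_cell - self.n_medium

    # -- (de)serialization: flat key-value config file ---------------------
    def to_file(self, path) -> None:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "OpticalConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "n_cell_override" in d and "mchc_g_dl" not in d:
            d.setdefault("mchc_g_dl", None)
        return cls(**d)


def refractive_index_from_mchc(mchc_g_dl: float, config: OpticalConfig) -> float:
    """Cell refractive index from hemoglobin concentration: ``n_w + beta * C``."""
    if mchc_g_dl is None or mchc_g_dl < 0:
        raise ParameterError(f"MCHC must be >= 0 g/dL, got {mchc_g_dl}")
    return config.n_water + config.beta_dl_per_g * mchc_g_dl


def phase_to_height(phase: np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Convert unwrapped phase (rad) to thickness (um): ``h = lambda*phi / (2*pi*dn)``.

    A pure linear map; negative phases map to negative heights and are left
    untouched here (the morphology stage clamps them).
    """
    dn = config.delta_n
    if dn <= 0:
        raise ConfigError(f"refractive contrast must be > 0, got {dn}")
    wavelength_um = config.wavelength_nm * 1e-3
    return np.asarray(phase, dtype=float) * wavelength_um / (2.0 * np.pi * dn)


def height_to_phase(height: np.ndarray, config: OpticalConfig) -> np.ndarray:
    """Inverse of :func:`phase_to_height`: ``phi = 2*pi*dn*h / lambda`` (rad)."""
    dn = config.delta_n
    if dn <= 0:
        raise ConfigError(f"refractive contrast must be > 0, got {dn}")
    wavelength_um = config.wavelength_nm * 1e-3
    return np.asarray(height, dtype=float) * (2.0 * np.pi * dn) / wavelength_um
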