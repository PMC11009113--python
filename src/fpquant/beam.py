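"""Illumination calibration: optical power to irradiance.

Three illumination geometries are covered:

* **Wide-field** (Köhler) — irradiance is measured power divided by the
  illuminated field area, I = P / A.
* **Gaussian laser spot** — for a 2-D Gaussian profile of standard deviation
  σ, the center irradiance is I₀ = P / (2πσ²); the relative intensity at
  radius r is exp(−r²/(2σ²)). ``fov_uniformity`` reports how much the
  illumination falls off from the center to the edge midpoint and corner of
  a square field of view, which justifies quoting the center value for a
  small FOV.
* **Scanned field** (point-scanning confocal) — mean irradiance is again
  P / (scanned area), identical arithmetic to wide-field.

``photon_flux`` converts an energy flux (W cm⁻²) to a photon flux at a given
wavelength, the quantity the photon-budget normalization of photobleaching
traces needs.

Interfaces take lengths in µm and areas in cm² (the units instruments
report); conversion to CGS happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import c, h

UM_TO_CM = 1e-4
HC_J_M = h * c  # ≈ 1.98645e-25 J·m

__all__ = [
    "IlluminationConfig",
    "widefield_irradiance",
    "gaussian_center_irradiance",
    "gaussian_intensity_ratio",
    "fov_uniformity",
    "photon_flux",
    "irradiance",
]


@dataclass(frozen=True)
class IlluminationConfig:
    """Illumination geometry and power for one experiment.

    mode: "widefield" | "gaussian" | "scanned".
    power in W; field_area in cm² (widefield/scanned); sigma in µm
    (gaussian); wavelength in nm.
    """

    mode: str
    power: float
    wavelength: float
    field_area: float | None = None
    sigma: float | None = None
    fov: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("widefield", "gaussian", "scanned"):
            raise ValueError(f"unknown illumination mode: {self.mode!r}")
        if self.power <= 0:
            raise ValueError("power must be positive")
        if self.mode in ("widefield", "scanned"):
            if self.field_area is None or self.field_area <= 0:
                raise ValueError(f"{self.mode} mode requires field_area > 0")
            if self.sigma is not None:
                raise ValueError(f"sigma is not a {self.mode} parameter")
        else:
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian mode requires sigma > 0")
            if self.field_area is not None:
                raise ValueError("field_area is not a gaussian parameter")


def widefield_irradiance(power: float, area: float) -> float:
    """I = P / A for uniform illumination. power in W, area in cm²."""
    if power <= 0 or area <= 0:
        raise ValueError("power and area must be positive")
    return power / area


def gaussian_center_irradiance(power: float, sigma: float) -> float:
    """Center irradiance P/(2πσ²) of a 2-D Gaussian beam. sigma in µm."""
    if power <= 0 or sigma <= 0:
        raise ValueError("power and sigma must be positive")
    sigma_cm = sigma * UM_TO_CM
    return power / (2.0 * math.pi * sigma_cm**2)


def gaussian_intensity_ratio(r: float, sigma: float) -> float:
    """Relative beam intensity exp(−r²/(2σ²)) at radius r (µm) from center."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if r < 0:
        raise ValueError("radius must be nonnegative")
    return math.exp(-(r**2) / (2.0 * sigma**2))


def fov_uniformity(fov: tuple[float, float], sigma: float) -> tuple[float, float]:
    """Fractional intensity reduction from beam center over a square-ish FOV.

    Returns (side_reduction, corner_reduction): the falloff 1 − exp(−r²/2σ²)
    at the midpoint of the longer FOV edge (r = half the longer side) and at
    the FOV corner (r = half diagonal). fov in µm.
    """
    w, hgt = fov
    if w <= 0 or hgt <= 0:
        raise ValueError("field of view must be positive")
    r_side = max(w, hgt) / 2.0
    r_corner = math.hypot(w, hgt) / 2.0
    side = 1.0 - gaussian_intensity_ratio(r_side, sigma)
    corner = 1.0 - gaussian_intensity_ratio(r_corner, sigma)
    return side, corner


def photon_flux(irradiance_w_cm2: float, wavelength: float) -> float:
    """Photon flux (photons cm⁻² s⁻¹) from irradiance (W cm⁻²) at λ (nm)."""
    if irradiance_w_cm2 <= 0 or wavelength <= 0:
        raise ValueError("irradiance and wavelength must be positive")
    return irradiance_w_cm2 * (wavelength * 1e-9) / HC_J_M


def irradiance(config: IlluminationConfig) -> float:
    """Irradiance (W cm⁻²) for the configured geometry.

    Wide-field and scanned-field share the P/A rule; the Gaussian spot uses
    its center value.
    """
    if config.mode == "gaussian":
        return gaussian_center_irradiance(config.power, config.sigma)
    return widefield_irradiance(config.power, config.field_area)
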