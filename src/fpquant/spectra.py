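"""Spectroscopic bookkeeping for fluorescent-protein characterization.

This module holds the per-protein photophysical constants (absorbance and
emission maxima, extinction coefficients, fluorescence quantum yield) and the
band arithmetic needed to compare fluorescent proteins (FPs) measured through
a real filter set:

* **Excitation efficiency** — how strongly a bandpass excites an FP, defined
  as the mean of the excitation spectrum (relative to its maximum) across the
  band.
* **Emission detection efficiency** — the fraction of total emitted photons
  that pass the detection bandpass (trapezoid-rule band integral over total
  integral).
* **Channel throughput** — the product of the two, used to put intensity
  measurements of spectrally different FPs on a common footing.
* **Extinction coefficients via alkali denaturation** — the denatured
  GFP-type chromophore absorbs maximally at 447 nm with a known
  ε = 44,000 M⁻¹cm⁻¹, so the native-state ε follows from an absorbance ratio.
* **Molecular brightness** — ε(λab) × QY, the intrinsic per-molecule
  brightness, reported in units of 10³ M⁻¹cm⁻¹.

Conventions: spectra are linearly resampled to a 1-nm grid before any band
operation; bandpasses are closed intervals [lo, hi] in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# ε of the alkali-denatured GFP-type chromophore at its 447-nm absorbance
# maximum, the anchor of the denaturation method (M⁻¹ cm⁻¹).
DENATURED_CHROMOPHORE_EPS = 44_000.0
DENATURED_CHROMOPHORE_PEAK_NM = 447.0

__all__ = [
    "Spectrum",
    "Bandpass",
    "FPPhotophysics",
    "excitation_efficiency",
    "emission_efficiency",
    "channel_throughput",
    "extinction_from_alkali",
    "eps_at_wavelength",
    "molecular_brightness",
    "round_half_away",
    "DENATURED_CHROMOPHORE_EPS",
]


@dataclass
class Spectrum:
    """A wavelength grid with relative intensities.

    kind is one of ``"excitation"``, ``"emission"``, ``"absorption"``.
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.size < 2:
            raise ValueError("spectrum needs at least 2 wavelength points")
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity shapes differ")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.kind not in ("excitation", "emission", "absorption"):
            raise ValueError(f"unknown spectrum kind: {self.kind!r}")

    def resample_1nm(self) -> "Spectrum":
        """Linear resampling onto an integer 1-nm grid spanning the data."""
        lo = math.ceil(self.wavelength[0])
        hi = math.floor(self.wavelength[-1])
        if hi < lo:
            raise ValueError("grid too narrow to resample at 1 nm")
        grid = np.arange(lo, hi + 1, dtype=float)
        return Spectrum(grid, np.interp(grid, self.wavelength, self.intensity), self.kind)

    def max_normalized(self) -> "Spectrum":
        peak = float(self.intensity.max())
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return Spectrum(self.wavelength, self.intensity / peak, self.kind)


@dataclass(frozen=True)
class Bandpass:
    """Closed wavelength interval [lo, hi] in nm of an optical filter."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("bandpass requires lo < hi")


@dataclass
class FPPhotophysics:
    """Photophysical constants of one fluorescent protein.

    eps_peak is the molar extinction coefficient at the absorbance maximum
    lambda_ab; eps_at_ex is ε at the excitation reference wavelength of the
    imaging system (483 nm for the filter sets modeled here). Both in
    M⁻¹ cm⁻¹. qy is the fluorescence quantum yield.
    """

    name: str
    lambda_ab: float
    lambda_em: float
    eps_peak: float
    eps_at_ex: float | None = None
    qy: float = field(default=1.0)

    def __post_init__(self) -> None:
        if not (0 < self.qy <= 1):
            raise ValueError("quantum yield must be in (0, 1]")
        if self.eps_peak <= 0:
            raise ValueError("eps_peak must be positive")
        if self.eps_at_ex is not None:
            if self.eps_at_ex <= 0:
                raise ValueError("eps_at_ex must be positive when given")
            if self.eps_peak < self.eps_at_ex:
                raise ValueError("eps_peak must be >= eps_at_ex")
        if self.lambda_em < self.lambda_ab:
            raise ValueError("emission maximum cannot be blue of absorbance maximum")


def _band_slice(grid: np.ndarray, band: Bandpass) -> np.ndarray:
    return (grid >= band.lo) & (grid <= band.hi)


def excitation_efficiency(spectrum: Spectrum, band: Bandpass) -> float:
    """Mean relative excitation intensity across the bandpass.

    The spectrum is resampled to 1 nm, divided by its global maximum, and
    averaged (unweighted) over grid points inside the band.
    """
    rs = spectrum.resample_1nm()
    peak = float(rs.intensity.max())
    if peak <= 0:
        raise ValueError("excitation spectrum is identically zero")
    inside = _band_slice(rs.wavelength, band)
    if not inside.any():
        raise ValueError("bandpass contains no grid points after 1-nm resampling")
    return float(np.mean(rs.intensity[inside]) / peak)


def emission_efficiency(spectrum: Spectrum, band: Bandpass) -> float:
    """Fraction of the integrated emission passing the bandpass.

    Trapezoid rule on the 1-nm resampled spectrum; a band that misses the
    grid entirely passes no photons and returns 0.
    """
    rs = spectrum.resample_1nm()
    total = float(np.trapezoid(rs.intensity, rs.wavelength))
    if total <= 0:
        raise ValueError("emission spectrum has zero total integral")
    inside = _band_slice(rs.wavelength, band)
    if inside.sum() < 2:
        return 0.0
    part = float(np.trapezoid(rs.intensity[inside], rs.wavelength[inside]))
    return part / total


def channel_throughput(
    ex_spec: Spectrum, em_spec: Spectrum, ex_band: Bandpass, em_band: Bandpass
) -> float:
    """Excitation efficiency × emission detection efficiency of one channel."""
    try:
        ex = excitation_efficiency(ex_spec, ex_band)
    except ValueError:
        # band entirely off the grid: the channel excites nothing
        ex = 0.0
    return ex * emission_efficiency(em_spec, em_band)


def extinction_from_alkali(a_native_at_peak: float, a_denatured_447: float) -> float:
    """ε at the native absorbance maximum from the alkali-denaturation ratio.

    Same protein concentration and path length in both measurements, so
    ε = 44,000 × A_native(λab) / A_denatured(447 nm).
    """
    if a_native_at_peak <= 0 or a_denatured_447 <= 0:
        raise ValueError("absorbances must be positive")
    return DENATURED_CHROMOPHORE_EPS * a_native_at_peak / a_denatured_447


def eps_at_wavelength(fp: FPPhotophysics, abs_spectrum: Spectrum, lam: float) -> float:
    """ε at an arbitrary wavelength from the max-normalized absorption spectrum."""
    if not (abs_spectrum.wavelength[0] <= lam <= abs_spectrum.wavelength[-1]):
        raise ValueError("wavelength outside the absorption spectrum grid")
    rel = float(np.interp(lam, abs_spectrum.wavelength, abs_spectrum.intensity))
    return fp.eps_peak * rel


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention of printed summary tables."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def molecular_brightness(fp: FPPhotophysics) -> tuple[float, int]:
    """Intrinsic molecular brightness, (ε_peak / 1000) × QY.

    Returns (raw value, integer as printed in summary tables), in units of
    10³ M⁻¹ cm⁻¹.
    """
    raw = fp.eps_peak / 1000.0 * fp.qy
    return raw, round_half_away(raw)
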