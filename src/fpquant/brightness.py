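"""Throughput- and reference-corrected cellular brightness and maturation.

Cellular brightness compares fluorescent proteins as they actually perform
in cells at a fixed time after transfection: each test FP is co-translated
with a red reference FP (mCherry) from one bicistronic message, so the
green/red intensity ratio cancels expression level. The raw ratio is then
divided by the green channel's spectral throughput for that FP (its spectrum
shifts relative to the filter set) and finally normalized to a reference FP.
The red-channel throughput is shared by all constructs and cancels in the
normalization.

Maturation curves apply the same ratio logic over time: the masked green
signal at each timepoint is divided by the red signal at the final timepoint
(the red reference matures late, so dividing per-timepoint would distort the
early phase) and corrected for throughput. A single-exponential approach to
plateau can then be fitted to estimate the maturation rate.

Signal pixels are defined against pre-expression reference images: a pixel
is signal if it exceeds the reference mean by five reference standard
deviations (a 5σ threshold has a Gaussian false-positive rate below 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CellField",
    "BrightnessResult",
    "MaskResult",
    "signal_mask",
    "cellular_brightness",
    "maturation_curve",
    "fit_maturation",
]


@dataclass
class CellField:
    """Spatially registered two-channel field (or per-cell intensity arrays)."""

    green: np.ndarray
    red: np.ndarray
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must share a shape")


@dataclass(frozen=True)
class BrightnessResult:
    raw_ratio: float
    throughput_corrected: float
    normalized: float | None = None


@dataclass
class MaskResult:
    mask: np.ndarray
    threshold: float
    degenerate: bool = False  # reference had zero variance


def signal_mask(image: np.ndarray, reference_images: np.ndarray) -> MaskResult:
    """Pixels exceeding mean + 5·sd of the reference (pre-signal) images.

    reference_images may be a single image or a stack; statistics pool all
    reference pixels. A constant reference (sd = 0) degenerates the
    threshold to the mean and is flagged.
    """
    image = np.asarray(image, dtype=float)
    ref = np.asarray(reference_images, dtype=float)
    if ref.shape[-2:] != image.shape:
        raise ValueError("reference images must match the image shape")
    mu = float(ref.mean())
    sd = float(ref.std())
    threshold = mu + 5.0 * sd
    return MaskResult(mask=image > threshold, threshold=threshold, degenerate=sd == 0.0)


def cellular_brightness(
    field: CellField,
    throughput_green: float,
    reference_value: float | None = None,
    mask: np.ndarray | None = None,
    background: float = 0.0,
) -> BrightnessResult:
    """Green/red brightness of one field, throughput corrected.

    raw_ratio = Σ green(masked) / Σ red(masked); throughput_corrected divides
    by the green-channel throughput; normalized divides further by the
    corrected value of the reference FP when given (so the reference itself
    reads exactly 1). A constant background offset, if known, is subtracted
    from both channels before summing.
    """
    if throughput_green <= 0:
        raise ValueError("green-channel throughput must be positive")
    if mask is None:
        mask = np.ones(field.green.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty signal mask")
    n = int(mask.sum())
    red_sum = float(field.red[mask].sum()) - background * n
    if red_sum <= 0:
        raise ValueError("no red signal in the masked region")
    raw = (float(field.green[mask].sum()) - background * n) / red_sum
    corrected = raw / throughput_green
    normalized = corrected / reference_value if reference_value is not None else None
    return BrightnessResult(raw_ratio=raw, throughput_corrected=corrected, normalized=normalized)


def maturation_curve(
    green_signals: np.ndarray,
    times: np.ndarray,
    red_at_final: float,
    throughput_green: float,
) -> np.ndarray:
    """Corrected green:red ratio over time.

    green_signals are the per-timepoint masked green totals; every timepoint
    is divided by the red reference signal at the final timepoint and by the
    green-channel throughput, so FPs with identical kinetics but different
    spectra give identical curves.
    """
    green_signals = np.asarray(green_signals, dtype=float)
    times = np.asarray(times, dtype=float)
    if green_signals.shape != times.shape or times.size < 2:
        raise ValueError("need >= 2 timepoints with matching signal values")
    if red_at_final <= 0:
        raise ValueError("red reference signal at the final timepoint must be positive")
    if throughput_green <= 0:
        raise ValueError("green-channel throughput must be positive")
    return green_signals / red_at_final / throughput_green


def _exp_approach(t, k, plateau):
    return plateau * (1.0 - np.exp(-k * t))


def fit_maturation(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of plateau·(1 − e^(−k·t)); returns (k, plateau)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    vmax = float(values.max())
    if vmax <= 0:
        raise ValueError("maturation curve never rises above zero")
    # crude initial rate from the time of half-plateau
    half_idx = int(np.searchsorted(values, vmax / 2))
    t_half = times[min(half_idx, times.size - 1)] or times[times > 0][0]
    p0 = (np.log(2.0) / t_half, vmax)
    popt, _ = curve_fit(_exp_approach, times, values, p0=p0, maxfev=10_000)
    return float(popt[0]), float(popt[1])
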