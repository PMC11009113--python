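"""Dispersibility scoring, pKa fitting and colocalization statistics.

Monomericity/dispersibility assays (OSER for ER-membrane whorls, Fluoppi
for phase-separated puncta) reduce to the percentage of normal-looking
cells among all transfected cells scored. ``proportion_score`` computes
that percentage and attaches a Wilson 95% confidence interval as a
precision aid (the interval is plumbing added by this package; the original
assays report bare percentages).

``fit_pka`` fits the Hill-type pH-quenching model
F(pH) = F_max / (1 + 10^(h·(pKa − pH))); the fluorescence pKa is the pH of
half-maximal fluorescence.

``colocalize`` implements threshold-filtered correlation analysis of two
channels: Otsu thresholds per channel, exclusion of pixels that are below
threshold in *both* channels or saturated in *either*, then the Pearson
correlation coefficient of the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AssayCount",
    "ProportionScore",
    "PkaFit",
    "ColocResult",
    "FitError",
    "proportion_score",
    "fit_pka",
    "colocalize",
    "otsu_threshold",
]


class FitError(RuntimeError):
    """A model fit could not be performed on the given series."""


@dataclass(frozen=True)
class AssayCount:
    construct: str
    assay: str  # "OSER" | "Fluoppi-PB1FP" | "Fluoppi-FPPB1"
    n_normal: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_normal <= self.n_total:
            raise ValueError("need 0 <= n_normal <= n_total")


@dataclass(frozen=True)
class ProportionScore:
    percent: float
    ci_low: float  # Wilson 95% bounds, percent
    ci_high: float


@dataclass(frozen=True)
class PkaFit:
    pka: float
    hill: float
    f_max: float


@dataclass(frozen=True)
class ColocResult:
    r: float
    n_total: int
    n_included: int
    n_below_both: int
    n_saturated: int
    threshold_a: float
    threshold_b: float


def proportion_score(count: AssayCount) -> ProportionScore:
    """Percentage of normal-looking cells with a Wilson 95% interval."""
    if count.n_total <= 0:
        raise ValueError("n_total must be positive to compute a score")
    lo, hi = proportion_confint(count.n_normal, count.n_total, alpha=0.05, method="wilson")
    return ProportionScore(
        percent=100.0 * count.n_normal / count.n_total,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
    )


def _hill(ph, pka, hill, f_max):
    return f_max / (1.0 + 10.0 ** (hill * (pka - ph)))


def fit_pka(ph: np.ndarray, fluorescence: np.ndarray) -> PkaFit:
    """Least-squares Hill fit of a pH titration.

    Requires an increasing transition inside the measured range: the series
    must dip below 80% and rise above 20% of its plateau, and fluorescence
    must rise with pH overall. Inverted or transitionless series raise
    FitError rather than returning a silently wrong pKa.
    """
    ph = np.asarray(ph, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if ph.size < 4:
        raise FitError("need at least 4 titration points")
    order = np.argsort(ph)
    ph, f = ph[order], f[order]
    fmax = float(f.max())
    if fmax <= 0:
        raise FitError("no fluorescence in the series")
    rel = f / fmax
    if not (rel.min() < 0.8 and rel.max() > 0.2):
        raise FitError("no transition within the measured pH range")
    if np.corrcoef(ph, f)[0, 1] < 0:
        raise FitError("fluorescence decreases with pH; not a protonation quench")

    # initialize pKa at the interpolated half-max crossing
    half = fmax / 2.0
    above = np.nonzero(f >= half)[0]
    pka0 = float(ph[above[0]]) if above.size else float(np.median(ph))
    try:
        popt, _ = curve_fit(
            _hill,
            ph,
            f,
            p0=(pka0, 1.0, fmax),
            bounds=([0.0, 1e-3, 0.0], [14.0, 10.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    return PkaFit(pka=float(popt[0]), hill=float(popt[1]), f_max=float(popt[2]))


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold on a 256-bin histogram over the data range."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("cannot threshold a constant channel")
    return float(threshold_otsu(values, nbins=256))


def colocalize(
    image_a: np.ndarray,
    image_b: np.ndarray,
    saturation_value: float | None = None,
) -> ColocResult:
    """Pearson correlation of two channels after threshold/saturation filtering.

    A pixel is kept if it exceeds the per-channel Otsu threshold in at least
    one channel and is not at the saturation value in either channel.
    """
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channels must have equal shapes")
    if saturation_value is not None:
        saturated = (a == saturation_value) | (b == saturation_value)
    else:
        saturated = np.zeros(a.shape, dtype=bool)
    # thresholds are computed on valid (unsaturated) pixels only, so a
    # saturated mode cannot drag the Otsu split off the background/signal
    # boundary
    valid = ~saturated
    if valid.sum() < 2:
        raise ValueError("fewer than 2 unsaturated pixels")
    ta = otsu_threshold(a[valid])
    tb = otsu_threshold(b[valid])
    below_both = (a <= ta) & (b <= tb)
    keep = ~below_both & ~saturated
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise ValueError("fewer than 2 pixels survive the filters")
    r = float(pearsonr(a[keep], b[keep]).statistic)
    return ColocResult(
        r=r,
        n_total=int(a.size),
        n_included=n_keep,
        n_below_both=int(below_both.sum()),
        n_saturated=int(saturated.sum()),
        threshold_a=ta,
        threshold_b=tb,
    )
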