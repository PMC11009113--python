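"""Synthetic-data generators with known ground truth.

Every input the characterization pipeline consumes can be generated here
with a stated statistical structure, so each downstream stage is testable
as a parameter-recovery problem:

* Gaussian excitation/emission spectrum pairs (a positive Stokes shift is
  enforced) for the throughput calculations.
* Mono/multi-exponential photobleaching decays with additive Gaussian noise;
  the true half-time is computed analytically (one component) or by root
  finding on the exact mixture (several components).
* Two-channel "bicistronic" cell fields: each cell expresses a lognormal
  number of molecules that emits in a green and a red channel with fixed
  per-molecule brightness, emulating equimolar co-translation of a test FP
  with a red reference FP.
* Single-exponential chromophore-maturation time courses.
* Sigmoidal (Hill) pH-quenching titrations.
* Bernoulli assay outcomes (normal-looking vs aberrant cells).
* Correlated two-channel pixel intensities for colocalization, with an
  optional saturated fraction.
* Time-lapse stacks that are static, rigidly shifting, or remodeling with a
  stated frame-to-frame texture correlation.

All randomness flows through one explicit integer seed; identical
(parameters, seed) give bit-identical outputs. Every generator returns a
``GroundTruth`` record sufficient for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .photobleach import BleachTrace
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_spectrum_pair",
    "gen_bleach_trace",
    "gen_bicistronic_field",
    "gen_maturation_course",
    "gen_titration_series",
    "gen_assay_counts",
    "gen_coloc_pair",
    "gen_motion_stack",
    "hill_fluorescence",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of the image-based generators.

    expression_mu/expression_sigma parameterize the lognormal per-cell
    molecule count (substantial cell-to-cell expression variation is the
    norm after transient transfection); noise_sd is additive Gaussian camera
    noise in intensity units; frame_interval in seconds.
    """

    seed: int = 0
    n_cells: int = 120
    expression_mu: float = 6.0
    expression_sigma: float = 0.5
    noise_sd: float = 1.0
    frame_interval: float = 0.4
    image_shape: tuple[int, int] = (256, 256)
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """True parameter values recorded alongside every generated dataset."""

    true_t_half: float | None = None
    true_pka: float | None = None
    true_hill: float | None = None
    true_proportion: float | None = None
    true_correlation: float | None = None
    shift_per_frame: float | None = None
    true_k_mat: float | None = None
    true_plateau: float | None = None
    true_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.true_correlation is not None and not -1 <= self.true_correlation <= 1:
            raise ValueError("true_correlation must lie in [-1, 1]")
        if self.true_proportion is not None and not 0 <= self.true_proportion <= 1:
            raise ValueError("true_proportion must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


# --------------------------------------------------------------------------
# spectra


def gen_spectrum_pair(
    peak_ex: float,
    peak_em: float,
    width_ex: float,
    width_em: float,
    grid: np.ndarray,
) -> tuple[Spectrum, Spectrum]:
    """Gaussian excitation/emission pair, each max-normalized to 1 at its peak.

    Shapes only matter downstream through band integrals, so plain Gaussians
    of the requested widths (standard deviations, nm) suffice. Deterministic.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if width_ex <= 0 or width_em <= 0:
        raise ValueError("spectral widths must be positive")
    if peak_em < peak_ex:
        raise ValueError("Stokes shift must be nonnegative (peak_em >= peak_ex)")
    ex = np.exp(-((grid - peak_ex) ** 2) / (2 * width_ex**2))
    em = np.exp(-((grid - peak_em) ** 2) / (2 * width_em**2))
    return (
        Spectrum(grid, ex, kind="excitation"),
        Spectrum(grid, em, kind="emission"),
    )


# --------------------------------------------------------------------------
# photobleaching


def _mixture(components: list[tuple[float, float]]):
    amps = np.array([a for a, _ in components], dtype=float)
    rates = np.array([k for _, k in components], dtype=float)
    return lambda t: np.sum(amps[:, None] * np.exp(-rates[:, None] * np.atleast_1d(t)), axis=0)


def gen_bleach_trace(
    components: list[tuple[float, float]],
    duration: float,
    dt: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BleachTrace, GroundTruth]:
    """Multi-exponential bleach decay, unit initial intensity, Gaussian noise.

    components: (amplitude fraction, decay rate s⁻¹) pairs, fractions summing
    to 1. The true half-time is ln2/k for one component, otherwise the root
    of the exact mixture found by bracketing and Brent's method.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one sample interval")
    if not components:
        raise ValueError("need at least one decay component")
    amps = np.array([a for a, _ in components], dtype=float)
    rates = np.array([k for _, k in components], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("decay rates must be positive")
    if not np.isclose(amps.sum(), 1.0, atol=1e-9):
        raise ValueError("amplitude fractions must sum to 1")

    time = np.arange(0.0, duration + dt / 2, dt)
    model = _mixture(components)
    clean = model(time)
    rng = np.random.default_rng(seed)
    intensity = clean + (rng.normal(0.0, noise_sd, size=time.shape) if noise_sd > 0 else 0.0)

    if len(components) == 1:
        true_t_half = float(np.log(2.0) / rates[0])
    else:
        f = lambda t: float(model(t)[0]) - 0.5
        hi = 1.0 / rates.min()
        while f(hi) > 0:
            hi *= 2.0
        true_t_half = float(brentq(f, 0.0, hi, xtol=1e-9))

    trace = BleachTrace(time=time, intensity=intensity)
    return trace, GroundTruth(true_t_half=true_t_half)


# --------------------------------------------------------------------------
# two-channel cell fields

_CELL_RADIUS = 5  # px


def gen_bicistronic_field(
    config: SimulationConfig,
    green_per_molecule: float,
    red_per_molecule: float,
):
    """Two-channel field of cells with a fixed green/red per-molecule ratio.

    Cells are disks placed on a jittered grid; each carries a lognormal
    molecule count expressed identically in both channels, so the per-cell
    green/red intensity ratio equals green_per_molecule/red_per_molecule in
    expectation. Returns (green image, red image, per-cell table dict,
    GroundTruth).
    """
    if green_per_molecule <= 0 or red_per_molecule <= 0:
        raise ValueError("per-molecule brightnesses must be positive")
    h, w = config.image_shape
    rng = np.random.default_rng(config.seed)

    pitch = 4 * _CELL_RADIUS
    ys = np.arange(pitch // 2, h - _CELL_RADIUS, pitch)
    xs = np.arange(pitch // 2, w - _CELL_RADIUS, pitch)
    sites = [(y, x) for y in ys for x in xs]
    if config.n_cells > len(sites):
        raise ValueError(
            f"image {config.image_shape} too small for {config.n_cells} cells "
            f"({len(sites)} sites available)"
        )

    green = np.full((h, w), config.background, dtype=float)
    red = np.full((h, w), config.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]

    chosen = rng.choice(len(sites), size=config.n_cells, replace=False)
    expr = rng.lognormal(config.expression_mu, config.expression_sigma, size=config.n_cells)
    jitter = rng.integers(-_CELL_RADIUS // 2, _CELL_RADIUS // 2 + 1, size=(config.n_cells, 2))

    table = {"cell": [], "y": [], "x": [], "expression": [], "green": [], "red": []}
    for i, (si, e) in enumerate(zip(chosen, expr)):
        cy = sites[si][0] + int(jitter[i, 0])
        cx = sites[si][1] + int(jitter[i, 1])
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= _CELL_RADIUS**2
        green[disk] += e * green_per_molecule
        red[disk] += e * red_per_molecule
        table["cell"].append(i)
        table["y"].append(cy)
        table["x"].append(cx)
        table["expression"].append(float(e))
        table["green"].append(float(e * green_per_molecule))
        table["red"].append(float(e * red_per_molecule))

    if config.noise_sd > 0:
        green += rng.normal(0.0, config.noise_sd, size=green.shape)
        red += rng.normal(0.0, config.noise_sd, size=red.shape)
    np.clip(green, 0.0, None, out=green)
    np.clip(red, 0.0, None, out=red)

    gt = GroundTruth(true_ratio=green_per_molecule / red_per_molecule)
    return green, red, table, gt


# --------------------------------------------------------------------------
# maturation


def gen_maturation_course(
    k_mat: float,
    plateau: float,
    timepoints: np.ndarray,
    red_final: float,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Single-exponential approach to plateau: green(t) = plateau·(1 − e^(−k t)).

    The red reference channel is reported as a single value at the final
    timepoint (the denominator the ratio analysis uses). Returns a table
    dict with columns time_s/green, the red_final scalar, and GroundTruth.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size == 0:
        raise ValueError("empty timepoints")
    if np.any(np.diff(timepoints) < 0):
        raise ValueError("timepoints must be nondecreasing")
    if k_mat <= 0:
        raise ValueError("maturation rate must be positive")
    rng = np.random.default_rng(seed)
    green = plateau * (1.0 - np.exp(-k_mat * timepoints))
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, size=green.shape)
    table = {"time_s": timepoints, "green": green}
    gt = GroundTruth(true_k_mat=k_mat, true_plateau=plateau)
    return table, red_final, gt


# --------------------------------------------------------------------------
# pH titration


def hill_fluorescence(ph: np.ndarray, pka: float, hill: float, f_max: float) -> np.ndarray:
    """Hill-type pH quenching: F(pH) = F_max / (1 + 10^(hill·(pKa − pH)))."""
    ph = np.asarray(ph, dtype=float)
    return f_max / (1.0 + 10.0 ** (hill * (pka - ph)))


def gen_titration_series(
    pka: float,
    hill: float,
    f_max: float,
    ph_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Sigmoidal pH titration; F(pKa) = F_max/2 by construction."""
    ph_grid = np.asarray(ph_grid, dtype=float)
    if ph_grid.size == 0:
        raise ValueError("empty pH grid")
    if np.any(ph_grid < 0) or np.any(ph_grid > 14):
        raise ValueError("pH values must lie within [0, 14]")
    if hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    rng = np.random.default_rng(seed)
    f = hill_fluorescence(ph_grid, pka, hill, f_max)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    table = {"ph": ph_grid, "fluorescence": f}
    return table, GroundTruth(true_pka=pka, true_hill=hill)


# --------------------------------------------------------------------------
# assay counts


def gen_assay_counts(p_normal: float, n_cells: int, seed: int = 0):
    """Binomial count of normal-looking cells among n_cells scored cells."""
    if not 0 <= p_normal <= 1:
        raise ValueError("p_normal must lie in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    n_normal = int(rng.binomial(n_cells, p_normal)) if n_cells > 0 else 0
    return (n_normal, n_cells), GroundTruth(true_proportion=p_normal)


# --------------------------------------------------------------------------
# colocalization pixels


def gen_coloc_pair(
    rho: float,
    n_pixels: int,
    saturation_fraction: float = 0.0,
    seed: int = 0,
    mean: float = 1000.0,
    sd: float = 100.0,
    saturation_value: float = 4095.0,
    background_fraction: float = 0.0,
    background_mean: float = 50.0,
    background_sd: float = 10.0,
):
    """Two intensity arrays with underlying bivariate-Gaussian correlation rho.

    Standard-normal pairs with correlation rho are mapped affinely to
    intensities mean + sd·z (sd ≪ mean/3, so negative values are negligible
    and clipped); the ⌊f·n⌋ brightest channel-A pixels are then set to the
    saturation value in both channels. With background_fraction > 0, that
    fraction of pixels is replaced by dim uncorrelated background in both
    channels (what an Otsu threshold is meant to exclude); rho then
    describes the signal population only.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must lie in [-1, 1]")
    if n_pixels <= 1:
        raise ValueError("need more than one pixel")
    if not 0 <= saturation_fraction < 1:
        raise ValueError("saturation_fraction must lie in [0, 1)")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_pixels)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n_pixels)
    a = np.clip(mean + sd * z1, 0.0, None)
    b = np.clip(mean + sd * z2, 0.0, None)
    n_back = int(np.floor(background_fraction * n_pixels))
    if n_back > 0:
        idx = rng.choice(n_pixels, size=n_back, replace=False)
        a[idx] = np.clip(rng.normal(background_mean, background_sd, n_back), 0.0, None)
        b[idx] = np.clip(rng.normal(background_mean, background_sd, n_back), 0.0, None)
    n_sat = int(np.floor(saturation_fraction * n_pixels))
    if n_sat > 0:
        idx = np.argsort(a)[-n_sat:]
        a[idx] = saturation_value
        b[idx] = saturation_value
    return a, b, GroundTruth(true_correlation=rho)


# --------------------------------------------------------------------------
# time-lapse motion stacks


def _smooth_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    tex = gaussian_filter(rng.standard_normal(shape), sigma=1.5, mode="wrap")
    tex /= tex.std()
    return tex


def gen_motion_stack(
    mode: str,
    shift_per_frame: float = 0.0,
    n_frames: int = 10,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    texture_corr: float = 0.5,
    offset: float = 100.0,
    amplitude: float = 10.0,
):
    """Time-lapse stack that is static, rigidly shifting, or remodeling.

    static: every frame identical. shifting: frame n+1 is frame n rolled by
    shift_per_frame pixels (rounded to integers; periodic boundary keeps the
    translation exact). remodeling: per-pixel AR(1) noise with frame-to-frame
    correlation texture_corr — deliberately spatially white, so the windowed
    correlation of consecutive frames matches texture_corr without
    small-window bias. Intensities are offset to stay nonnegative.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if mode not in ("static", "shifting", "remodeling"):
        raise ValueError(f"unknown motion mode: {mode!r}")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_frames,) + shape, dtype=float)

    if mode in ("static", "shifting"):
        tex = _smooth_texture(rng, shape)
        step = int(round(shift_per_frame)) if mode == "shifting" else 0
        frame = tex
        for i in range(n_frames):
            stack[i] = offset + amplitude * frame
            if step:
                frame = np.roll(frame, step, axis=1)
        gt = GroundTruth(
            shift_per_frame=float(step),
            true_correlation=1.0 if step == 0 else None,
        )
    else:
        if not -1 <= texture_corr <= 1:
            raise ValueError("texture_corr must lie in [-1, 1]")
        prev = rng.standard_normal(shape)
        stack[0] = offset + amplitude * prev
        innov_sd = np.sqrt(max(0.0, 1.0 - texture_corr**2))
        for i in range(1, n_frames):
            prev = texture_corr * prev + innov_sd * rng.standard_normal(shape)
            stack[i] = offset + amplitude * prev
        gt = GroundTruth(true_correlation=texture_corr, shift_per_frame=0.0)

    np.clip(stack, 0.0, None, out=stack)
    return stack, gt
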