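"""Pulldown depletion assays → adsorption isotherms → Langmuir fits.

A pulldown sample records the absorbance of labeled peptide before (A_i)
and after (A_f) exposure to a fixed number of cells.  Assuming absorbance
proportional to free-peptide concentration, the bound amount is
C_bound = C0·(1 − A_f/A_i); the free concentration at equilibrium is
C_eq = C0 − C_bound.  Bound moles per unit cell surface area (cells
treated as discrete spheres, area = count·π·d²) against C_eq gives the
adsorption isotherm, fitted to the Langmuir model

    P/A = Ka·N·C_eq / (1 + Ka·C_eq)

with Ka the association constant (L/mol) and N the maximum (monolayer)
surface concentration (mol/m²).  All quantities are SI internally.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import AssayDesignError, DataError, FitError, MeasurementError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PulldownSample:
    """One depletion measurement (SI units: mol/L, meters, liters)."""

    C0: float
    A_i: float
    A_f: float
    cell_count: float
    cell_diameter: float
    volume: float
    peptide_id: str = ""

    def __post_init__(self) -> None:
        if self.A_i <= 0:
            raise MeasurementError(f"initial absorbance must be > 0, got {self.A_i}")
        if self.A_f < 0:
            raise MeasurementError(f"final absorbance must be >= 0, got {self.A_f}")
        if self.C0 < 0:
            raise MeasurementError(f"initial concentration must be >= 0, got {self.C0}")
        if self.cell_count <= 0 or self.cell_diameter <= 0 or self.volume <= 0:
            raise MeasurementError("cell count, diameter, and volume must be positive")


@dataclass(frozen=True)
class IsothermPoint:
    """Free concentration (mol/L) vs bound surface density (mol/m²)."""

    C_eq: float
    surface_density: float

    def __post_init__(self) -> None:
        if self.C_eq < 0 or self.surface_density < 0:
            raise MeasurementError("isotherm point values must be non-negative")


@dataclass(frozen=True)
class LangmuirFit:
    """Fitted Langmuir parameters with standard errors and fit correlation."""

    Ka: float
    N: float
    se_Ka: float
    se_N: float
    r: float
    model: str = "langmuir"


def bound_concentration(C0: float, A_i: float, A_f: float) -> float:
    """Bound peptide concentration C0·(1 − A_f/A_i), clamped to [0, C0]."""
    if A_i <= 0:
        raise MeasurementError(f"initial absorbance must be > 0, got {A_i}")
    c_bound = C0 * (1.0 - A_f / A_i)
    if c_bound < 0.0:
        logger.warning(
            "negative computed binding (A_f=%g > A_i=%g); clamped to 0", A_f, A_i
        )
        return 0.0
    if c_bound > C0:
        logger.warning("computed binding exceeds C0; clamped to C0=%g", C0)
        return C0
    return c_bound


def total_surface_area(cell_count: float, cell_diameter: float) -> float:
    """Total surface area (m²) of ``cell_count`` spheres of the given diameter."""
    if cell_count <= 0 or cell_diameter <= 0:
        raise MeasurementError("cell count and diameter must be positive")
    return cell_count * math.pi * cell_diameter**2


def build_isotherm(samples: list[PulldownSample]) -> list[IsothermPoint]:
    """Convert depletion samples to isotherm points, sorted by C_eq.

    All samples must share cell count, diameter, and volume (one surface).
    """
    if not samples:
        return []
    ref = samples[0]
    for s in samples[1:]:
        if not (
            math.isclose(s.cell_count, ref.cell_count)
            and math.isclose(s.cell_diameter, ref.cell_diameter)
            and math.isclose(s.volume, ref.volume)
        ):
            raise AssayDesignError(
                "samples in one isotherm must share cell count, diameter, and volume"
            )
    area = total_surface_area(ref.cell_count, ref.cell_diameter)
    points = []
    for s in samples:
        c_bound = bound_concentration(s.C0, s.A_i, s.A_f)
        c_eq = s.C0 - c_bound
        density = c_bound * s.volume / area
        points.append(IsothermPoint(C_eq=c_eq, surface_density=density))
    return sorted(points, key=lambda p: p.C_eq)


def langmuir(c_eq, Ka, N):
    """Langmuir isotherm P/A = Ka·N·C_eq/(1 + Ka·C_eq)."""
    c_eq = np.asarray(c_eq, dtype=float)
    return Ka * N * c_eq / (1.0 + Ka * c_eq)


def _check_points(points) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.C_eq for p in points], dtype=float)
    y = np.array([p.surface_density for p in points], dtype=float)
    if len(np.unique(x)) < 4:
        raise DataError(
            f"Langmuir fitting needs >= 4 points with distinct C_eq, "
            f"got {len(np.unique(x))}"
        )
    return x, y


def _reciprocal_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Double-reciprocal linearization 1/(P/A) = 1/N + (1/(Ka·N))·(1/C_eq)."""
    mask = (x > 0) & (y > 0)
    if mask.sum() >= 2:
        res = stats.linregress(1.0 / x[mask], 1.0 / y[mask])
        if res.intercept > 0 and res.slope > 0:
            n0 = 1.0 / res.intercept
            return res.intercept / res.slope, n0
    # fallback for data the linearization cannot handle
    n0 = max(float(y.max()), 1e-30) * 2.0
    ka0 = 1.0 / max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-30)
    return ka0, n0


def fit_langmuir(points: list[IsothermPoint], weighting: str = "proportional") -> LangmuirFit:
    """Nonlinear least-squares Langmuir fit with double-reciprocal start.

    ``weighting="proportional"`` (default) weights residuals by 1/C_eq:
    under the depletion readout, multiplicative absorbance noise enters
    the bound density with standard deviation proportional to the free
    concentration, so this is the matching heteroscedastic model.
    ``weighting="uniform"`` is ordinary least squares.
    """
    x, y = _check_points(points)
    ka0, n0 = _reciprocal_init(x, y)
    if weighting == "proportional":
        sigma = np.maximum(x, 1e-3 * x.max())
    elif weighting == "uniform":
        sigma = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                langmuir, x, y, p0=(ka0, n0), sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
    except RuntimeError as exc:
        raise FitError(
            f"Langmuir fit did not converge (init Ka={ka0:g}, N={n0:g})",
            init=(ka0, n0),
        ) from exc
    ka, n = popt
    se = np.sqrt(np.diag(pcov))
    fitted = langmuir(x, ka, n)
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, fitted)[0, 1])
    else:
        r = 0.0
    return LangmuirFit(Ka=float(ka), N=float(n), se_Ka=float(se[0]),
                       se_N=float(se[1]), r=r)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def classify_isotherm(points: list[IsothermPoint], r2_threshold: float = 0.8) -> str:
    """Classify an isotherm as "langmuir", "linear", or "other".

    Compares the Langmuir model with a line through the origin by
    small-sample-corrected AIC; if the winning model explains less than
    ``r2_threshold`` of the variance, the isotherm is "other" (complex or
    multistep binding, or pure noise).
    """
    x, y = _check_points(points)
    n = len(x)
    tss = float(np.sum((y - y.mean()) ** 2))

    slope = float(np.sum(x * y) / np.sum(x * x)) if np.any(x != 0) else 0.0
    rss_lin = float(np.sum((y - slope * x) ** 2))
    aicc_lin = _aicc(rss_lin, n, 1)

    try:
        fit = fit_langmuir(points, weighting="uniform")
        rss_lang = float(np.sum((y - langmuir(x, fit.Ka, fit.N)) ** 2))
        aicc_lang = _aicc(rss_lang, n, 2)
    except FitError:
        rss_lang, aicc_lang = math.inf, math.inf

    if aicc_lang < aicc_lin:
        best, rss = "langmuir", rss_lang
    else:
        best, rss = "linear", rss_lin
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-30 else 0.0)
    return best if r2 >= r2_threshold else "other"
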