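"""Reduction of static and dynamic light-scattering observations.

Static side: relative scattering intensities referenced to toluene are
converted to excess Rayleigh ratios and apparent molar masses. Dynamic
side: intensity autocorrelation functions are reduced to decay-rate
distributions by a regularized inverse Laplace transform (CONTIN-style
Tikhonov regularization with non-negativity) or to cumulants, and decay
rates are mapped to diffusion coefficients and Stokes radii.

Unit conventions: wavelengths in nm, angles in degrees, temperature in K,
viscosity in mPa s, dn/dc in mL/g, Rayleigh ratios in cm^-1,
concentrations in mg/mL, lags in s, diffusion coefficients in m^2/s,
radii in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import nnls

from .constants import AVOGADRO, BOLTZMANN

__all__ = [
    "InstrumentConfig",
    "IntensityRecord",
    "AcfCurve",
    "DecayDistribution",
    "CumulantResult",
    "scattering_vector",
    "optical_constant",
    "excess_rayleigh_ratio",
    "apparent_mass",
    "relative_mass",
    "cumulant_fit",
    "ilt_regularized",
    "rate_to_diffusion",
    "stokes_radius",
    "diffusion_from_radius",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and solvent parameters of the light-scattering setup.

    Defaults describe a 532 nm / 90 degree instrument with aqueous PBS at
    23 C (n = 1.333, eta = 0.932 mPa s), dn/dc = 0.19 mL/g, and toluene as
    the absolute-intensity reference (R = 2.1e-5 cm^-1 at 532 nm,
    n = 1.496).
    """

    wavelength_nm: float = 532.0
    scattering_angle_deg: float = 90.0
    temperature_K: float = 296.15
    solvent_refractive_index: float = 1.333
    solvent_viscosity_mPas: float = 0.932
    dndc_ml_g: float = 0.19
    reference_rayleigh_ratio_cm: float = 2.1e-5
    reference_refractive_index: float = 1.496

    def __post_init__(self):
        for name in (
            "wavelength_nm", "temperature_K", "solvent_refractive_index",
            "solvent_viscosity_mPas", "dndc_ml_g",
            "reference_rayleigh_ratio_cm", "reference_refractive_index",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.scattering_angle_deg < 180:
            raise ValueError("scattering angle must lie in (0, 180) degrees")


#: Acetate/glycerol formulation buffer preset (pH 4.5); viscosity is the
#: user-editable field most affected by the 18 mg/mL glycerol.
FORMULATION_BUFFER = InstrumentConfig(
    solvent_refractive_index=1.335, solvent_viscosity_mPas=0.98
)


@dataclass(frozen=True)
class IntensityRecord:
    """Mean static scattering intensities at one concentration (same gain)."""

    mean_intensity_sample: float
    mean_intensity_solvent: float
    mean_intensity_reference: float
    concentration_mg_ml: float

    def __post_init__(self):
        if self.mean_intensity_reference <= 0:
            raise ValueError("reference (toluene) intensity must be positive")
        if self.concentration_mg_ml <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class AcfCurve:
    """Normalized intensity autocorrelation data: g2(tau) - 1 vs lag."""

    lags_s: np.ndarray
    g2_minus_1: np.ndarray
    coherence_factor_hint: Optional[float] = None

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.g2_minus_1 = np.asarray(self.g2_minus_1, dtype=float)
        if self.lags_s.ndim != 1 or self.lags_s.size < 10:
            raise ValueError("need at least 10 lag points")
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags_s.shape != self.g2_minus_1.shape:
            raise ValueError("lags and g2-1 must have the same length")
        if self.coherence_factor_hint is not None and not (
            0 < self.coherence_factor_hint <= 1
        ):
            raise ValueError("coherence factor must lie in (0, 1]")

    def usable_range(self) -> tuple[np.ndarray, np.ndarray]:
        """Truncate at the first non-positive g2-1 point (noise tail)."""
        bad = np.nonzero(self.g2_minus_1 <= 0)[0]
        stop = bad[0] if bad.size else self.g2_minus_1.size
        return self.lags_s[:stop], self.g2_minus_1[:stop]


@dataclass
class DecayDistribution:
    """Intensity-weighted decay-rate distribution G(Gamma) on a log grid.

    ``lag_min_s``/``lag_max_s`` record the usable lag window of the curve
    the distribution was inverted from; they bound the decay rates the
    data can actually resolve. Modes placed by the solver wholly outside
    that window are boundary artifacts of the inversion (they fit noise,
    not decay) and are excluded from the reported moments by default.
    """

    grid: np.ndarray  # decay rates Gamma in 1/s, strictly increasing
    weights: np.ndarray  # non-negative, normalized to sum 1
    regularization_parameter: float
    lag_min_s: float = 0.0
    lag_max_s: float = math.inf
    degenerate: bool = False

    #: a mode is considered resolved only if its mean rate is below
    #: ``FAST_MARGIN / lag_min`` — faster decays are over before the
    #: first correlator lag and cannot be genuine.
    FAST_MARGIN = 0.3

    def modes(self) -> list:
        """Contiguous positive segments as (slice, weight, mean_rate)."""
        out = []
        pos = self.weights > 0
        i = 0
        n = self.weights.size
        while i < n:
            if pos[i]:
                j = i
                while j + 1 < n and pos[j + 1]:
                    j += 1
                sl = slice(i, j + 1)
                w = float(self.weights[sl].sum())
                mr = float(self.weights[sl] @ self.grid[sl]) / w
                out.append((sl, w, mr))
                i = j + 1
            else:
                i += 1
        return out

    def resolved_window(self) -> tuple[float, float]:
        lo = 1.0 / self.lag_max_s if self.lag_max_s < math.inf else 0.0
        hi = self.FAST_MARGIN / self.lag_min_s if self.lag_min_s > 0 else math.inf
        return lo, hi

    def mean_rate(self, resolved_only: bool = True) -> float:
        """Intensity-weighted mean decay rate in 1/s.

        With ``resolved_only`` (default) the moment runs over the modes
        whose mean rate lies inside the resolved window; if no mode
        qualifies, all modes are used.
        """
        if not resolved_only:
            return float(np.dot(self.weights, self.grid))
        lo, hi = self.resolved_window()
        keep = [(w, mr) for _, w, mr in self.modes() if lo <= mr <= hi]
        if not keep:
            return float(np.dot(self.weights, self.grid))
        tot = sum(w for w, _ in keep)
        return sum(w * mr for w, mr in keep) / tot

    def mean_diffusion(self, config: InstrumentConfig,
                       resolved_only: bool = True) -> float:
        """Intensity-weighted mean diffusion coefficient, m^2/s."""
        q = scattering_vector(config)
        return self.mean_rate(resolved_only) / q**2


@dataclass
class CumulantResult:
    beta: float
    mean_rate: float  # 1/s
    polydispersity: float  # mu2 / mean_rate^2


def scattering_vector(config: InstrumentConfig) -> float:
    """Magnitude of the scattering vector q = (4 pi n / lambda) sin(theta/2), 1/m."""
    lam_m = config.wavelength_nm * 1e-9
    theta = math.radians(config.scattering_angle_deg)
    return 4 * math.pi * config.solvent_refractive_index / lam_m * math.sin(theta / 2)


def optical_constant(config: InstrumentConfig) -> float:
    """SLS optical constant K = 4 pi^2 n^2 (dn/dc)^2 / (N_A lambda^4), cgs.

    With dn/dc in cm^3/g and lambda in cm, K has units cm^2 mol g^-2, so
    K * c[g/cm^3] * M[g/mol] is a Rayleigh ratio in cm^-1.
    """
    lam_cm = config.wavelength_nm * 1e-7
    n = config.solvent_refractive_index
    return (
        4 * math.pi**2 * n**2 * config.dndc_ml_g**2 / (AVOGADRO * lam_cm**4)
    )


def excess_rayleigh_ratio(rec: IntensityRecord, config: InstrumentConfig) -> float:
    """Excess Rayleigh ratio in cm^-1 from toluene-referenced intensities.

    R_ex = (I_s - I_0)/I_tol * R_tol * (n/n_tol)^2; the refractive-index
    ratio corrects the scattering volume seen by the detector.
    """
    ratio = (
        rec.mean_intensity_sample - rec.mean_intensity_solvent
    ) / rec.mean_intensity_reference
    n_corr = (
        config.solvent_refractive_index / config.reference_refractive_index
    ) ** 2
    return ratio * config.reference_rayleigh_ratio_cm * n_corr


def apparent_mass(rec: IntensityRecord, config: InstrumentConfig) -> float:
    """Apparent molar mass M_app = R_ex / (K c) in g/mol.

    Returns 0.0 (with a warning) when the sample shows no excess
    scattering over the solvent.
    """
    r_ex = excess_rayleigh_ratio(rec, config)
    if r_ex <= 0:
        warnings.warn(
            "sample intensity does not exceed solvent; apparent mass set to 0",
            stacklevel=2,
        )
        return 0.0
    c_g_cm3 = rec.concentration_mg_ml * 1e-3
    return r_ex / (optical_constant(config) * c_g_cm3)


def relative_mass(m_app: float, monomer_mass: float) -> float:
    """M_rel = apparent mass over the sequence-derived monomer mass."""
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    return m_app / monomer_mass


def cumulant_fit(acf: AcfCurve, order: int = 2) -> CumulantResult:
    """Cumulant analysis: weighted polynomial fit of ln sqrt(g2-1).

    ln sqrt(g2-1) = 0.5 ln beta - mean_rate * tau + (mu2/2) tau^2. Points
    after the first non-positive g2-1 value are discarded; the fit is
    amplitude-weighted so the early, high-signal lags dominate.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    lags, y = acf.usable_range()
    if lags.size < order + 2:
        raise ValueError("too few usable (positive) ACF points for cumulant fit")
    z = 0.5 * np.log(y)
    # weights ~ signal amplitude: delta(ln y) = delta(y)/y
    coeffs = np.polyfit(lags, z, deg=order, w=y)
    if order == 1:
        mu2 = 0.0
        slope, intercept = coeffs
    else:
        half_mu2, slope, intercept = coeffs
        mu2 = 2.0 * half_mu2
    mean_rate = -slope
    # require a resolvable decay over the fitted range, not just slope != 0
    if mean_rate * (lags[-1] - lags[0]) < 1e-6:
        raise ValueError("no decay detected over the usable lag range")
    return CumulantResult(
        beta=float(np.exp(2 * intercept)),
        mean_rate=float(mean_rate),
        polydispersity=float(mu2 / mean_rate**2),
    )


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _nnls_tikhonov(K, y, L, alpha):
    A = np.vstack([K, alpha * L])
    b = np.concatenate([y, np.zeros(L.shape[0])])
    g, _ = nnls(A, b)
    resid = float(np.linalg.norm(K @ g - y))
    smooth = float(np.linalg.norm(L @ g))
    return g, resid, smooth


def _l_curve_corner(residuals, smoothness):
    """Corner of the (log rho, log eta) L-curve by the triangle method.

    The corner is the point farthest from the chord joining the curve's
    endpoints — more robust than discrete curvature when the residual
    branch is nearly flat.
    """
    eps = 1e-300
    x = np.log10(np.asarray(residuals) + eps)
    y = np.log10(np.asarray(smoothness) + eps)
    if len(x) < 3:
        return len(x) // 2
    # normalize both axes so the chord distance is scale-free
    xs = (x - x.min()) / max(np.ptp(x), eps)
    ys = (y - y.min()) / max(np.ptp(y), eps)
    p0 = np.array([xs[0], ys[0]])
    p1 = np.array([xs[-1], ys[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord) + eps
    pts = np.column_stack([xs, ys]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def ilt_regularized(
    acf: AcfCurve,
    grid_size: int = 150,
    alpha: Optional[float] = None,
    n_alpha: int = 20,
    method: str = "residual_tolerance",
    residual_tolerance: float = 1.02,
    noise_sigma: Optional[float] = None,
) -> DecayDistribution:
    """Regularized inverse Laplace transform of a DLS autocorrelation curve.

    Fits the field correlation g1 = sqrt(g2 - 1) (Siegert relation) with a
    non-negative superposition of exponentials on a log-spaced decay-rate
    grid spanning [0.1/tau_max, 10/tau_min]:

        min_G ||K G - y||^2 + alpha^2 ||L G||^2,  G >= 0

    with K_ij = exp(-Gamma_j tau_i), L the second-difference operator on
    the log-rate grid, and rows weighted by the g1 amplitude (the
    inverse-variance weighting for correlator baseline noise).

    When ``alpha`` is not given it is chosen over a ``n_alpha``-point
    logarithmic scan by one of three rules: ``'residual_tolerance'``
    (default) takes the largest alpha whose residual stays within
    ``residual_tolerance`` times the best residual of the scan — the
    smoothest solution the data do not reject; ``'l_curve'`` takes the
    corner of the (log residual, log seminorm) curve; ``'discrepancy'``
    matches the residual to ``noise_sigma``. The coherence factor beta
    is absorbed into the weights, which are normalized to sum 1.
    """
    lags, g2m1 = acf.usable_range()
    if lags.size < 4:
        raise ValueError("too few usable ACF points for inversion")
    y = np.sqrt(g2m1)
    grid = np.geomspace(0.1 / lags[-1], 10.0 / lags[0], grid_size)
    K = np.exp(-np.outer(lags, grid))
    L = _second_difference(grid_size)
    w = y / y.max()
    K = K * w[:, None]
    y = y * w

    if alpha is not None:
        g, _, _ = _nnls_tikhonov(K, y, L, alpha)
        chosen = alpha
    else:
        alphas = np.geomspace(1e-4, 1e2, n_alpha)
        sols, resids, smooths = [], [], []
        for a in alphas:
            g, r, s = _nnls_tikhonov(K, y, L, a)
            sols.append(g)
            resids.append(r)
            smooths.append(s)
        if method == "residual_tolerance":
            r_min = min(resids)
            idx = max(
                i for i, r in enumerate(resids)
                if r <= residual_tolerance * r_min + 1e-12
            )
        elif method == "l_curve":
            idx = _l_curve_corner(resids, smooths)
        elif method == "discrepancy":
            if noise_sigma is None:
                raise ValueError("discrepancy principle needs noise_sigma")
            target = noise_sigma * math.sqrt(len(y))
            idx = int(np.argmin(np.abs(np.asarray(resids) - target)))
        else:
            raise ValueError(f"unknown alpha-selection method {method!r}")
        g = sols[idx]
        chosen = float(alphas[idx])

    total = g.sum()
    if total <= 0:
        return DecayDistribution(
            grid, np.zeros_like(g), chosen,
            lag_min_s=float(lags[0]), lag_max_s=float(lags[-1]),
            degenerate=True,
        )
    return DecayDistribution(
        grid, g / total, chosen,
        lag_min_s=float(lags[0]), lag_max_s=float(lags[-1]),
    )


def rate_to_diffusion(mean_rate: float, config: InstrumentConfig) -> float:
    """D = Gamma / q^2, m^2/s."""
    return mean_rate / scattering_vector(config) ** 2


def stokes_radius(diffusion_m2_s: float, config: InstrumentConfig) -> float:
    """Stokes-Einstein radius R_S = kB T / (6 pi eta D), in nm."""
    if diffusion_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    eta = config.solvent_viscosity_mPas * 1e-3  # Pa s
    r_m = BOLTZMANN * config.temperature_K / (6 * math.pi * eta * diffusion_m2_s)
    return r_m * 1e9


def diffusion_from_radius(radius_nm: float, config: InstrumentConfig) -> float:
    """Inverse of :func:`stokes_radius`: D in m^2/s for a radius in nm."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    eta = config.solvent_viscosity_mPas * 1e-3
    return BOLTZMANN * config.temperature_K / (6 * math.pi * eta * radius_nm * 1e-9)
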