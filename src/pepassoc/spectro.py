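"""Spectroscopy reductions: CD, tryptophan fluorescence, NOE distances.

Circular dichroism signals are converted to mean-residue or molar
ellipticities; alpha-helix content is estimated from the 222 nm
mean-residue ellipticity with a chain-length-corrected single-wavelength
estimator. Fluorescence emission spectra are concentration-normalized
and the emission maximum is located by a local parabolic fit. NOESY
cross-peak intensities convert to interproton distances through the
r^-6 law against a reference pair of known separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "NoePeak",
    "mean_residue_ellipticity",
    "molar_ellipticity",
    "helix_fraction",
    "subtract_blank",
    "fluorescence_lambda_max",
    "LambdaMaxResult",
    "noe_distance",
]


@dataclass
class Spectrum:
    """A wavelength-resolved signal with the context needed for conversion.

    ``signal`` units depend on the experiment: millidegrees for CD,
    arbitrary counts for fluorescence. Concentration in mg/mL, pathlength
    in cm.
    """

    wavelengths_nm: np.ndarray
    signal: np.ndarray
    pathlength_cm: float = 1.0
    concentration_mg_ml: float = 1.0
    molar_mass_da: float = 0.0
    n_residues: int = 0

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        d = np.diff(self.wavelengths_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelengths must be strictly monotone")
        if self.wavelengths_nm.shape != self.signal.shape:
            raise ValueError("wavelengths and signal must have the same length")
        if self.pathlength_cm <= 0 or self.concentration_mg_ml <= 0:
            raise ValueError("pathlength and concentration must be positive")

    @property
    def mean_residue_weight(self) -> float:
        if self.n_residues <= 0 or self.molar_mass_da <= 0:
            raise ValueError("molar mass and residue count required")
        return self.molar_mass_da / self.n_residues


def mean_residue_ellipticity(spec: Spectrum) -> np.ndarray:
    """theta_MRW = theta[mdeg] * MRW / (10 * l[cm] * c[mg/mL]), deg cm^2/dmol."""
    return spec.signal * spec.mean_residue_weight / (
        10.0 * spec.pathlength_cm * spec.concentration_mg_ml
    )


def molar_ellipticity(spec: Spectrum) -> np.ndarray:
    """theta_M = theta_MRW * n_residues (whole-molecule molar basis)."""
    return spec.signal * spec.molar_mass_da / (
        10.0 * spec.pathlength_cm * spec.concentration_mg_ml
    )


def helix_fraction(
    theta_mrw_222: float,
    n_residues: int,
    theta_inf: float = -39500.0,
    chain_length_k: float = 2.57,
) -> float:
    """Alpha-helix fraction from the 222 nm mean-residue ellipticity.

    f_H = theta222 / (theta_inf * (1 - k/n)): the single-wavelength
    estimator with the finite-chain correction (defaults theta_inf =
    -39500 deg cm^2/dmol, k = 2.57). Returned unclamped; a coil-baseline
    variant is obtained by passing a nonzero ``theta_coil``-adjusted
    theta222 upstream.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    return theta_mrw_222 / (theta_inf * (1.0 - chain_length_k / n_residues))


def subtract_blank(spec: Spectrum, blank: Spectrum) -> Spectrum:
    """Solvent-blank subtraction after concentration normalization.

    Both spectra must share a wavelength grid; the blank (e.g. free
    tryptophan in the same solvent) is subtracted point-wise from the
    concentration-normalized sample signal.
    """
    if not np.array_equal(spec.wavelengths_nm, blank.wavelengths_nm):
        raise ValueError("sample and blank must share the wavelength grid")
    norm = spec.signal / spec.concentration_mg_ml - blank.signal
    return Spectrum(
        wavelengths_nm=spec.wavelengths_nm.copy(),
        signal=norm,
        pathlength_cm=spec.pathlength_cm,
        concentration_mg_ml=1.0,
        molar_mass_da=spec.molar_mass_da,
        n_residues=spec.n_residues,
    )


@dataclass(frozen=True)
class LambdaMaxResult:
    lambda_max_nm: float
    at_edge: bool  # True when the discrete maximum sits on the spectrum edge


def fluorescence_lambda_max(
    spec: Spectrum, window_nm: float = 5.0
) -> LambdaMaxResult:
    """Emission maximum from a parabola fitted around the discrete maximum.

    The signal is concentration-normalized first; points within
    ``window_nm`` of the discrete maximum feed a quadratic fit whose
    vertex is returned. A maximum on the spectrum edge is flagged and the
    discrete value returned unchanged.
    """
    wl = spec.wavelengths_nm
    y = spec.signal / spec.concentration_mg_ml
    imax = int(np.argmax(y))
    if imax == 0 or imax == y.size - 1:
        return LambdaMaxResult(float(wl[imax]), at_edge=True)
    sel = np.abs(wl - wl[imax]) <= window_nm
    if sel.sum() < 3:
        raise ValueError("need at least 3 points around the maximum")
    a, b, _ = np.polyfit(wl[sel], y[sel], 2)
    if a >= 0:  # no curvature: fall back to the discrete maximum
        return LambdaMaxResult(float(wl[imax]), at_edge=False)
    return LambdaMaxResult(float(-b / (2 * a)), at_edge=False)


@dataclass(frozen=True)
class NoePeak:
    """Integrated NOESY cross-peak intensity."""

    intensity: float
    label: str = ""

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("NOE intensity must be positive")


def noe_distance(
    peak: NoePeak, reference: NoePeak, r_ref_angstrom: float = 2.55
) -> float:
    """Interproton distance r = r_ref * (I_ref / I)^(1/6), in Angstrom.

    The default reference distance 2.55 A is the fixed separation of the
    tryptophan ring H1-H2 pair used to calibrate the intensity scale.
    """
    return r_ref_angstrom * (reference.intensity / peak.intensity) ** (1.0 / 6.0)
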