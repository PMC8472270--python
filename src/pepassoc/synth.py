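"""Seeded forward models generating every input the analysis consumes.

Each generator is the exact forward model of the formulas its consumer
inverts, so zero-noise round-trips are identities within solver
tolerance. Defaults emulate the exendin-4-like study conditions: a
4187.6 Da monomer with a 1.4 nm Stokes radius associating into trimers
with visible dissociation below ~0.2 mM, 12 log-spaced concentrations
over 0.01-2 mM, 10% relative error on apparent mass and 3% on Stokes
radius, lognormal for positive observables and additive Gaussian for
ACF points. All randomness flows from the single seed of a
numpy Generator; nothing touches global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .association import (
    AssociationModel,
    AssociationSeries,
    apparent_radius_curve,
    relative_mass_curve,
)
from .scattering import (
    AcfCurve,
    InstrumentConfig,
    IntensityRecord,
    diffusion_from_radius,
    optical_constant,
    scattering_vector,
)
from .spectro import Spectrum
from .structure import AtomSet

__all__ = [
    "GeneratorSpec",
    "default_exendin_model",
    "gen_acf",
    "gen_intensity_record",
    "gen_association_series",
    "gen_helix_coords",
    "gen_c3_template",
    "gen_spectrum",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Noise levels and concentration grid of the synthetic study."""

    seed: int = 0
    acf_noise_sigma: float = 0.0
    mass_relerr: float = 0.10
    radius_relerr: float = 0.03
    n_concentrations: int = 12
    conc_range_mM: tuple = (0.01, 2.0)

    def __post_init__(self):
        if min(self.acf_noise_sigma, self.mass_relerr, self.radius_relerr) < 0:
            raise ValueError("noise levels must be >= 0")

    def concentration_grid(self) -> np.ndarray:
        lo, hi = self.conc_range_mM
        return np.geomspace(lo, hi, self.n_concentrations)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_exendin_model() -> AssociationModel:
    """Exendin-4-like monomer <-> trimer model.

    K3 = 1e9 M^-2 places the half-association transition (M_rel ~ 2)
    near 0.1 mM, matching visible dissociation below ~0.2 mM.
    """
    return AssociationModel(
        monomer_mass=4187.6,
        species=((1, 0.0), (3, 9.0)),
        monomer_radius_nm=1.4,
        radius_exponent=0.44,
    )


def gen_acf(
    species: Sequence[tuple],
    config: InstrumentConfig,
    lags_s: Optional[np.ndarray] = None,
    beta: float = 0.8,
    noise_sigma: float = 0.0,
    rel_noise_sigma: float = 0.0,
    seed: int = 0,
) -> AcfCurve:
    """Multi-exponential intensity ACF for species given as (R_S nm, weight).

    g2 - 1 = beta * (sum_i w_i exp(-D_i q^2 tau))^2 + noise, with D_i
    from the Stokes-Einstein inversion of each radius and the intensity
    weights normalized to sum 1. ``noise_sigma`` adds Gaussian noise of
    fixed amplitude; ``rel_noise_sigma`` adds multiplicative Gaussian
    noise (signal-proportional, the shape typical of well-averaged
    correlator data).
    """
    radii = np.array([r for r, _ in species], dtype=float)
    weights = np.array([w for _, w in species], dtype=float)
    if np.any(weights <= 0) or np.any(radii <= 0):
        raise ValueError("radii and weights must be positive")
    weights = weights / weights.sum()
    q = scattering_vector(config)
    rates = np.array(
        [diffusion_from_radius(r, config) * q**2 for r in radii]
    )
    if lags_s is None:
        # span ~4 decades around the slowest/fastest decay
        lags_s = np.geomspace(0.01 / rates.max(), 10.0 / rates.min(), 160)
    lags_s = np.asarray(lags_s, dtype=float)
    g1 = np.sum(weights[:, None] * np.exp(-np.outer(rates, lags_s)), axis=0)
    g2m1 = beta * g1**2
    if noise_sigma > 0 or rel_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if rel_noise_sigma > 0:
            g2m1 = g2m1 * (1.0 + rng.normal(0.0, rel_noise_sigma, g2m1.shape))
        if noise_sigma > 0:
            g2m1 = g2m1 + rng.normal(0.0, noise_sigma, size=g2m1.shape)
    return AcfCurve(lags_s=lags_s, g2_minus_1=g2m1, coherence_factor_hint=beta)


def gen_intensity_record(
    molar_mass_da: float,
    concentration_mg_ml: float,
    config: InstrumentConfig,
    solvent_intensity: float = 1000.0,
    reference_intensity: float = 50000.0,
) -> IntensityRecord:
    """Static-scattering intensities that encode a given molar mass.

    Inverts the apparent-mass reduction exactly: the sample excess over
    solvent is chosen so the excess Rayleigh ratio equals K c M.
    """
    r_ex = (
        optical_constant(config) * concentration_mg_ml * 1e-3 * molar_mass_da
    )
    n_corr = (
        config.solvent_refractive_index / config.reference_refractive_index
    ) ** 2
    excess = r_ex / (config.reference_rayleigh_ratio_cm * n_corr) * reference_intensity
    return IntensityRecord(
        mean_intensity_sample=solvent_intensity + excess,
        mean_intensity_solvent=solvent_intensity,
        mean_intensity_reference=reference_intensity,
        concentration_mg_ml=concentration_mg_ml,
    )


def gen_association_series(
    model: AssociationModel,
    spec: GeneratorSpec,
    with_radius: bool = True,
) -> AssociationSeries:
    """Noisy M_rel(c) and R_S(c) series from the exact association model.

    Observables are multiplied by lognormal noise whose sigma matches
    the spec's relative errors (median-unbiased: mean of log is 0).
    """
    rng = spec.rng()
    c = spec.concentration_grid()
    m_rel = relative_mass_curve(c, model)
    if spec.mass_relerr > 0:
        m_rel = m_rel * rng.lognormal(0.0, spec.mass_relerr, size=c.size)
    r_s = None
    if with_radius:
        r_s = apparent_radius_curve(c, model)
        if spec.radius_relerr > 0:
            r_s = r_s * rng.lognormal(0.0, spec.radius_relerr, size=c.size)
    return AssociationSeries(
        concentrations_mM=c,
        m_rel=m_rel,
        m_rel_relerr=spec.mass_relerr if spec.mass_relerr > 0 else 0.10,
        r_s_nm=r_s,
        r_s_relerr=spec.radius_relerr if spec.radius_relerr > 0 else 0.03,
    )


def gen_helix_coords(
    n_residues: int,
    rise_angstrom: float = 1.5,
    twist_deg: float = 100.0,
    radius_angstrom: float = 2.3,
    chain_id: str = "A",
) -> AtomSet:
    """Synthetic ideal-helix C-alpha trace (3.6 residues/turn by default)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n_residues)
    ang = np.radians(twist_deg) * i
    coords = np.column_stack(
        [radius_angstrom * np.cos(ang), radius_angstrom * np.sin(ang),
         rise_angstrom * i]
    )
    return AtomSet(
        chain_ids=np.full(n_residues, chain_id),
        res_ids=i + 1,
        res_names=np.full(n_residues, "ALA"),
        atom_names=np.full(n_residues, "CA"),
        coords=coords,
    )


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def gen_c3_template(
    monomer: AtomSet, radial_offset_angstrom: float = 10.0
) -> AtomSet:
    """Synthetic C3-symmetric trimer template built from a monomer.

    Three copies of the (centered) monomer are shifted radially and
    rotated by 0/120/240 degrees about z; a stand-in for a trimeric
    crystal template when no experimental oligomer is available.
    """
    centered = monomer.coords - monomer.coords.mean(axis=0)
    pieces = []
    for k, chain in enumerate("ABC"):
        rot = _rotation_z(2.0 * math.pi * k / 3.0)
        coords = (centered + np.array([radial_offset_angstrom, 0.0, 0.0])) @ rot.T
        pieces.append(
            AtomSet(
                np.full(len(monomer), chain),
                monomer.res_ids.copy(),
                monomer.res_names.copy(),
                monomer.atom_names.copy(),
                coords,
            )
        )
    return AtomSet(
        np.concatenate([p.chain_ids for p in pieces]),
        np.concatenate([p.res_ids for p in pieces]),
        np.concatenate([p.res_names for p in pieces]),
        np.concatenate([p.atom_names for p in pieces]),
        np.concatenate([p.coords for p in pieces]),
    )


def gen_spectrum(
    kind: str,
    target: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    wavelengths_nm: Optional[np.ndarray] = None,
    pathlength_cm: float = 0.1,
    concentration_mg_ml: float = 0.2,
    molar_mass_da: float = 4187.6,
    n_residues: int = 39,
) -> Spectrum:
    """Synthetic CD or fluorescence spectrum.

    kind='cd': sum of Gaussian helix bands (minima at 208 and 222 nm) and
    a coil band (198 nm), rescaled so the mean-residue ellipticity at
    222 nm equals ``target`` exactly at zero noise; the stored signal is
    in millidegrees for the given pathlength/concentration.

    kind='fluorescence': Gaussian emission band peaked at ``target`` nm
    (width 30 nm) on a 290-450 nm grid.

    Noise is additive Gaussian on the stored signal, seeded.
    """
    rng = np.random.default_rng(seed)
    if kind == "cd":
        wl = (
            np.arange(190.0, 261.0, 1.0)
            if wavelengths_nm is None
            else np.asarray(wavelengths_nm, dtype=float)
        )
        helix = -(
            np.exp(-0.5 * ((wl - 208.0) / 6.0) ** 2)
            + np.exp(-0.5 * ((wl - 222.0) / 7.0) ** 2)
        ) + 0.9 * np.exp(-0.5 * ((wl - 192.0) / 5.0) ** 2)
        shape_222 = np.interp(222.0, wl, helix)
        theta_mrw = helix * (target / shape_222)
        mrw = molar_mass_da / n_residues
        signal_mdeg = theta_mrw * 10.0 * pathlength_cm * concentration_mg_ml / mrw
        if noise_sigma > 0:
            signal_mdeg = signal_mdeg + rng.normal(0, noise_sigma, wl.size)
        return Spectrum(wl, signal_mdeg, pathlength_cm, concentration_mg_ml,
                        molar_mass_da, n_residues)
    if kind == "fluorescence":
        wl = (
            np.arange(290.0, 451.0, 1.0)
            if wavelengths_nm is None
            else np.asarray(wavelengths_nm, dtype=float)
        )
        signal = np.exp(-0.5 * ((wl - target) / 30.0) ** 2)
        if noise_sigma > 0:
            signal = signal + rng.normal(0, noise_sigma * signal.max(), wl.size)
        return Spectrum(wl, signal, pathlength_cm, concentration_mg_ml,
                        molar_mass_da, n_residues)
    raise ValueError(f"unknown spectrum kind {kind!r}")
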