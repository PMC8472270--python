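"""Mass-action self-association models and fitting.

A peptide A is allowed to populate a monomer plus a small set of defined
oligomers A_n (e.g. monomer <-> trimer, optionally extended by a hexamer
treated as a dimer of trimers). Equilibrium constants are on the molar
species basis, K_n = [A_n]/[A]^n, and totals are monomer-equivalent.
The model predicts the weight-average relative mass M_rel(c) measured by
static light scattering and the z-average apparent Stokes radius R_S(c)
measured by dynamic light scattering, and is fitted to concentration
series of either or both observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "AssociationModel",
    "AssociationSeries",
    "FitResult",
    "solve_species",
    "weight_average_mass",
    "relative_mass_curve",
    "apparent_radius",
    "fit_association",
]


@dataclass(frozen=True)
class AssociationModel:
    """Monomer <-> n-mer mass-action model.

    Parameters
    ----------
    monomer_mass : float
        Monomer molar mass M1 in Da.
    species : tuple[tuple[int, float], ...]
        Ordered ``(stoichiometry n, log10 K_n)`` pairs. The first entry
        must be the monomer ``(1, 0.0)``; stoichiometries strictly
        increase. K_n is on the molar species basis [A_n]/[A]^n, so its
        units are M^(1-n).
    monomer_radius_nm : float
        Stokes radius of the monomer, R1.
    radius_exponent : float
        nu in R_n = R1 * n^nu. 1/3 for compact spheres, 1/2 for Gaussian
        coils; the default 0.44 reflects oligomers of intermediate
        compactness.
    """

    monomer_mass: float
    species: tuple = ((1, 0.0),)
    monomer_radius_nm: float = 1.4
    radius_exponent: float = 0.44

    def __post_init__(self):
        if self.monomer_mass <= 0:
            raise ValueError("monomer mass must be positive")
        ns = [n for n, _ in self.species]
        if not ns or ns[0] != 1:
            raise ValueError("first species must be the monomer (n=1)")
        if self.species[0][1] != 0.0:
            raise ValueError("monomer log10_K must be 0 (K1 = 1)")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("stoichiometries must strictly increase")
        if self.monomer_radius_nm <= 0:
            raise ValueError("monomer radius must be positive")
        if not 0 < self.radius_exponent <= 1:
            raise ValueError("radius exponent must lie in (0, 1]")

    @property
    def stoichiometries(self) -> np.ndarray:
        return np.array([n for n, _ in self.species], dtype=float)

    @property
    def constants(self) -> np.ndarray:
        return np.array([10.0 ** lk for _, lk in self.species])

    def species_radius(self, n: float) -> float:
        return self.monomer_radius_nm * n**self.radius_exponent

    def with_log10_k(self, log10_ks: Sequence[float]) -> "AssociationModel":
        """Copy of the model with the oligomer log10 K values replaced."""
        if len(log10_ks) != len(self.species) - 1:
            raise ValueError("need one log10_K per oligomeric species")
        new = ((1, 0.0),) + tuple(
            (n, float(lk)) for (n, _), lk in zip(self.species[1:], log10_ks)
        )
        return replace(self, species=new)


@dataclass
class AssociationSeries:
    """Concentration series of reduced light-scattering observables.

    Concentrations are total (monomer-equivalent) in mM; relative errors
    default to the experimental 10% on apparent mass and 3% on Stokes
    radius.
    """

    concentrations_mM: np.ndarray
    m_rel: np.ndarray
    m_rel_relerr: float = 0.10
    r_s_nm: Optional[np.ndarray] = None
    r_s_relerr: float = 0.03

    def __post_init__(self):
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        self.m_rel = np.asarray(self.m_rel, dtype=float)
        if np.any(self.concentrations_mM <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations_mM) <= 0):
            raise ValueError("concentrations must be sorted strictly increasing")
        if self.m_rel.shape != self.concentrations_mM.shape:
            raise ValueError("m_rel length mismatch")
        if self.r_s_nm is not None:
            self.r_s_nm = np.asarray(self.r_s_nm, dtype=float)
            if self.r_s_nm.shape != self.concentrations_mM.shape:
                raise ValueError("r_s length mismatch")


@dataclass
class FitResult:
    params: dict  # name -> estimate
    stderr: dict  # name -> standard error (may contain None)
    residual_sum: float
    n_obs: int
    n_varied: int
    aicc: float
    converged: bool
    lmfit_result: object = field(repr=False, default=None)

    def model(self, template: AssociationModel) -> AssociationModel:
        """Template with this fit's log10 K estimates substituted."""
        lks = [
            self.params[f"log10_K{n}"] for n, _ in template.species[1:]
        ]
        out = template.with_log10_k(lks)
        if "monomer_radius_nm" in self.params:
            out = replace(out, monomer_radius_nm=self.params["monomer_radius_nm"])
        if "radius_exponent" in self.params:
            out = replace(out, radius_exponent=self.params["radius_exponent"])
        return out


def solve_species(c_total_M: float, model: AssociationModel) -> np.ndarray:
    """Molar concentration of each species at a monomer-equivalent total.

    The free monomer m solves sum_i n_i K_i m^(n_i) = c_total; the left
    side is strictly increasing in m, so bisection on [0, c_total] is
    robust. Converged to 1e-12 relative on m.
    """
    if c_total_M <= 0:
        raise ValueError("total concentration must be positive")
    ns = model.stoichiometries
    ks = model.constants

    def total(m):
        return float(np.sum(ns * ks * m**ns))

    # bisect to the floating-point limit: the conservation error scales
    # with d(total)/dm, which can be orders of magnitude above 1
    lo, hi = 0.0, c_total_M
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if total(mid) > c_total_M:
            hi = mid
        else:
            lo = mid
    m = 0.5 * (lo + hi)
    return ks * m**ns


def weight_average_mass(c_total_M: float, model: AssociationModel) -> float:
    """Weight-average molar mass M_w = M1 sum(n^2 c_n) / sum(n c_n), Da."""
    conc = solve_species(c_total_M, model)
    ns = model.stoichiometries
    return model.monomer_mass * float(
        np.sum(ns**2 * conc) / np.sum(ns * conc)
    )


def relative_mass_curve(c_total_mM, model: AssociationModel) -> np.ndarray:
    """M_rel(c) = M_w(c)/M1 on a grid of mM totals."""
    c = np.atleast_1d(np.asarray(c_total_mM, dtype=float))
    return np.array(
        [weight_average_mass(ci * 1e-3, model) / model.monomer_mass for ci in c]
    )


def apparent_radius(c_total_M: float, model: AssociationModel) -> float:
    """Apparent (z-average) Stokes radius of the equilibrium mixture, nm.

    Species are intensity-weighted (w_n ~ n^2 c_n, the Rayleigh limit);
    diffusion coefficients average as D_z = sum(w D)/sum(w) and the
    returned radius is the Stokes-Einstein inverse of D_z, which reduces
    to the intensity-weighted harmonic mean of the species radii.
    """
    conc = solve_species(c_total_M, model)
    ns = model.stoichiometries
    w = ns**2 * conc
    radii = model.monomer_radius_nm * ns**model.radius_exponent
    return float(np.sum(w) / np.sum(w / radii))


def apparent_radius_curve(c_total_mM, model: AssociationModel) -> np.ndarray:
    c = np.atleast_1d(np.asarray(c_total_mM, dtype=float))
    return np.array([apparent_radius(ci * 1e-3, model) for ci in c])


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_association(
    data: AssociationSeries,
    model_template: AssociationModel,
    vary_radius: bool = False,
    vary_exponent: bool = False,
    n_starts: int = 5,
    log10_k_bounds: tuple = (-3.0, 18.0),
) -> FitResult:
    """Weighted least-squares fit of an association model to a series.

    Minimizes sum(((obs - pred)/sigma)^2) jointly over the M_rel channel
    and, when present, the R_S channel, with sigma taken from the series'
    relative errors. log10 K values are fitted within box bounds with
    ``n_starts`` deterministic multi-starts (offsets around the template
    values) to guard against local minima. The monomer mass is fixed from
    sequence, never fitted. Reports AICc for model selection.
    """
    if data.concentrations_mM.size < 4:
        raise ValueError("need at least 4 concentration points")
    oligomers = model_template.species[1:]
    if not oligomers:
        raise ValueError("model must contain at least one oligomeric species")

    def residuals(params):
        lks = [params[f"log10_K{n}"].value for n, _ in oligomers]
        m = model_template.with_log10_k(lks)
        if vary_radius:
            m = replace(m, monomer_radius_nm=params["monomer_radius_nm"].value)
        if vary_exponent:
            m = replace(m, radius_exponent=params["radius_exponent"].value)
        res = [
            (data.m_rel - relative_mass_curve(data.concentrations_mM, m))
            / (data.m_rel_relerr * data.m_rel)
        ]
        if data.r_s_nm is not None:
            res.append(
                (data.r_s_nm - apparent_radius_curve(data.concentrations_mM, m))
                / (data.r_s_relerr * data.r_s_nm)
            )
        return np.concatenate(res)

    offsets = [0.0, -2.0, 2.0, -4.0, 4.0][: max(1, n_starts)]
    best = None
    for off in offsets:
        params = lmfit.Parameters()
        for n, lk in oligomers:
            start = min(max(lk + off, log10_k_bounds[0]), log10_k_bounds[1])
            params.add(f"log10_K{n}", value=start, min=log10_k_bounds[0],
                       max=log10_k_bounds[1])
        if vary_radius:
            params.add("monomer_radius_nm", value=model_template.monomer_radius_nm,
                       min=0.3, max=10.0)
        if vary_exponent:
            params.add("radius_exponent", value=model_template.radius_exponent,
                       min=0.05, max=1.0)
        try:
            out = lmfit.minimize(residuals, params, method="least_squares")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out

    if best is None:
        raise RuntimeError("all fit starts failed")

    n_obs = data.concentrations_mM.size * (2 if data.r_s_nm is not None else 1)
    k = int(best.nvarys)
    rss = float(best.chisqr)
    return FitResult(
        params={p: float(best.params[p].value) for p in best.params},
        stderr={p: (float(best.params[p].stderr)
                    if best.params[p].stderr is not None else None)
                for p in best.params},
        residual_sum=rss,
        n_obs=n_obs,
        n_varied=k,
        aicc=_aicc(rss, n_obs, k),
        converged=bool(best.success),
        lmfit_result=best,
    )
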