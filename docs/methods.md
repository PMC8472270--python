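# Methods

This note documents the models, numerical choices and known limitations of
the analysis chain, module by module.

## Sequence calculators

Average masses sum the standard average residue-mass table (G 57.0519 … W
186.2132 Da) plus one water, 18.0153 Da. The **free-acid C-terminus is the
default** because the specific-absorbance bookkeeping used to set peptide
concentrations is anchored to free-acid masses; the amide option subtracts
0.984 Da. Covalent conjugates (e.g. a γ-Glu–palmitoyl chain on a lysine) are
handled purely as a user-supplied mass delta — no structure-aware chemistry
— and d-amino-acid positions are mass-neutral annotations. Extinction
coefficients use the Pace/ProtParam composition rule (Trp 5500, Tyr 1490,
cystine 125 M⁻¹cm⁻¹); reduced cysteines contribute nothing, and disulfide
pairs must be declared explicitly.

Charge profiles average per-residue charges (D/E −1, K/R +1, H +0.5, others
0) over an odd sliding window (default 5). The +0.5 histidine convention
follows the common charge-plot tools; it is configurable (set H to 0, or to
a Henderson–Hasselbalch value for a chosen pH). The hydrophobic moment is
the modulus of the complex sum Σ H_i·e^{iδi} per residue with δ = 100°
(3.6 residues/turn); the default Fauchère–Pliška scale matches the common
helical-wheel servers, with the Eisenberg consensus scale selectable by
name. No pKa-based net-charge curves or monoisotopic masses are provided.

## Static light scattering

Apparent molar masses come from the excess Rayleigh ratio against a toluene
reference: R_ex = ((I_s − I_0)/I_tol)·R_tol·(n/n_tol)², M_app = R_ex/(K·c)
with the optical constant K = 4π²n²(dn/dc)²/(N_A λ⁴) in cgs-consistent
units. Defaults: λ = 532 nm, θ = 90°, T = 296.15 K (23 °C), PBS-like
solvent (n = 1.333, η = 0.932 mPa·s), dn/dc = 0.19 mL/g, and a
literature-typical toluene Rayleigh ratio of 2.1 × 10⁻⁵ cm⁻¹ at 532 nm with
n_tol = 1.496. A preset for an acetate/glycerol formulation buffer is
provided with a user-editable viscosity. A sample showing no excess over
the solvent returns mass 0 with a warning rather than a negative mass. No
second-virial or multi-angle (Zimm/Guinier) corrections are applied: the
reducer returns the ideal-solution apparent mass at one angle.

## Dynamic light scattering

The field correlation is obtained from the measured intensity correlation
through the Siegert relation, g1 = √(g2 − 1); trailing points at or below
zero are truncated, not clipped. Two reducers are provided.

**Cumulant analysis** fits ln √(g2−1) = ½ln β − Γ̄τ + (µ₂/2)τ² by
amplitude-weighted polynomial least squares; it is exact on noiseless
single exponentials and serves as the cross-check for the inversion (the
two agree within 3% on unimodal data at ≤2% noise).

**Regularized inversion** solves

    min_G ||W(K·G − y)||² + α²||L·G||²,  G ≥ 0,

with K_ij = exp(−Γ_j τ_i) on a 150-point log-spaced grid spanning
[0.1/τ_max, 10/τ_min], L the second-difference operator on the log grid,
and W the g1-amplitude weighting (inverse-variance for correlator baseline
noise). Non-negativity is enforced by NNLS on the stacked system.

Numerical choices that matter here:

- **Choice of α.** α is scanned over 20 logarithmic points. The default
  selector is a parsimony rule: the largest α whose residual norm stays
  within 1.02× the best residual of the scan — the smoothest distribution
  the data cannot reject. The L-curve corner (triangle method) and the
  discrepancy principle (given a noise level) are selectable alternatives.
  In Monte-Carlo trials the L-curve corner systematically lands on the
  oversmoothed branch for these kernels, inflating the z-average rate by
  3–5%, which is why it is not the default.
- **Boundary artifacts.** The prescribed grid deliberately extends a decade
  beyond the fastest measurable decay (10/τ_min ⇒ kernel support e⁻¹⁰ at
  the first lag). At the fast edge the solver can park noise-fitting weight
  that is invisible to the data but catastrophic for an arithmetic mean
  rate. Reported moments therefore follow the per-peak convention:
  contiguous positive segments of the distribution are treated as modes,
  and modes whose mean rate falls outside the resolvable window
  [1/τ_max, 0.3/τ_min] are excluded from `mean_rate()`/`mean_diffusion()`
  (the raw distribution is returned untouched, so callers can inspect
  everything). With this convention, 100-seed Monte-Carlo recovery of a
  unimodal 1%-noise ACF returns the mean diffusion coefficient with ~1%
  ensemble bias, and a Γ-ratio-100 bimodal input splits 0.50/0.50.
- The reported mean D is the intensity-weighted mean of the (mode-filtered)
  distribution; Stokes radii then follow from R_S = k_B T/(6πηD).

The reducer accepts pre-averaged curves only; photon-count statistics and
correlator hardware behavior are out of scope.

## Mass-action association

Self-association is modelled as a monomer plus a small set of defined
oligomers with molar-species equilibrium constants K_n = [A_n]/[A]^n and
monomer-equivalent totals; a hexamer may be written as a dimer of trimers,
K₆' = [A₆]/[A₃]², which maps onto the monomer basis as K₆ = K₆'·K₃². The
free monomer at a given total solves the strictly increasing closure
Σ n K_n m^n = c and is found by bisection run to the floating-point limit
(the conservation residual scales with d(total)/dm, so a loose tolerance on
m is not enough).

Predictions: M_w = M₁·Σn²c_n/Σn c_n for the SLS channel, and for the DLS
channel intensity weights w_n ∝ n²c_n with D_z = Σw D/Σw, returning the
apparent radius as the intensity-weighted harmonic mean of the species
radii. Species radii follow R_n = R₁·n^ν with ν = 0.44 by default — between
the compact 1/3 and coil 1/2 exponents, matching the intermediate
compactness these oligomers show — and ν can be frozen or fitted.

Fitting minimizes Σ((obs−pred)/σ)² jointly over both channels, with σ from
the series' relative errors (defaults 10% on M_rel, 3% on R_S). Constants
are fitted in log₁₀K with box bounds and five deterministic multi-starts
(offsets 0, ±2, ±4 around the template values) to avoid local minima. The
monomer mass is always fixed from sequence: dissociation below the
detection limit means data never constrain the monomer plateau. Model
comparison uses AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1). Parameter
recovery under the default noise model (50 seeds): median |Δlog₁₀K₃| ≈
0.05, bias ≈ −0.03; AICc identifies a generating trimer+hexamer model over
a trimer-only model in 50/50 replicates. Isodesmic/indefinite association
and kinetics are out of scope.

## Compactness index

Reference lines are power laws R_S = aM^b. Defaults: folded b = 0.33
anchored at lysozyme (14.3 kDa, 1.9 nm); denatured b = 0.5 anchored so a
4.2 kDa coil has R_S = 1.8 nm (an extended ~4 kDa peptide chain). Both are
fully configurable. **Interpolation is in log-radius** —
CI = (ln R_coil − ln R_S)/(ln R_coil − ln R_glob) — because the references
are power laws; this is the key reproducibility caveat, so a linear-in-R
variant exists and every result is tagged with the method used. CI is not
clamped: values outside [0, 1] flag a reference-set mismatch rather than
being hidden. Series propagation uses the first-order expansion
σ_CI² = (∂CI/∂lnM)²σ_lnM² + (∂CI/∂lnR)²σ_lnR², validated against
Monte-Carlo to 5%. Fitting new scaling laws to reference databases is out
of scope.

## Spectroscopy

CD conversions are the exact linear maps θ_MRW = θ·MRW/(10·l·c) (MRW =
M/n_residues) and θ_M = θ·M/(10·l·c). The helix fraction uses the
chain-length-corrected single-wavelength estimator f_H = θ₂₂₂/(θ∞(1 − k/n))
with θ∞ = −39500 deg·cm²·dmol⁻¹ and k = 2.57; which empirical variant a
given lab used is often ambiguous, so the constants are exposed and results
should be quoted with them. Fluorescence maxima come from a parabola fitted
to points within ±5 nm of the discrete maximum of the
concentration-normalized spectrum — robust to normalization artifacts in
inner-filter-affected data — with an explicit edge flag when the maximum
sits on the spectrum boundary. A blank spectrum (e.g. free tryptophan in
the same solvent) can be subtracted after concentration normalization. NOE
distances use r = r_ref·(I_ref/I)^{1/6} with the tryptophan ring H1–H2 pair
(2.55 Å) as the canonical reference. Full CD deconvolution and chemical
shift analysis are out of scope.

## Structural modelling and hydrodynamics

PDB I/O is delegated to biotite behind a small `AtomSet` container
(parallel label/coordinate arrays); NMR ensembles default to model 1,
altloc A/blank is kept, hydrogens are dropped by default. Superposition is
the closed-form Kabsch solution (SVD of the paired-coordinate covariance,
determinant-corrected so the rotation is always proper); degenerate
(collinear) pairings are rejected. Oligomer construction superposes one
monomer copy per template chain using Cα atoms of a residue map
(monomer → template residue ids; defaults to the ids common to both) and
reports per-chain RMSDs so alternative mappings can be compared — the right
residue subset for a given template is a genuine judgment call, so it is
never hard-coded.

The hydrodynamic radius uses the Kirkwood double-sum approximation with one
bead per residue at the Cα (a per-heavy-atom mode exists for sensitivity
checks). Bead radii come from equipartition of the molecular volume:
σ = (3·M·v̄/(4π·N_A·N_b))^{1/3}, with the partial specific volume v̄ =
0.725 cm³/g by default. The Kirkwood estimate is exact for a single sphere,
has the closed form R_S = (4/3)σ for a touching equal dimer, and runs a few
percent (typically 3–8%) from shell-model calculations on compact
assemblies; a multiplicative calibration factor (default 1.0) is exposed.
Energy minimization, clash resolution, rotational diffusion and intrinsic
viscosity are out of scope — the templated oligomer is a rigid alignment by
design.

## Synthetic data

Every generator is the exact forward model of the formulas its consumer
inverts, so zero-noise round-trips are identities within solver tolerance,
and all randomness flows from a single seed through a local
`numpy.random.Generator` — no global state. The default scenario emulates
an exendin-4-like study: M₁ = 4187.6 Da, R₁ = 1.4 nm, monomer ⇌ trimer with
log₁₀K₃ = 9 (placing the M_rel ≈ 2 transition near 0.1 mM, with visible
dissociation below ~0.2 mM), 12 log-spaced concentrations over 0.01–2 mM,
and relative errors of 10% on apparent mass and 3% on Stokes radius.
Mass/radius noise is multiplicative lognormal (strictly positive
observables); ACF noise can be additive Gaussian (correlator baseline
noise) or multiplicative (signal-proportional); spectra get additive
Gaussian noise. Synthetic coordinates are ideal-helix Cα traces (rise
1.5 Å, twist 100°, radius 2.3 Å, giving the canonical 3.8 Å Cα–Cα
distance), and a C3-symmetric synthetic template stands in for a trimeric
crystal form where no experimental oligomer structure is available.

What the generators do **not** emulate: photon-count statistics, baseline
drift and dust events in scattering data; concentration-dependent solution
non-ideality (second virial coefficients); spectral band-shape families
beyond simple Gaussian mixtures; and real side-chain packing in templated
oligomers. Passing tests therefore demonstrate correctness of the
*inversions and estimators under the stated noise models*, not robustness
to every instrumental artifact of real data.

## Problem sizes

The test suite and the reproduction script use the study-scale problem
sizes throughout: 100-seed Monte-Carlo for the inversion recovery, 50-seed
recovery and model-selection studies for the association fits (12
concentrations each), 150-point inversion grids with 20-point α scans, and
10⁴-draw Monte-Carlo for the error-propagation check. The full suite runs
in a few minutes on one CPU.
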