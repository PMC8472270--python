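"""Reduce simulated static and dynamic light-scattering data.

Synthesizes a toluene-referenced intensity record encoding a trimer of
exendin-4 and a noisy autocorrelation function for a 2.3 nm particle,
then runs both reductions: Rayleigh-ratio apparent mass and
CONTIN-style inverse Laplace transform to a decay-rate distribution,
diffusion coefficient and Stokes radius.
"""

import pepassoc as pa

config = pa.InstrumentConfig()  # 532 nm, 90 deg, PBS at 23 C
monomer_mass = 4187.6

# --- static side: intensities -> apparent molar mass
record = pa.gen_intensity_record(3 * monomer_mass, concentration_mg_ml=0.8,
                                 config=config)
m_app = pa.apparent_mass(record, config)
m_rel = pa.relative_mass(m_app, monomer_mass)
print(f"SLS: apparent mass {m_app:,.0f} g/mol -> M_rel = {m_rel:.2f}")

# --- dynamic side: ACF -> D distribution -> Stokes radius
acf = pa.gen_acf([(2.3, 1.0)], config, rel_noise_sigma=0.01, seed=7)
dist = pa.ilt_regularized(acf)
d_mean = dist.mean_diffusion(config)
r_s = pa.stokes_radius(d_mean, config)
cum = pa.cumulant_fit(acf)
print(f"DLS: alpha = {dist.regularization_parameter:.3g}, "
      f"D = {d_mean:.3e} m^2/s, R_S = {r_s:.2f} nm")
print(f"     cumulant cross-check: rate {cum.mean_rate:,.0f}/s, "
      f"PDI {cum.polydispersity:.3f}")
print()
print(f"M_rel near 3 identifies the trimer; the {r_s:.2f} nm Stokes radius")
print("matches the generator's 2.3 nm input, closing the round trip.")
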