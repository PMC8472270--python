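"""Fit a monomer <-> trimer equilibrium to a noisy concentration series.

Simulates M_rel(c) and R_S(c) for an exendin-4-like peptide (12
log-spaced concentrations, 0.01-2 mM, 10%/3% relative errors), then
fits the trimerization constant and compares one- and two-constant
models by AICc.
"""

import pepassoc as pa

truth = pa.default_exendin_model()  # log10 K3 = 9 on the M^-2 molar basis
series = pa.gen_association_series(truth, pa.GeneratorSpec(seed=11))

fit = pa.fit_association(series, truth.with_log10_k([7.0]))
k3, err = fit.params["log10_K3"], fit.stderr["log10_K3"]
print(f"trimer model : log10 K3 = {k3:.2f} +/- {err:.2f} (truth 9.00)")
print(f"               AICc = {fit.aicc:.1f}, converged = {fit.converged}")

hexamer = pa.AssociationModel(
    monomer_mass=truth.monomer_mass,
    species=((1, 0.0), (3, 9.0), (6, 23.0)),
    monomer_radius_nm=truth.monomer_radius_nm,
    radius_exponent=truth.radius_exponent,
)
fit2 = pa.fit_association(series, hexamer.with_log10_k([8.0, 20.0]),
                          log10_k_bounds=(-3.0, 30.0))
print(f"+hexamer     : AICc = {fit2.aicc:.1f}")
better = "trimer" if fit.aicc < fit2.aicc else "trimer+hexamer"
print()
print(f"AICc prefers the {better} model for these data; with data generated")
print("from a pure trimer equilibrium the extra hexamer constant is not")
print("rewarded, mirroring the model selection applied to measured series.")
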