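"""Sequence-level properties of exendin-4.

Computes the quantities needed before any scattering experiment: the
average molecular mass (used to convert apparent masses to oligomer
sizes), the 280 nm extinction coefficient and specific absorbance (used
to set concentrations photometrically), the sliding-window charge
profile, and the hydrophobic moment of the central helix (residues
6-28), which measures how amphipathic — and therefore how
association-prone — the helix is.
"""

import pepassoc as pa

peptide = pa.PeptideRecord("exendin-4", pa.EXENDIN4_SEQUENCE)

mass = pa.average_mass(peptide)
eps = pa.extinction_280(peptide)
a280 = pa.specific_absorbance(peptide)
print(f"{peptide.name}: {len(peptide.sequence)} residues")
print(f"  average mass        : {mass:.1f} Da")
print(f"  extinction (280 nm) : {eps:.0f} /M/cm")
print(f"  A(280, 1cm, 1mg/mL) : {a280:.3f}")

profile = pa.charge_profile(peptide.sequence, window=5)
most_negative = min(profile, key=lambda t: t[1])
print(f"  charge window min   : {most_negative[1]:+.2f} at position {most_negative[0]}")

helix = peptide.sequence[5:28]  # central helical segment, residues 6-28
mu_h = pa.hydrophobic_moment(helix)
print(f"  hydrophobic moment  : {mu_h:.3f} (Fauchere-Pliska, helix 6-28)")
print()
print("A large hydrophobic moment marks an amphipathic helix whose apolar")
print("face can drive self-association; the mass and A280 anchor all")
print("concentration and oligomer-size determinations downstream.")
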