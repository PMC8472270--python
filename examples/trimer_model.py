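"""Template-based trimer model and its Kirkwood Stokes radius.

Builds a trimer by superposing a monomer onto each chain of a trimeric
template and predicts the hydrodynamic radius with the Kirkwood bead
model (one bead per residue, bead volume from M vbar / N_A).

With no arguments a synthetic ideal-helix monomer and a C3-symmetric
synthetic template are used. To reproduce the analysis on experimental
structures, pass the monomer NMR structure and a trimeric crystal
template as PDB files:

    python examples/trimer_model.py monomer.pdb template.pdb

e.g. PDB entries 1JRJ (exendin-4 in 30% TFE, model 1) and 3UC7 (cyclized
Trp-cage miniprotein, whose crystal packs as dimers of trimers); the
resulting trimer R_S can be compared with the 2.2-2.4 nm obtained from
shell-model hydrodynamics and measured for oligomeric exendin-4.
"""

import sys

import numpy as np

import pepassoc as pa

MONOMER_MASS = 4187.6  # exendin-4, Da

if len(sys.argv) == 3:
    monomer = pa.read_structure(sys.argv[1], model_index=1)
    template = pa.read_structure(sys.argv[2])
    # pair the monomer's C-terminal 20 residues with the template's
    # 20-residue chains (the miniprotein is an N-terminally truncated
    # derivative); override if your template numbers residues differently
    mono_res = sorted(set(int(r) for r in monomer.ca_only().res_ids))[-20:]
    tmpl_res = sorted(set(int(r) for r in template.ca_only().res_ids))
    residue_map = dict(zip(mono_res, tmpl_res[: len(mono_res)]))
    # keep the first three chains: the trimeric subunit of the crystal
    chains = template.chains()[:3]
    keep = np.array([c in chains for c in template.chain_ids])
    template = template.select(keep)
else:
    print("(no PDB files given: using synthetic helix + C3 template)")
    monomer = pa.gen_helix_coords(39)
    template = pa.gen_c3_template(monomer, radial_offset_angstrom=10.0)
    residue_map = None

result = pa.build_oligomer(monomer, template, residue_map)
for chain, rmsd in result.per_chain_rmsd.items():
    print(f"chain {chain}: superposition RMSD {rmsd:.2f} A")

r_mono = pa.hydrodynamic_radius(monomer, MONOMER_MASS)
r_tri = pa.hydrodynamic_radius(result.atoms, 3 * MONOMER_MASS)
print(f"Kirkwood R_S monomer : {r_mono:.2f} nm")
print(f"Kirkwood R_S trimer  : {r_tri:.2f} nm")
print()
print("The trimer radius exceeds the monomer's; for the experimental")
print("exendin-4/Trp-cage templating it should fall near the measured")
print("2.2-2.4 nm of the oligomeric peptide (Kirkwood vs shell-model")
print("differences are a few percent).")
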