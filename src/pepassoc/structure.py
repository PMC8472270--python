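"""Oligomer templating and bead-model hydrodynamics.

A monomer structure is superposed (Kabsch least-squares, reflection
corrected) onto each chain of a template oligomer to produce a rigid
oligomer model, and the Stokes radius of any coordinate set is predicted
with the Kirkwood double-sum bead approximation: one bead per residue
(at the C-alpha) with the bead radius set by equipartition of the
molecular volume M * vbar / N_A over the beads,

    1/R_S = 1/(N sigma) + (1/N^2) sum_{i != j} 1/r_ij.

The Kirkwood estimate runs a few percent from shell-model calculations
(HYDROPRO-class); a multiplicative calibration factor is exposed.

PDB reading/writing is delegated to biotite behind the AtomSet surface.
"""

from __future__ import annotations

import io
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import AVOGADRO

__all__ = [
    "AtomSet",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "kabsch_superpose",
    "transform",
    "build_oligomer",
    "OligomerResult",
    "hydrodynamic_radius",
]


@dataclass
class AtomSet:
    """Labeled 3-D coordinates: parallel arrays over atoms, coords in Angstrom."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray  # (N, 3) Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for name in ("chain_ids", "res_ids", "res_names", "atom_names"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    def __len__(self):
        return self.coords.shape[0]

    def select(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(
            self.chain_ids[mask], self.res_ids[mask], self.res_names[mask],
            self.atom_names[mask], self.coords[mask],
        )

    def ca_only(self) -> "AtomSet":
        return self.select(self.atom_names == "CA")

    def chains(self) -> list:
        seen = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen

    @classmethod
    def from_biotite(cls, arr: struc.AtomArray) -> "AtomSet":
        return cls(
            chain_ids=np.asarray(arr.chain_id),
            res_ids=np.asarray(arr.res_id),
            res_names=np.asarray(arr.res_name),
            atom_names=np.asarray(arr.atom_name),
            coords=np.asarray(arr.coord, dtype=float),
        )

    def to_biotite(self) -> struc.AtomArray:
        arr = struc.AtomArray(len(self))
        arr.chain_id = self.chain_ids.astype("U4")
        arr.res_id = self.res_ids.astype(int)
        arr.res_name = self.res_names.astype("U5")
        arr.atom_name = self.atom_names.astype("U6")
        arr.element = np.array(
            [n.lstrip("0123456789")[:1] for n in self.atom_names], dtype="U2"
        )
        arr.coord = self.coords.astype(np.float32)
        return arr


_ELEMENT_H = ("H", "D")


def _is_hydrogen(atom_name: str) -> bool:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] in _ELEMENT_H


def read_structure(
    source,
    model_index: int = 1,
    heavy_only: bool = True,
    ca_only: bool = False,
) -> AtomSet:
    """Read one model of a PDB file (path, handle or text) into an AtomSet.

    Keeps altloc 'A'/blank; drops hydrogens when ``heavy_only`` and keeps
    only C-alpha atoms when ``ca_only``. NMR ensembles default to model 1.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"unparsable coordinate fields on line {lineno}: {line!r}"
                ) from None

    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError("no ATOM records found in input")
    if not 1 <= model_index <= n_models:
        raise ValueError(
            f"model {model_index} not present; available models: 1..{n_models}"
        )
    arr = pdb.get_structure(model=model_index, altloc="first")
    arr = arr[~arr.hetero]
    atoms = AtomSet.from_biotite(arr)
    if ca_only:
        return atoms.ca_only()
    if heavy_only:
        keep = np.array([not _is_hydrogen(n) for n in atoms.atom_names])
        return atoms.select(keep)
    return atoms


def write_pdb(atoms: AtomSet, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(pdb_structure := atoms.to_biotite())
    pdb.write(str(path))


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) Angstrom
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, AtomSet):
        return obj.coords
    return np.asarray(obj, dtype=float)


def kabsch_superpose(
    mobile,
    target,
    pairing: Optional[Sequence[tuple]] = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto target.

    ``pairing`` lists (mobile_index, target_index) atom pairs; by default
    atoms are paired by order (requiring equal counts). The optimal
    rotation comes from the SVD of the covariance of the centered paired
    coordinates, with the reflection corrected by the determinant sign so
    the result is always a proper rotation.
    """
    x = _as_coords(mobile)
    y = _as_coords(target)
    if pairing is not None:
        mi = np.array([p[0] for p in pairing], dtype=int)
        ti = np.array([p[1] for p in pairing], dtype=int)
        x, y = x[mi], y[ti]
    if x.shape != y.shape:
        raise ValueError("mobile and target pairings differ in size")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) pairing")
    u, _, vt = np.linalg.svd(x0.T @ y0)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = (u @ diag @ vt).T
    trans = yc - rot @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((x @ rot.T + trans - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def transform(atoms: AtomSet, result: SuperpositionResult) -> AtomSet:
    return AtomSet(
        atoms.chain_ids.copy(), atoms.res_ids.copy(), atoms.res_names.copy(),
        atoms.atom_names.copy(), result.apply(atoms.coords),
    )


@dataclass
class OligomerResult:
    atoms: AtomSet
    per_chain_rmsd: dict  # new chain id -> C-alpha RMSD of the superposition


def build_oligomer(
    monomer: AtomSet,
    template: AtomSet,
    residue_map: Optional[dict] = None,
) -> OligomerResult:
    """Superpose one monomer copy onto each template chain.

    ``residue_map`` maps monomer residue ids to template residue ids;
    C-alpha atoms of the mapped residues define the superposition. When
    omitted, residues with ids common to monomer and template are paired.
    Output chains are relabeled A, B, C, ... in template-chain order.
    """
    mono_ca = monomer.ca_only()
    mono_ids = {int(r): i for i, r in enumerate(mono_ca.res_ids)}

    if residue_map is None:
        template_ids = set(int(r) for r in template.ca_only().res_ids)
        residue_map = {r: r for r in sorted(set(mono_ids) & template_ids)}
    missing = [r for r in residue_map if r not in mono_ids]
    if missing:
        raise ValueError(f"residue map references absent monomer residues: {missing}")

    pieces, rmsds = [], {}
    labels = string.ascii_uppercase
    for k, chain in enumerate(template.chains()):
        tmpl_ca = template.select(
            (template.chain_ids == chain) & (template.atom_names == "CA")
        )
        tmpl_ids = {int(r): i for i, r in enumerate(tmpl_ca.res_ids)}
        absent = [t for t in residue_map.values() if t not in tmpl_ids]
        if absent:
            raise ValueError(
                f"residue map references residues absent from template chain "
                f"{chain!r}: {absent}"
            )
        mob = np.array([mono_ca.coords[mono_ids[m]] for m in residue_map])
        tgt = np.array([tmpl_ca.coords[tmpl_ids[t]] for t in residue_map.values()])
        sup = kabsch_superpose(mob, tgt)
        placed = transform(monomer, sup)
        new_chain = labels[k % len(labels)]
        placed.chain_ids = np.full(len(placed), new_chain, dtype=placed.chain_ids.dtype)
        pieces.append(placed)
        rmsds[new_chain] = sup.rmsd

    out = AtomSet(
        np.concatenate([p.chain_ids for p in pieces]),
        np.concatenate([p.res_ids for p in pieces]),
        np.concatenate([p.res_names for p in pieces]),
        np.concatenate([p.atom_names for p in pieces]),
        np.concatenate([p.coords for p in pieces]),
    )
    return OligomerResult(atoms=out, per_chain_rmsd=rmsds)


def hydrodynamic_radius(
    atoms,
    molar_mass_da: float,
    vbar_cm3_g: float = 0.725,
    bead_mode: str = "per_residue",
    calibration: float = 1.0,
) -> float:
    """Kirkwood bead-model Stokes radius in nm.

    Beads sit at C-alpha positions (``per_residue``) or at every atom
    present (``per_atom``); each bead radius sigma comes from dividing
    the molecular volume M vbar / N_A equally among the beads. The
    Kirkwood approximation

        1/R_S = 1/(N sigma) + (1/N^2) sum_{i != j} 1/r_ij

    is exact for a single sphere and accurate to a few percent for
    compact assemblies; ``calibration`` rescales the result.
    """
    if molar_mass_da <= 0 or vbar_cm3_g <= 0:
        raise ValueError("mass and vbar must be positive")
    if isinstance(atoms, AtomSet):
        centers = atoms.ca_only().coords if bead_mode == "per_residue" else atoms.coords
    else:
        centers = np.asarray(atoms, dtype=float)
    if bead_mode not in ("per_residue", "per_atom"):
        raise ValueError(f"unknown bead mode {bead_mode!r}")
    centers_nm = centers / 10.0  # Angstrom -> nm
    n = centers_nm.shape[0]
    if n < 1:
        raise ValueError("need at least one bead center")

    volume_nm3 = molar_mass_da * vbar_cm3_g / AVOGADRO * 1e21
    sigma = (3.0 * volume_nm3 / (4.0 * math.pi * n)) ** (1.0 / 3.0)

    if n == 1:
        return calibration * sigma
    diff = centers_nm[:, None, :] - centers_nm[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    iu = np.triu_indices(n, k=1)
    pair = dist[iu]
    if np.any(pair == 0):
        i, j = iu[0][pair == 0][0], iu[1][pair == 0][0]
        raise ValueError(f"coincident bead centers at indices {i} and {j}")
    inv_sum = 2.0 * float(np.sum(1.0 / pair))
    inv_rs = 1.0 / (n * sigma) + inv_sum / n**2
    return calibration / inv_rs
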