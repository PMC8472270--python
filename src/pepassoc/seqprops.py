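"""Sequence-level calculators for peptides.

Average molecular mass, 280 nm extinction coefficient and specific
absorbance (the quantities used to determine peptide concentration
photometrically), a sliding-window charge profile, and helical-wheel
geometry with the Eisenberg hydrophobic moment.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .constants import (
    AMIDE_DELTA,
    AVERAGE_RESIDUE_MASS,
    CANONICAL_RESIDUES,
    EPSILON_CYSTINE,
    EPSILON_TRP,
    EPSILON_TYR,
    HYDROPHOBICITY_SCALES,
    WATER_MASS,
)

__all__ = [
    "PeptideRecord",
    "average_mass",
    "extinction_280",
    "specific_absorbance",
    "charge_profile",
    "hydrophobic_moment",
    "helical_wheel",
    "read_fasta",
    "EXENDIN4_SEQUENCE",
]

#: 39-residue exendin-4 (exenatide) sequence.
EXENDIN4_SEQUENCE = "HGEGTFTSDLSKQMEEEAVRLFIEWLKNGGPSSGAPPPS"

#: Sliding-window charge convention of the EMBOSS-style charge plot:
#: Asp/Glu -1, Lys/Arg +1, His +0.5, everything else 0.
DEFAULT_CHARGES = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


def _validate_sequence(sequence: str) -> None:
    for pos, aa in enumerate(sequence, start=1):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"unknown residue code {aa!r} at position {pos}; "
                "only the 20 canonical one-letter codes are accepted"
            )


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide chain with terminal chemistry and optional conjugate mass.

    Parameters
    ----------
    name : str
        Identifier used in reports.
    sequence : str
        One-letter amino-acid string (20 canonical codes only).
    c_terminal : {"free_acid", "amide"}
        C-terminal chemistry; the amide removes 0.984 Da relative to the
        free acid.
    conjugate_mass_delta : float
        Mass (Da, >= 0) of a covalent adduct such as a gamma-Glu-palmitoyl
        chain; treated purely as a mass shift.
    d_residues : frozenset[int]
        1-based positions flagged as d-stereoisomers. Mass-neutral
        annotation only.
    """

    name: str
    sequence: str
    c_terminal: str = "free_acid"
    conjugate_mass_delta: float = 0.0
    d_residues: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        _validate_sequence(self.sequence)
        if self.c_terminal not in ("free_acid", "amide"):
            raise ValueError(f"c_terminal must be free_acid or amide, got {self.c_terminal!r}")
        if self.conjugate_mass_delta < 0:
            raise ValueError("conjugate_mass_delta must be >= 0")
        bad = [p for p in self.d_residues if not 1 <= p <= len(self.sequence)]
        if bad:
            raise ValueError(f"d-residue positions outside sequence: {bad}")

    def count(self, residue: str) -> int:
        return self.sequence.count(residue)


def average_mass(peptide: PeptideRecord) -> float:
    """Average molecular mass in Da.

    Sum of average residue masses plus one water (free acid) or water
    minus 0.984 Da (amide), plus any conjugate mass delta.
    """
    mass = sum(AVERAGE_RESIDUE_MASS[aa] for aa in peptide.sequence) + WATER_MASS
    if peptide.c_terminal == "amide":
        mass -= AMIDE_DELTA
    return mass + peptide.conjugate_mass_delta


def extinction_280(peptide: PeptideRecord, n_cystine: int = 0) -> float:
    """Molar extinction coefficient at 280 nm in M^-1 cm^-1.

    epsilon = 5500 nTrp + 1490 nTyr + 125 ncystine. Reduced cysteines do
    not absorb; disulfide pairs must be declared via ``n_cystine``.
    """
    if n_cystine < 0 or 2 * n_cystine > peptide.count("C"):
        raise ValueError("n_cystine inconsistent with cysteine content")
    return (
        EPSILON_TRP * peptide.count("W")
        + EPSILON_TYR * peptide.count("Y")
        + EPSILON_CYSTINE * n_cystine
    )


def specific_absorbance(peptide: PeptideRecord, n_cystine: int = 0) -> float:
    """A(280 nm, 1 cm, 1 mg/mL) = epsilon / average mass."""
    return extinction_280(peptide, n_cystine) / average_mass(peptide)


def charge_profile(
    sequence: str,
    window: int = 5,
    charges: dict | None = None,
) -> list[tuple[int, float]]:
    """Sliding-window mean residue charge.

    Returns ``(center_position, mean_charge)`` for every full window,
    1-based center positions. ``charges`` overrides the per-residue charge
    table (default: D/E -1, K/R +1, H +0.5).
    """
    _validate_sequence(sequence)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > len(sequence):
        raise ValueError(f"window {window} longer than sequence ({len(sequence)})")
    table = DEFAULT_CHARGES if charges is None else charges
    vals = [table.get(aa, 0.0) for aa in sequence]
    half = window // 2
    out = []
    for center in range(half, len(sequence) - half):
        mean = sum(vals[center - half : center + half + 1]) / window
        out.append((center + 1, mean))
    return out


def hydrophobic_moment(
    sequence: str,
    delta_deg: float = 100.0,
    scale: str | dict = "fauchere_pliska",
) -> float:
    """Mean hydrophobic moment per residue (dimensionless in scale units).

    muH = (1/N) | sum_i H_i exp(j * delta * i) | with i = 0..N-1 and delta
    the per-residue helical rotation (100 degrees for an alpha helix).
    """
    _validate_sequence(sequence)
    if not sequence:
        raise ValueError("sequence must be non-empty")
    table = HYDROPHOBICITY_SCALES[scale] if isinstance(scale, str) else scale
    missing = sorted({aa for aa in sequence if aa not in table})
    if missing:
        raise ValueError(f"hydrophobicity scale missing residues: {missing}")
    delta = math.radians(delta_deg)
    s = sum(table[aa] * math.sin(delta * i) for i, aa in enumerate(sequence))
    c = sum(table[aa] * math.cos(delta * i) for i, aa in enumerate(sequence))
    return math.hypot(s, c) / len(sequence)


def helical_wheel(
    sequence: str, delta_deg: float = 100.0
) -> list[tuple[int, str, float]]:
    """Helical-wheel angles: residue i sits at (delta * i) mod 360 degrees."""
    _validate_sequence(sequence)
    return [(i, aa, (delta_deg * i) % 360.0) for i, aa in enumerate(sequence)]


def read_fasta(source) -> list[PeptideRecord]:
    """Read peptide records from a FASTA file path, handle, or string."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = io.StringIO(source)
    return [
        PeptideRecord(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(source, "fasta")
    ]
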