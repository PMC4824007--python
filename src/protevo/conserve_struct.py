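"""Alignment-column conservation profiles and residue-contact analysis.

Conservation is the sequence-logo information content: for a column with
non-gap count n and residue frequencies f[a],

    H  = -sum f[a] log2 f[a]
    IC = log2(20) - H - e_n,      e_n = 19 / (2 ln2 n)

with the small-sample correction e_n togglable, gaps excluded from the
denominators, and IC clipped at 0 from below. Columns are addressed through
reference-sequence numbering (the p-th non-gap residue of a chosen row).

Contacts are distance-based: two residues are in contact when their minimal
heavy-atom distance is at most a cutoff (default 4.5 A); contact chemistry
is classified from the residue pair and the atoms involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, Alignment, GAP_CHARS, StructureModel

LOG2_20 = math.log2(20.0)

HYDROPHOBIC = set("AVLIMFWYP")
POSITIVE = set("KRH")
NEGATIVE = set("DE")
# charged side-chain atom names in PDB nomenclature
_CHARGED_ATOMS = {
    "K": {"NZ"}, "R": {"NH1", "NH2", "NE"}, "H": {"ND1", "NE2"},
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"},
}
_BACKBONE = {"N", "CA", "C", "O"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def map_reference_positions(aln: Alignment, ref_id: str,
                            positions: Sequence[int]) -> list[int]:
    """Map 1-based residue positions of the reference row to 1-based
    alignment columns (column c holds the p-th non-gap reference char)."""
    row = aln.row(ref_id)
    nongap_cols = [i + 1 for i, c in enumerate(row) if c not in GAP_CHARS]
    out = []
    for p in positions:
        if p < 1 or p > len(nongap_cols):
            raise ValueError(
                f"position {p} outside reference {ref_id!r} "
                f"(length {len(nongap_cols)})")
        out.append(nongap_cols[p - 1])
    return out


@dataclass(frozen=True)
class ColumnConservation:
    column: int                      # 1-based alignment column
    reference_position: int | None   # 1-based in reference row, if mapped
    frequencies: dict[str, float]
    entropy: float                   # bits
    information_content: float       # bits, clipped at 0
    consensus: str
    n: int                           # non-gap count


def conservation_profile(aln: Alignment, columns: Sequence[int],
                         ref_id: str | None = None,
                         small_sample_correction: bool = True
                         ) -> list[ColumnConservation]:
    """Per-column frequencies, entropy and information content.

    ``columns`` are 1-based alignment columns; gaps are excluded from the
    denominator; an all-gap column is an error. When ``ref_id`` is given
    each column is annotated with the matching reference position (None if
    the reference has a gap there).
    """
    ref_row = aln.row(ref_id) if ref_id is not None else None
    out: list[ColumnConservation] = []
    for col in columns:
        if col < 1 or col > aln.n_columns:
            raise ValueError(f"column {col} outside alignment")
        chars = [c for c in aln.column(col - 1) if c not in GAP_CHARS]
        if not chars:
            raise ValueError(f"column {col} is all gaps")
        n = len(chars)
        freqs = {a: chars.count(a) / n for a in sorted(set(chars))}
        H = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        e_n = 19.0 / (2.0 * math.log(2.0) * n) if small_sample_correction else 0.0
        ic = max(0.0, LOG2_20 - H - e_n)
        consensus = max(sorted(freqs), key=lambda a: freqs[a])
        ref_pos = None
        if ref_row is not None and ref_row[col - 1] not in GAP_CHARS:
            ref_pos = sum(1 for c in ref_row[:col] if c not in GAP_CHARS)
        out.append(ColumnConservation(column=col, reference_position=ref_pos,
                                      frequencies=freqs, entropy=H,
                                      information_content=ic,
                                      consensus=consensus, n=n))
    return out


# ---------------------------------------------------------------------------
# Contacts

@dataclass(frozen=True)
class ContactQuery:
    pairs: tuple[tuple[int, int], ...]   # reference-numbered residue pairs
    chain_a: str
    chain_b: str
    cutoff: float = 4.5                  # Angstrom

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass(frozen=True)
class ContactResult:
    position_a: int
    position_b: int
    residue_a: str        # one-letter (X if unknown)
    residue_b: str
    min_distance: float
    contact: bool
    classification: str   # hydrophobic | electrostatic | other


def _one_letter(res_name: str) -> str:
    return _THREE_TO_ONE.get(res_name.upper(), "X")


def min_heavy_atom_distance(res_a, res_b) -> float:
    """Minimal Euclidean distance over all heavy-atom pairs."""
    xa = np.array([[a.x, a.y, a.z] for a in res_a.atoms])
    xb = np.array([[a.x, a.y, a.z] for a in res_b.atoms])
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def classify_contact(res_a, res_b,
                     charged_cutoff: float = 4.0,
                     hydrophobic_cutoff: float = 4.5) -> str:
    """Chemistry of a residue pair from its atoms.

    electrostatic: opposite-charge pair (K/R/H vs D/E) with charged-group
    atoms within ``charged_cutoff``; hydrophobic: both residues apolar with
    side-chain carbons within ``hydrophobic_cutoff``; otherwise other.
    """
    a1, b1 = _one_letter(res_a.name), _one_letter(res_b.name)

    def _min_over(res_x, res_y, names_x, names_y) -> float:
        ax = [a for a in res_x.atoms if a.name in names_x]
        ay = [a for a in res_y.atoms if a.name in names_y]
        if not ax or not ay:
            return math.inf
        return min(math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))
                   for p, q in product(ax, ay))

    opposite = ((a1 in POSITIVE and b1 in NEGATIVE)
                or (a1 in NEGATIVE and b1 in POSITIVE))
    if opposite:
        d = _min_over(res_a, res_b,
                      _CHARGED_ATOMS.get(a1, set()), _CHARGED_ATOMS.get(b1, set()))
        if d <= charged_cutoff:
            return "electrostatic"
    if a1 in HYDROPHOBIC and b1 in HYDROPHOBIC:
        sc_a = {a.name for a in res_a.atoms
                if a.name.startswith("C") and a.name not in _BACKBONE}
        sc_b = {a.name for a in res_b.atoms
                if a.name.startswith("C") and a.name not in _BACKBONE}
        d = _min_over(res_a, res_b, sc_a, sc_b)
        if d <= hydrophobic_cutoff:
            return "hydrophobic"
    return "other"


def residue_contacts(model: StructureModel,
                     query: ContactQuery) -> list[ContactResult]:
    """Minimal heavy-atom distances and contact classification for each
    queried residue pair."""
    out: list[ContactResult] = []
    for pa, pb in query.pairs:
        try:
            res_a = model.residue(query.chain_a, pa)
        except KeyError:
            raise KeyError(f"residue {pa} missing from chain {query.chain_a!r}")
        try:
            res_b = model.residue(query.chain_b, pb)
        except KeyError:
            raise KeyError(f"residue {pb} missing from chain {query.chain_b!r}")
        d = min_heavy_atom_distance(res_a, res_b)
        contact = d <= query.cutoff
        cls = classify_contact(res_a, res_b) if contact else "other"
        out.append(ContactResult(position_a=pa, position_b=pb,
                                 residue_a=_one_letter(res_a.name),
                                 residue_b=_one_letter(res_b.name),
                                 min_distance=d, contact=contact,
                                 classification=cls))
    return out
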