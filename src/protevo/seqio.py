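"""Readers, writers and core domain types for every external format the
pipeline touches.

Conventions
-----------
* All residue positions and coordinates exposed to users are 1-based and
  inclusive.
* The amino-acid alphabet is the 20 standard residues plus ``X``.
  Selenocysteine (``U``) and pyrrolysine (``O``) are mapped to ``X`` with a
  warning so the alphabet stays closed.
* Parsing either yields entities that satisfy their invariants or fails
  loudly; the only silent drops are documented ones (hydrogen atoms,
  ``#`` comment lines).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP_CHARS = {"-", "."}


class SeqIOError(ValueError):
    """Raised on any malformed input file."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence belonging to one organism."""

    id: str
    organism: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in ALPHABET]
        if bad:
            pos, c = bad[0]
            raise SeqIOError(
                f"record {self.id!r}: illegal character {c!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """All protein records of one organism plus its taxonomic placement."""

    organism: str
    records: list[ProteinRecord]
    taxon_path: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SeqIOError(
                    f"proteome {self.organism!r}: duplicate record id {rec.id!r}"
                )
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rec_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered (id, gapped sequence) rows."""

    rows: list[tuple[str, str]]
    id: str = "aln"

    def __post_init__(self) -> None:
        if not self.rows:
            raise SeqIOError("alignment with no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise SeqIOError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        for rid, s in self.rows:
            ungapped = ungap(s)
            if not ungapped:
                raise SeqIOError(f"alignment row {rid!r} is all gaps")
            bad = set(ungapped) - ALPHABET
            if bad:
                raise SeqIOError(f"alignment row {rid!r}: illegal characters {bad}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        """Column ``i`` (0-based internal index) as a string of characters."""
        return "".join(s[i] for _, s in self.rows)

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)


def ungap(s: str) -> str:
    return "".join(c for c in s if c not in GAP_CHARS)


class Taxonomy:
    """A rooted tree whose leaves are organisms and whose internal nodes
    carry unique clade names.

    The *focal path* is the ordered list of clade names from the root to a
    designated focal clade (e.g. LECA -> ... -> Metazoa); emergence epochs
    are assigned along it.
    """

    def __init__(self, tree: dendropy.Tree, focal_clade: str | None = None):
        self._tree = tree
        self._clades: dict[str, dendropy.Node] = {}
        self._leaves: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                name = _node_label(node)
                if name is None:
                    raise SeqIOError("unlabeled leaf in taxonomy")
                if name in self._leaves:
                    raise SeqIOError(f"duplicate organism {name!r} in taxonomy")
                self._leaves[name] = node
            else:
                name = _node_label(node)
                if name is not None:
                    if name in self._clades:
                        raise SeqIOError(f"duplicate clade name {name!r} in taxonomy")
                    self._clades[name] = node
        root_label = _node_label(tree.seed_node)
        if tree.seed_node.is_leaf() or root_label is None:
            raise SeqIOError("taxonomy root must be a named internal node")
        self.root_clade: str = root_label
        self.focal_clade = focal_clade
        self.focal_path: list[str] = []
        if focal_clade is not None:
            self.focal_path = self._path_to(focal_clade)

    def _path_to(self, clade: str) -> list[str]:
        if clade not in self._clades:
            raise SeqIOError(f"unknown clade {clade!r}")
        node = self._clades[clade]
        path: list[str] = []
        while node is not None:
            label = _node_label(node)
            if label is None:
                raise SeqIOError(
                    f"unlabeled internal node on path from root to {clade!r}"
                )
            path.append(label)
            node = node.parent_node
        return list(reversed(path))

    @property
    def organisms(self) -> list[str]:
        return sorted(self._leaves)

    @property
    def clades(self) -> list[str]:
        return sorted(self._clades)

    def leaves_under(self, clade: str) -> set[str]:
        if clade not in self._clades:
            raise SeqIOError(f"unknown clade {clade!r}")
        node = self._clades[clade]
        return {_node_label(lf) for lf in node.leaf_iter()}

    def taxon_path(self, organism: str) -> list[str]:
        """Named clades from the root down to (excluding) the organism leaf."""
        if organism not in self._leaves:
            raise SeqIOError(f"unknown organism {organism!r}")
        node = self._leaves[organism].parent_node
        path: list[str] = []
        while node is not None:
            label = _node_label(node)
            if label is not None:
                path.append(label)
            node = node.parent_node
        return list(reversed(path))

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


@dataclass(frozen=True)
class InteractionRecord:
    """One binary protein-protein interaction with its detection method."""

    protein_a: str
    protein_b: str
    method: str
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.method:
            raise SeqIOError(
                f"interaction {self.protein_a}-{self.protein_b}: empty method"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    index: int  # 1-based author numbering
    name: str
    atoms: list[Atom] = field(default_factory=list)


class StructureModel:
    """Heavy-atom coordinate model: chains -> residues -> atoms."""

    def __init__(self, chains: Mapping[str, list[Residue]]):
        self.chains: dict[str, list[Residue]] = {}
        for chain_id, residues in chains.items():
            prev = -math.inf
            for res in residues:
                if res.index <= prev:
                    raise SeqIOError(
                        f"chain {chain_id}: residue numbering not strictly "
                        f"increasing at {res.index}"
                    )
                prev = res.index
                for atom in res.atoms:
                    if not all(math.isfinite(v) for v in (atom.x, atom.y, atom.z)):
                        raise SeqIOError(
                            f"chain {chain_id} residue {res.index}: "
                            f"non-finite coordinate"
                        )
            self.chains[chain_id] = list(residues)

    def residue(self, chain: str, index: int) -> Residue:
        if chain not in self.chains:
            raise KeyError(f"chain {chain!r} not in model")
        for res in self.chains[chain]:
            if res.index == index:
                return res
        raise KeyError(f"residue {index} not in chain {chain!r}")


# ---------------------------------------------------------------------------
# FASTA

def _clean_sequence(raw: str, rec_id: str, strict: bool = True) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "U" in seq or "O" in seq:
        warnings.warn(
            f"record {rec_id!r}: U/O residues mapped to X", stacklevel=3
        )
        seq = seq.replace("U", "X").replace("O", "X")
    for i, c in enumerate(seq):
        if c not in ALPHABET:
            raise SeqIOError(
                f"record {rec_id!r}: illegal character {c!r} at position {i + 1}"
            )
    return seq


def read_fasta(path: str | Path, organism: str | None = None) -> Proteome:
    """Read one organism's proteome from a FASTA file.

    The organism identifier defaults to the file stem. Lowercase letters are
    uppercased, multi-line sequences concatenated and a single terminal stop
    (``*``) stripped.
    """
    path = Path(path)
    organism = organism if organism is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_seq: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        seq = _clean_sequence("".join(cur_seq), cur_id)
        records.append(ProteinRecord(id=cur_id, organism=organism, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                if not cur_id:
                    raise SeqIOError(f"{path}: empty FASTA header")
                if cur_id in seen:
                    raise SeqIOError(f"{path}: duplicate id {cur_id!r}")
                seen.add(cur_id)
                cur_seq = []
            else:
                if cur_id is None:
                    raise SeqIOError(f"{path}: sequence before first header")
                cur_seq.append(line)
    flush()
    return Proteome(organism=organism, records=records)


def write_fasta(proteome: Proteome | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    records = proteome.records if isinstance(proteome, Proteome) else list(proteome)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_alignment(path: str | Path, aln_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file (gap characters ``-`` or ``.``)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    cur_id: str | None = None
    cur_seq: list[str] = []

    def flush() -> None:
        if cur_id is not None:
            rows.append((cur_id, "".join(cur_seq).upper()))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0]
                cur_seq = []
            else:
                cur_seq.append(line)
    flush()
    return Alignment(rows=rows, id=aln_id or path.stem)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Taxonomy

def read_taxonomy(path: str | Path, focal_clade: str | None = None) -> Taxonomy:
    """Read a rooted Newick tree with internal-node clade labels."""
    with open(path) as fh:
        text = fh.read()
    return taxonomy_from_newick(text, focal_clade=focal_clade)


def taxonomy_from_newick(text: str, focal_clade: str | None = None) -> Taxonomy:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        if "uplicate" in str(exc):
            raise SeqIOError(f"duplicate clade name in taxonomy: {exc}") from exc
        raise SeqIOError(f"malformed Newick: {exc}") from exc
    return Taxonomy(tree, focal_clade=focal_clade)


# ---------------------------------------------------------------------------
# PSI-MI TAB-like interactions

DEFAULT_MITAB_COLUMNS = {"protein_a": 0, "protein_b": 1, "method": 2, "source_db": 3}


def read_mitab(path: str | Path,
               columns: Mapping[str, int] | None = None) -> list[InteractionRecord]:
    """Read tab-delimited interaction records.

    ``columns`` maps the field names ``protein_a``, ``protein_b``, ``method``
    and (optionally) ``source_db`` to 0-based column indices. Lines starting
    with ``#`` are comments and skipped.
    """
    cols = dict(DEFAULT_MITAB_COLUMNS if columns is None else columns)
    for key in ("protein_a", "protein_b", "method"):
        if key not in cols:
            raise SeqIOError(f"column mapping missing required field {key!r}")
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                a = fields[cols["protein_a"]].strip()
                b = fields[cols["protein_b"]].strip()
                method = fields[cols["method"]].strip()
                src = fields[cols["source_db"]].strip() if "source_db" in cols else ""
            except IndexError:
                raise SeqIOError(f"{path}: line {lineno}: missing mapped column")
            if not method:
                raise SeqIOError(f"{path}: line {lineno}: empty method field")
            records.append(InteractionRecord(a, b, method, src))
    return records


def write_mitab(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_a\tprotein_b\tmethod\tsource_db\n")
        for r in records:
            fh.write(f"{r.protein_a}\t{r.protein_b}\t{r.method}\t{r.source_db}\n")


# ---------------------------------------------------------------------------
# PDB ATOM-record subset

def read_coords(path: str | Path) -> StructureModel:
    """Parse the ATOM records of a PDB-format file into a StructureModel.

    Only ``ATOM`` records are read; hydrogens are dropped; for alternate
    locations only blank or ``A`` is kept.
    """
    chains: dict[str, dict[int, Residue]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("ATOM"):
                continue
            atom_name = line[12:16].strip()
            altloc = line[16]
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or "A"
            element = line[76:78].strip() if len(line) >= 78 else ""
            if altloc not in (" ", "A"):
                continue
            is_h = (element == "H") if element else atom_name.lstrip("0123456789").startswith("H")
            if is_h:
                continue
            try:
                res_index = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise SeqIOError(f"{path}: line {lineno}: malformed numeric field")
            res_map = chains.setdefault(chain_id, {})
            res = res_map.get(res_index)
            if res is None:
                res = Residue(index=res_index, name=res_name)
                res_map[res_index] = res
            res.atoms.append(Atom(atom_name, x, y, z))
    return StructureModel(
        {cid: [res_map[i] for i in sorted(res_map)] for cid, res_map in chains.items()}
    )
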