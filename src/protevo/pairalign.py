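"""Global and local pairwise alignment with affine gap costs.

This is the ranking engine behind the reciprocal-best-hit step: each
candidate homolog is aligned locally (Smith-Waterman, BLOSUM62, gap open 11 /
extend 1 — the familiar protein-BLAST defaults) against every sequence of the
reference proteome and the best-scoring reference protein decides the verdict.

A gap of length k costs ``gap_open + k * gap_extend``. Dynamic programming is
delegated to :class:`Bio.Align.PairwiseAligner`; the result surface exposes
integer scores, the gapped alignment strings, and 1-based inclusive
start/end coordinates in each input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, Proteome, ProteinRecord

MATRIX_ALPHABET = AMINO_ACIDS + "X"


class SubstitutionMatrix:
    """Symmetric residue substitution scores over the 20 AA plus X.

    X scores 0 against every residue so unknown positions neither reward nor
    penalize an alignment.
    """

    def __init__(self, scores: "Align.substitution_matrices.Array", name: str = ""):
        self.name = name
        arr = substitution_matrices.Array(alphabet=MATRIX_ALPHABET, dims=2)
        for a in MATRIX_ALPHABET:
            for b in MATRIX_ALPHABET:
                if a == "X" or b == "X":
                    arr[a, b] = 0.0
                else:
                    arr[a, b] = float(scores[a, b])
        self._array = arr
        self._check_symmetric()

    def _check_symmetric(self) -> None:
        m = np.asarray(self._array)
        if not np.array_equal(m, m.T):
            raise ValueError(f"substitution matrix {self.name!r} is not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self._array[a, b])

    @property
    def array(self) -> "Align.substitution_matrices.Array":
        return self._array

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls(substitution_matrices.load("BLOSUM62"), name="BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Load a matrix in the standard NCBI text format."""
        return cls(substitution_matrices.read(str(path)), name=Path(path).stem)


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal pairwise alignment.

    ``start_a``/``end_a`` (and b) are 1-based inclusive coordinates of the
    aligned region in each input; an empty local alignment has score 0 and
    all coordinates 0.
    """

    score: int
    aligned_a: str
    aligned_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    @property
    def is_empty(self) -> bool:
        return not self.aligned_a and not self.aligned_b


def _make_aligner(m: SubstitutionMatrix, gap_open: int, gap_extend: int,
                  mode: str) -> Align.PairwiseAligner:
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = m.array
    # first gap position costs open+extend so gap(k) = open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _result_from(alignment) -> AlignmentResult:
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return AlignmentResult(int(round(alignment.score)), "", "", 0, 0, 0, 0)
    sa, ea = int(blocks_a[0][0]), int(blocks_a[-1][1])
    sb, eb = int(blocks_b[0][0]), int(blocks_b[-1][1])
    return AlignmentResult(
        score=int(round(alignment.score)),
        aligned_a=str(alignment[0]),
        aligned_b=str(alignment[1]),
        start_a=sa + 1, end_a=ea, start_b=sb + 1, end_b=eb,
    )


def global_align(a: str, b: str, m: SubstitutionMatrix | None = None,
                 gap_open: int = 11, gap_extend: int = 1) -> AlignmentResult:
    """Optimal Needleman-Wunsch alignment under affine gap costs."""
    m = m or SubstitutionMatrix.blosum62()
    aligner = _make_aligner(m, gap_open, gap_extend, "global")
    if not a and not b:
        return AlignmentResult(0, "", "", 0, 0, 0, 0)
    if not a or not b:
        k = max(len(a), len(b))
        score = -(gap_open + k * gap_extend)
        return AlignmentResult(score, a or "-" * k, b or "-" * k,
                               1 if a else 0, len(a), 1 if b else 0, len(b))
    alignment = aligner.align(a, b)[0]
    # a global alignment spans both sequences entirely
    return AlignmentResult(int(round(alignment.score)),
                           str(alignment[0]), str(alignment[1]),
                           1, len(a), 1, len(b))


def local_align(a: str, b: str, m: SubstitutionMatrix | None = None,
                gap_open: int = 11, gap_extend: int = 1) -> AlignmentResult:
    """Optimal Smith-Waterman alignment; empty (score 0) when nothing
    scores positively."""
    m = m or SubstitutionMatrix.blosum62()
    if not a or not b:
        return AlignmentResult(0, "", "", 0, 0, 0, 0)
    aligner = _make_aligner(m, gap_open, gap_extend, "local")
    score = int(round(aligner.score(a, b)))
    if score <= 0:
        return AlignmentResult(0, "", "", 0, 0, 0, 0)
    return _result_from(aligner.align(a, b)[0])


def local_score(a: str, b: str, m: SubstitutionMatrix | None = None,
                gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman score only (no traceback; fast path for ranking)."""
    m = m or SubstitutionMatrix.blosum62()
    if not a or not b:
        return 0
    aligner = _make_aligner(m, gap_open, gap_extend, "local")
    return max(0, int(round(aligner.score(a, b))))


def rank_proteome(query: ProteinRecord | str, ref: Proteome,
                  m: SubstitutionMatrix | None = None,
                  gap_open: int = 11, gap_extend: int = 1) -> list[tuple[str, int]]:
    """Rank every reference protein by local alignment score to the query.

    Descending by score; ties broken by lexicographic id so the ranking is
    deterministic.
    """
    if len(ref) == 0:
        raise ValueError("empty reference proteome")
    m = m or SubstitutionMatrix.blosum62()
    qseq = query.sequence if isinstance(query, ProteinRecord) else query
    aligner = _make_aligner(m, gap_open, gap_extend, "local")
    scored = []
    for rec in ref:
        s = max(0, int(round(aligner.score(qseq, rec.sequence))))
        scored.append((rec.id, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
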