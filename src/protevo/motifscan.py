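"""Short linear-motif scanning and per-taxon occurrence statistics.

Endocytic adaptor and accessory proteins talk to the clathrin/AP2 core
through degenerate peptide motifs carried in their disordered terminal
"tails" (the terminal region outside all predicted globular domains).
The built-in patterns are the classical binding motifs:

* ``AP2``       ``DP[WF]|F.D.F|WV.F|F.F.[FL]``  (C-terminal tail)
* ``clathrin``  ``L[FILMV].[FILMV][DE]|L[FILMV].[DE][FILMV]`` (clathrin box,
  C-terminal tail)
* ``EH``        ``NPF`` (Eps15-homology domain ligand, C-terminal tail)

Stonin-like families are scanned in the N-terminal region instead.

Per-taxon statistics follow the occurrence / median-count convention:
occurrence = organisms carrying the motif in the family protein divided by
all organisms of the taxon; the median is over motif counts of the
motif-possessing proteins only.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profilehmm import (DomainArchitecture, EvalueCalibration, ProfileModel,
                         evalue, forward_score)
from .seqio import ProteinRecord

C_TAIL = "C_tail"
N_TAIL = "N_tail"
FULL = "full"


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str
    region_policy: str = C_TAIL

    def __post_init__(self) -> None:
        if self.region_policy not in (C_TAIL, N_TAIL, FULL):
            raise ValueError(f"unknown region policy {self.region_policy!r}")
        re.compile(self.pattern)  # must compile

    @property
    def alternatives(self) -> list[str]:
        return self.pattern.split("|")


BUILTIN_PATTERNS: dict[str, MotifPattern] = {
    "AP2": MotifPattern("AP2", r"DP[WF]|F.D.F|WV.F|F.F.[FL]", C_TAIL),
    "clathrin": MotifPattern(
        "clathrin", r"L[FILMV].[FILMV][DE]|L[FILMV].[DE][FILMV]", C_TAIL),
    "EH": MotifPattern("EH", r"NPF", C_TAIL),
}


@dataclass(frozen=True)
class TailRegion:
    """A terminal segment free of globular domains, 1-based in its parent."""

    sequence: str
    start: int
    end: int
    policy: str

    @property
    def is_empty(self) -> bool:
        return not self.sequence


def extract_tail(rec: ProteinRecord | str, arch: DomainArchitecture,
                 policy: str = C_TAIL) -> TailRegion:
    """Extract the tail region given the resolved domain architecture.

    C-tail: after the last domain envelope; N-tail: before the first; with
    no domains the whole sequence is the tail. Zero-length tails are valid.
    """
    seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
    L = len(seq)
    if policy == FULL or len(arch) == 0:
        return TailRegion(seq, 1, L, policy)
    if policy == C_TAIL:
        start = arch.hits[-1].end + 1
        if start > L:
            return TailRegion("", 0, 0, policy)
        return TailRegion(seq[start - 1:], start, L, policy)
    if policy == N_TAIL:
        end = arch.hits[0].start - 1
        if end < 1:
            return TailRegion("", 0, 0, policy)
        return TailRegion(seq[:end], 1, end, policy)
    raise ValueError(f"unknown policy {policy!r}")


def scan_motif(region: TailRegion | str,
               pat: MotifPattern) -> tuple[int, list[int]]:
    """Count motif matches in a region.

    Every start position whose suffix matches any alternative counts once;
    overlapping matches are all counted, a position matching several
    alternatives only once. Returns (count, 1-based start positions).
    """
    text = region.sequence if isinstance(region, TailRegion) else region
    starts: set[int] = set()
    for alt in pat.alternatives:
        rx = re.compile(f"(?=({alt}))")
        for m in rx.finditer(text):
            starts.add(m.start() + 1)
    positions = sorted(starts)
    return len(positions), positions


@dataclass(frozen=True)
class MotifStats:
    pattern_name: str
    taxon: str
    occurrence: float           # organisms with motif / organisms in taxon
    median_count: float | None  # over motif-possessing proteins; None if none
    n_organisms: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.occurrence <= 1.0):
            raise ValueError("occurrence outside [0, 1]")


def motif_occurrence(counts_by_organism: Mapping[str, Sequence[int]],
                     tax_group: Iterable[str], pat: MotifPattern,
                     taxon_name: str = "",
                     denominator: str = "all") -> MotifStats:
    """Per-taxon occurrence fraction and median motif count.

    ``counts_by_organism`` maps organism -> motif counts of its family
    proteins (one entry per paralog; organisms without a homolog may be
    absent or map to an empty list). An organism possesses the motif when
    ANY of its paralogs carries at least one match.

    ``denominator='all'`` counts every organism of the taxon group in the
    denominator (the default); ``'with_homolog'`` restricts it to organisms
    that have at least one family protein.
    """
    group = sorted(set(tax_group))
    if not group:
        raise ValueError("empty taxon group")
    if denominator not in ("all", "with_homolog"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    possess: list[str] = []
    per_protein_counts: list[int] = []
    n_total = 0
    for org in group:
        counts = list(counts_by_organism.get(org, []))
        has_protein = len(counts) > 0
        if denominator == "all" or has_protein:
            n_total += 1
        if any(c > 0 for c in counts):
            possess.append(org)
            per_protein_counts.extend(c for c in counts if c > 0)
    if n_total == 0:
        raise ValueError("no organisms in denominator")
    occurrence = len(possess) / n_total
    median = statistics.median(per_protein_counts) if per_protein_counts else None
    return MotifStats(pattern_name=pat.name, taxon=taxon_name or "group",
                      occurrence=occurrence, median_count=median,
                      n_organisms=n_total)


@dataclass(frozen=True)
class ApaResult:
    sequence_id: str
    best_evalue: float
    neg_log10_evalue: float
    passes: bool


def apa_search(records: Iterable[ProteinRecord], apa_profile: ProfileModel,
               cal: EvalueCalibration,
               threshold: float = 0.01) -> list[ApaResult]:
    """Profile search for the AP2-activating (APA) region of muniscins.

    Reports the per-record best e-value (db_size = 1), its negative decimal
    logarithm (for threshold-line plots: pass iff -log10 E >= 2 at the
    default threshold) and the pass flag E <= threshold.
    """
    out: list[ApaResult] = []
    for rec in records:
        bits = forward_score(apa_profile, rec.sequence)
        E = evalue(bits, cal, db_size=1)
        out.append(ApaResult(sequence_id=rec.id, best_evalue=E,
                             neg_log10_evalue=float(-np.log10(max(E, 1e-300))),
                             passes=E <= threshold))
    return out
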