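"""The survey core: homolog calling, paralog counting, emergence mapping.

For each query family and each proteome the procedure is:

1. forward-search the proteome with the family profile (sequence e-value
   threshold, default 0.01);
2. annotate the domain architecture of each hit and compare it with the
   family's reference (animal) architecture;
3. unless the family is flagged ``relax_reciprocal``, align the hit against
   the reference proteome and require that one of the family's designated
   members ranks first (reciprocal best hit);
4. accept as *homolog* any hit with a full architecture passing the
   reciprocal test; if none is accepted but some hit has a partial
   architecture and passes reciprocity, the family is scored
   *analog_ancestor* in that organism; otherwise *absent*.

Emergence epochs are read off a rooted taxonomy: the epoch of a family is
the smallest named clade on the root-to-focal-clade path containing every
organism where the family is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import pairalign
from .profilehmm import (DomainArchitecture, EvalueCalibration, ProfileModel,
                         SearchHit, annotate_domains, scan_proteome)
from .seqio import Proteome, ProteinRecord, Taxonomy

HOMOLOG = "homolog"
ANALOG_ANCESTOR = "analog_ancestor"
ABSENT = "absent"
NOT_FOUND = "not_found"


@dataclass
class QueryFamily:
    """One query family: its seed profile, reference architecture and the
    designated members in the reference proteome (the 'human paralog set')."""

    family_id: str
    seed_alignment_id: str
    reference_architecture: list[str]
    designated_members: list[str]
    relax_reciprocal: bool = False
    collapse_repeats: bool = True

    def __post_init__(self) -> None:
        if not self.reference_architecture:
            raise ValueError(f"family {self.family_id}: empty reference architecture")
        if not self.designated_members:
            raise ValueError(f"family {self.family_id}: no designated members")


@dataclass
class HitEvidence:
    hit: SearchHit
    architecture: DomainArchitecture
    architecture_verdict: str           # full | partial | none
    reciprocal: bool | None             # None when not evaluated
    accepted: bool


@dataclass
class HomologCall:
    family_id: str
    organism: str
    status: str                         # homolog | analog_ancestor | absent
    accepted_hits: list[SearchHit]
    evidence: list[HitEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == HOMOLOG and not self.accepted_hits:
            raise ValueError("homolog status requires >= 1 accepted hit")
        if self.status == ABSENT and self.accepted_hits:
            raise ValueError("absent status forbids accepted hits")


def _collapse_runs(ids: Sequence[str]) -> list[str]:
    out: list[str] = []
    for d in ids:
        if not out or out[-1] != d:
            out.append(d)
    return out


def match_architecture(hit_domains: Sequence[str], ref_arch: Sequence[str],
                       collapse_repeats: bool = True) -> str:
    """Compare a hit's ordered domain ids with the reference architecture.

    ``full``: the ordered domain lists are identical; with
    ``collapse_repeats`` tandem runs of the same domain match regardless of
    copy number (a 2xSH3 and a 5xSH3 protein share a full architecture).
    ``partial``: not full but at least one shared domain id. ``none``
    otherwise.
    """
    hit_ids = list(hit_domains)
    ref_ids = list(ref_arch)
    if collapse_repeats:
        same = _collapse_runs(hit_ids) == _collapse_runs(ref_ids)
    else:
        same = hit_ids == ref_ids
    if same:
        return "full"
    if set(hit_ids) & set(ref_ids):
        return "partial"
    return "none"


def reciprocal_check(hit: ProteinRecord, ref_proteome: Proteome,
                     designated: Iterable[str],
                     matrix: "pairalign.SubstitutionMatrix | None" = None,
                     gap_open: int = 11, gap_extend: int = 1,
                     top_cache: dict[str, str] | None = None) -> bool:
    """True iff a designated member ranks first in the reciprocal ranking.

    ``top_cache`` memoizes the top-ranked reference id per hit id (the
    ranking is independent of which family queries it).
    """
    designated = set(designated)
    missing = designated - {rec.id for rec in ref_proteome}
    if missing:
        raise ValueError(f"designated ids not in reference proteome: {sorted(missing)}")
    if top_cache is not None and hit.id in top_cache:
        return top_cache[hit.id] in designated
    ranking = pairalign.rank_proteome(hit, ref_proteome, m=matrix,
                                      gap_open=gap_open, gap_extend=gap_extend)
    if top_cache is not None:
        top_cache[hit.id] = ranking[0][0]
    return ranking[0][0] in designated


def call_homologs(family: QueryFamily,
                  proteome: Proteome,
                  family_profile: ProfileModel,
                  family_cal: EvalueCalibration,
                  domain_profiles: Mapping[str, ProfileModel],
                  domain_cals: Mapping[str, EvalueCalibration],
                  ref_proteome: Proteome,
                  seq_threshold: float = 0.01,
                  dom_threshold: float = 0.01,
                  matrix: "pairalign.SubstitutionMatrix | None" = None,
                  arch_cache: dict[str, DomainArchitecture] | None = None,
                  top_cache: dict[str, str] | None = None) -> HomologCall:
    """Run the full forward + architecture + reciprocal procedure for one
    family in one proteome.

    ``arch_cache`` (record id -> architecture) and ``top_cache`` (record id
    -> top reciprocal reference id) memoize the family-independent pieces
    across families scanning the same proteome.
    """
    hits = scan_proteome(family_profile, proteome, family_cal,
                         threshold=seq_threshold)
    dps = [domain_profiles[d] for d in sorted(set(domain_profiles))]
    cals = dict(domain_cals)
    evidence: list[HitEvidence] = []
    accepted: list[SearchHit] = []
    partial_reciprocal = False
    matrix = matrix or pairalign.SubstitutionMatrix.blosum62()
    for hit in hits:
        rec = proteome.get(hit.sequence_id)
        if arch_cache is not None and rec.id in arch_cache:
            arch = arch_cache[rec.id]
        else:
            arch = annotate_domains(rec, dps, cals, threshold=dom_threshold)
            if arch_cache is not None:
                arch_cache[rec.id] = arch
        verdict = match_architecture(arch.domain_ids,
                                     family.reference_architecture,
                                     collapse_repeats=family.collapse_repeats)
        recip: bool | None = None
        ok = False
        if verdict == "full":
            if family.relax_reciprocal:
                ok = True
            else:
                recip = reciprocal_check(rec, ref_proteome,
                                         family.designated_members,
                                         matrix=matrix, top_cache=top_cache)
                ok = recip
        elif verdict == "partial":
            recip = reciprocal_check(rec, ref_proteome,
                                     family.designated_members, matrix=matrix,
                                     top_cache=top_cache)
            if recip:
                partial_reciprocal = True
        evidence.append(HitEvidence(hit=hit, architecture=arch,
                                    architecture_verdict=verdict,
                                    reciprocal=recip, accepted=ok))
        if ok:
            accepted.append(hit)
    if accepted:
        status = HOMOLOG
    elif partial_reciprocal:
        status = ANALOG_ANCESTOR
    else:
        status = ABSENT
    return HomologCall(family_id=family.family_id, organism=proteome.organism,
                       status=status, accepted_hits=accepted, evidence=evidence)


# ---------------------------------------------------------------------------
# Aggregation

@dataclass
class EmergenceMatrix:
    presence: pd.DataFrame        # families x organisms, bool
    clade_presence: pd.DataFrame  # families x clades, bool (OR over members)
    epochs: dict[str, str]        # family -> clade name or NOT_FOUND


def count_paralogs(calls: Iterable[HomologCall]) -> pd.DataFrame:
    """Families x organisms table of accepted-hit counts."""
    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        rows.setdefault(call.family_id, {})[call.organism] = len(call.accepted_hits)
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    return table.sort_index().reindex(sorted(table.columns), axis=1)


def emergence_epoch(present_organisms: Iterable[str], tax: Taxonomy) -> str:
    """Smallest named clade on the focal path (root included) containing all
    organisms where the family is present; ``not_found`` if none are."""
    present = set(present_organisms)
    if not present:
        return NOT_FOUND
    for org in present:
        if org not in tax.organisms:
            raise ValueError(f"organism {org!r} not in taxonomy")
    path = tax.focal_path or [tax.root_clade]
    epoch = tax.root_clade
    for clade in path:  # root -> focal; keep descending while containing all
        if present <= tax.leaves_under(clade):
            epoch = clade
        else:
            break
    return epoch


def build_emergence_matrix(calls: Iterable[HomologCall],
                           tax: Taxonomy) -> EmergenceMatrix:
    calls = list(calls)
    families = sorted({c.family_id for c in calls})
    organisms = sorted({c.organism for c in calls})
    presence = pd.DataFrame(False, index=families, columns=organisms)
    for c in calls:
        presence.loc[c.family_id, c.organism] = c.status == HOMOLOG
    clades = tax.clades
    clade_presence = pd.DataFrame(False, index=families, columns=clades)
    for clade in clades:
        members = tax.leaves_under(clade) & set(organisms)
        if members:
            clade_presence[clade] = presence[sorted(members)].any(axis=1)
    epochs = {
        fam: emergence_epoch(
            [o for o in organisms if presence.loc[fam, o]], tax)
        for fam in families
    }
    return EmergenceMatrix(presence=presence, clade_presence=clade_presence,
                           epochs=epochs)
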