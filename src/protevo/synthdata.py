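"""Synthetic taxonomies, proteomes and interaction data with planted truth.

The generator emulates protein families evolving along a labelled rooted
taxonomy: each family member is a chain of conserved domain blocks joined
by linkers and flanked by N/C tails. Along every branch residues substitute
under an equal-exchangeability (Jukes-Cantor-style, 20-state) model; domain
blocks evolve under a reduced rate multiplier and contain no indels, so the
domain-architecture ground truth is unambiguous. Clade-rooted events create
the evolutionary scenarios the survey is meant to recover:

* ``origin_clade``       family exists only below this clade
* ``DomainGain/Loss``    architecture change in a subtree (e.g. tandem
  repeat expansion)
* ``MotifPlant``         a linear-motif instance written into a tail and
  protected from substitution thereafter
* ``Duplication``        extra gene copies in a subtree
* ``Loss``               family lost in a subtree

Alongside the sequences a TruthTable records, per (family, organism), the
expected homolog status, paralog count, per-pattern motif counts in the
true tail, and the expected emergence epoch per family — everything a
pipeline run can be scored against.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import (AMINO_ACIDS, Alignment, InteractionRecord, Proteome,
                    ProteinRecord, Taxonomy, taxonomy_from_newick,
                    write_alignment, write_fasta, write_mitab)
from .profilehmm import blosum62_background

# ---------------------------------------------------------------------------
# Events

@dataclass(frozen=True)
class DomainGain:
    domain_id: str
    length: int = 60
    after: str | None = None    # insert after the run of this domain id
    copies: int = 1


@dataclass(frozen=True)
class DomainLoss:
    domain_id: str


@dataclass(frozen=True)
class MotifPlant:
    pattern_name: str
    instance: str               # concrete motif string, e.g. "DPW"
    region: str = "C_tail"      # C_tail | N_tail
    count: int = 1


@dataclass(frozen=True)
class Duplication:
    count: int = 1              # number of EXTRA copies


@dataclass(frozen=True)
class Loss:
    pass


Event = DomainGain | DomainLoss | MotifPlant | Duplication | Loss


@dataclass
class FamilySpec:
    """Recipe for one evolving family."""

    family_id: str
    architecture: list[tuple[str, int]]        # ordered (domain id, length)
    origin_clade: str | None = None            # None -> present from the root
    events: dict[str, list[Event]] = field(default_factory=dict)
    rate: float = 0.05                         # subs/site per unit branch
    domain_rate_multiplier: float = 0.4
    n_tail_length: int = 12
    c_tail_length: int = 60
    linker_length: int = 15
    tail_policy: str = "C_tail"                # motif-bearing terminal region
    analog_for: str | None = None              # truth counts toward this family

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("substitution rate must be >= 0")
        if not self.architecture:
            raise ValueError(f"family {self.family_id}: empty architecture")


# ---------------------------------------------------------------------------
# Sequence machinery

_BG = blosum62_background()


def _sample_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(20, size=n, p=_BG)


def _jc_substitute(rng: np.random.Generator, codes: np.ndarray,
                   protected: np.ndarray, t: float) -> None:
    """One branch of the 20-state equal-exchangeability chain (in place).

    ``t`` is the expected number of substitutions per site on the branch;
    the exact transition has P(change) = (19/20)(1 - exp(-(20/19) t)) with
    the replacement uniform over the other 19 residues, so branch
    composition is exact and the pairwise difference between two leaves at
    total path length T follows the closed form (19/20)(1 - exp(-(20/19)T)).
    """
    if t <= 0 or len(codes) == 0:
        return
    p_change = (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * t))
    mask = (rng.random(len(codes)) < p_change) & ~protected
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return
    shift = rng.integers(1, 20, size=len(idx))
    codes[idx] = (codes[idx] + shift) % 20


@dataclass
class _Segment:
    kind: str                  # n_tail | domain | linker | c_tail
    domain_id: str | None
    codes: np.ndarray
    protected: np.ndarray

    def copy(self) -> "_Segment":
        return _Segment(self.kind, self.domain_id, self.codes.copy(),
                        self.protected.copy())

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class _Gene:
    segments: list[_Segment]

    def copy(self) -> "_Gene":
        return _Gene([s.copy() for s in self.segments])

    def sequence(self) -> str:
        return "".join(AMINO_ACIDS[k]
                       for seg in self.segments for k in seg.codes)

    def domain_ids(self) -> list[str]:
        return [s.domain_id for s in self.segments if s.kind == "domain"]

    def domain_spans(self) -> list[tuple[str, int, int]]:
        """(domain id, 1-based start, end) of every domain block."""
        out = []
        pos = 0
        for seg in self.segments:
            if seg.kind == "domain":
                out.append((seg.domain_id, pos + 1, pos + len(seg)))
            pos += len(seg)
        return out

    def tail(self, region: str) -> tuple[str, int]:
        """(tail string, 1-based start) for the requested terminal region."""
        if region == "N_tail":
            seg = self.segments[0]
            if seg.kind != "n_tail":
                return "", 0
            return "".join(AMINO_ACIDS[k] for k in seg.codes), 1
        seg = self.segments[-1]
        if seg.kind != "c_tail":
            return "", 0
        start = sum(len(s) for s in self.segments[:-1]) + 1
        return "".join(AMINO_ACIDS[k] for k in seg.codes), start


class DomainRegistry:
    """Root consensus blocks per domain id, shared across families so that
    deliberately related families (e.g. an analog sharing one domain) carry
    homologous blocks."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._blocks: dict[str, np.ndarray] = {}

    def root_block(self, domain_id: str, length: int) -> np.ndarray:
        if domain_id not in self._blocks:
            self._blocks[domain_id] = _sample_codes(self._rng, length)
        blk = self._blocks[domain_id]
        if len(blk) != length:
            raise ValueError(
                f"domain {domain_id!r} requested with inconsistent length")
        return blk.copy()


# ---------------------------------------------------------------------------
# Taxonomy generation

def generate_taxonomy(n_per_clade: int = 2,
                      clade_series: Sequence[str] = (
                          "LECA", "Amorphea", "Obazoa", "Opisthokonta",
                          "Holozoa", "Metazoa"),
                      outgroup_clades: Sequence[str] = ("Discoba",
                                                        "Archaeplastida"),
                      branch_length: float = 1.0,
                      seed: int = 0) -> Taxonomy:
    """A nested taxonomy along a focal path plus basal outgroup clades.

    Every named clade (nested and outgroup) carries ``n_per_clade`` leaf
    organisms named ``<clade>_<i>``. Deterministic given the arguments (the
    seed is accepted for interface symmetry; the topology is a function of
    the configuration).
    """
    if n_per_clade < 1 or not clade_series:
        raise ValueError("need at least one clade and one organism per clade")
    bl = f":{branch_length:g}"

    def leaves(clade: str) -> list[str]:
        return [f"{clade}_{i + 1}{bl}" for i in range(n_per_clade)]

    def nest(idx: int) -> str:
        clade = clade_series[idx]
        parts = leaves(clade)
        if idx + 1 < len(clade_series):
            parts.append(nest(idx + 1))
        return "(" + ",".join(parts) + ")" + clade + bl

    root_clade = clade_series[0]
    parts = [
        "(" + ",".join(leaves(og)) + ")" + og + bl for og in outgroup_clades
    ]
    parts += leaves(root_clade)
    if len(clade_series) > 1:
        parts.append(nest(1))
    newick = "(" + ",".join(parts) + ")" + root_clade + ";"
    return taxonomy_from_newick(newick, focal_clade=clade_series[-1])


# ---------------------------------------------------------------------------
# Family evolution

def _branch_length(node) -> float:
    return node.edge.length if node.edge.length is not None else 1.0


def evolve_family(spec: FamilySpec, tax: Taxonomy, seed: int,
                  registry: DomainRegistry | None = None
                  ) -> dict[str, list[_Gene]]:
    """Evolve one family over the taxonomy; returns organism -> gene copies.

    Events fire at the root of their clade and apply to the whole subtree;
    unknown clade names are an error.
    """
    known = set(tax.clades)
    for clade in spec.events:
        if clade not in known:
            raise ValueError(
                f"family {spec.family_id}: event references unknown clade {clade!r}")
    if spec.origin_clade is not None and spec.origin_clade not in known:
        raise ValueError(
            f"family {spec.family_id}: unknown origin clade {spec.origin_clade!r}")

    rng = np.random.default_rng(seed)
    registry = registry or DomainRegistry(np.random.default_rng(seed + 7919))

    segs: list[_Segment] = []
    if spec.n_tail_length:
        segs.append(_Segment("n_tail", None,
                             _sample_codes(rng, spec.n_tail_length),
                             np.zeros(spec.n_tail_length, bool)))
    for i, (dom, length) in enumerate(spec.architecture):
        if i > 0 and spec.linker_length:
            segs.append(_Segment("linker", None,
                                 _sample_codes(rng, spec.linker_length),
                                 np.zeros(spec.linker_length, bool)))
        blk = registry.root_block(dom, length)
        segs.append(_Segment("domain", dom, blk, np.zeros(length, bool)))
    if spec.c_tail_length:
        segs.append(_Segment("c_tail", None,
                             _sample_codes(rng, spec.c_tail_length),
                             np.zeros(spec.c_tail_length, bool)))
    root_gene = _Gene(segs)

    out: dict[str, list[_Gene]] = {}

    def apply_events(genes: list[_Gene], events: Iterable[Event]) -> list[_Gene]:
        for ev in events:
            if isinstance(ev, Loss):
                return []
            if isinstance(ev, Duplication):
                genes = genes + [g.copy() for g in genes[:1] * ev.count]
            elif isinstance(ev, DomainLoss):
                for g in genes:
                    g.segments = [s for s in g.segments
                                  if not (s.kind == "domain"
                                          and s.domain_id == ev.domain_id)]
            elif isinstance(ev, DomainGain):
                blk0 = registry.root_block(ev.domain_id, ev.length)
                for g in genes:
                    anchor = None
                    if ev.after is not None:
                        for k, s in enumerate(g.segments):
                            if s.kind == "domain" and s.domain_id == ev.after:
                                anchor = k
                    insert_at = (anchor + 1 if anchor is not None
                                 else len(g.segments) - 1)
                    new = []
                    for _ in range(ev.copies):
                        blk = blk0.copy()
                        _jc_substitute(rng, blk, np.zeros(len(blk), bool), 0.05)
                        new.append(_Segment("domain", ev.domain_id, blk,
                                            np.zeros(len(blk), bool)))
                    g.segments[insert_at:insert_at] = new
            elif isinstance(ev, MotifPlant):
                inst = np.array([AMINO_ACIDS.index(c) for c in ev.instance])
                for g in genes:
                    seg = (g.segments[0] if ev.region == "N_tail"
                           else g.segments[-1])
                    want = seg.kind == ("n_tail" if ev.region == "N_tail"
                                        else "c_tail")
                    if not want or len(seg) < (len(inst) + 4) * ev.count:
                        raise ValueError(
                            f"family {spec.family_id}: tail too short to "
                            f"plant motif {ev.instance!r}")
                    # evenly spaced, away from the domain boundary; slide
                    # right past any previously planted (protected) window
                    gap = len(seg) // (ev.count + 1)
                    for k in range(ev.count):
                        at = min(gap * (k + 1), len(seg) - len(inst))
                        while (at + len(inst) <= len(seg)
                               and seg.protected[at:at + len(inst)].any()):
                            at += 1
                        if at + len(inst) > len(seg):
                            raise ValueError(
                                f"family {spec.family_id}: no free tail "
                                f"window for motif {ev.instance!r}")
                        seg.codes[at:at + len(inst)] = inst
                        seg.protected[at:at + len(inst)] = True
        return genes

    def visit(node, genes: list[_Gene], active: bool) -> None:
        label = None
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if node.is_leaf():
            if active and genes:
                out[label] = genes
            return
        if not active and label == spec.origin_clade:
            active = True
        here = [g.copy() for g in genes] if active else genes
        if active and label in spec.events:
            here = apply_events(here, spec.events[label])
        for child in node.child_nodes():
            t = _branch_length(child) * spec.rate
            if active and here:
                child_genes = [g.copy() for g in here]
                for g in child_genes:
                    for s in g.segments:
                        mult = (spec.domain_rate_multiplier
                                if s.kind == "domain" else 1.0)
                        _jc_substitute(rng, s.codes, s.protected, t * mult)
            else:
                child_genes = here
            visit(child, child_genes, active)

    root_active = spec.origin_clade is None or spec.origin_clade == tax.root_clade
    visit(tax._tree.seed_node, [root_gene], root_active)
    return out


# ---------------------------------------------------------------------------
# Truth derivation

def _probe_motif(text: str, pattern: str) -> int:
    """Independent per-position motif count (tiny regex probe)."""
    alts = pattern.split("|")
    n = 0
    for i in range(len(text)):
        if any(re.match(alt, text[i:]) for alt in alts):
            n += 1
    return n


def _planted_epoch(present: set[str], tax: Taxonomy) -> str:
    if not present:
        return "not_found"
    epoch = tax.root_clade
    for clade in tax.focal_path:
        if present <= tax.leaves_under(clade):
            epoch = clade
        else:
            break
    return epoch


@dataclass
class TruthTable:
    """Expected pipeline outputs for one generated fixture."""

    rows: pd.DataFrame          # family, organism, status, paralogs, motifs
    epochs: dict[str, str]      # family -> expected emergence epoch

    def status(self, family: str, organism: str) -> str:
        df = self.rows
        sel = df[(df["family"] == family) & (df["organism"] == organism)]
        return sel.iloc[0]["status"] if len(sel) else "absent"

    def paralogs(self, family: str, organism: str) -> int:
        df = self.rows
        sel = df[(df["family"] == family) & (df["organism"] == organism)]
        return int(sel.iloc[0]["paralogs"]) if len(sel) else 0

    def to_tsv(self, path: str | Path) -> None:
        df = self.rows.copy()
        df["epoch"] = df["family"].map(self.epochs).fillna("not_found")
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Whole-fixture generation

@dataclass
class SurveyFixture:
    taxonomy: Taxonomy
    proteomes: dict[str, Proteome]
    seed_alignments: dict[str, Alignment]          # family -> seed MSA
    domain_alignments: dict[str, Alignment]        # domain -> seed MSA
    families: dict[str, "object"]                  # family -> QueryFamily
    truth: TruthTable
    reference_organism: str
    tail_policies: dict[str, str] = field(default_factory=dict)
    apa_seed: Alignment | None = None
    apa_family: str = "FCHO"
    interactions: list[InteractionRecord] = field(default_factory=list)
    interaction_truth: set = field(default_factory=set)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
        (outdir / "seeds").mkdir(exist_ok=True)
        (outdir / "domains").mkdir(exist_ok=True)
        for org, prot in sorted(self.proteomes.items()):
            write_fasta(prot, outdir / "proteomes" / f"{org}.fasta")
        for fam, aln in sorted(self.seed_alignments.items()):
            write_alignment(aln, outdir / "seeds" / f"{fam}.afa")
        for dom, aln in sorted(self.domain_alignments.items()):
            write_alignment(aln, outdir / "domains" / f"{dom}.afa")
        if self.apa_seed is not None:
            write_alignment(self.apa_seed, outdir / "seeds" / "APA.afa")
        with open(outdir / "taxonomy.nwk", "w") as fh:
            fh.write(self.taxonomy.newick() + "\n")
        write_mitab(self.interactions, outdir / "interactions.tsv")
        self.truth.to_tsv(outdir / "truth.tsv")
        self._write_config(outdir)

    def _write_config(self, outdir: Path) -> None:
        import yaml

        from .motifscan import BUILTIN_PATTERNS

        cfg = {
            "paths": {
                "proteomes": "proteomes",
                "seeds": "seeds",
                "domains": "domains",
                "taxonomy": "taxonomy.nwk",
                "interactions": "interactions.tsv",
            },
            "thresholds": {"sequence_evalue": 0.01, "domain_evalue": 0.01,
                           "apa_evalue": 0.01},
            "reference_organism": self.reference_organism,
            "apa": ({"seed": "seeds/APA.afa", "family": self.apa_family}
                    if self.apa_seed is not None else None),
            "families": {
                fam: {
                    "seed_alignment": f"seeds/{fam}.afa",
                    "reference_architecture": qf.reference_architecture,
                    "designated_members": qf.designated_members,
                    "relax_reciprocal": qf.relax_reciprocal,
                    "collapse_repeats": qf.collapse_repeats,
                    "tail_policy": self.tail_policies.get(fam, "C_tail"),
                }
                for fam, qf in sorted(self.families.items())
            },
            "motifs": {name: p.pattern
                       for name, p in BUILTIN_PATTERNS.items()},
        }
        with open(outdir / "survey.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


# AP2-activating-region stand-in planted into holozoan FCHO tails; chosen to
# avoid every built-in linear-motif pattern (synthetic, not the real APA).
APA_INSTANCE = "GQSTNAWGQAEHMKTSGNPAWGQS"

DEFAULT_TRUE_EDGES = (
    ("AP2A", "CLT"), ("AP2A", "CALM"), ("AP2A", "EPS15"), ("AP2A", "FCHO"),
    ("AP2A", "DNM"), ("AP2A", "STON"), ("CLT", "CALM"), ("EPS15", "ITSN"),
    ("EPS15", "FCHO"), ("ITSN", "FCHO"),
)


def default_family_specs() -> list[FamilySpec]:
    """Eight families encoding the survey's canonical scenarios: four
    ancient (root) families, two opisthokont gains (one with a tandem
    repeat expansion), a holozoan innovation with an ancient partial-
    architecture relative (the dynamin/DRP situation), and a metazoan
    newcomer with a clade-specific duplication."""
    return [
        FamilySpec("CLT", [("CHCR", 90), ("TD40", 70)]),
        FamilySpec("AP2A", [("ADAP", 110)]),
        FamilySpec("CALM", [("ANTH", 90)], events={
            "Holozoa": [MotifPlant("AP2", "DPW", "C_tail", count=2),
                        MotifPlant("clathrin", "LIDLE", "C_tail")],
            "Opisthokonta": [MotifPlant("EH", "NPF", "C_tail")],
        }),
        FamilySpec("EPS15", [("EH", 70), ("COIL", 60)]),
        FamilySpec("ITSN", [("EH", 70), ("COIL", 60), ("SH3", 55)],
                   origin_clade="Opisthokonta",
                   events={"Holozoa": [DomainGain("SH3", 55, after="SH3",
                                                  copies=3)]}),
        FamilySpec("FCHO", [("FCH", 80), ("MHD", 100)],
                   origin_clade="Opisthokonta",
                   events={"Holozoa": [MotifPlant("APA", APA_INSTANCE,
                                                  "C_tail")]}),
        FamilySpec("DNM", [("GTPASE", 130), ("PH", 90)],
                   origin_clade="Holozoa"),
        FamilySpec("DRP", [("GTPASE", 130)], analog_for="DNM",
                   events={"Holozoa": [Loss()]}),
        FamilySpec("STON", [("SHD", 70), ("MUHD", 90)], origin_clade="Metazoa",
                   events={"Metazoa": [Duplication(2),
                                       MotifPlant("EH", "NPF", "N_tail")]},
                   n_tail_length=40, c_tail_length=20, tail_policy="N_tail"),
    ]


def generate_survey_fixture(specs: Sequence[FamilySpec] | None = None,
                            tax: Taxonomy | None = None,
                            seed: int = 42,
                            n_decoys: int = 200,
                            decoy_length: tuple[int, int] = (120, 480),
                            motif_registry: Mapping[str, str] | None = None,
                            reference_organism: str | None = None,
                            n_seed_rows: int = 4) -> SurveyFixture:
    """Generate a complete survey fixture with planted ground truth."""
    from .motifscan import BUILTIN_PATTERNS
    from .orthology import QueryFamily

    specs = list(default_family_specs() if specs is None else specs)
    tax = tax or generate_taxonomy(seed=seed)
    patterns = dict(motif_registry) if motif_registry is not None else {
        name: p.pattern for name, p in BUILTIN_PATTERNS.items()}
    rng = np.random.default_rng(seed)
    registry = DomainRegistry(np.random.default_rng(seed + 7919))
    focal = tax.focal_path[-1] if tax.focal_path else tax.root_clade
    ref_org = reference_organism or sorted(tax.leaves_under(focal))[0]

    genes_by_family: dict[str, dict[str, list[_Gene]]] = {}
    for k, spec in enumerate(specs):
        genes_by_family[spec.family_id] = evolve_family(
            spec, tax, seed=int(rng.integers(0, 2 ** 31 - 1)),
            registry=registry)

    # --- proteomes: family members + decoys
    proteomes: dict[str, Proteome] = {}
    for org in tax.organisms:
        records: list[ProteinRecord] = []
        for spec in specs:
            for k, gene in enumerate(genes_by_family[spec.family_id].get(org, [])):
                records.append(ProteinRecord(
                    id=f"{spec.family_id}_{org}_c{k + 1}",
                    organism=org, sequence=gene.sequence()))
        lo, hi = decoy_length
        for i in range(n_decoys):
            L = int(rng.integers(lo, hi + 1))
            records.append(ProteinRecord(
                id=f"dec_{org}_{i + 1}", organism=org,
                sequence="".join(AMINO_ACIDS[c] for c in _sample_codes(rng, L))))
        proteomes[org] = Proteome(organism=org, records=records,
                                  taxon_path=tax.taxon_path(org))

    # --- seed alignments from the deepest focal-clade organisms whose
    # members share the reference architecture (ungapped by construction)
    seed_rows_pool: list[str] = []
    for clade in reversed(tax.focal_path or [tax.root_clade]):
        for org in sorted(tax.leaves_under(clade)):
            if org not in seed_rows_pool:
                seed_rows_pool.append(org)

    seed_alignments: dict[str, Alignment] = {}
    domain_alignments: dict[str, Alignment] = {}
    families: dict[str, QueryFamily] = {}
    dom_rows: dict[str, list[tuple[str, str]]] = {}
    for spec in specs:
        if spec.analog_for is not None:
            continue
        fam_genes = genes_by_family[spec.family_id]
        if ref_org not in fam_genes:
            raise ValueError(
                f"family {spec.family_id}: no member in reference organism")
        ref_gene = fam_genes[ref_org][0]
        ref_len = len(ref_gene.sequence())
        ref_arch = ref_gene.domain_ids()
        rows: list[tuple[str, str]] = []
        for org in seed_rows_pool:
            if org not in fam_genes:
                continue
            g = fam_genes[org][0]
            if g.domain_ids() == ref_arch and len(g.sequence()) == ref_len:
                rows.append((f"{spec.family_id}_{org}_c1", g.sequence()))
            if len(rows) == n_seed_rows:
                break
        if len(rows) < 2:
            raise ValueError(
                f"family {spec.family_id}: fewer than 2 alignable seed rows")
        seed_alignments[spec.family_id] = Alignment(rows=rows,
                                                    id=spec.family_id)
        # domain seed rows from the same organisms, cut at true block spans
        seed_orgs = [rid.split("_", 1)[1].rsplit("_c", 1)[0] for rid, _ in rows]
        for org in seed_orgs:
            g = fam_genes[org][0]
            seq = g.sequence()
            for dom, s, e in g.domain_spans():
                dom_rows.setdefault(dom, [])
                rid = f"{dom}_{spec.family_id}_{org}"
                if len([r for r in dom_rows[dom] if r[0].startswith(f"{dom}_{spec.family_id}")]) < n_seed_rows:
                    dom_rows[dom].append((rid, seq[s - 1:e]))
        families[spec.family_id] = QueryFamily(
            family_id=spec.family_id,
            seed_alignment_id=spec.family_id,
            reference_architecture=ref_arch,
            designated_members=[f"{spec.family_id}_{ref_org}_c{k + 1}"
                                for k in range(len(fam_genes[ref_org]))],
        )
    for dom, rows in dom_rows.items():
        # keep only the first family's rows (block lengths are identical)
        fam0 = rows[0][0].split("_")[1]
        keep = [r for r in rows if r[0].split("_")[1] == fam0]
        domain_alignments[dom] = Alignment(rows=keep, id=dom)

    # --- truth table
    truth_rows = []
    epochs: dict[str, str] = {}
    analog_orgs: dict[str, set[str]] = {}
    for spec in specs:
        if spec.analog_for is None:
            continue
        analog_orgs.setdefault(spec.analog_for, set()).update(
            genes_by_family[spec.family_id].keys())
    for spec in specs:
        if spec.analog_for is not None:
            continue
        fam_genes = genes_by_family[spec.family_id]
        present = set(fam_genes)
        epochs[spec.family_id] = _planted_epoch(present, tax)
        for org in tax.organisms:
            genes = fam_genes.get(org, [])
            if genes:
                status = "homolog"
            elif org in analog_orgs.get(spec.family_id, set()):
                status = "analog_ancestor"
            else:
                status = "absent"
            motifs: dict[str, int] = {}
            for name, pattern in patterns.items():
                total = 0
                for g in genes:
                    text, _ = g.tail(spec.tail_policy)
                    total += _probe_motif(text, pattern)
                motifs[name] = total
            truth_rows.append({
                "family": spec.family_id, "organism": org, "status": status,
                "paralogs": len(genes), "motifs": json.dumps(motifs),
            })
    truth = TruthTable(rows=pd.DataFrame(
        truth_rows, columns=["family", "organism", "status", "paralogs",
                             "motifs"]), epochs=epochs)

    # APA seed: three lightly diverged copies of the planted region
    # (mirrors a three-species experimental seed)
    apa_seed = None
    plants = [ev for spec in specs for evs in spec.events.values()
              for ev in evs
              if isinstance(ev, MotifPlant) and ev.pattern_name == "APA"]
    if plants:
        inst = np.array([AMINO_ACIDS.index(c) for c in plants[0].instance])
        rows = []
        for k in range(3):
            codes = inst.copy()
            _jc_substitute(rng, codes, np.zeros(len(codes), bool), 0.05)
            rows.append((f"apa_seed_{k + 1}",
                         "".join(AMINO_ACIDS[c] for c in codes)))
        apa_seed = Alignment(rows=rows, id="APA")

    edges = [(a, b) for a, b in DEFAULT_TRUE_EDGES
             if a in families and b in families]
    interactions, interaction_truth = generate_interactions(
        edges, noise=12 if edges else 0, seed=seed + 1,
        nodes=sorted(families) or None)
    tail_policies = {s.family_id: s.tail_policy for s in specs
                     if s.analog_for is None}
    return SurveyFixture(taxonomy=tax, proteomes=proteomes,
                         seed_alignments=seed_alignments,
                         domain_alignments=domain_alignments,
                         families=families, truth=truth,
                         reference_organism=ref_org,
                         tail_policies=tail_policies,
                         apa_seed=apa_seed,
                         interactions=interactions,
                         interaction_truth=interaction_truth)


# ---------------------------------------------------------------------------
# Interaction fixtures

def generate_interactions(true_edges: Iterable[tuple[str, str]],
                          noise: int = 0, seed: int = 0,
                          nodes: Sequence[str] | None = None
                          ) -> tuple[list[InteractionRecord], set[frozenset]]:
    """Whitelist-method records for the true edges plus ``noise``
    blacklist-method records among random node pairs. Returns the record
    list and the truth edge set."""
    from .pin import DEFAULT_BLACKLIST, DEFAULT_WHITELIST

    rng = np.random.default_rng(seed)
    true_edges = sorted({tuple(sorted(e)) for e in true_edges})
    node_pool = sorted(nodes) if nodes else sorted({n for e in true_edges for n in e})
    records: list[InteractionRecord] = []
    for i, (a, b) in enumerate(true_edges):
        method = DEFAULT_WHITELIST[i % len(DEFAULT_WHITELIST)]
        records.append(InteractionRecord(a, b, method, "synthdb"))
    for i in range(noise):
        a, b = rng.choice(node_pool, size=2, replace=True)
        method = DEFAULT_BLACKLIST[i % len(DEFAULT_BLACKLIST)]
        records.append(InteractionRecord(str(a), str(b), method, "noisedb"))
    truth = {frozenset(e) if e[0] != e[1] else frozenset([e[0]])
             for e in true_edges}
    return records, truth


def write_interactions(records: Sequence[InteractionRecord],
                       path: str | Path) -> None:
    write_mitab(records, path)
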