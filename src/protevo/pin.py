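"""Evidence-filtered protein-interaction network assembly.

Interaction records from curated databases mix detection methods of very
different reliability. The survey keeps only direct biochemical evidence
(affinity purification of complexes, protein-fragment complementation,
reconstituted in-vitro complexes, Far Western blotting, biochemical
activity) and drops high-throughput screens, colocalization,
cofractionation and two-hybrid data. Methods on neither list are dropped
conservatively, with a warning for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .seqio import InteractionRecord

logger = logging.getLogger(__name__)

DEFAULT_WHITELIST = (
    "affinity purification",
    "protein-fragment complementation",
    "reconstituted complex",
    "far western",
    "biochemical activity",
)
DEFAULT_BLACKLIST = (
    "two-hybrid",
    "colocalization",
    "cofractionation",
    "high throughput",
    "high-throughput",
)


@dataclass(frozen=True)
class EvidencePolicy:
    """Method whitelist/blacklist; matching is case-insensitive substring."""

    whitelist: tuple[str, ...] = DEFAULT_WHITELIST
    blacklist: tuple[str, ...] = DEFAULT_BLACKLIST

    def __post_init__(self) -> None:
        overlap = {w.lower() for w in self.whitelist} & {b.lower() for b in self.blacklist}
        if overlap:
            raise ValueError(f"whitelist and blacklist overlap: {sorted(overlap)}")

    def classify(self, method: str) -> str:
        m = method.lower()
        if any(b.lower() in m for b in self.blacklist):
            return "blacklisted"
        if any(w.lower() in m for w in self.whitelist):
            return "whitelisted"
        return "unlisted"


def filter_interactions(records: Iterable[InteractionRecord],
                        policy: EvidencePolicy | None = None
                        ) -> list[InteractionRecord]:
    """Keep whitelisted records only; blacklisted always dropped; unlisted
    methods dropped with a logged warning (conservative default)."""
    policy = policy or EvidencePolicy()
    kept: list[InteractionRecord] = []
    for rec in records:
        verdict = policy.classify(rec.method)
        if verdict == "whitelisted":
            kept.append(rec)
        elif verdict == "unlisted":
            logger.warning("dropping interaction %s-%s: unlisted method %r",
                           rec.protein_a, rec.protein_b, rec.method)
    return kept


def build_network(records: Iterable[InteractionRecord],
                  epochs: Mapping[str, str] | None = None,
                  class_map: Mapping[str, str] | None = None) -> nx.Graph:
    """Assemble the undirected network from (already filtered) records.

    Parallel records collapse onto one edge carrying the record list;
    self-loops are retained and flagged. Nodes are annotated with their
    family's emergence epoch (``unknown`` if absent from the matrix) and a
    functional class from ``class_map`` (accessory / CLASP / hub).
    """
    epochs = dict(epochs or {})
    class_map = dict(class_map or {})
    g = nx.Graph()
    for rec in sorted(records, key=lambda r: (r.protein_a, r.protein_b, r.method)):
        a, b = rec.protein_a, rec.protein_b
        for n in (a, b):
            if not g.has_node(n):
                g.add_node(n)
        if g.has_edge(a, b):
            g.edges[a, b]["records"].append(rec)
        else:
            g.add_edge(a, b, records=[rec], self_loop=(a == b))
    for n in class_map:
        if not g.has_node(n):
            g.add_node(n)
    for n in g.nodes:
        g.nodes[n]["epoch"] = epochs.get(n, "unknown")
        g.nodes[n]["functional_class"] = class_map.get(n, "unknown")
    return g


def export_network(g: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML (lossless), SIF (edges only) or
    edge-TSV (edges + record counts)."""
    path = Path(path)
    if fmt == "graphml":
        h = nx.Graph()
        for n, data in g.nodes(data=True):
            h.add_node(n, epoch=data.get("epoch", "unknown"),
                       functional_class=data.get("functional_class", "unknown"))
        for a, b, data in g.edges(data=True):
            recs = data.get("records", [])
            h.add_edge(a, b, n_records=len(recs),
                       methods=";".join(sorted({r.method for r in recs})),
                       self_loop=bool(data.get("self_loop", False)))
        nx.write_graphml(h, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(g.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tn_records\tmethods\n")
            for a, b, data in sorted(g.edges(data=True)):
                recs = data.get("records", [])
                methods = ";".join(sorted({r.method for r in recs}))
                fh.write(f"{a}\t{b}\t{len(recs)}\t{methods}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))
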