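"""Orchestration of the full survey: profiles, calibration, homolog calls,
emergence mapping, motif statistics, APA search and network assembly, from a
single config or an in-memory fixture.

All randomness flows from the configured seed; identical inputs and seed
reproduce identical outputs (outputs are written via write-then-rename so a
failed run leaves no truncated files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import orthology, pin
from .motifscan import (BUILTIN_PATTERNS, MotifPattern, apa_search,
                        extract_tail, motif_occurrence, scan_motif)
from .orthology import (EmergenceMatrix, HomologCall, QueryFamily,
                        build_emergence_matrix, call_homologs, count_paralogs)
from .pairalign import SubstitutionMatrix
from .profilehmm import (EvalueCalibration, ProfileModel, build_profile,
                         calibrate)
from .seqio import (Alignment, Proteome, Taxonomy, read_alignment, read_fasta,
                    read_mitab, read_taxonomy)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class SurveyConfig:
    proteomes_dir: Path
    seeds_dir: Path
    domains_dir: Path
    taxonomy_path: Path
    interactions_path: Path | None
    families: dict[str, QueryFamily]
    tail_policies: dict[str, str]
    motif_registry: dict[str, str]
    reference_organism: str
    focal_clade: str | None = None
    seq_threshold: float = 0.01
    dom_threshold: float = 0.01
    apa_threshold: float = 0.01
    apa_seed_path: Path | None = None
    apa_family: str | None = None
    n_null: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.proteomes_dir, self.seeds_dir, self.domains_dir,
                  self.taxonomy_path):
            if not Path(p).exists():
                raise ConfigError(f"missing input path: {p}")
        for t in (self.seq_threshold, self.dom_threshold, self.apa_threshold):
            if t <= 0:
                raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int = 0) -> "SurveyConfig":
        path = Path(path)
        base = path.parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            paths = raw["paths"]
            fams = {}
            tails = {}
            for fam, fd in raw["families"].items():
                fams[fam] = QueryFamily(
                    family_id=fam,
                    seed_alignment_id=fam,
                    reference_architecture=list(fd["reference_architecture"]),
                    designated_members=list(fd["designated_members"]),
                    relax_reciprocal=bool(fd.get("relax_reciprocal", False)),
                    collapse_repeats=bool(fd.get("collapse_repeats", True)),
                )
                tails[fam] = fd.get("tail_policy", "C_tail")
            thr = raw.get("thresholds", {})
            apa = raw.get("apa") or {}
            return cls(
                proteomes_dir=base / paths["proteomes"],
                seeds_dir=base / paths["seeds"],
                domains_dir=base / paths["domains"],
                taxonomy_path=base / paths["taxonomy"],
                interactions_path=(base / paths["interactions"]
                                   if paths.get("interactions") else None),
                families=fams, tail_policies=tails,
                motif_registry=dict(raw.get("motifs", {})),
                reference_organism=raw["reference_organism"],
                seq_threshold=float(thr.get("sequence_evalue", 0.01)),
                dom_threshold=float(thr.get("domain_evalue", 0.01)),
                apa_threshold=float(thr.get("apa_evalue", 0.01)),
                apa_seed_path=(base / apa["seed"]) if apa else None,
                apa_family=apa.get("family") if apa else None,
                seed=seed,
            )
        except KeyError as exc:
            raise ConfigError(f"config missing key: {exc}") from None


@dataclass
class SurveyResult:
    calls: list[HomologCall]
    emergence: EmergenceMatrix
    paralogs: pd.DataFrame
    motif_counts: pd.DataFrame          # family, organism, pattern, count
    motif_stats: pd.DataFrame           # family, clade, pattern, O, median
    apa_report: pd.DataFrame
    network: "pin.nx.Graph"
    profiles: dict[str, ProfileModel]
    calibrations: dict[str, EvalueCalibration]


def _pooled_lengths(proteomes: Mapping[str, Proteome]) -> np.ndarray:
    return np.array([len(rec) for prot in proteomes.values() for rec in prot])


def run_survey_data(proteomes: Mapping[str, Proteome],
                    seed_alignments: Mapping[str, Alignment],
                    domain_alignments: Mapping[str, Alignment],
                    taxonomy: Taxonomy,
                    families: Mapping[str, QueryFamily],
                    reference_organism: str,
                    tail_policies: Mapping[str, str] | None = None,
                    motif_registry: Mapping[str, str] | None = None,
                    interactions=None,
                    apa_seed: Alignment | None = None,
                    apa_family: str | None = None,
                    seq_threshold: float = 0.01,
                    dom_threshold: float = 0.01,
                    apa_threshold: float = 0.01,
                    n_null: int = 1000,
                    seed: int = 0) -> SurveyResult:
    """Run the whole survey on in-memory inputs."""
    if reference_organism not in proteomes:
        raise ConfigError(f"reference organism {reference_organism!r} has no proteome")
    tail_policies = dict(tail_policies or {})
    registry = {name: MotifPattern(name, pat)
                for name, pat in (motif_registry
                                  or {n: p.pattern
                                      for n, p in BUILTIN_PATTERNS.items()}
                                  ).items()}
    lengths = _pooled_lengths(proteomes)
    matrix = SubstitutionMatrix.blosum62()

    # ---- profiles + one calibration per profile (pooled length null)
    profiles: dict[str, ProfileModel] = {}
    cals: dict[str, EvalueCalibration] = {}
    domain_profiles: dict[str, ProfileModel] = {}
    for k, (name, aln) in enumerate(sorted(seed_alignments.items())):
        profiles[name] = build_profile(aln, profile_id=name)
    for k, (name, aln) in enumerate(sorted(domain_alignments.items())):
        domain_profiles[name] = build_profile(aln, profile_id=name)
    all_profiles = {**profiles, **domain_profiles}
    for k, name in enumerate(sorted(all_profiles)):
        cal_seed = (seed * 100003 + k * 1009 + 1) % (2 ** 31 - 1)
        cals[name] = calibrate(all_profiles[name], n_null=n_null,
                               len_dist=lengths, seed=cal_seed)
        logger.info("calibrated %s: mu=%.2f", name, cals[name].mu)

    # ---- homolog calls (architecture and reciprocal rankings are memoized
    # per record: they do not depend on which family found the hit)
    ref_proteome = proteomes[reference_organism]
    calls: list[HomologCall] = []
    arch_cache: dict[str, "object"] = {}
    top_cache: dict[str, str] = {}
    for fam in sorted(families):
        qf = families[fam]
        for org in sorted(proteomes):
            call = call_homologs(
                qf, proteomes[org], profiles[fam], cals[fam],
                domain_profiles, cals, ref_proteome,
                seq_threshold=seq_threshold, dom_threshold=dom_threshold,
                matrix=matrix, arch_cache=arch_cache, top_cache=top_cache)
            calls.append(call)
    emergence = build_emergence_matrix(calls, taxonomy)
    paralogs = count_paralogs(calls)

    # ---- motif statistics on accepted hits' tails
    count_rows = []
    for call in calls:
        policy = tail_policies.get(call.family_id, "C_tail")
        per_hit: dict[str, int] = {name: 0 for name in registry}
        for ev in call.evidence:
            if not ev.accepted:
                continue
            rec = proteomes[call.organism].get(ev.hit.sequence_id)
            tail = extract_tail(rec, ev.architecture, policy)
            for name, pat in registry.items():
                c, _ = scan_motif(tail, pat)
                count_rows.append({"family": call.family_id,
                                   "organism": call.organism,
                                   "protein": ev.hit.sequence_id,
                                   "pattern": name, "count": c})
    motif_counts = pd.DataFrame(
        count_rows, columns=["family", "organism", "protein", "pattern", "count"])

    stat_rows = []
    clades = ([taxonomy.root_clade] + [c for c in taxonomy.clades
                                       if c != taxonomy.root_clade])
    for fam in sorted(families):
        sub = motif_counts[motif_counts["family"] == fam]
        for clade in clades:
            group = sorted(taxonomy.leaves_under(clade) & set(proteomes))
            if not group:
                continue
            for name, pat in registry.items():
                counts_by_org = {
                    org: list(sub[(sub["organism"] == org)
                                  & (sub["pattern"] == name)]["count"])
                    for org in group
                }
                stats = motif_occurrence(counts_by_org, group, pat,
                                         taxon_name=clade)
                stat_rows.append({
                    "family": fam, "clade": clade, "pattern": name,
                    "occurrence": stats.occurrence,
                    "median_count": stats.median_count,
                    "n_organisms": stats.n_organisms,
                })
    motif_stats = pd.DataFrame(
        stat_rows, columns=["family", "clade", "pattern", "occurrence",
                            "median_count", "n_organisms"])

    # ---- APA-style profile search over the target family's accepted hits
    apa_rows = []
    if apa_seed is not None and apa_family is not None:
        apa_profile = build_profile(apa_seed, profile_id="APA")
        apa_cal = calibrate(apa_profile, n_null=n_null, len_dist=lengths,
                            seed=(seed * 100003 + 999983) % (2 ** 31 - 1))
        targets = []
        for call in calls:
            if call.family_id != apa_family:
                continue
            for hit in call.accepted_hits:
                targets.append(proteomes[call.organism].get(hit.sequence_id))
        for res in apa_search(targets, apa_profile, apa_cal,
                              threshold=apa_threshold):
            apa_rows.append(dataclasses.asdict(res))
    apa_report = pd.DataFrame(
        apa_rows, columns=["sequence_id", "best_evalue",
                           "neg_log10_evalue", "passes"])

    # ---- network
    filtered = pin.filter_interactions(interactions or [])
    network = pin.build_network(filtered, epochs=emergence.epochs)

    return SurveyResult(calls=calls, emergence=emergence, paralogs=paralogs,
                        motif_counts=motif_counts, motif_stats=motif_stats,
                        apa_report=apa_report, network=network,
                        profiles=all_profiles, calibrations=cals)


# ---------------------------------------------------------------------------
# File-based entry point

def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_survey(cfg: SurveyConfig, outdir: str | Path) -> Path:
    """Run the survey from files and write the standard outputs.

    Produces emergence_matrix.tsv, paralog_table.tsv, motif_stats.tsv,
    apa_report.tsv, network.graphml, calls.jsonl and run.log in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    proteomes = {}
    for f in sorted(Path(cfg.proteomes_dir).glob("*.fasta")):
        prot = read_fasta(f)
        proteomes[prot.organism] = prot
    taxonomy = read_taxonomy(cfg.taxonomy_path,
                             focal_clade=cfg.focal_clade)
    if taxonomy.focal_clade is None:
        # deepest named clade on the path to the reference organism
        path = taxonomy.taxon_path(cfg.reference_organism)
        taxonomy = read_taxonomy(cfg.taxonomy_path, focal_clade=path[-1])
    seeds = {fam: read_alignment(Path(cfg.seeds_dir) / f"{fam}.afa", fam)
             for fam in cfg.families}
    domains = {p.stem: read_alignment(p, p.stem)
               for p in sorted(Path(cfg.domains_dir).glob("*.afa"))}
    interactions = (read_mitab(cfg.interactions_path)
                    if cfg.interactions_path
                    and Path(cfg.interactions_path).exists() else [])
    apa_seed = (read_alignment(cfg.apa_seed_path, "APA")
                if cfg.apa_seed_path else None)

    result = run_survey_data(
        proteomes=proteomes, seed_alignments=seeds,
        domain_alignments=domains, taxonomy=taxonomy,
        families=cfg.families, reference_organism=cfg.reference_organism,
        tail_policies=cfg.tail_policies, motif_registry=cfg.motif_registry,
        interactions=interactions, apa_seed=apa_seed,
        apa_family=cfg.apa_family,
        seq_threshold=cfg.seq_threshold, dom_threshold=cfg.dom_threshold,
        apa_threshold=cfg.apa_threshold, n_null=cfg.n_null, seed=cfg.seed)
    write_survey_outputs(result, outdir, cfg=cfg)
    return outdir


def write_survey_outputs(result: SurveyResult, outdir: str | Path,
                         cfg: SurveyConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    em = result.emergence
    em_table = em.presence.astype(int).copy()
    em_table["epoch"] = [em.epochs[f] for f in em_table.index]
    _atomic_write(outdir / "emergence_matrix.tsv",
                  lambda p: em_table.to_csv(p, sep="\t"))
    _atomic_write(outdir / "clade_presence.tsv",
                  lambda p: em.clade_presence.astype(int).to_csv(p, sep="\t"))
    _atomic_write(outdir / "paralog_table.tsv",
                  lambda p: result.paralogs.to_csv(p, sep="\t"))
    _atomic_write(outdir / "motif_stats.tsv",
                  lambda p: result.motif_stats.to_csv(p, sep="\t", index=False))
    _atomic_write(outdir / "apa_report.tsv",
                  lambda p: result.apa_report.to_csv(p, sep="\t", index=False))
    _atomic_write(outdir / "network.graphml",
                  lambda p: pin.export_network(result.network, p, "graphml"))

    def write_calls(p: Path) -> None:
        with open(p, "w") as fh:
            for call in result.calls:
                fh.write(json.dumps({
                    "family": call.family_id,
                    "organism": call.organism,
                    "status": call.status,
                    "accepted": [
                        {"id": h.sequence_id, "evalue": h.evalue,
                         "bits": h.bits,
                         "envelope": [h.env_start, h.env_end]}
                        for h in call.accepted_hits],
                    "evidence": [
                        {"id": ev.hit.sequence_id,
                         "architecture": ev.architecture.domain_ids,
                         "verdict": ev.architecture_verdict,
                         "reciprocal": ev.reciprocal,
                         "accepted": ev.accepted}
                        for ev in call.evidence],
                }, sort_keys=True) + "\n")

    _atomic_write(outdir / "calls.jsonl", write_calls)

    def write_log(p: Path) -> None:
        with open(p, "w") as fh:
            if cfg is not None:
                blob = {
                    "seed": cfg.seed,
                    "thresholds": [cfg.seq_threshold, cfg.dom_threshold,
                                   cfg.apa_threshold],
                    "families": sorted(cfg.families),
                    "n_null": cfg.n_null,
                }
                digest = hashlib.sha256(
                    json.dumps(blob, sort_keys=True).encode()).hexdigest()
                fh.write(f"config_sha256\t{digest}\n")
                fh.write(f"seed\t{cfg.seed}\n")
            for name, cal in sorted(result.calibrations.items()):
                fh.write(f"calibration\t{name}\tmu={cal.mu:.6f}\t"
                         f"beta={cal.beta:.6f}\tn={cal.n_null}\n")

    _atomic_write(outdir / "run.log", write_log)
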