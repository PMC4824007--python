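# protevo

Comparative survey of protein-family emergence across a eukaryotic
taxonomy, built around the machinery of clathrin-mediated endocytosis
(CME): profile-based homolog search with reciprocal-best-hit and
domain-architecture validation, short-linear-motif scanning with per-taxon
statistics, emergence-epoch assignment, paralog counting, evidence-filtered
protein-interaction networks, and alignment-anchored conservation/contact
analysis. A first-class synthetic-data generator plants families with known
evolutionary histories along a labelled taxonomy so every stage of the
pipeline can be validated against ground truth without any downloads.

## Who this is for

Researchers tracing when protein machines (here: the endocytic coat —
clathrin, the AP2 adaptor, muniscins, CLASPs) arose and how they were
remodelled across the eukaryotic tree, and anyone who needs a transparent,
fully testable re-implementation of the classic survey recipe:

1. build a profile HMM per family from a seed alignment of model organisms;
2. forward-search every proteome at a sequence e-value threshold of 0.01;
3. keep hits whose ordered domain architecture matches the animal
   reference (tandem repeat copy number tolerated);
4. require the hit to be a reciprocal best hit against the reference
   proteome (Smith–Waterman, BLOSUM62, gap 11/1), with a per-family
   relaxation for very distant homologs;
5. map each family onto the earliest clade of the root-to-focal path whose
   organisms contain all detections (the *emergence epoch*), and count
   accepted paralogs per organism.

Best reciprocal hits with only partially matching architectures are
reported as putative analogs/ancestors (e.g. dynamin-related proteins that
share the GTPase domain but lack the PH domain).

## The model at the core

Scoring uses a simplified single-hit Plan7 profile HMM: match states with
position-specific emissions (background-proportional pseudocounts, total
mass 1), insert states emitting the background, delete states, uniform
1/M local entry/exit. The forward bit score is

    S = log2 [ P(s | profile, local single-hit) / P(s | background) ]

computed exactly (no heuristic filters). E-values come from a Gumbel law
fitted to forward scores of i.i.d. background sequences by left-censored
maximum likelihood on the upper tail, with `E = Z * (1 - F(S))` and `Z`
the number of sequences scanned. Motif scanning applies the classical
endocytic patterns (`DP[WF]|F.D.F|WV.F|F.F.[FL]` for AP2 binding,
`L[FILMV].[FILMV][DE]|L[FILMV].[DE][FILMV]` for clathrin boxes, `NPF` for
EH domains) to the domain-free terminal tails, and reports per-taxon
occurrence `O = n_with_motif / n_total` and the median count over
motif-bearing proteins. Conservation is sequence-logo information content
`IC = log2 20 − H − e_n` with the small-sample correction
`e_n = 19/(2 ln2 · n)`.

## Worked example

```bash
protevo simulate --out fixture --seed 42        # synthetic proteomes + truth
protevo survey --config fixture/survey.yaml --out run --seed 1
```

`run/emergence_matrix.tsv` then contains one row per family — presence per
organism plus the inferred epoch. For the default fixture:

```
        ...  epoch
AP2A    ...  LECA
CALM    ...  LECA
CLT     ...  LECA
DNM     ...  Holozoa
EPS15   ...  LECA
FCHO    ...  Opisthokonta
ITSN    ...  Opisthokonta
STON    ...  Metazoa
```

meaning, e.g., that clathrin-like and AP2-like families trace back to the
last eukaryotic common ancestor, the dynamin-like family is a holozoan
innovation, and the stonin-like family is metazoan-only — exactly the
histories planted by the generator (`fixture/truth.tsv`). The paralog
table reports 3 STON copies in metazoans (a planted duplication) and 1
copy elsewhere; `run/calls.jsonl` records, per organism, the evidence
trail — e.g. DNM in outgroup organisms is called `analog_ancestor`: the
forward hit shares the GTPase domain, lacks PH, yet reciprocally matches
the reference dynamin. Smaller single-purpose subcommands (`motifs`,
`network`, `conserve`, `contacts`) expose the individual analyses.

## Layout

```
src/protevo/
  seqio.py           formats: FASTA, Newick taxonomy, PSI-MI-TAB-like TSV,
                     PDB ATOM subset; core domain types
  pairalign.py       affine-gap global/local alignment + reciprocal ranking
  profilehmm.py      profile building, forward/Viterbi, calibration, scans,
                     domain-architecture annotation
  orthology.py       homolog calls, paralog counts, emergence mapping
  motifscan.py       tail extraction, motif patterns, per-taxon statistics
  pin.py             evidence filtering and network assembly/export
  conserve_struct.py logo information content, residue contacts
  synthdata.py       planted-truth generator (taxonomies, proteomes,
                     interactions)
  pipeline.py        end-to-end orchestration from a single config
  cli.py             protevo simulate|survey|motifs|network|conserve|contacts
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
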