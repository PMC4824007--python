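# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic data does and does not emulate, and the known
limitations.

## Profile model

A simplified Plan7 architecture in single-hit mode: M match states with
position-specific emission distributions, insert states I_1..I_{M-1}
emitting the background, delete states D_1..D_M, and begin/end wrapping.
Multihit alignment, MSV/SSV-style filters and DNA profiles are deliberately
out of scope: the survey needs ranking and thresholding semantics, not
parity with any particular search tool.

**Seed estimation.** Alignment columns with a gap fraction strictly below
50% become match states (exactly 50% → insert). Match emissions use
background-proportional pseudocounts with total mass 1.0:
`e[a] = (count[a] + q[a]) / (n + 1)`; transitions use Laplace 0.1. Both
choices stabilize the very small seed alignments this survey works with
(2–4 rows, one per model organism). `X` residues are excluded from counts
and emit the background at scoring time (zero log-odds), so unknown
residues neither help nor hurt a hit. The background `q` is the standard
BLOSUM62 marginal frequency vector. Insertions following a deletion in a
seed row cannot be represented in Plan7 (no D→I transition); the count is
folded into D→M, a negligible approximation for near-ungapped seeds.

**Scoring modes.** In `local` mode (the search mode) the aligned core may
enter and exit at any match state, each carrying probability 1/M; flanking
sequence and insert emissions contribute zero log-odds. In `glocal` mode
the model is a proper generative HMM (entry through begin at the first
residue, exit at position M with the last residue); this mode exists so
tests can verify exact probability normalization (the summed probability
of all length-3 sequences under a no-indel length-3 profile is 1 within
1e-9). Forward and Viterbi are exact; the implementation runs in scaled
linear (odds) space with per-row renormalization, which is algebraically
identical to log-space dynamic programming and validated against full path
enumeration to 1e-9 on small instances.

**Envelopes.** Hit envelopes (and domain boundaries) are the sequence
positions consumed by match/insert states on the Viterbi path. All
user-facing coordinates are 1-based inclusive.

## E-value calibration

For each profile, `n_null` i.i.d. background sequences are sampled with
lengths drawn from the pooled empirical length distribution of the scanned
proteomes, scored with forward, and a Gumbel law is fitted. The fit is a
*left-censored* maximum-likelihood fit: only the upper 5% of null scores
enter the likelihood as observations; the rest contribute a censored term
`n_cens · log F(c)`. Rationale: e-values only ever query the right tail,
and the bulk of a forward-score null sample deviates from the Gumbel shape
enough that a full-sample fit substantially overstates tail p-values
(roughly 2x at p = 0.01 in our diagnostics), while a censored fit at the
5% point brackets the operating region (0.05–0.001) and is accurate on
held-out nulls at both p = 0.05 and p = 0.01. A method-of-moments fallback
guards against optimizer failure. `E = Z · (1 − F(S))` with `Z` the number
of sequences in the scanned proteome (per-database semantics) for family
scans, and `Z = 1` for per-sequence domain tests and the APA search.

Calibration defaults: `n_null = 1000` in the survey pipeline (one
calibration per profile against the pooled length distribution — the
pooled default keeps e-values comparable across proteomes and the cost
linear in the number of profiles), `n_null = 10,000` where calibration
accuracy itself is being measured. Deterministic given the seed.

## Homolog calling

Per family and proteome: forward search at sequence e-value ≤ 0.01; domain
architecture of each hit annotated with the curated domain profiles
(domain e-value ≤ 0.01, iterative envelope masking so tandem repeats are
all recovered, greedy overlap resolution by ascending e-value);
architecture compared to the animal reference with run-length collapse
(`collapse_repeats`, default on — a 2×SH3 and a 5×SH3 protein share a
full architecture); reciprocal best hit against the reference proteome by
Smith–Waterman (BLOSUM62, gap open 11, extend 1 — protein-search
defaults), requiring any member of the designated reference paralog set to
rank first (ties broken lexicographically for reproducibility). The
reciprocal requirement can be relaxed per family for very distant homologs
(architecture-only acceptance). Hits with full architecture that pass
accept as homologs (all retained — paralogs are counted, not collapsed);
if none accept but a partial-architecture hit passes reciprocity, the
family is scored `analog_ancestor`; hits passing reciprocity with
architecture verdict `none` are reported absent, evidence retained.

The emergence epoch of a family is the smallest named clade on the
root-to-focal-clade path containing every organism with an accepted
homolog; a single organism suffices to mark presence (configurable). An
organism set spanning outgroups resolves to the root.

Pairwise alignment itself is delegated to Bio.Align.PairwiseAligner
(affine gaps, `gap(k) = open + k·extend`); tie-breaking among co-optimal
tracebacks follows the library's deterministic first alignment — scores,
which are all the reciprocal criterion uses, are unaffected.

## Motif statistics

Motifs are scanned only in the terminal tail outside all resolved domain
envelopes (C-terminal by default; N-terminal for stonin-like families);
inter-domain linkers are not scanned (a `linkers` option exists but is
off). Every start position matching any alternative of the pattern counts
once; overlapping matches all count — alternation patterns make
non-overlapping greedy scans order-dependent, so the per-position rule is
the reproducible choice. Per taxon, occurrence is the fraction of
organisms whose family protein (ANY paralog) carries ≥ 1 match, with all
organisms of the taxon in the denominator by default (organisms lacking
the family count against occurrence; `denominator="with_homolog"`
restricts). The median is over the motif counts of motif-bearing proteins
only, and is undefined when there are none.

The APA (AP2-activating) region is searched with a small profile built
from a three-sequence seed; a record passes when its best e-value is
≤ 0.01, i.e. −log10 E ≥ 2 — the dashed-line convention used in
threshold plots. The bundled APA seed is synthetic (the generator plants a
24-residue stand-in region in holozoan muniscin tails); tests assert
threshold behaviour, not any real organism's values.

## Interaction-network evidence

Only direct biochemical detection methods are kept: affinity purification
of complexes, protein-fragment complementation, reconstituted in-vitro
complexes, Far Western blotting, biochemical activity. High-throughput
screens, colocalization, cofractionation and two-hybrid data are always
dropped. Matching is case-insensitive substring against an editable
whitelist/blacklist — source databases use different vocabularies, so the
lists encode experiment classes, not exact terms; methods on neither list
are dropped conservatively with a logged warning. Parallel records
collapse to one edge carrying its evidence; self-loops are retained and
flagged.

## Conservation and contacts

Logo information content per column: gaps excluded from the denominator,
`IC = log2 20 − H − e_n`, small-sample correction `e_n = 19/(2 ln2 · n)`
togglable (on by default for logo output, off in closed-form tests), IC
clipped at 0. Columns are addressed via reference-sequence numbering (the
p-th non-gap residue of a chosen row).

Contacts are distance-based — the criterion behind published "deduced
contact" figures is rarely stated, so the package adopts common structural
practice and exposes the cutoffs: contact when the minimal heavy-atom
distance is ≤ 4.5 Å; electrostatic when an opposite-charge pair (K/R/H vs
D/E) has charged-group atoms ≤ 4.0 Å; hydrophobic when two apolar residues
have side-chain carbons ≤ 4.5 Å; otherwise "other". Hydrogens and
non-'A' altlocs are ignored at parse time.

## Synthetic data: what it emulates, and what it does not

Each family member is a chain of conserved domain blocks joined by linkers
and flanked by tails. Substitution follows the 20-state
equal-exchangeability (Jukes–Cantor-style) chain applied exactly per
branch — `P(change) = (19/20)(1 − exp(−(20/19) t))`, replacement uniform
over the other 19 residues — so branch composition is exact and the
pairwise difference between leaves at path distance T has the closed form
`(19/20)(1 − exp(−(20/19)T))`, which the tests verify. Domain blocks
evolve at a reduced rate (default multiplier 0.4) and contain no indels,
keeping the architecture truth unambiguous. Defaults: rate 0.05
substitutions/site per unit branch, branch lengths 1.0, tails 12/60
residues, linkers 15 — chosen so that families diverge visibly across the
tree (tails reach ~30% divergence between the most distant leaves) while
staying within profile sensitivity, the regime the survey is designed for.

Clade-rooted events create the planted histories: family origin clades,
domain gain/loss (including tandem repeat expansion), gene duplication,
loss, and motif planting. Planted motif instances are protected from
substitution thereafter — this makes the truth table exactly derivable
from spec + seed at the cost of realism (real motifs drift); occurrence
statistics measured on evolved tails away from planted instances remain
stochastic. The default fixture (6 nested clades: LECA → Amorphea →
Obazoa → Opisthokonta → Holozoa → Metazoa, plus 2 basal outgroup clades,
2 organisms per clade, 8 families, 200 background decoys per proteome)
encodes the canonical scenarios: four root families, two opisthokont
gains (one with an SH3-style repeat expansion), a holozoan innovation
with an ancient partial-architecture relative sharing only the GTPase
domain (the dynamin/DRP situation), and a metazoan newcomer with a
lineage-specific duplication.

Not emulated: realistic indel processes, rate heterogeneity across sites,
codon structure, gene-tree/species-tree discordance, compositional bias,
and real proteome size (~200 sequences per organism vs tens of
thousands). Passing the planted-truth tests therefore demonstrates that
the pipeline's logic is correct and its statistics calibrated under its
own model assumptions — not that the survey's sensitivity on real,
deeply divergent proteomes matches these recovery rates.

## Problem sizes

The suite and the acceptance script run the full survey once on the
default fixture (16 proteomes × ~208 sequences, 8 family + 13 domain
profiles at `n_null = 1000`), use 10,000-sample null sets where
calibration accuracy is itself the quantity under test, and validate the
dynamic-programming cores by exhaustive enumeration at small sizes
(profiles M ≤ 3 with sequences ≤ 4; alignments ≤ 4×4). These sizes were
chosen to exercise every code path at full fidelity while keeping a
complete run in the minutes range on a single core.

## Known limitations

* The profile HMM is single-hit: a protein containing two well-separated
  copies of the same *family* (not domain) yields one envelope; domain
  annotation recovers repeats via masking instead.
* E-value calibration assumes i.i.d. background sequences; compositional
  bias in real proteomes would require a biased-composition null.
* The reciprocal step ranks by Smith–Waterman score, not by a second
  profile search; for highly repetitive proteins the two can disagree.
* GraphML export is lossless for annotations; SIF drops record lists.
* The structure reader covers the PDB ATOM subset only (no MODEL/ANISOU,
  no mmCIF).
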