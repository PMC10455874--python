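# Methods

## Background and scope

The p25alpha domain defines the TPPP (tubulin polymerization promoting
protein) family and is tied to the presence of a eukaryotic flagellum or
cilium. Seed plants (Spermatophyta) — with the exception of cycads and
*Ginkgo biloba*, whose male gametes are flagellated — lack cilia, and no
p25alpha-domain protein is known from land plants. A seed-plant transcriptome
or EST record that encodes the domain is therefore anomalous and must be one
of three things: a contaminant read from a fungus, protist, or animal that
was co-extracted with the plant material; a horizontal gene transfer (HGT);
or a genuine orthologous relic. `p25screen` implements the screening
procedure that separates these explanations. It does **not** run BLAST,
build alignments, or infer trees; it consumes FASTA sequences, tabular BLAST
output, and support-annotated Newick trees, and emits per-sequence calls.

## Domain detection (motif + coverage)

Two degenerate motifs diagnose the domain:

* the Rossmann-like nonamer `GXGXGXXGR` at the conserved C-terminus;
* the N-terminal signature `L(F)xxxFxxF(Y)xxF` (positions 1 and 8 admit the
  parenthesised alternative), 11 residues.

Motifs are matched exactly (a `max_mismatch` knob, default 0, exists for
sensitivity studies). `X` in a sequence matches only wildcard positions.
Scanning a nucleotide record means scanning all six conceptual translations;
translation uses the standard code, renders stops as `*` *without*
terminating (assemblies routinely contain spurious in-frame stops), and
renders ambiguous codons as `X`. The frame with the highest total evidence
(motif count + covered reference fraction) wins; ties prefer low |frame| and
the forward strand.

Domain completeness is measured by aligning the candidate to a reference
consensus (default: a bundled 160-residue **synthetic** consensus — no real
p25alpha sequence ships with the package; users can supply their own via
`--ref`). Alignment is local (Smith–Waterman) with linear scoring
(match +2, mismatch −1, gap −2). A global alignment is the wrong tool here:
when the domain is a small fraction of a long translated frame, the global
optimum provably scatters the domain rather than aligning it to its
reference region. Within the aligned columns, maximal positive-scoring
stretches of reference positions (Ruzzo–Tompa maximal scoring subsequences;
sequence insertions charge their gap penalty) are trimmed, and segments below
`min_segment_score` (default 12, ≈ 6 net matches) are discarded — this keeps
the ~5%-identity noise that any aligner drags along from registering as
coverage.

Coverage classes use coverage-extent rules with `T = floor(L·(1−tail_fraction))`
(tail_fraction default 0.25) and slack `s = max(2, 0.05·L)`:

| class | rule |
|---|---|
| `full` | covered fraction ≥ 0.9 |
| `none` | covered fraction < 0.2 |
| `cterm_only` | min covered position ≥ T − s |
| `cterm_missing` | max covered position < T − s |
| `cterm_partial` | otherwise |

Extent rules (rather than exact position-set tests) absorb the ±3-column
jitter local alignment shows at domain edges, and make the boundary case —
a domain body that stops exactly at the tail — classify as the C-terminally
incomplete (`cterm_partial`) form it represents.

The five-way type call is a decision list, first match wins:

1. DCX annotation + `cterm_only` → **apicortin** (partial p25alpha fused to
   a doublecortin domain; DCX presence is an input annotation, not computed —
   detecting it would be a profile-HMM problem outside this package's scope);
2. ≥ 2 Rossmann hits → **fungal_type** (full domain plus an extra C-tail copy);
3. 1 Rossmann + `full` → **long** (animal-type);
4. 0 Rossmann + `cterm_partial` → **short**;
5. 0 Rossmann + N-terminal motif + `cterm_missing` → **truncated**;
6. no evidence at all → **none**; anything else → **ambiguous**.

`ambiguous` is deliberate: borderline evidence is surfaced, not forced into
a type.

## Best-hit incongruence screen

BLAST tabular rows (standard 12-column outfmt-6; `qcovs`/`ssciname` may be
appended, and query coverage can be computed from a query-length table as
`100·(qend−qstart+1)/qlen`). Per query the winner is the maximal bitscore,
ties broken by higher identity, then lexicographically smallest subject id.
A taxonomy map (species → group → category over
`{self_clade, fungi, oomycota, animal, protist, other}`; self clade default
Streptophyta) categorizes the subject; unmapped species fall to `other` with
a warning rather than aborting, because real tables contain species no map
knows.

Classification thresholds (percent, configurable):

* `self` — best hit inside the self clade;
* `evident_contamination` — identity ≥ 98 (an essentially identical foreign
  sequence; 98 rather than 100 because near-identity with a database relative
  of the true source is already conclusive);
* `likely_contamination` — identity **and** coverage strictly > 90;
* `candidate_foreign` — everything weaker, left to the tree stage.

The window screen expands flagged accessions to their ±w sequential
neighbors (default w = 5, an 11-wide window) under a shared
prefix + zero-padded-number scheme, and the tally report counts best hits
per category, the non-self dual-rule (> 90/> 90) set, the stricter > 97/> 97
subset, and the per-species breakdown within the dual set. In summaries the
animal/protist/other categories collapse into "other".

## Tree placement

Trees are read as written (an outgroup option reroots first); numeric
internal labels are supports, values > 1 are treated as percentages.
Maximal query-only clades are collapsed into single pseudo-leaves first, so
identical contaminants in several assemblies are judged as one unit. The
call inspects only the query's local neighborhood:

* sibling subtree pure in one foreign group G, and the grandparent's other
  side also contains G → **nested** in G;
* sibling pure G, no G above → **sister** to G;
* sibling already mixes ≥ 2 groups → **outside**;
* support at the decision (parent) node below `min_support` (default 0.5,
  the usual reporting floor for Bayesian posteriors; 0.95 gives a strict
  mode) → **unresolved**. Absent supports are not gated.

Polytomy siblings contribute the union of their groups (conservative:
pushes toward outside/unresolved). The verdict table combines placement with
the hit class — the logic being that a transfer old enough to be fixed in a
plant genome would have diverged, so high identity favors contamination:

| placement \ hit class | evident/likely | candidate |
|---|---|---|
| nested | contamination | contamination_or_hgt |
| sister | contamination | unresolved |
| outside | contamination_or_hgt (conflict flagged) | putative_ortholog |
| unresolved | unresolved | unresolved |

For totality, a `self` best hit maps to `putative_ortholog` and a hitless
query to `unresolved` regardless of placement.

## Synthetic data

The generators replace database downloads with planted-truth inputs.

* **Proteins** (`gen_tppp_protein`): the type layouts are cut from the
  consensus — long = full consensus; fungal-type = consensus + a second copy
  of the C-terminal quarter (two Rossmanns); short = first 75%; truncated =
  first 60%; apicortin = last 25% with the DCX flag set. Padding is i.i.d.
  uniform over the 20 amino acids; accidental motif formation in padding is
  possible by design and measured, not suppressed — recovery tests compare
  against truth labels.
* **Transcriptomes** (`gen_contaminated_transcriptome`): uniform-composition
  random background transcripts (400–800 nt) plus contaminants
  back-translated with uniform synonymous codons on a random strand, all
  under sequential accession-style ids so the window screen applies.
  Translating the planted strand reproduces the planted protein exactly.
* **Best-hit tables** (`gen_blast_table`): per-class identity/coverage bands,
  by default evident ∈ [98, 100] × [60, 100], likely ∈ [90.6, 97.4] ×
  [90.6, 99], candidate ∈ [40, 75] × [40, 95] — mirroring the band structure
  of real screens and disjoint with respect to the default thresholds so
  recovery is exact; bands that straddle thresholds are recorded as warnings
  in the truth table. Subject species are drawn from a small pool of taxa
  that actually appear in published plant-assembly contamination screens.
* **Trees** (`gen_placement_tree`): ≥ 2 pure-group clades with random
  topologies; the query is grafted constructively — strictly inside a pure
  clade (nested), on a pure clade's stem (sister), or above a multi-group
  subtree (outside) — with all supports 1.0. The generator never calls the
  classifier, so recovery tests are non-circular.

All generators are deterministic under their seed; changing the seed changes
residues/topologies but never planted labels.

What the synthetic data does **not** emulate: real codon usage and base
composition, assembly artifacts (chimeras, quality dropoff), E-value
structure, rate heterogeneity, or low-support tree regions. Passing recovery
tests therefore demonstrates the correctness of the decision logic under its
stated assumptions, not the sensitivity of the screen on real assemblies.

## Problem sizes and numerical choices

The bundled worked example is the 22-query window screen (two queries
hitless). Recovery checks run at: 50 seeds × 3 placement classes on 7-leaf
trees; 1000 random proteins (≤ 500 aa) for the scanner/oracle equivalence;
exhaustive subsets of random trees up to 8 leaves for monophyly; a
13-record transcriptome bundle for the end-to-end run. Ties are broken
deterministically everywhere (frame: low |frame|, forward first; best hit:
identity then subject id; collapse and traversal orders are fixed), so
identical configurations reproduce byte-identical reports.

## Known limitations

* A single best local alignment measures coverage; two domain fragments
  separated by a long unrelated insertion may register as one bridged
  segment or only the stronger fragment.
* Best-hit logic only (no LCA over multiple hits), matching the screening
  procedure this package implements.
* The nested/sister distinction uses parent + grandparent only; deeper
  foreign structure is ignored. A query sister to one phylum inside a larger
  multi-phylum arrangement is judged by the same local rule.
* The bundled reference consensus is synthetic; absolute coverage values on
  real sequences depend on the user-supplied consensus.
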