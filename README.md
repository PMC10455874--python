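# p25screen

Screening seed-plant transcriptome assemblies for p25alpha-domain sequences,
and deciding per sequence between **contamination**, **horizontal gene
transfer (HGT)**, and **genuine orthology**.

## The problem

The p25alpha domain of TPPP-like proteins (tubulin polymerization promoting
proteins) occurs in organisms possessing a eukaryotic flagellum/cilium —
animals, flagellated fungi, many protists. Seed plants lack cilia (cycads
and *Ginkgo* excepted), so a plant TSA/EST record encoding the domain is an
anomaly that needs an explanation. `p25screen` is for researchers curating
plant assemblies or re-using public transcriptome data: it finds such
records, types them, and classifies the most plausible explanation.

The screen has three evidence layers:

1. **Motif/architecture scan.** The domain is diagnosed by the Rossmann-like
   motif `GXGXGXXGR` at its conserved C-terminus and the N-terminal
   signature `L(F)xxxFxxF(Y)xxF`, combined with coverage of a reference
   consensus under local alignment. Motif count × coverage class × an
   external DCX-domain annotation yields the five-way type call: *long*,
   *short*, *truncated*, *fungal-type* TPPP, or *apicortin*. Nucleotide
   input is scanned in all six reading frames.
2. **Best-hit incongruence screen.** From BLAST tabular output, the best hit
   per query (max bitscore) is categorized taxonomically. With identity *p*
   and query coverage *c* (percent): a self-clade hit is `self`;
   *p* ≥ 98 → `evident_contamination`; *p* > 90 **and** *c* > 90 →
   `likely_contamination`; else `candidate_foreign`. A window screen expands
   flagged accessions to their ±w sequential neighbors and tallies their
   best hits — the quick test for how contaminated an assembly is beyond the
   sequences that triggered the search.
3. **Tree placement.** In a support-annotated tree, a query (or collapsed
   query clade) is **nested** in a foreign group G, **sister** to it, or
   **outside** (its sibling subtree already mixes groups); decisions below a
   support floor are **unresolved**. Placement × hit class gives the verdict:
   nested/sister with high identity → contamination; nested with low
   identity → contamination-or-HGT; outside with low identity → putative
   ortholog; sister with low identity → unresolved.

A synthetic-data module generates planted-truth inputs for every stage
(typed proteins, contaminated mock transcriptomes, best-hit tables with
class-dependent identity/coverage bands, placement trees), so the whole
pipeline is testable offline. See `docs/methods.md` for the model details
and assumptions.

## Worked example

The package bundles a worked example: a window screen of 22 sequential
*Betula papyrifera* (paper birch) TSA accessions around known p25alpha hits,
with each accession's best protein hit, identity, coverage, and subject
taxonomy.

```python
from p25screen import (load_table2_fixture, best_hit_per_query,
                       screen_queries, tally_report)

queries, rows, tax = load_table2_fixture()
report = screen_queries(best_hit_per_query(rows), tax, all_queries=queries)
t = tally_report(report)
print(f"queries: {t.n_queries}  with hits: {t.n_with_hits}")
print(f"best-hit categories: {t.collapsed}")
print(f"dual rule (>90% identity and coverage, non-self): {t.dual_count}")
print(f"strict dual (>97%): {t.strong_dual_count}")
```

prints

```
queries: 22  with hits: 20
best-hit categories: {'self': 2, 'fungi': 12, 'oomycota': 3, 'other': 3}
dual rule (>90% identity and coverage, non-self): 6
strict dual (>97%): 4
```

Reading: of the 20 windowed accessions with a protein hit, only 2 have a
plant best hit; 12 are fungal, 3 oomycete, 3 other (protist/animal). Six
non-plant best hits exceed 90% in both identity and coverage (5 fungi, 1
oomycete) — near-identical foreign sequences in a birch assembly, i.e.
clear contamination — and 4 of them exceed 97%. Three of the six come from
the same ascomycete, *Dactylonectria macrodidyma*.

The same machinery is scriptable from the shell:

```sh
p25screen scan --in transcripts.fasta --dcx dcx.tsv          # type sequences
p25screen screen --blast hits.tsv --tax taxonomy.tsv          # classify best hits
p25screen window --accessions all.txt --flagged hits.txt --w 5
p25screen place --tree tree.nwk --groups groups.tsv --query-prefix PLANT_
p25screen simulate transcriptome --seed 7 --outdir sim/       # planted-truth data
p25screen run --fasta in.fasta --blast hits.tsv --tax tax.tsv ...
```

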