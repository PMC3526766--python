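# vhcrss

Cross-species analysis of the **3′ cryptic recombination signal sequence
(3′cRSS)** embedded near the end of germline immunoglobulin heavy-chain
variable (VH) genes.

## The scientific problem

VH replacement is a RAG-mediated secondary rearrangement in which an
upstream germline VH invades an already rearranged VHDJH exon. It requires
a heptamer-like cryptic RSS — canonically `TACTGTG` — embedded at the 3′
end of the rearranged V exon, overlapping codons 103–105 (IMGT numbering):
the invariant Cys104 `TGT` codon supplies the `GT` of the critical 3′
`GTG` core, and the following codon (usually a `GCN` alanine) supplies the
final `G`. The short stretch of nucleotides downstream of the heptamer can
survive replacement as a *footprint*, and because it is strongly A/G-rich
it tends to add charged (often positively charged, D/E/K/R/H with K/R/H
positive) residues to CDR3.

`vhcrss` implements this analysis as a reusable pipeline for curated
germline VH/DH gene sets of any jawed vertebrate:

1. **Anchoring** — locate Cys104 either exactly from an IMGT-gapped
   V-REGION (aligned nucleotide positions 310–312) or heuristically from
   the conserved (Y/F/W)-Y-C end of FR3.
2. **Heptamer scan** — extract the 7-mer at codons 103–105 and classify it
   as canonical (`TACTGTG`/`CACTGTG`), GTG-bearing (`NNNNGTG`, positions
   5–7 = `GTG`), or other; tally Cys104 `TGT` usage, residue-105 `GCN`
   usage, and GT retention among motif-violating heptamers.
3. **Footprint charge** — translate the post-heptamer nucleotides in three
   reading frames (offsets 2/0/1 nt; a 7-nt tetrapod footprint encodes
   1/2/2 residues, a 9-nt teleost one 2/3/2) and pool charged-residue
   frequencies against the random-codon baseline 14/64 ≈ 22% and a
   best-frame DH upper bound.
4. **Grouping** — aggregate heptamer frequencies per family and per
   cross-species clade group from a declarative YAML scheme, with an
   optional deterministic neighbor-joining guide tree on FR1–FR3
   alignments.
5. **Simulation** — a seeded generator emits synthetic repertoires with a
   known ground-truth ledger, so every stage is testable without any
   database download.

## Worked example

```bash
vhcrss simulate --seed 5 --out sim/
vhcrss scan -f sim/vh.fasta -a sim/vh_annotations.tsv \
       --gapped sim/vh.gapped.fasta -o out/
```

The simulate step reports the ledger summary:

```
simulated 96 countable VH genes (canonical 58, GTG 83, other 13) + 10 DH -> sim
```

and `out/family_summary.csv` ends with a totals row whose cells use the
`pct (n/N)` convention of published repertoire tables:

```
species,family,n_canonical,n_gtg,n_other,n_incomplete,n_total,pct_canonical,pct_gtg,pct_other
...
synthetic,Total,58,83,13,0,96,60.4 (58/96),86.5 (83/96),13.5 (13/96)
```

meaning 60.4% of the 96 functional genes carry a canonical heptamer and
86.5% carry the critical 3′ GTG — and, because detection is deterministic,
these counts equal the generator's ledger exactly. Adding
`vhcrss footprint ... --dh-fasta sim/dh.fasta` produces
`charge_summary.csv` with per-frame pooled charged frequencies (frame I
above 60% under the default A/G-rich footprint composition), the DH
best-frame upper bound, and the constant 14/64 baseline row.

The same analysis is available as a library:

```python
from vhcrss import GeneratorConfig, generate_repertoire, run_scan

rep, ledger = generate_repertoire(GeneratorConfig(seed=5))
scan = run_scan(rep)
print(scan.summary.tail(1))
```

## Scope

The package consumes already-annotated gene sets (FASTA plus a TSV of
species/family/functionality); it does not find V genes in genome
scaffolds, call functionality, or infer alleles, and it does not perform
Bayesian phylogenetics or multiple sequence alignment — clade groups come
from the declarative scheme, and alignments are consumed, never produced.
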