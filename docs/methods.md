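# Methods

## Coordinate conventions

All nucleotide intervals are 0-based and half-open; codon index `c` covers
nucleotides `[3c, 3c+3)`. IMGT codon numbers are 1-based, so in a gap-free
IMGT-gapped V-REGION the 2nd-CYS (Cys104) occupies aligned nucleotide
positions 310–312 (1-based) and maps to ungapped codon index 103. IMGT gap
runs come in codon multiples; a gapped record whose gaps before position
310 are not a multiple of three is reported as a low-confidence anchor
rather than silently rounded.

## Anchoring

Two anchoring routes exist because curated repertoires come in two shapes.
IMGT-gapped records give the Cys104 position exactly: count non-gap
characters before aligned position 310 and divide by three. Ungapped
records fall back to a heuristic: translate the natural frame (assumed to
start at nucleotide 0), take the 3′-most Cys codon within the final
`window_codons` codons (default 12 — generous cover for the FR3 end plus
the short 3′ tail), and mark the anchor confident only when the conserved
framework context is present (residue two positions upstream aromatic
Y/F/W, or the preceding residue Y). A codon containing `N` never matches
Cys. The window default and the confidence rule are package choices, not
field standards; both are configurable, and anchor provenance
(`IMGT_GAPPED` vs `HEURISTIC`, confident or not) is carried into all
outputs so heuristic calls can be audited.

## Heptamer extraction and classification

With Cys104 at codon index `c`, the candidate cryptic-RSS heptamer is
`seq[3(c−1) .. 3(c+1)+1)`: codons 103–104 plus the first nucleotide of
codon 105. Classification partitions complete calls into:

* `CANONICAL` — exactly `TACTGTG` or `CACTGTG` (reported as one column,
  with the two motifs also counted separately);
* `GTG_TYPE` — positions 5–7 equal `GTG`. Canonical heptamers satisfy this
  too, so the inclusive "NNNNGTG" count is always ≥ the canonical count;
* `OTHER` — everything else; `N` never matches a motif position.

Only this codon-anchored heptamer is scanned. `CAC`/`GTG` trinucleotides
elsewhere in the gene may act as cryptic signals in receptor revision, but
counting them is a different analysis and deliberately out of scope.
Incomplete calls (no anchor, or sequence truncated before codon 105's
first nucleotide) are excluded from every percentage denominator.

GT retention is tallied over `OTHER`-class heptamers only: positions 5–6
(the last two nucleotides of the Cys codon) equal to `GT`, i.e. the Cys
codon is `TGT` rather than `TGC`. Codon usage tallies count Cys104 = `TGT`
over all complete calls and residue-105 = `GC.` (alanine, any third base)
over calls whose full codon 105 exists.

## Footprint charge in three reading frames

The footprint is everything 3′ of the heptamer. Its first two nucleotides
complete codon 105 (the heptamer consumed one nucleotide of it); that
partial codon belongs to neither tally, which pins the frame offsets:

| frame | offset (nt) | residues on 7 nt | on 9 nt |
|-------|-------------|------------------|---------|
| I     | 2           | 1                | 2       |
| II    | 0           | 2                | 3       |
| III   | 1           | 2                | 2       |

Frame I is the natural continuation of the V reading frame; frames II and
III arise when a replacement event shifts the register. Only codons wholly
inside the footprint are translated. Stop codons render `*` and ambiguous
codons `X`; both count as non-charged residues in denominators — a
conservative choice (it can only deflate charged frequency) that is
configurable only by filtering footprints upstream. Charged residues are
{D, E, K, R, H} (14 of the 64 standard codons, hence the 14/64 ≈ 22%
random baseline), positive {K, R, H} (10 codons), negative {D, E}
(4 codons).

Aggregation across genes is residue-pooled by default: numerators and
denominators add, so summaries are invariant under reordering and under
splitting a scope into sub-scopes. Ratios reported as `n/N` over residues
(e.g. positive-among-charged tallies) are only meaningful under pooling,
which is why it is the default; a per-gene-mean mode is available behind
the `aggregation` flag for sensitivity checks. The two modes differ
whenever footprint lengths differ across genes.

For DH segments the statistic is per-gene best-frame: translate offsets
0/1/2 over complete codons, take the frame with the highest charged
fraction (ties break toward the lowest offset), then average over
functional genes. Because the maximizing frame is chosen per gene, this is
an upper bound on the charge DH segments actually contribute, and it is
labelled as such in outputs.

## Grouping and the guide tree

Clade-group membership is a declarative YAML mapping from
`species:family` pairs to group labels; a pair assigned to two groups is a
config error, and unmapped pairs are summarized under `unassigned` rather
than dropped. Group frequency tables therefore conserve the per-family
counts exactly. Tree inference plays no role in the frequency computation:
the optional guide tree exists for exploratory checks of a scheme against
sequence data. It is classical neighbor joining on pairwise p-distances
(mismatches over valid sites, sites with a gap or `N` in either sequence
excluded pairwise), with a lexicographic tie-break on taxon labels so the
Newick output is byte-stable, branch lengths clamped at zero on output,
and the standard three-point formulas closing the final trifurcation. On
an additive distance matrix the reconstruction is exact, which is the test
oracle; the implementation is cross-checked against an independent NJ
implementation on the same matrices.

## Percentage rendering

Published repertoire tables use `pct (n/N)` cells with one decimal,
half-up rounding, trailing `.0` trimmed (`100 (8/8)`, `86.9 (93/107)`),
and `-` for zero counts. `format_pct` reproduces this exactly, using
decimal arithmetic to avoid binary-float rounding artifacts at `.x5`
boundaries.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated. Each gene is built codon-wise: a sense-codon scaffold through
codon 102 (Cys-free, so the planted Cys104 is unambiguous), a Tyr codon at
position 102 (the conserved context the anchoring heuristic relies on),
codons 103–105 drawn from the configured class mix, and a footprint drawn
i.i.d. from the configured base weights. Classes are planted at the codon
level — canonical classes force `TAC`/`CAC` + `TGT` + `G…`; `GTG_TYPE`
draws a non-canonical codon 103 with `TGT` + `G…`; `OTHER` breaks the
motif structurally (a `TGT` Cys codon followed by a non-G nucleotide, or a
`TGC` Cys codon) — so detection must genuinely locate the heptamer.
Footprints whose natural-frame translation contains a Cys, or that would
make codon 105 a Cys or stop, are rejected and redrawn; this keeps every
gene anchorable by both routes and is the only rejection step.

Default parameters, chosen to emulate a mammalian (mouse-like) curated
repertoire: class mix 0.600/0.045/0.224/0.131
(canonical-TAC/canonical-CAC/GTG-type/other, putting the total GTG-bearing
fraction at 0.869), residue-105 alanine probability 0.82 (applied where
codon 105 starts with G; an `OTHER` gene with a retained-GT heptamer
cannot be Ala, so the realized marginal is slightly lower), Cys104 `TGT`
probability 0.55 where the class leaves it free (equivalently the
GT-retention rate among motif-violating heptamers — positions 5–6 *are*
the Cys codon's tail, so one knob covers both), footprint length 7
(tetrapod style; 9 for teleost style), and footprint base weights
A 0.50 / G 0.42 / C 0.04 / T 0.04. The footprint weights are deliberately
more A/G-rich than a casual reading of "A/G-rich" might suggest: under an
i.i.d. base model the expected per-codon charged fraction is ~0.65 at
these weights, which is what it takes to reproduce the >60% frame-I
charged frequency that curated repertoires exhibit. Real footprints
achieve that frequency at more moderate A+G content because their codon
usage is positionally structured (AGA/GAA-type codons in frame I); the
i.i.d. model trades that structure for a clean composition-fidelity
property. Passing tests on generated data therefore validate the
*detection and accounting* machinery exactly, and the charge statistics
distributionally — they do not certify behaviour on real repertoires with
positional codon structure, truncated records, or mis-annotated
functionality.

A `footprint_charged_codon_p` override plants whole frame-II (offset 0)
codons that are charged with a given probability, for parameter-recovery
studies; in that mode the residue-105 preference is overridden and the
ledger records what was actually drawn. DH segments are generated
analogously: frame-0 codons charged with probability
`dh_charged_codon_p` (default 0.15 — DH segments rarely encode charged
residues), lengths uniform on 9–24 nt, and the per-gene best-frame value
computed by exhaustive enumeration at generation time and stored in the
ledger.

Decoys are available for filter testing: `n_secondary_alleles` appends
`*02` duplicates and `n_pseudogenes` appends non-functional genes; both
are flagged `counted=False` in the ledger. Gapped output inserts gap runs
(0–2 codons by default) at aligned codon 32, inside the CDR1 region, so
gapped-anchor index arithmetic is exercised with true Cys104 indices of
101–103. All randomness flows through one `numpy` generator seeded from
the config; the per-gene draw order is documented in the generator and
treated as part of the output contract.

## Problem sizes

The validation suite runs the motif-scan oracle on 10,000 genes,
ledger-exactness scenarios of ~100–240 genes including a 107-gene
16-family mouse-shaped configuration, charge recovery on 2,000 genes per
planted fraction (6,000 frame-II residues each), and NJ exactness on 4–6
taxon additive matrices. These sizes put binomial standard errors near or
below one percentage point, which is tight enough to detect any systematic
accounting error while keeping the whole suite desk-scale.

## Known limitations

* The anchoring heuristic assumes the sequence is in-frame from its first
  nucleotide; 5′-truncated records that break frame will anchor wrongly or
  not at all (they surface as non-confident or incomplete).
* Heptamer classification is exact-match; degenerate bases never match, so
  low-quality sequences inflate the `OTHER` class rather than being
  flagged separately.
* The generator does not model sequence evolution (substitutions or
  indels along a phylogeny) or V(D)J rearrangement itself; the guide tree
  on generated data is therefore not a meaningful phylogeny, and group
  assignments in tests are arbitrary labels.
* p-distance NJ is a guide, not an inference method; for publication-grade
  phylogenies use a dedicated tool and import the grouping as config.
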