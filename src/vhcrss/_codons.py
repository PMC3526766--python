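"""Codon-level helpers shared across the package.

Translation is table-driven from Biopython's standard genetic code rather
than Bio.Seq.translate, so that the handling of incomplete and ambiguous
codons is explicit: only complete codons are translated, stop codons render
``*``, and any codon containing a character outside {A,C,G,T} renders ``X``.
Both ``*`` and ``X`` count as (non-charged) residues in denominators.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stops as '*' (64 entries)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

CHARGED = frozenset("DEKRH")
POSITIVE = frozenset("KRH")
NEGATIVE = frozenset("DE")

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))
CHARGED_CODONS = tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] in CHARGED)
UNCHARGED_SENSE_CODONS = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in CHARGED
)


def translate_codon(codon: str) -> str:
    """Translate one complete codon; 'X' for anything ambiguous."""
    return CODON_TO_AA.get(codon, "X")


def translate_frame(seq: str, offset: int) -> str:
    """Translate the complete codons of ``seq`` starting at ``offset`` nt.

    Trailing nucleotides that do not fill a codon are ignored.
    """
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    n_codons = max(0, (len(seq) - offset)) // 3
    return "".join(
        translate_codon(seq[offset + 3 * i : offset + 3 * i + 3])
        for i in range(n_codons)
    )


def charged_codon_census(aa_set: frozenset[str] = CHARGED) -> int:
    """Number of the 64 standard codons whose product lies in ``aa_set``.

    With the default charged set {D,E,K,R,H} this is 14, the random
    baseline (14/64 ~ 22%) against which footprint charge is compared.
    """
    return sum(1 for aa in CODON_TO_AA.values() if aa in aa_set)
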