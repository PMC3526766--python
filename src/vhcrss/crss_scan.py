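"""Extraction and classification of the embedded 3'cRSS heptamer.

The candidate cryptic recombination signal is the 7-mer spanning codons
103-104 plus the first nucleotide of codon 105: the Cys104 TGT codon
supplies the GT of the critical 3' GTG core and the following codon
(usually a GCN alanine) supplies the final G. Heptamers are partitioned
into three classes:

* ``CANONICAL`` — exactly TACTGTG or CACTGTG;
* ``GTG_TYPE``  — positions 5-7 equal GTG (the "NNNNGTG" column; canonical
  heptamers satisfy this too, so per-family GTG counts include them);
* ``OTHER``     — everything else.

Calls that cannot be made because the anchor is missing or the sequence is
too short are ``INCOMPLETE`` and excluded from percentage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .anchoring import AnchorResult
from .repertoire_io import VhGene

CANONICAL_HEPTAMERS = ("TACTGTG", "CACTGTG")


class HeptamerClass(str, Enum):
    CANONICAL = "CANONICAL"
    GTG_TYPE = "GTG_TYPE"
    OTHER = "OTHER"
    INCOMPLETE = "INCOMPLETE"


@dataclass(frozen=True)
class HeptamerCall:
    """The located heptamer of one gene plus codon-usage facts."""

    gene_id: str
    heptamer: Optional[str]
    klass: HeptamerClass
    gt_retained: bool
    cys104_codon: Optional[str] = None
    residue105_first_nt: Optional[str] = None
    residue105_codon: Optional[str] = None
    residue105_is_ala: bool = False
    cys104_codon_index: Optional[int] = None
    note: str = ""

    @property
    def is_complete(self) -> bool:
        return self.klass is not HeptamerClass.INCOMPLETE

    @property
    def is_gtg(self) -> bool:
        """True for the inclusive NNNNGTG column (canonical included)."""
        return self.klass in (HeptamerClass.CANONICAL, HeptamerClass.GTG_TYPE)


def classify_heptamer(heptamer: str) -> HeptamerClass:
    """Classify a 7-nt heptamer; N never matches the motif tests."""
    if len(heptamer) != 7:
        raise ValueError(f"heptamer must be 7 nt, got {len(heptamer)}")
    if heptamer in CANONICAL_HEPTAMERS:
        return HeptamerClass.CANONICAL
    if heptamer[4:7] == "GTG":
        return HeptamerClass.GTG_TYPE
    return HeptamerClass.OTHER


def extract_heptamer(gene: VhGene, anchor: AnchorResult) -> HeptamerCall:
    """Slice and classify the codon-103..105 heptamer around the anchor.

    With Cys104 at codon index ``c``, the heptamer is
    ``seq[3(c-1) : 3(c+1)+1)`` — six nucleotides of codons 103-104 plus the
    first nucleotide of codon 105. Bounds failures yield INCOMPLETE.
    """
    if not anchor.found:
        return HeptamerCall(
            gene.gene_id, None, HeptamerClass.INCOMPLETE, False,
            note=f"no anchor: {anchor.note}",
        )
    c = anchor.cys104_codon_index
    seq = gene.seq_nt
    start, end = 3 * (c - 1), 3 * (c + 1) + 1
    if c < 1 or end > len(seq):
        return HeptamerCall(
            gene.gene_id, None, HeptamerClass.INCOMPLETE, False,
            note="sequence too short for codons 103-105 around anchor",
        )
    heptamer = seq[start:end]
    res105_codon = seq[3 * (c + 1) : 3 * (c + 2)]
    res105_full = res105_codon if len(res105_codon) == 3 else None
    return HeptamerCall(
        gene_id=gene.gene_id,
        heptamer=heptamer,
        klass=classify_heptamer(heptamer),
        gt_retained=heptamer[4:6] == "GT",
        cys104_codon=seq[3 * c : 3 * c + 3],
        residue105_first_nt=heptamer[6],
        residue105_codon=res105_full,
        residue105_is_ala=res105_full is not None
        and res105_full.startswith("GC"),
        cys104_codon_index=c,
    )


def gt_retention_stat(calls: Iterable[HeptamerCall]) -> tuple[int, int]:
    """Among OTHER-class heptamers, how many retain GT at positions 5-6.

    Returns (numerator, denominator); (0, 0) when no OTHER calls exist.
    """
    others = [c for c in calls if c.klass is HeptamerClass.OTHER]
    return sum(1 for c in others if c.gt_retained), len(others)


def codon_usage(calls: Iterable[HeptamerCall]) -> dict[str, tuple[int, int]]:
    """Per-repertoire codon-usage tallies behind the heptamer.

    ``cys104_TGT``: Cys104 codon is TGT (vs TGC) among complete calls.
    ``residue105_GCN``: the codon after Cys104 encodes Ala (GC-anything),
    counted only over genes whose full codon 105 is available.
    """
    complete = [c for c in calls if c.is_complete]
    tgt_n = sum(1 for c in complete if c.cys104_codon == "TGT")
    with_105 = [c for c in complete if c.residue105_codon is not None]
    gcn_n = sum(1 for c in with_105 if c.residue105_is_ala)
    return {
        "cys104_TGT": (tgt_n, len(complete)),
        "residue105_GCN": (gcn_n, len(with_105)),
    }


def format_pct(n: int, total: int) -> str:
    """Render ``pct (n/N)`` in the published table style.

    One decimal place, round half up, trailing ``.0`` trimmed; zero counts
    render as ``-``: 93/107 -> ``86.9 (93/107)``, 8/8 -> ``100 (8/8)``.
    """
    if total == 0 or n == 0:
        return "-"
    pct = Decimal(100 * n) / Decimal(total)
    s = str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    if s.endswith(".0"):
        s = s[:-2]
    return f"{s} ({n}/{total})"


def scan_calls(
    calls: Sequence[HeptamerCall],
) -> dict[str, int]:
    """Class tallies over a set of calls (complete calls only for n_*)."""
    complete = [c for c in calls if c.is_complete]
    return {
        "n_canonical": sum(
            1 for c in complete if c.klass is HeptamerClass.CANONICAL
        ),
        "n_gtg": sum(1 for c in complete if c.is_gtg),
        "n_other": sum(
            1 for c in complete if c.klass is HeptamerClass.OTHER
        ),
        "n_incomplete": len(calls) - len(complete),
        "n_total": len(complete),
    }


def family_summary(
    genes: Sequence[VhGene], calls: Sequence[HeptamerCall]
) -> pd.DataFrame:
    """Per-family heptamer-class table with a Total row per species.

    Columns mirror the published layout: canonical (TACTGTG/CACTGTG,
    inclusive of both), the inclusive NNNNGTG column, and Others, each as a
    count and a ``pct (n/N)`` string.
    """
    if len(genes) != len(calls):
        raise ValueError("genes and calls must be parallel sequences")
    by_key: dict[tuple[str, str], list[HeptamerCall]] = {}
    order: list[tuple[str, str]] = []
    for g, c in zip(genes, calls):
        key = (g.species, g.family)
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(c)

    rows = []
    for species, fam in order:
        tallies = scan_calls(by_key[(species, fam)])
        rows.append({"species": species, "family": fam, **tallies})
    df = pd.DataFrame(
        rows,
        columns=["species", "family", "n_canonical", "n_gtg", "n_other",
                 "n_incomplete", "n_total"],
    )

    totals = []
    for species in df["species"].unique():
        sub = df[df["species"] == species]
        totals.append(
            {
                "species": species,
                "family": "Total",
                **{
                    c: int(sub[c].sum())
                    for c in ["n_canonical", "n_gtg", "n_other",
                              "n_incomplete", "n_total"]
                },
            }
        )
    df = pd.concat([df, pd.DataFrame(totals)], ignore_index=True)

    df["pct_canonical"] = [
        format_pct(n, t) for n, t in zip(df["n_canonical"], df["n_total"])
    ]
    df["pct_gtg"] = [
        format_pct(n, t) for n, t in zip(df["n_gtg"], df["n_total"])
    ]
    df["pct_other"] = [
        format_pct(n, t) for n, t in zip(df["n_other"], df["n_total"])
    ]
    return df


def calls_to_frame(calls: Iterable[HeptamerCall]) -> pd.DataFrame:
    """One row per gene, suitable for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "heptamer": c.heptamer or "",
                "class": c.klass.value,
                "gt_retained": c.gt_retained,
                "cys104_codon": c.cys104_codon or "",
                "residue105_codon": c.residue105_codon or "",
                "residue105_is_ala": c.residue105_is_ala,
                "note": c.note,
            }
            for c in calls
        ]
    )
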