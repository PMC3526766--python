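"""Locating the 2nd-CYS (Cys104, IMGT numbering) anchor in VH genes.

Everything downstream — the embedded heptamer at codons 103-105 and the
footprint 3' of it — is defined relative to the conserved cysteine at IMGT
position 104, which closes framework region 3 and forms the intradomain
disulfide bond. Two strategies are provided:

* ``anchor_from_gapped`` reads the position straight off an IMGT-gapped
  V-REGION, where codon 104 occupies aligned nucleotide positions 310-312
  (1-based).
* ``anchor_heuristic`` is a fallback for ungapped sequences: it translates
  the natural frame and picks the 3'-most Cys in a trailing window,
  using the conserved (Y/F/W)-x-C / Y-C context of the FR3 end as a
  confidence signal.

Coordinate convention used package-wide: 0-based, half-open nucleotide
intervals; codon index ``c`` covers nucleotides ``[3c, 3c+3)``. IMGT codon
numbers are 1-based, so gap-free codon 104 has codon index 103.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from ._codons import translate_codon
from .repertoire_io import VhGene

#: 1-based aligned nucleotide positions of codon 104 in an IMGT-gapped V-REGION
CYS104_ALIGNED_START = 310
CYS104_ALIGNED_END = 312

AROMATIC = frozenset("YFW")


class AnchorMethod(str, Enum):
    IMGT_GAPPED = "IMGT_GAPPED"
    HEURISTIC = "HEURISTIC"


@dataclass(frozen=True)
class AnchorResult:
    """Location of the Cys104 codon in a gene's ungapped sequence."""

    gene_id: str
    cys104_codon_index: Optional[int]
    method: AnchorMethod
    confident: bool
    note: str = ""

    @property
    def found(self) -> bool:
        return self.cys104_codon_index is not None


def anchor_from_gapped(gene: VhGene) -> AnchorResult:
    """Map IMGT-aligned codon 104 to an ungapped codon index.

    Returns an absent, non-confident anchor if the gapped form is truncated
    before aligned position 312 or if codon 104 contains gap characters.
    """
    if gene.gapped_nt is None:
        raise ValueError(f"{gene.gene_id}: no gapped sequence available")
    g = gene.gapped_nt
    lo, hi = CYS104_ALIGNED_START - 1, CYS104_ALIGNED_END  # 0-based half-open
    if len(g) < hi:
        return AnchorResult(
            gene.gene_id, None, AnchorMethod.IMGT_GAPPED, False,
            f"gapped sequence truncated at {len(g)} < {hi} aligned positions",
        )
    codon104_aligned = g[lo:hi]
    if "." in codon104_aligned:
        return AnchorResult(
            gene.gene_id, None, AnchorMethod.IMGT_GAPPED, False,
            "aligned codon 104 contains gap characters",
        )
    n_before = sum(1 for ch in g[:lo] if ch != ".")
    if n_before % 3 != 0:
        return AnchorResult(
            gene.gene_id, None, AnchorMethod.IMGT_GAPPED, False,
            "gaps before codon 104 are not codon-aligned",
        )
    idx = n_before // 3
    codon = gene.seq_nt[3 * idx : 3 * idx + 3]
    if translate_codon(codon) != "C":
        return AnchorResult(
            gene.gene_id, idx, AnchorMethod.IMGT_GAPPED, False,
            f"codon at IMGT position 104 is {codon!r}, not cysteine",
        )
    return AnchorResult(gene.gene_id, idx, AnchorMethod.IMGT_GAPPED, True)


def anchor_heuristic(gene: VhGene, window_codons: int = 12) -> AnchorResult:
    """Pick the 3'-most Cys codon within the final ``window_codons`` codons.

    The sequence is assumed in-frame from its first nucleotide. Confidence
    requires the conserved FR3 context: the residue two codons upstream is
    aromatic (Y/F/W) or the immediately preceding residue is Y. A codon
    containing N is never a Cys match.
    """
    n_codons = len(gene.seq_nt) // 3
    if n_codons == 0:
        return AnchorResult(
            gene.gene_id, None, AnchorMethod.HEURISTIC, False,
            "sequence shorter than one codon",
        )
    start = max(0, n_codons - window_codons)
    cys_idx: Optional[int] = None
    for c in range(start, n_codons):
        if translate_codon(gene.seq_nt[3 * c : 3 * c + 3]) == "C":
            cys_idx = c  # keep scanning: 3'-most wins
    if cys_idx is None:
        return AnchorResult(
            gene.gene_id, None, AnchorMethod.HEURISTIC, False,
            f"no Cys codon in final {window_codons} codons",
        )

    def _aa(c: int) -> str:
        if c < 0:
            return ""
        return translate_codon(gene.seq_nt[3 * c : 3 * c + 3])

    confident = _aa(cys_idx - 2) in AROMATIC or _aa(cys_idx - 1) == "Y"
    note = "" if confident else "FR3 aromatic context not found"
    return AnchorResult(
        gene.gene_id, cys_idx, AnchorMethod.HEURISTIC, confident, note
    )


def anchor_gene(gene: VhGene, window_codons: int = 12) -> AnchorResult:
    """Gapped anchoring when available, heuristic otherwise."""
    if gene.gapped_nt is not None:
        res = anchor_from_gapped(gene)
        if res.found and res.confident:
            return res
    return anchor_heuristic(gene, window_codons=window_codons)


def anchors_to_frame(results: Iterable[AnchorResult]) -> pd.DataFrame:
    """Tabulate anchor results (gene_id, index, method, confident, note)."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "cys104_codon_index": r.cys104_codon_index,
                "method": r.method.value,
                "confident": r.confident,
                "note": r.note,
            }
            for r in results
        ],
        columns=["gene_id", "cys104_codon_index", "method", "confident", "note"],
    )
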