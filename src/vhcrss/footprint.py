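"""Charge analysis of the nucleotides 3' of the embedded heptamer.

After a VH replacement event the recipient gene can leave the short
stretch downstream of its 3'cRSS behind in the product ("footprint"),
contributing residues to CDR3. This module extracts that stretch from
germline genes, translates it in the three reading frames a footprint can
adopt, and tallies charged amino-acid content; a parallel best-frame
statistic is computed for germline DH segments as the comparison baseline.

Frame convention (offsets in nucleotides from the footprint start):

* frame I   — offset 2: the natural continuation of the V reading frame.
  The heptamer consumed one nucleotide of codon 105, so the first two
  footprint nucleotides complete that codon; the partial codon belongs to
  neither tally and only codons wholly inside the footprint are scored.
* frame II  — offset 0;
* frame III — offset 1.

A 7-nt footprint (typical of tetrapods) therefore encodes (1, 2, 2)
residues in frames I/II/III and a 9-nt one (typical of teleosts) (2, 3, 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from ._codons import (
    CHARGED,
    NEGATIVE,
    POSITIVE,
    charged_codon_census,
    translate_frame,
)
from .crss_scan import HeptamerCall
from .repertoire_io import DhGene, VhGene

FRAME_OFFSETS: dict[str, int] = {"I": 2, "II": 0, "III": 1}

#: The random-expectation baseline: 14 of the 64 codons encode D/E/K/R/H.
RANDOM_CHARGED_FRACTION = charged_codon_census() / 64.0


@dataclass(frozen=True)
class FrameReading:
    """Translation of one reading frame of a footprint."""

    label: str
    offset: int
    peptide: str

    @property
    def n_residues(self) -> int:
        return len(self.peptide)

    @property
    def n_positive(self) -> int:
        return sum(1 for aa in self.peptide if aa in POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for aa in self.peptide if aa in NEGATIVE)

    @property
    def n_charged(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class Footprint:
    """The nucleotides 3' of a gene's heptamer with per-frame readings."""

    gene_id: str
    seq: str
    frames: tuple[FrameReading, ...] = ()

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def frame(self, label: str) -> FrameReading:
        for fr in self.frames:
            if fr.label == label:
                return fr
        raise KeyError(label)


@dataclass(frozen=True)
class ChargeSummary:
    """Pooled charged-residue tallies for one scope (species/group/frame)."""

    scope: str
    frame_label: str
    n_charged: int
    n_positive: int
    n_negative: int
    n_total: int

    @property
    def frequency(self) -> Optional[float]:
        return self.n_charged / self.n_total if self.n_total else None

    @property
    def positive_fraction(self) -> Optional[float]:
        """Positively charged share among charged residues."""
        return self.n_positive / self.n_charged if self.n_charged else None


def extract_footprint(gene: VhGene, call: HeptamerCall) -> Footprint:
    """Everything after the heptamer's last nucleotide (may be empty).

    With Cys104 at codon index ``c`` the heptamer ends at nucleotide
    ``3(c+1)+1``, so the footprint is ``seq[3(c+1)+1:]``.
    """
    if not call.is_complete or call.cys104_codon_index is None:
        raise ValueError(
            f"{gene.gene_id}: cannot extract footprint from incomplete call"
        )
    start = 3 * (call.cys104_codon_index + 1) + 1
    if gene.seq_nt[start - 7 : start] != call.heptamer:
        raise ValueError(
            f"{gene.gene_id}: heptamer call does not match sequence"
        )
    return Footprint(gene_id=gene.gene_id, seq=gene.seq_nt[start:])


def translate_frames(fp: Footprint) -> Footprint:
    """Populate the three frame readings (complete codons only).

    Stop codons render ``*`` and ambiguous codons ``X``; both count as
    non-charged residues in denominators.
    """
    frames = tuple(
        FrameReading(label, off, translate_frame(fp.seq, off))
        for label, off in FRAME_OFFSETS.items()
    )
    return Footprint(gene_id=fp.gene_id, seq=fp.seq, frames=frames)


def pool_charge(
    footprints: Iterable[Footprint],
    frame_label: str,
    scope: str = "all",
) -> ChargeSummary:
    """Residue-pooled charge tally for one frame across many genes.

    Numerators and denominators add across genes, so the summary is
    invariant under reordering and under splitting/recombining scopes.
    """
    n_pos = n_neg = n_tot = 0
    for fp in footprints:
        fr = fp.frame(frame_label)
        n_pos += fr.n_positive
        n_neg += fr.n_negative
        n_tot += fr.n_residues
    return ChargeSummary(
        scope=scope,
        frame_label=frame_label,
        n_charged=n_pos + n_neg,
        n_positive=n_pos,
        n_negative=n_neg,
        n_total=n_tot,
    )


def mean_charge(
    footprints: Sequence[Footprint], frame_label: str, scope: str = "all"
) -> Optional[float]:
    """Per-gene-mean alternative: average of per-gene charged fractions."""
    fracs = []
    for fp in footprints:
        fr = fp.frame(frame_label)
        if fr.n_residues:
            fracs.append(fr.n_charged / fr.n_residues)
    return sum(fracs) / len(fracs) if fracs else None


def charge_frequency(
    footprints: Sequence[Footprint],
    frame_label: str,
    aggregation: Literal["pooled", "mean"] = "pooled",
    scope: str = "all",
) -> Optional[float]:
    """Charged-residue frequency under the chosen aggregation mode."""
    if aggregation == "pooled":
        return pool_charge(footprints, frame_label, scope).frequency
    if aggregation == "mean":
        return mean_charge(footprints, frame_label, scope)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def dh_best_frame_charged(dh: DhGene) -> Optional[float]:
    """Max-over-frames charged fraction for one DH gene.

    All three offsets (0, 1, 2) are translated over complete codons; the
    frame with the highest charged fraction is returned (ties break toward
    the lowest offset). None when no frame yields a residue. Because the
    best frame is chosen per gene, species averages of this statistic are
    an upper bound on the charge DH genes actually contribute.
    """
    best: Optional[float] = None
    for off in (0, 1, 2):
        pep = translate_frame(dh.seq_nt, off)
        if not pep:
            continue
        frac = sum(1 for aa in pep if aa in CHARGED) / len(pep)
        if best is None or frac > best:
            best = frac
    return best


def dh_species_mean(dh_genes: Sequence[DhGene]) -> Optional[float]:
    """Arithmetic mean of the per-gene best-frame fraction (upper bound)."""
    vals = [
        v for v in (dh_best_frame_charged(d) for d in dh_genes if d.functional)
        if v is not None
    ]
    return sum(vals) / len(vals) if vals else None


def footprints_to_frame(footprints: Iterable[Footprint]) -> pd.DataFrame:
    """Per-gene footprint table (one row per gene, frames as columns)."""
    rows = []
    for fp in footprints:
        row: dict[str, object] = {
            "gene_id": fp.gene_id,
            "footprint": fp.seq,
            "length_nt": fp.length_nt,
        }
        for fr in fp.frames:
            row[f"frame_{fr.label}_peptide"] = fr.peptide
            row[f"frame_{fr.label}_n_charged"] = fr.n_charged
            row[f"frame_{fr.label}_n_positive"] = fr.n_positive
            row[f"frame_{fr.label}_n_residues"] = fr.n_residues
        rows.append(row)
    return pd.DataFrame(rows)


def charge_summary_table(
    footprints: Sequence[Footprint],
    dh_genes: Sequence[DhGene] = (),
    scope: str = "all",
    aggregation: Literal["pooled", "mean"] = "pooled",
) -> pd.DataFrame:
    """Per-frame charged frequencies plus DH and random-baseline rows."""
    rows = []
    for label in FRAME_OFFSETS:
        summ = pool_charge(footprints, label, scope)
        freq = charge_frequency(footprints, label, aggregation, scope)
        rows.append(
            {
                "scope": scope,
                "frame": label,
                "n_charged": summ.n_charged,
                "n_positive": summ.n_positive,
                "n_total": summ.n_total,
                "charged_frequency": freq,
                "positive_fraction": summ.positive_fraction,
            }
        )
    if dh_genes:
        rows.append(
            {
                "scope": scope,
                "frame": "DH_best(upper bound)",
                "n_charged": None,
                "n_positive": None,
                "n_total": len(dh_genes),
                "charged_frequency": dh_species_mean(dh_genes),
                "positive_fraction": None,
            }
        )
    rows.append(
        {
            "scope": scope,
            "frame": "random_baseline",
            "n_charged": charged_codon_census(),
            "n_positive": None,
            "n_total": 64,
            "charged_frequency": RANDOM_CHARGED_FRACTION,
            "positive_fraction": None,
        }
    )
    return pd.DataFrame(rows)
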