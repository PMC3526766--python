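"""Reading, validating, filtering and writing germline VH/DH repertoires.

A repertoire is a FASTA file of nucleotide sequences plus a sidecar
annotation TSV (columns ``gene_id, species, family, functional, source``).
FASTA headers carry only the gene identifier; the richer metadata —
family labels like ``IGHV1 (J558)``, functionality calls — lives in the
table. An optional sibling FASTA holds IMGT-gapped forms of the same
sequences (gap character ``.``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_NT = frozenset("ACGTN")
_VALID_GAPPED = frozenset("ACGTN.")

ANNOTATION_COLUMNS = ["gene_id", "species", "family", "functional", "source"]


class RepertoireError(ValueError):
    """Raised for malformed or inconsistent repertoire inputs."""


def normalize_nt(raw: str, allow_gaps: bool = False) -> str:
    """Upper-case, U->T, '-'->'.'; reject anything outside {A,C,G,T,N[,.]}.

    Idempotent: normalizing twice equals normalizing once.
    """
    s = raw.strip().upper().replace("U", "T").replace("-", ".")
    valid = _VALID_GAPPED if allow_gaps else _VALID_NT
    bad = set(s) - valid
    if bad:
        raise RepertoireError(
            f"invalid nucleotide character(s) {sorted(bad)} in sequence"
        )
    if not allow_gaps and not s:
        raise RepertoireError("empty sequence")
    return s


@dataclass(frozen=True)
class VhGene:
    """One germline VH gene with its annotation.

    ``seq_nt`` is the ungapped coding nucleotide sequence, assumed in-frame
    from its first nucleotide. ``gapped_nt``, when present, is the
    IMGT-gapped V-REGION form and must equal ``seq_nt`` after gap removal.
    """

    gene_id: str
    species: str
    family: str
    functional: bool
    seq_nt: str
    gapped_nt: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_nt", normalize_nt(self.seq_nt))
        if self.gapped_nt is not None:
            g = normalize_nt(self.gapped_nt, allow_gaps=True)
            object.__setattr__(self, "gapped_nt", g)
            if g.replace(".", "") != self.seq_nt:
                raise RepertoireError(
                    f"{self.gene_id}: gapped form does not match ungapped "
                    "sequence after gap removal"
                )

    @property
    def allele(self) -> Optional[str]:
        """Allele suffix after the last '*', or None if the ID carries none."""
        _, star, suffix = self.gene_id.rpartition("*")
        return suffix if star else None


@dataclass(frozen=True)
class DhGene:
    """One germline DH (diversity) gene segment."""

    gene_id: str
    species: str
    functional: bool
    seq_nt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq_nt", normalize_nt(self.seq_nt))


@dataclass
class Repertoire:
    """Ordered collection of VH (and optionally DH) genes of one species."""

    species: str
    genes: list[VhGene] = field(default_factory=list)
    dh_genes: list[DhGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RepertoireError(f"duplicate gene_id(s): {sorted(dupes)}")
        off = [g.gene_id for g in self.genes if g.species != self.species]
        if off:
            raise RepertoireError(
                f"genes with species != {self.species!r}: {off}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise RepertoireError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def read_annotations(path: Path) -> pd.DataFrame:
    """Read the annotation TSV, validating the header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise RepertoireError(f"{path}: missing column(s) {missing}")
    if "source" not in df.columns:
        df["source"] = ""
    bad = df.loc[~df["functional"].str.lower().isin(["true", "false"]), "gene_id"]
    if len(bad):
        raise RepertoireError(
            f"{path}: functional must be true/false; bad rows: {list(bad)}"
        )
    df["functional"] = df["functional"].str.lower() == "true"
    return df


def read_repertoire(
    fasta_path: str | Path,
    annotations_path: str | Path,
    gapped_fasta_path: str | Path | None = None,
    dh_fasta_path: str | Path | None = None,
    dh_annotations_path: str | Path | None = None,
) -> Repertoire:
    """Assemble a :class:`Repertoire` from FASTA + annotation TSV.

    Every FASTA record must have an annotation row and vice versa; orphans
    on either side raise :class:`RepertoireError` listing the IDs.
    """
    seqs = _read_fasta(Path(fasta_path))
    ann = read_annotations(Path(annotations_path))
    gapped = _read_fasta(Path(gapped_fasta_path)) if gapped_fasta_path else {}

    fasta_ids = set(seqs)
    table_ids = set(ann["gene_id"])
    orphan_fa = sorted(fasta_ids - table_ids)
    orphan_tab = sorted(table_ids - fasta_ids)
    if orphan_fa or orphan_tab:
        raise RepertoireError(
            "annotation/sequence mismatch: "
            f"FASTA-only IDs {orphan_fa}; table-only IDs {orphan_tab}"
        )

    species = ann["species"].iloc[0] if len(ann) else "unknown"
    genes = [
        VhGene(
            gene_id=row.gene_id,
            species=row.species,
            family=row.family,
            functional=bool(row.functional),
            seq_nt=seqs[row.gene_id],
            gapped_nt=gapped.get(row.gene_id),
            source=row.source,
        )
        for row in ann.itertuples()
    ]

    dh_genes: list[DhGene] = []
    if dh_fasta_path is not None:
        dh_seqs = _read_fasta(Path(dh_fasta_path))
        if dh_annotations_path is not None:
            dh_ann = read_annotations(Path(dh_annotations_path))
            dh_genes = [
                DhGene(row.gene_id, row.species, bool(row.functional),
                       dh_seqs[row.gene_id])
                for row in dh_ann.itertuples()
            ]
        else:
            dh_genes = [
                DhGene(gid, species, True, s) for gid, s in dh_seqs.items()
            ]

    return Repertoire(species=species, genes=genes, dh_genes=dh_genes)


def filter_functional_allele01(rep: Repertoire) -> Repertoire:
    """Keep functional genes whose allele suffix is absent or ``01``.

    Mirrors the repertoire-curation rule used for heptamer counting: only
    functional genes enter the denominators, and where a gene has several
    alleles only the *01 allele represents it. Order-preserving and
    idempotent.
    """
    kept = [
        g for g in rep.genes
        if g.functional and (g.allele is None or g.allele == "01")
    ]
    dh_kept = [d for d in rep.dh_genes if d.functional]
    return Repertoire(species=rep.species, genes=kept, dh_genes=dh_kept)


def write_repertoire(
    rep: Repertoire,
    fasta_path: str | Path,
    annotations_path: str | Path,
    gapped_fasta_path: str | Path | None = None,
    dh_fasta_path: str | Path | None = None,
    dh_annotations_path: str | Path | None = None,
) -> None:
    """Write a repertoire so that :func:`read_repertoire` round-trips it."""
    fasta_path = Path(fasta_path)
    records = [
        SeqRecord(Seq(g.seq_nt), id=g.gene_id, description="")
        for g in rep.genes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    rows = [
        {
            "gene_id": g.gene_id,
            "species": g.species,
            "family": g.family,
            "functional": str(g.functional).lower(),
            "source": g.source,
        }
        for g in rep.genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        annotations_path, sep="\t", index=False
    )

    gapped_genes = [g for g in rep.genes if g.gapped_nt is not None]
    if gapped_fasta_path is None and gapped_genes:
        gapped_fasta_path = fasta_path.with_name(
            fasta_path.stem + ".gapped" + fasta_path.suffix
        )
    if gapped_fasta_path is not None:
        SeqIO.write(
            [SeqRecord(Seq(g.gapped_nt), id=g.gene_id, description="")
             for g in gapped_genes],
            str(gapped_fasta_path), "fasta",
        )

    if dh_fasta_path is not None:
        SeqIO.write(
            [SeqRecord(Seq(d.seq_nt), id=d.gene_id, description="")
             for d in rep.dh_genes],
            str(dh_fasta_path), "fasta",
        )
        if dh_annotations_path is not None:
            dh_rows = [
                {
                    "gene_id": d.gene_id,
                    "species": d.species,
                    "family": "DH",
                    "functional": str(d.functional).lower(),
                    "source": "",
                }
                for d in rep.dh_genes
            ]
            pd.DataFrame(dh_rows, columns=ANNOTATION_COLUMNS).to_csv(
                dh_annotations_path, sep="\t", index=False
            )
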