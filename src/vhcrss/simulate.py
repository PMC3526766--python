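"""Seeded synthetic germline VH/DH repertoires with a ground-truth ledger.

The generator emulates the statistical structure of curated germline VH
repertoires: an in-frame framework scaffold through codon 102 ending in
the conserved Tyr context, codons 103-105 drawn from a configurable mix
of heptamer classes (canonical TACTGTG/CACTGTG, non-canonical NNNNGTG,
or motif-violating "other"), a Cys104 codon (TGT/TGC) consistent with the
class, a residue-105 alanine (GCN) preference, and a short A/G-rich
footprint (7 nt tetrapod-style, 9 nt teleost-style) after the heptamer.
Classes are planted at the *codon* level, so the scanning pipeline must
genuinely find the heptamer rather than being handed it.

Default parameter values reflect the repertoire structure reported for
mammalian (mouse-like) germline sets: ~64.5% canonical and ~86.9%
GTG-bearing heptamers, ~82% Ala at residue 105, and a ~55% GT-retention
rate among motif-violating heptamers. Footprint bases are drawn i.i.d.
from a strongly A/G-rich distribution (A 0.50, G 0.42), under which the
expected per-codon charged fraction is ~0.65 — above the 60% frame-I
floor seen in curated repertoires; an i.i.d. model needs this much A/G
enrichment because it lacks the positional codon structure of real
footprints.

Every draw is recorded in a :class:`TruthLedger`, the oracle against
which pipeline output is checked exactly (detection is deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._codons import (
    CHARGED,
    CHARGED_CODONS,
    SENSE_CODONS,
    UNCHARGED_SENSE_CODONS,
    translate_codon,
    translate_frame,
)
from .repertoire_io import DhGene, Repertoire, VhGene

CLASSES = ("CANONICAL_TAC", "CANONICAL_CAC", "GTG_TYPE", "OTHER")

_TYR_CODONS = ("TAT", "TAC")
_SCAFFOLD_CODONS = tuple(c for c in SENSE_CODONS if translate_codon(c) != "C")
_BASES = ("A", "C", "G", "T")


class GeneratorConfigError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic repertoire generator.

    ``p_class`` gives the heptamer-class mix; ``p_cys_tgt`` is the
    probability that Cys104 uses TGT where the class leaves the choice
    free (the OTHER class) — since heptamer positions 5-6 are the last
    two nucleotides of the Cys codon, this doubles as the GT-retention
    probability among motif-violating heptamers. ``footprint_charged_codon_p``,
    when set, overrides the base-composition draw and plants frame-II
    (offset 0) codons that are charged with that probability — used for
    parameter-recovery studies.
    """

    seed: int = 0
    species: str = "synthetic"
    n_families: int = 8
    genes_per_family: int | Sequence[int] = 12
    p_class: dict[str, float] = field(
        default_factory=lambda: {
            "CANONICAL_TAC": 0.600,
            "CANONICAL_CAC": 0.045,
            "GTG_TYPE": 0.224,
            "OTHER": 0.131,
        }
    )
    p_cys_tgt: float = 0.55
    p_res105_ala: float = 0.82
    footprint_len: int = 7
    footprint_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.50, "G": 0.42, "C": 0.04, "T": 0.04}
    )
    footprint_charged_codon_p: Optional[float] = None
    fr_scaffold_len_codons: int = 105
    emit_gapped: bool = True
    gap_codons_range: tuple[int, int] = (0, 2)
    gap_at_codon: int = 32
    n_pseudogenes: int = 0
    n_secondary_alleles: int = 0
    dh_count: int = 10
    dh_len_range: tuple[int, int] = (9, 24)
    dh_charged_codon_p: float = 0.15

    def validate(self) -> None:
        if set(self.p_class) - set(CLASSES):
            raise GeneratorConfigError(
                f"unknown class keys {set(self.p_class) - set(CLASSES)}"
            )
        total = sum(self.p_class.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise GeneratorConfigError(f"p_class sums to {total}, not 1")
        wtot = sum(self.footprint_base_weights.get(b, 0.0) for b in _BASES)
        if not math.isclose(wtot, 1.0, abs_tol=1e-9):
            raise GeneratorConfigError(
                f"footprint_base_weights sum to {wtot}, not 1"
            )
        if self.footprint_len not in (7, 9):
            raise GeneratorConfigError(
                f"footprint_len must be 7 or 9, got {self.footprint_len}"
            )
        p_needs_tgt = sum(
            self.p_class.get(k, 0.0)
            for k in ("CANONICAL_TAC", "CANONICAL_CAC", "GTG_TYPE")
        )
        if p_needs_tgt > 0 and self.p_cys_tgt == 0:
            raise GeneratorConfigError(
                "GTG-bearing classes require Cys104=TGT but p_cys_tgt is 0"
            )
        if self.fr_scaffold_len_codons < 105:
            raise GeneratorConfigError(
                "fr_scaffold_len_codons must be >= 105 to reach codon 105"
            )
        for p_name in ("p_cys_tgt", "p_res105_ala", "dh_charged_codon_p"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(f"{p_name}={p} outside [0, 1]")
        if self.footprint_charged_codon_p is not None and not (
            0.0 <= self.footprint_charged_codon_p <= 1.0
        ):
            raise GeneratorConfigError("footprint_charged_codon_p outside [0, 1]")
        lo, hi = self.gap_codons_range
        if lo < 0 or hi < lo:
            raise GeneratorConfigError("invalid gap_codons_range")
        if not self.emit_gapped and (lo, hi) != (0, 0):
            pass  # gaps only affect the gapped rendering, not seq_nt

    def family_sizes(self) -> list[int]:
        if isinstance(self.genes_per_family, int):
            return [self.genes_per_family] * self.n_families
        sizes = list(self.genes_per_family)
        if len(sizes) != self.n_families:
            raise GeneratorConfigError(
                "genes_per_family list length must equal n_families"
            )
        return sizes


@dataclass
class TruthLedger:
    """Per-gene ground truth plus the implied class counts."""

    genes: pd.DataFrame
    dh: pd.DataFrame

    @property
    def expected_counts(self) -> dict[str, int]:
        g = self.genes[self.genes["counted"]]
        n_can = int(g["true_class"].str.startswith("CANONICAL").sum())
        n_gtg_only = int((g["true_class"] == "GTG_TYPE").sum())
        n_other = int((g["true_class"] == "OTHER").sum())
        return {
            "n_canonical": n_can,
            "n_gtg": n_can + n_gtg_only,
            "n_other": n_other,
            "n_total": len(g),
        }


def _choice(rng: np.random.Generator, options: Sequence[str],
            p: Sequence[float] | None = None) -> str:
    return str(options[rng.choice(len(options), p=p)])


def _draw_codon103(rng: np.random.Generator, klass: str) -> str:
    if klass == "CANONICAL_TAC":
        return "TAC"
    if klass == "CANONICAL_CAC":
        return "CAC"
    pool = tuple(c for c in _SCAFFOLD_CODONS if c not in ("TAC", "CAC"))
    return _choice(rng, pool)


def _weighted_base(rng: np.random.Generator, weights: dict[str, float],
                   exclude: str = "") -> str:
    pool = [b for b in _BASES if b not in exclude]
    w = np.array([weights[b] for b in pool])
    return _choice(rng, pool, w / w.sum())


def _draw_h7(rng: np.random.Generator, klass: str, cys_codon: str,
             weights: dict[str, float]) -> str:
    """Heptamer position 7 = the first nucleotide of codon 105.

    GTG-bearing classes require G; OTHER with a TGT Cys codon (positions
    5-6 = GT) must avoid G to break the motif; OTHER with TGC already
    fails the test and is unconstrained.
    """
    if klass in ("CANONICAL_TAC", "CANONICAL_CAC", "GTG_TYPE"):
        return "G"
    if cys_codon == "TGT":
        return _weighted_base(rng, weights, exclude="G")
    return _weighted_base(rng, weights)


def _draw_footprint(rng: np.random.Generator, cfg: GeneratorConfig,
                    h7: str) -> tuple[str, bool]:
    """Post-heptamer nucleotides; the first two complete codon 105.

    Codon 105 is ``h7 + footprint[0:2]``, so the residue-105 alanine
    preference (GCN) constrains footprint position 0 to C (or away from C)
    whenever position 7 of the heptamer is G; positions 1..end are i.i.d.
    from the base weights. Footprints whose natural-frame (offset 2)
    translation contains a Cys are rejected so the planted Cys104 stays
    the 3'-most cysteine. Returns (footprint, residue105_is_ala).
    """
    weights = cfg.footprint_base_weights
    ala = h7 == "G" and rng.random() < cfg.p_res105_ala
    for _ in range(1000):
        if cfg.footprint_charged_codon_p is not None:
            # parameter-recovery mode: frame-II (offset 0) codons are
            # planted whole, overriding the residue-105 preference
            n_codons = cfg.footprint_len // 3
            parts = []
            for _ in range(n_codons):
                if rng.random() < cfg.footprint_charged_codon_p:
                    parts.append(_choice(rng, CHARGED_CODONS))
                else:
                    parts.append(_choice(rng, UNCHARGED_SENSE_CODONS))
            tail = "".join(
                _weighted_base(rng, weights)
                for _ in range(cfg.footprint_len - 3 * n_codons)
            )
            fp = "".join(parts) + tail
        else:
            if ala:
                first = "C"
            elif h7 == "G":
                first = _weighted_base(rng, weights, exclude="C")
            else:
                first = _weighted_base(rng, weights)
            fp = first + "".join(
                _weighted_base(rng, weights)
                for _ in range(cfg.footprint_len - 1)
            )
        # keep the planted Cys104 the 3'-most cysteine and codon 105 sense
        if (
            "C" not in translate_frame(fp, 2)
            and translate_codon(h7 + fp[:2]) not in ("C", "*")
        ):
            is_ala = h7 == "G" and fp[0] == "C"
            return fp, is_ala
    raise GeneratorConfigError(
        "could not draw a footprint without an in-frame Cys"
    )


def _build_gene(rng: np.random.Generator, cfg: GeneratorConfig,
                gene_id: str, family: str) -> tuple[VhGene, dict]:
    klass = _choice(
        rng, CLASSES, [cfg.p_class.get(k, 0.0) for k in CLASSES]
    )
    gap_codons = (
        int(rng.integers(cfg.gap_codons_range[0], cfg.gap_codons_range[1] + 1))
        if cfg.emit_gapped
        else 0
    )
    cys_idx = 103 - gap_codons  # 0-based codon index of Cys104

    # scaffold codons 0..cys_idx-3 (codon "102" is the Tyr context);
    # Cys codons are excluded from the whole scaffold so the 3'-most Cys
    # in the heuristic window is always the planted one
    scaffold = [
        _choice(rng, _SCAFFOLD_CODONS) for _ in range(cys_idx - 2)
    ]
    tyr102 = _choice(rng, _TYR_CODONS)
    codon103 = _draw_codon103(rng, klass)
    if klass == "OTHER":
        cys_codon = "TGT" if rng.random() < cfg.p_cys_tgt else "TGC"
    else:
        cys_codon = "TGT"
    h7 = _draw_h7(rng, klass, cys_codon, cfg.footprint_base_weights)
    footprint, is_ala = _draw_footprint(rng, cfg, h7)
    codon105 = h7 + footprint[:2]

    seq = "".join(scaffold) + tyr102 + codon103 + cys_codon + h7 + footprint
    heptamer = codon103 + cys_codon + h7

    gapped = None
    if cfg.emit_gapped:
        cut = 3 * (cfg.gap_at_codon - 1)
        gapped = seq[:cut] + "." * (3 * gap_codons) + seq[cut:]

    gene = VhGene(
        gene_id=gene_id,
        species=cfg.species,
        family=family,
        functional=True,
        seq_nt=seq,
        gapped_nt=gapped,
        source="synthetic",
    )
    truth = {
        "gene_id": gene_id,
        "family": family,
        "true_class": klass,
        "heptamer": heptamer,
        "cys104_codon_index": cys_idx,
        "cys104_codon": cys_codon,
        "residue105_codon": codon105,
        "residue105_is_ala": is_ala,
        "gt_retained": heptamer[4:6] == "GT",
        "footprint": footprint,
        "footprint_len": len(footprint),
        "gap_codons": gap_codons,
        "counted": True,
    }
    return gene, truth


def generate_repertoire(cfg: GeneratorConfig) -> tuple[Repertoire, TruthLedger]:
    """Draw a full VH (+DH) repertoire and its ground-truth ledger.

    Draw order per gene is fixed (class, gap width, scaffold codons 5'->3',
    Tyr102, codon 103, Cys codon where free, codon 105, footprint), so a
    given (seed, config) pair always yields byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[VhGene] = []
    truths: list[dict] = []
    for f, size in enumerate(cfg.family_sizes(), start=1):
        family = f"VH{f}"
        for i in range(1, size + 1):
            gene_id = f"VH{f}-{i}*01"
            gene, truth = _build_gene(rng, cfg, gene_id, family)
            genes.append(gene)
            truths.append(truth)

    # optional decoys exercising the functional/allele filter: they are
    # emitted but flagged counted=False in the ledger
    for j in range(cfg.n_secondary_alleles):
        src = genes[j % len(genes)]
        dup = VhGene(
            gene_id=src.gene_id.replace("*01", "*02"),
            species=src.species,
            family=src.family,
            functional=True,
            seq_nt=src.seq_nt,
            gapped_nt=src.gapped_nt,
            source="synthetic allele duplicate",
        )
        genes.append(dup)
        truths.append({"gene_id": dup.gene_id, "family": dup.family,
                       "true_class": "NA", "counted": False})
    for j in range(cfg.n_pseudogenes):
        gene, truth = _build_gene(rng, cfg, f"VHP-{j + 1}*01", "VHP")
        gene = replace(gene, functional=False)
        truth["counted"] = False
        truth["true_class"] = "NA"
        genes.append(gene)
        truths.append(truth)

    dh_genes, dh_truth = _generate_dh(rng, cfg)
    rep = Repertoire(species=cfg.species, genes=genes, dh_genes=dh_genes)
    ledger = TruthLedger(
        genes=pd.DataFrame(truths), dh=pd.DataFrame(dh_truth)
    )
    return rep, ledger


def _generate_dh(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[list[DhGene], list[dict]]:
    genes: list[DhGene] = []
    truths: list[dict] = []
    lo, hi = cfg.dh_len_range
    for i in range(1, cfg.dh_count + 1):
        length = int(rng.integers(lo, hi + 1))
        n_codons = length // 3
        parts = []
        for _ in range(n_codons):
            if rng.random() < cfg.dh_charged_codon_p:
                parts.append(_choice(rng, CHARGED_CODONS))
            else:
                parts.append(_choice(rng, UNCHARGED_SENSE_CODONS))
        tail = "".join(_choice(rng, _BASES) for _ in range(length - 3 * n_codons))
        seq = "".join(parts) + tail
        gene = DhGene(f"DH{i}*01", cfg.species, True, seq)
        genes.append(gene)
        # exhaustive best-frame oracle at generation time
        best = None
        for off in (0, 1, 2):
            pep = translate_frame(seq, off)
            if pep:
                frac = sum(1 for aa in pep if aa in CHARGED) / len(pep)
                if best is None or frac > best:
                    best = frac
        truths.append(
            {"gene_id": gene.gene_id, "length": length,
             "best_frame_charged": best}
        )
    return genes, truths


def generate_dh_set(cfg: GeneratorConfig) -> tuple[list[DhGene], pd.DataFrame]:
    """DH segments only, with their generation-time best-frame oracle."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, truths = _generate_dh(rng, cfg)
    return genes, pd.DataFrame(truths)


def mouse_shaped_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A 107-gene scenario shaped like a murine germline repertoire.

    Family sizes follow the published 16-family breakdown (51, 8, 6, 1,
    10, 5, 3, 6, 4, 2, 2, 1, 2, 4, 1, 1); the default class mix puts the
    total GTG-bearing fraction at 0.869.
    """
    sizes = [51, 8, 6, 1, 10, 5, 3, 6, 4, 2, 2, 1, 2, 4, 1, 1]
    params = dict(
        seed=seed,
        species="synthetic_mouse_like",
        n_families=len(sizes),
        genes_per_family=sizes,
    )
    params.update(overrides)
    return GeneratorConfig(**params)
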