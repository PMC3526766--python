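"""End-to-end orchestration: read -> filter -> anchor -> scan -> summarize.

These functions are the library face of the command-line interface; each
returns plain dataclasses/DataFrames so they compose in notebooks as well
as in the CLI. Stage tallies are conserved: every input gene ends up in
exactly one of {summarized, filtered-out, incomplete}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .anchoring import AnchorResult, anchor_gene, anchors_to_frame
from .crss_scan import (
    HeptamerCall,
    calls_to_frame,
    codon_usage,
    extract_heptamer,
    family_summary,
    gt_retention_stat,
)
from .footprint import (
    Footprint,
    charge_summary_table,
    extract_footprint,
    footprints_to_frame,
    translate_frames,
)
from .grouping import GroupScheme, group_frequencies
from .repertoire_io import Repertoire, filter_functional_allele01

logger = logging.getLogger("vhcrss")


@dataclass
class ScanResult:
    """Everything the heptamer scan produced for one repertoire."""

    repertoire: Repertoire          # after functional/allele filtering
    n_input: int
    n_filtered_out: int
    anchors: list[AnchorResult]
    calls: list[HeptamerCall]
    summary: pd.DataFrame           # per-family table with Total row

    @property
    def n_incomplete(self) -> int:
        return sum(1 for c in self.calls if not c.is_complete)

    @property
    def complete_pairs(self):
        return [
            (g, c)
            for g, c in zip(self.repertoire.genes, self.calls)
            if c.is_complete
        ]


def run_scan(rep: Repertoire, window_codons: int = 12) -> ScanResult:
    """Filter to functional *01 genes, anchor Cys104, call heptamers."""
    n_input = len(rep.genes)
    filtered = filter_functional_allele01(rep)
    n_out = n_input - len(filtered.genes)
    if n_out:
        logger.info("filtered out %d non-functional/secondary-allele genes",
                    n_out)
    anchors = [anchor_gene(g, window_codons=window_codons) for g in filtered]
    calls = [
        extract_heptamer(g, a) for g, a in zip(filtered.genes, anchors)
    ]
    summary = family_summary(filtered.genes, calls)
    logger.info(
        "scanned %d genes (%d incomplete)", len(calls),
        sum(1 for c in calls if not c.is_complete),
    )
    return ScanResult(
        repertoire=filtered,
        n_input=n_input,
        n_filtered_out=n_out,
        anchors=anchors,
        calls=calls,
        summary=summary,
    )


@dataclass
class FootprintResult:
    footprints: list[Footprint]
    per_gene: pd.DataFrame
    summary: pd.DataFrame


def run_footprint(
    scan: ScanResult,
    aggregation: Literal["pooled", "mean"] = "pooled",
) -> FootprintResult:
    """Extract and translate footprints; build the charge-summary table."""
    footprints = [
        translate_frames(extract_footprint(g, c))
        for g, c in scan.complete_pairs
    ]
    dh = [d for d in scan.repertoire.dh_genes if d.functional]
    if not dh:
        logger.warning("no functional DH genes; DH column omitted")
    summary = charge_summary_table(
        footprints, dh, scope=scan.repertoire.species, aggregation=aggregation
    )
    return FootprintResult(
        footprints=footprints,
        per_gene=footprints_to_frame(footprints),
        summary=summary,
    )


def run_group(scan: ScanResult, scheme: GroupScheme) -> pd.DataFrame:
    """Per-group heptamer-class frequencies from a scan result."""
    genes = [g for g, _ in zip(scan.repertoire.genes, scan.calls)]
    return group_frequencies(genes, scan.calls, scheme)


def write_scan_outputs(scan: ScanResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-gene and summary tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "anchors": outdir / "anchors.tsv",
        "calls": outdir / "heptamer_calls.tsv",
        "summary": outdir / "family_summary.csv",
        "stats": outdir / "scan_stats.tsv",
    }
    anchors_to_frame(scan.anchors).to_csv(paths["anchors"], sep="\t", index=False)
    calls_to_frame(scan.calls).to_csv(paths["calls"], sep="\t", index=False)
    scan.summary.to_csv(paths["summary"], index=False)
    usage = codon_usage(scan.calls)
    gt_n, gt_d = gt_retention_stat(scan.calls)
    stats = pd.DataFrame(
        [
            {"stat": "n_input", "numerator": scan.n_input, "denominator": ""},
            {"stat": "n_filtered_out", "numerator": scan.n_filtered_out,
             "denominator": ""},
            {"stat": "n_incomplete", "numerator": scan.n_incomplete,
             "denominator": ""},
            {"stat": "cys104_TGT", "numerator": usage["cys104_TGT"][0],
             "denominator": usage["cys104_TGT"][1]},
            {"stat": "residue105_GCN",
             "numerator": usage["residue105_GCN"][0],
             "denominator": usage["residue105_GCN"][1]},
            {"stat": "gt_retention_among_other", "numerator": gt_n,
             "denominator": gt_d},
        ]
    )
    stats.to_csv(paths["stats"], sep="\t", index=False)
    return paths


def write_footprint_outputs(
    res: FootprintResult, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "per_gene": outdir / "footprints.tsv",
        "summary": outdir / "charge_summary.csv",
    }
    res.per_gene.to_csv(paths["per_gene"], sep="\t", index=False)
    res.summary.to_csv(paths["summary"], index=False)
    return paths
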