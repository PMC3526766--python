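"""Cross-species clade grouping of VH families and an NJ guide tree.

VH gene families from different species fall into cross-species clades
that persist through the birth-and-death evolution of the locus (the
groups A-H analysis). Group membership here is a declarative mapping from
(species, family) pairs to group labels, loaded from a YAML config; an
optional deterministic neighbor-joining tree on a user-supplied FR1-FR3
nucleotide alignment supports exploratory grouping but plays no role in
the frequency computation.

The NJ implementation is deliberately in-house: classical
Saitou-Nei/Studier-Keppler agglomeration with a lexicographic tie-break on
taxon labels, so identical inputs always give byte-identical Newick. Its
exactness on additive distance matrices is the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .crss_scan import HeptamerCall, format_pct, scan_calls
from .repertoire_io import RepertoireError, VhGene


class GroupSchemeError(ValueError):
    """Raised for invalid group-scheme configs."""


@dataclass(frozen=True)
class GroupScheme:
    """Mapping from (species, family) to a clade group label."""

    mapping: Mapping[tuple[str, str], str]
    groups: tuple[str, ...]

    def group_of(self, species: str, family: str) -> Optional[str]:
        return self.mapping.get((species, family))


def load_group_scheme(config_path: str | Path) -> GroupScheme:
    """Load a scheme config: ``{groups: {A: ["species:family", ...], ...}}``.

    A (species, family) pair assigned to two groups is a config error.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    groups_cfg = cfg.get("groups", cfg)
    if not isinstance(groups_cfg, dict):
        raise GroupSchemeError("config must map group labels to member lists")
    mapping: dict[tuple[str, str], str] = {}
    order: list[str] = []
    for label, members in groups_cfg.items():
        order.append(str(label))
        for entry in members or []:
            species, sep, family = str(entry).partition(":")
            if not sep or not family:
                raise GroupSchemeError(
                    f"group {label}: entry {entry!r} is not 'species:family'"
                )
            key = (species.strip(), family.strip())
            if key in mapping:
                raise GroupSchemeError(
                    f"{key[0]}:{key[1]} assigned to both "
                    f"{mapping[key]} and {label}"
                )
            mapping[key] = str(label)
    return GroupScheme(mapping=mapping, groups=tuple(order))


def group_frequencies(
    genes: Sequence[VhGene],
    calls: Sequence[HeptamerCall],
    scheme: GroupScheme,
) -> pd.DataFrame:
    """Per-group heptamer-class counts with ``pct (n/N)`` rendering.

    Genes whose (species, family) is absent from the scheme are summarized
    under the reserved label ``unassigned`` rather than dropped. Groups
    with no genes are omitted.
    """
    if len(genes) != len(calls):
        raise ValueError("genes and calls must be parallel sequences")
    buckets: dict[str, list[HeptamerCall]] = {}
    for g, c in zip(genes, calls):
        label = scheme.group_of(g.species, g.family) or "unassigned"
        buckets.setdefault(label, []).append(c)

    rows = []
    for label in list(scheme.groups) + ["unassigned"]:
        if label not in buckets:
            continue
        tallies = scan_calls(buckets[label])
        rows.append(
            {
                "group": label,
                **tallies,
                "pct_canonical": format_pct(
                    tallies["n_canonical"], tallies["n_total"]
                ),
                "pct_gtg": format_pct(tallies["n_gtg"], tallies["n_total"]),
                "pct_other": format_pct(
                    tallies["n_other"], tallies["n_total"]
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_canonical", "n_gtg", "n_other", "n_incomplete",
                 "n_total", "pct_canonical", "pct_gtg", "pct_other"],
    )


# --------------------------------------------------------------------------
# Neighbor joining on p-distances
# --------------------------------------------------------------------------

_GAPLIKE = frozenset(".-N")


@dataclass(frozen=True)
class GuideTree:
    """An unrooted NJ tree over alignment sequence IDs."""

    leaves: tuple[str, ...]
    newick: str


def p_distance_matrix(
    ids: Sequence[str], seqs: Sequence[str]
) -> pd.DataFrame:
    """Pairwise p-distance: mismatches / valid sites.

    Sites where either sequence has a gap ('.', '-') or N are excluded
    pairwise. Sequences must be equal length. A pair with no valid sites
    gets distance 0.
    """
    lens = {len(s) for s in seqs}
    if len(lens) > 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lens)}")
    n = len(ids)
    d = np.zeros((n, n))
    up = [s.upper().replace("-", ".") for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            valid = mism = 0
            for a, b in zip(up[i], up[j]):
                if a in _GAPLIKE or b in _GAPLIKE:
                    continue
                valid += 1
                if a != b:
                    mism += 1
            d[i, j] = d[j, i] = mism / valid if valid else 0.0
    return pd.DataFrame(d, index=list(ids), columns=list(ids))


def _fmt_bl(x: float) -> str:
    return f"{max(x, 0.0):.6f}"


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Classical NJ agglomeration; returns a Newick string.

    Ties in the Q criterion break toward the lexicographically smallest
    (label_i, label_j) pair, making the output fully deterministic.
    Negative branch-length estimates are clamped to zero in the output.
    On an additive matrix the reconstruction is exact.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[(a, b)] = float(dist.iat[i, j])
    subtree: dict[str, str] = {lab: lab for lab in labels}
    active = sorted(labels)
    k = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best: Optional[tuple[float, str, str]] = None
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = D[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        new = f"__node{k}"
        k += 1
        subtree[new] = (
            f"({subtree[a]}:{_fmt_bl(la)},{subtree[b]}:{_fmt_bl(lb)})"
        )
        for c in active:
            if c in (a, b):
                continue
            dnc = 0.5 * (D[(a, c)] + D[(b, c)] - dab)
            D[(new, c)] = D[(c, new)] = dnc
        active = sorted(c for c in active if c not in (a, b)) + [new]
        active.sort()

    a, b, c = active
    # three-point formulas for the final unresolved trifurcation
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    return (
        f"({subtree[a]}:{_fmt_bl(la)},{subtree[b]}:{_fmt_bl(lb)},"
        f"{subtree[c]}:{_fmt_bl(lc)});"
    )


def nj_guide_tree(
    aligned_fasta: str | Path,
    regions: Sequence[tuple[int, int]] | None = None,
) -> GuideTree:
    """NJ tree from an aligned FASTA, optionally restricted to columns.

    ``regions`` is a list of 1-based inclusive column ranges (e.g. the
    FR1-FR3 intervals of an IMGT-numbered alignment); None uses all
    columns. Requires >= 3 equal-length sequences.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(aligned_fasta), "fasta"):
        if rec.id in ids:
            raise RepertoireError(f"duplicate alignment id {rec.id!r}")
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if len(ids) < 3:
        raise ValueError("guide tree requires at least 3 taxa")
    if regions:
        sliced = []
        for s in seqs:
            parts = []
            for lo, hi in regions:
                if not (1 <= lo <= hi <= len(s)):
                    raise ValueError(f"region ({lo}, {hi}) out of bounds")
                parts.append(s[lo - 1 : hi])
            sliced.append("".join(parts))
        seqs = sliced
    dist = p_distance_matrix(ids, seqs)
    return GuideTree(leaves=tuple(ids), newick=neighbor_joining(dist))
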