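"""Group-scheme loading, per-group frequencies, p-distance, NJ exactness."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from vhcrss.grouping import (
    GroupSchemeError,
    load_group_scheme,
    neighbor_joining,
    nj_guide_tree,
    p_distance_matrix,
)
from vhcrss.pipeline import run_group, run_scan


def _write_scheme(tmp_path, mapping):
    path = tmp_path / "scheme.yaml"
    import yaml

    path.write_text(yaml.safe_dump({"groups": mapping}))
    return path


def test_load_scheme_bidirectional_lookup(tmp_path):
    path = _write_scheme(
        tmp_path,
        {"A": ["sp1:VH1", "sp2:VH3"], "B": ["sp1:VH2"]},
    )
    scheme = load_group_scheme(path)
    assert scheme.groups == ("A", "B")
    assert scheme.group_of("sp1", "VH1") == "A"
    assert scheme.group_of("sp1", "VH2") == "B"
    assert scheme.group_of("sp1", "VH9") is None


def test_duplicate_family_assignment_is_config_error(tmp_path):
    path = _write_scheme(tmp_path, {"A": ["sp:VH1"], "B": ["sp:VH1"]})
    with pytest.raises(GroupSchemeError, match="sp:VH1"):
        load_group_scheme(path)


def test_empty_scheme_marks_everything_unassigned(tmp_path, small_repertoire):
    _, rep, _ = small_repertoire
    scan = run_scan(rep)
    scheme = load_group_scheme(_write_scheme(tmp_path, {}))
    df = run_group(scan, scheme)
    assert list(df["group"]) == ["unassigned"]
    assert df["n_total"].sum() == len(scan.repertoire.genes)


def test_group_totals_conserve_family_totals(tmp_path, small_repertoire):
    cfg, rep, ledger = small_repertoire
    scan = run_scan(rep)
    scheme = load_group_scheme(
        _write_scheme(
            tmp_path,
            {
                "X": [f"{cfg.species}:VH1", f"{cfg.species}:VH2"],
                "Y": [f"{cfg.species}:VH3", f"{cfg.species}:VH4",
                      f"{cfg.species}:VH5"],
            },
        )
    )
    groups = run_group(scan, scheme)
    fam = scan.summary[scan.summary["family"] != "Total"]
    for label, fams in (("X", ["VH1", "VH2"]), ("Y", ["VH3", "VH4", "VH5"])):
        sub = fam[fam["family"].isin(fams)]
        row = groups[groups["group"] == label].iloc[0]
        for col in ("n_canonical", "n_gtg", "n_other", "n_total"):
            assert row[col] == sub[col].sum()


# --------------------------------------------------------------------------
# p-distance and neighbor joining
# --------------------------------------------------------------------------


def test_p_distance_symmetric_bounded_gap_aware():
    ids = ["a", "b", "c"]
    seqs = ["ACGTACGT", "ACGTACGA", "AC.TNCGA"]
    d = p_distance_matrix(ids, seqs)
    assert np.allclose(d.values, d.values.T)
    assert (np.diag(d.values) == 0).all()
    assert ((d.values >= 0) & (d.values <= 1)).all()
    assert d.loc["a", "b"] == pytest.approx(1 / 8)
    # a vs c: sites 3 and 5 excluded (gap, N) -> 6 valid, 1 mismatch
    assert d.loc["a", "c"] == pytest.approx(1 / 6)


def test_p_distance_requires_equal_lengths():
    with pytest.raises(ValueError, match="unequal"):
        p_distance_matrix(["a", "b"], ["ACGT", "ACG"])


def _patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


def _tree_distance_matrix(newick, labels):
    dist = _patristic(newick)
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = dist(labels[i], labels[j])
    return pd.DataFrame(m, index=labels, columns=labels)


def test_nj_exact_on_hand_built_additive_4_taxon_matrix():
    # tree ((A:2,B:3):1,C:4,D:5): AB=5 AC=7 AD=8 BC=8 BD=9 CD=9
    labels = ["A", "B", "C", "D"]
    m = pd.DataFrame(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
        index=labels, columns=labels, dtype=float,
    )
    newick = neighbor_joining(m)
    assert _tree_distance_matrix(newick, labels).round(9).equals(
        m.round(9)
    )
    # A and B are neighbors in the reconstruction
    tree = dendropy.Tree.get(data=newick, schema="newick")
    ab = [lf for lf in tree.leaf_node_iter()
          if lf.taxon.label in ("A", "B")]
    assert ab[0].parent_node is ab[1].parent_node


@pytest.mark.parametrize(
    "true_newick, labels",
    [
        ("((A:1,B:2):1,C:3,(D:4,E:5):1);", list("ABCDE")),
        ("((A:2,B:1):2,(C:3,(D:1,E:2):1):1,F:4);", list("ABCDEF")),
    ],
)
def test_nj_recovers_additive_trees_of_5_and_6_taxa(true_newick, labels):
    m = _tree_distance_matrix(true_newick, labels)
    newick = neighbor_joining(m)
    recovered = _tree_distance_matrix(newick, labels)
    assert np.allclose(recovered.values, m.values, atol=1e-9)


def test_nj_matches_scikit_bio_topology_on_additive_matrix():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    true_newick = "((A:1,B:2):1,C:3,(D:4,E:5):1);"
    labels = list("ABCDE")
    m = _tree_distance_matrix(true_newick, labels)
    ours = dendropy.Tree.get(data=neighbor_joining(m), schema="newick")
    theirs_newick = str(
        skbio_nj(DistanceMatrix(m.values, ids=labels))
    )
    tns = ours.taxon_namespace
    theirs = dendropy.Tree.get(
        data=theirs_newick, schema="newick", taxon_namespace=tns
    )
    ours.encode_bipartitions()
    theirs.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(
        ours, theirs
    ) == 0


def test_nj_guide_tree_from_alignment(tmp_path):
    fa = tmp_path / "aln.fasta"
    fa.write_text(
        ">s1\nACGTACGTAC\n>s2\nACGTACGTAC\n>s3\nTGCATGCATG\n"
    )
    gt = nj_guide_tree(fa)
    assert set(gt.leaves) == {"s1", "s2", "s3"}
    # the two identical sequences sit at zero distance
    assert "s1:0.000000" in gt.newick and "s2:0.000000" in gt.newick


def test_nj_guide_tree_region_slicing_and_min_taxa(tmp_path):
    fa = tmp_path / "aln.fasta"
    fa.write_text(">s1\nAAAATTTT\n>s2\nAAAACCCC\n")
    with pytest.raises(ValueError, match="3 taxa"):
        nj_guide_tree(fa)
    fa.write_text(">s1\nAAAATTTT\n>s2\nAAAACCCC\n>s3\nAAAAGGGG\n")
    # restricted to the identical first 4 columns: star tree, zero lengths
    gt = nj_guide_tree(fa, regions=[(1, 4)])
    assert gt.newick.count("0.000000") == 3
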