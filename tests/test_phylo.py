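"""Alignment trimming, NJ inference, and the HGT verdict rules."""

import numpy as np
import pytest

from archpan.phylo_hgt import (
    GeneTree,
    LeafTaxon,
    call_hgt,
    call_hgt_exhaustive,
    donor_spectrum,
    infer_tree,
    time_transfer,
    tree_splits,
    trim_alignment,
)
from conftest import random_tree_newick

# -- trimming -----------------------------------------------------------------


def test_trim_removes_columns_above_gap_threshold():
    rows = [("s%d" % i, "A-A") for i in range(3)] + [("s%d" % i, "AAA") for i in range(3, 10)]
    # column 1 has 3/10 = 0.30 gaps -> removed
    out = trim_alignment(rows, 0.20)
    assert all(s == "AA" for _, s in out)


def test_trim_keeps_boundary_columns():
    rows = [("s%d" % i, "A-A") for i in range(2)] + [("s%d" % i, "AAA") for i in range(2, 10)]
    # column 1 has exactly 0.20 gaps -> retained (strictly more than 20% goes)
    out = trim_alignment(rows, 0.20)
    assert all(len(s) == 3 for _, s in out)


def test_trim_gapfree_is_identity():
    rows = [("a", "MKV"), ("b", "MKI")]
    assert trim_alignment(rows, 0.20) == rows


def test_trim_all_columns_removed_raises():
    with pytest.raises(ValueError):
        trim_alignment([("a", "-"), ("b", "-")], 0.20)


# -- NJ -----------------------------------------------------------------------


def _simulate_family(rng, n_query=3):
    """Tiny planted alignment: query clade + two bacterial phyla."""
    from archpan.phylo_hgt import AA_ALPHABET

    L = 150

    def evolve(seq, bl):
        out = seq.copy()
        hit = rng.random(L) < 1 - np.exp(-bl)
        out[hit] = (out[hit] + rng.integers(1, 20, hit.sum())) % 20
        return out

    def s(x):
        return "".join(AA_ALPHABET[i] for i in x)

    root = rng.integers(0, 20, L)
    qa = evolve(root, 0.4)
    align, tax = [], {}
    for i in range(n_query):
        align.append((f"q{i}", s(evolve(qa, 0.05))))
        tax[f"q{i}"] = LeafTaxon("Archaea", "Thaumarchaeota", is_query=True)
    for ph in ("PhylX", "PhylY"):
        anc = evolve(root, 0.45)
        for i in range(6):
            lab = f"{ph}_{i}"
            align.append((lab, s(evolve(anc, 0.15))))
            tax[lab] = LeafTaxon("Bacteria", ph)
    return align, tax


def test_nj_recovers_additive_four_taxon_topology():
    # distances additive on ((a,b),(c,d)): internal edge length 2
    align = None
    from archpan.phylo_hgt import _nj, _tree_bipartitions

    D = np.array(
        [
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ],
        dtype=float,
    )
    tree = _nj(D, ["a", "b", "c", "d"])
    splits = _tree_bipartitions(tree, frozenset("abcd"))
    assert frozenset("cd") in splits or frozenset("ab") in splits


def test_infer_tree_deterministic_under_seed(rng):
    align, _ = _simulate_family(rng)
    t1 = infer_tree(align, seed=5, n_boot=30)
    t2 = infer_tree(align, seed=5, n_boot=30)
    assert t1.newick == t2.newick


def test_infer_tree_requires_four_rows():
    with pytest.raises(ValueError):
        infer_tree([("a", "MK"), ("b", "MK"), ("c", "MK")])


def test_query_clade_recovered_with_support(rng):
    hits = 0
    for _ in range(10):
        align, tax = _simulate_family(rng)
        tree = infer_tree(align, seed=3, n_boot=50)
        leaves, splits = tree_splits(tree.newick)
        q = frozenset(l for l in leaves if tax[l].is_query)
        sup = max(
            (s for side, s in splits.items() if side == q or leaves - side == q),
            default=0.0,
        )
        if sup >= 0.8:
            hits += 1
    assert hits >= 9


# -- verdict rules -------------------------------------------------------------


def _tax_for(labels):
    """Taxonomy from structured labels: q* query, arch* archaea, else
    Phylum_N bacteria."""
    tax = {}
    for lab in labels:
        if lab.startswith("q"):
            tax[lab] = LeafTaxon("Archaea", "Thaumarchaeota", is_query=True)
        elif lab.startswith("arch"):
            tax[lab] = LeafTaxon("Archaea", "Euryarchaeota")
        else:
            tax[lab] = LeafTaxon("Bacteria", lab.split("_")[0])
    return tax


def test_minimal_nested_positive():
    nwk = "(((q1:0.1,q2:0.1)1.0:0.1,((fX_1:0.1,fX_2:0.1)1.0:0.1,(fX_3:0.1,(fX_4:0.1,fX_5:0.1)1.0:0.1)1.0:0.1)1.0:0.1)1.0:0.1,(arch_1:0.1,arch_2:0.1)1.0:0.1,arch_3:0.1);"
    v = call_hgt(nwk, _tax_for(["q1", "q2", "fX_1", "fX_2", "fX_3", "fX_4", "fX_5", "arch_1", "arch_2", "arch_3"]))
    assert v.status == "hgt"
    assert v.criterion == "nested_in_phylum"
    assert v.donor_phylum == "fX"


def test_minimal_native_negative():
    # query sister to the other-archaea clade, bacteria outside
    nwk = "(((q1:0.1,q2:0.1)1.0:0.1,(arch_1:0.1,(arch_2:0.1,(arch_3:0.1,(arch_4:0.1,arch_5:0.1)1.0:0.1)1.0:0.1)1.0:0.1)1.0:0.1)1.0:0.1,((fX_1:0.1,fX_2:0.1)1.0:0.1,(fY_1:0.1,fY_2:0.1)1.0:0.1)1.0:0.1);"
    v = call_hgt(nwk, _tax_for(["q1", "q2", "arch_1", "arch_2", "arch_3", "arch_4", "arch_5", "fX_1", "fX_2", "fY_1", "fY_2"]))
    assert v.status == "native"


def test_no_query_leaves_raises():
    with pytest.raises(ValueError):
        call_hgt("((a:1,b:1)0.9:1,(c:1,d:1)0.9:1);", _tax_for(["arch_a", "arch_b", "arch_c", "arch_d"]))


def _random_case(rng, n_leaves):
    kinds = ["q", "arch", "PhA", "PhB", "PhC"]
    labels = []
    n_q = int(rng.integers(1, 3))
    for i in range(n_q):
        labels.append(f"q{i}")
    for i in range(n_leaves - n_q):
        kind = kinds[int(rng.integers(1, len(kinds)))]
        labels.append(f"{kind}_{i}")
    nwk = random_tree_newick(rng, labels)
    return nwk, _tax_for(labels)


def test_verdicts_match_exhaustive_oracle_on_random_trees(rng):
    agree = 0
    n_cases = 400
    for _ in range(n_cases):
        n = int(rng.integers(5, 9))
        nwk, tax = _random_case(rng, n)
        a = call_hgt(nwk, tax, min_bacterial_leaves=3)
        b = call_hgt_exhaustive(nwk, tax, min_bacterial_leaves=3)
        assert (a.status, a.criterion, a.donor_phylum) == (
            b.status,
            b.criterion,
            b.donor_phylum,
        ), nwk
        agree += 1
    assert agree == n_cases


def test_verdict_invariant_under_leaf_permutation(rng):
    import dendropy

    for _ in range(30):
        nwk, tax = _random_case(rng, 8)
        v1 = call_hgt(nwk, tax, min_bacterial_leaves=3)
        # re-serialize with rotated children: a pure presentation change
        t = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True)
        for node in t.preorder_node_iter():
            node._child_nodes.reverse()
        nwk2 = t.as_string(schema="newick", suppress_rooting=True).strip()
        v2 = call_hgt(nwk2, tax, min_bacterial_leaves=3)
        assert (v1.status, v1.criterion, v1.donor_phylum) == (
            v2.status,
            v2.criterion,
            v2.donor_phylum,
        )


def _reroot_preserving_supports(nwk, rng):
    """Reroot at a random internal edge, then restore each internal node's
    label from the original unrooted split -> support map (supports are edge
    properties, so they must follow the bipartition, not the node)."""
    import dendropy

    leaves, splits = tree_splits(nwk)
    ref = min(leaves)
    t = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True)
    internal = [
        e
        for e in t.preorder_edge_iter()
        if e.head_node.parent_node is not None and not e.head_node.is_leaf()
    ]
    edge = internal[int(rng.integers(0, len(internal)))]
    t.reroot_at_edge(edge, update_bipartitions=False)
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            node.label = None
            continue
        below = frozenset(x.taxon.label for x in node.leaf_iter())
        side = below if ref not in below else leaves - below
        sup = splits.get(side)
        node.label = f"{sup:.4f}" if sup is not None else None
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def test_verdict_invariant_under_rerooting(rng):
    for _ in range(30):
        nwk, tax = _random_case(rng, 8)
        v1 = call_hgt(nwk, tax, min_bacterial_leaves=3)
        nwk2 = _reroot_preserving_supports(nwk, rng)
        v2 = call_hgt(nwk2, tax, min_bacterial_leaves=3)
        assert (v1.status, v1.criterion, v1.donor_phylum) == (
            v2.status,
            v2.criterion,
            v2.donor_phylum,
        ), (nwk, nwk2)


def test_raising_min_support_is_conservative(rng):
    for _ in range(60):
        nwk, tax = _random_case(rng, 8)
        lo = call_hgt(nwk, tax, min_support=0.3, min_bacterial_leaves=3)
        hi = call_hgt(nwk, tax, min_support=0.9, min_bacterial_leaves=3)
        if lo.status == "native":
            assert hi.status != "hgt"
        if lo.status != "hgt":
            assert hi.status != "hgt"


# -- timing + donors ------------------------------------------------------------


def test_timing_from_pangenome_class():
    from archpan.phylo_hgt import HgtVerdict

    hgt = HgtVerdict("c", "hgt", criterion="nested_in_phylum", donor_domain="Bacteria")
    assert time_transfer(hgt, "lineage_core").timing == "early"
    assert time_transfer(hgt, "shell").timing == "late"
    conflict = time_transfer(hgt, "archaeal_core")
    assert conflict.timing == "n/a" and conflict.conflict
    native = HgtVerdict("c", "native")
    assert time_transfer(native, "shell").timing == "n/a"


def test_donor_spectrum_sums_to_one_and_handles_empty():
    from archpan.phylo_hgt import HgtVerdict

    vs = [
        HgtVerdict("a", "hgt", donor_phylum="X", timing="early"),
        HgtVerdict("b", "hgt", donor_phylum="X", timing="early"),
        HgtVerdict("c", "hgt", donor_phylum=None, timing="late"),
        HgtVerdict("d", "native"),
    ]
    spec = donor_spectrum(vs)
    assert spec["early"] == {"X": 1.0}
    assert spec["late"] == {"unassigned": 1.0}
    assert donor_spectrum([]) == {}
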