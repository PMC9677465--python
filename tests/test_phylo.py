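"""Alignments, distances, neighbour joining, tree metrics, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from panmag.calling import CallingParams, call_dataset
from panmag.errors import ConfigurationError
from panmag.magsim import DegradationProfile, simulate_dataset
from panmag.pangenome import PanGenome, build_pangenome
from panmag.phylo import (
    build_core_alignment,
    compare_trees,
    distance_matrix,
    enrichment,
    nj_tree,
)
from panmag.species import expected_within_identity


# ---------------------------------------------------------------------------
# minimal independent NJ implementation (test oracle)
# ---------------------------------------------------------------------------

def oracle_nj(ids, dist):
    """Classic O(n^3) neighbour joining; returns a set of bipartitions."""
    nodes = {i: frozenset([ids[i]]) for i in range(len(ids))}
    d = {(i, j): dist[i][j] for i in nodes for j in nodes if i != j}
    splits = []
    nxt = len(ids)
    while len(nodes) > 3:
        r = {i: sum(d[i, k] for k in nodes if k != i) for i in nodes}
        n = len(nodes)
        best = min(((d[i, j] - (r[i] + r[j]) / (n - 2), i, j)
                    for i in nodes for j in nodes if i < j))
        _, i, j = best
        new = nxt
        nxt += 1
        merged = nodes[i] | nodes[j]
        splits.append(merged)
        for k in list(nodes):
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes[new] = merged
        del nodes[i], nodes[j]
    leaves = frozenset(ids)
    out = set()
    for side in splits:
        if 2 <= len(side) <= len(ids) - 2:
            if min(ids) in side:
                side = leaves - side
            out.add(frozenset(side))
    return out


def _tree_bipartitions(newick, ids):
    from io import StringIO

    from skbio import TreeNode
    tree = TreeNode.read(StringIO(newick))
    leaves = sorted(t.name for t in tree.tips())
    anchor, full = leaves[0], frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def _random_trees(rng, labels):
    """Random unrooted binary tree as a Newick string."""
    nodes = [f"{x}" for x in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"


class TestCoreAlignment:
    def test_undegraded_alignment_has_no_gaps(self, small_pan, small_calls):
        ids, matrix = build_core_alignment(small_pan, small_calls)
        assert len(ids) == small_pan.n_assemblies
        assert not (matrix == ord("-")).any()
        by_id = {c.call_id: c for c in small_calls}
        width = sum(by_id[c.representative_call_id].length
                    for c in small_pan.clusters
                    if small_pan.partition[c.cluster_id] == "core")
        assert matrix.shape[1] == width

    def test_partial_call_produces_gap_block(self, small_pan, small_calls):
        import copy
        calls = copy.deepcopy(small_calls)
        core_cluster = next(c for c in small_pan.clusters
                            if small_pan.partition[c.cluster_id] == "core")
        target = next(c for c in calls
                      if c.call_id == core_cluster.member_call_ids[-1])
        target.sequence = target.sequence[:-30]
        target.partial_3prime = True
        ids, matrix = build_core_alignment(small_pan, calls)
        assert int((matrix == ord("-")).sum()) == 30
        row = ids.index(target.assembly_id)
        assert (matrix[row] == ord("-")).sum() == 30

    def test_p_distance_matches_substitution_closed_form(self, small_model,
                                                         small_pan, small_calls):
        ids, matrix = build_core_alignment(small_pan, small_calls)
        _, dist = distance_matrix((ids, matrix), "p_distance")
        expected = 1.0 - expected_within_identity(small_model.within_family_divergence)
        off_diag = dist[np.triu_indices(len(ids), 1)]
        # ~12 kb of aligned core sequence per pair: tight Monte-Carlo error
        se = np.sqrt(expected * (1 - expected) / matrix.shape[1])
        assert abs(off_diag.mean() - expected) < 4 * se
        assert np.allclose(dist, dist.T) and np.allclose(np.diag(dist), 0)

    def test_no_single_copy_core_is_an_error(self, small_pan, small_calls):
        broken = small_pan.reclassified(100.0)
        broken = PanGenome(clusters=broken.clusters,
                           presence_matrix=broken.presence_matrix,
                           si_threshold=90.0, cg_threshold=100.0,
                           partition={cid: "cloud" for cid in broken.partition},
                           cluster_family=broken.cluster_family,
                           representative_seqs=broken.representative_seqs)
        with pytest.raises(ConfigurationError):
            build_core_alignment(broken, small_calls)


class TestDistances:
    def test_identical_rows_zero_distance(self):
        ids = ["a", "b"]
        matrix = np.frombuffer(b"ACGTACGT", dtype=np.uint8).reshape(1, -1)
        matrix = np.vstack([matrix, matrix])
        _, dist = distance_matrix((ids, matrix), "p_distance")
        assert dist[0, 1] == 0.0

    def test_jaccard_example(self):
        df = pd.DataFrame([[1, 0], [1, 1], [0, 1]], index=["c0", "c1", "c2"],
                          columns=["a", "b"])
        _, dist = distance_matrix(df, "jaccard")
        assert dist[0, 1] == pytest.approx(2 / 3)

    def test_jaccard_matches_set_formula(self, rng):
        mat = rng.integers(0, 2, size=(40, 6))
        mat[0] = 1  # avoid empty assemblies
        df = pd.DataFrame(mat, index=[f"c{i}" for i in range(40)],
                          columns=[f"a{i}" for i in range(6)])
        ids, dist = distance_matrix(df, "jaccard")
        cols = {a: {i for i in range(40) if mat[i][j]} for j, a in enumerate(ids)}
        for i, j in itertools.combinations(range(6), 2):
            x, y = cols[ids[i]], cols[ids[j]]
            assert dist[i, j] == pytest.approx(1 - len(x & y) / len(x | y))

    def test_zero_overlap_is_an_error(self):
        matrix = np.frombuffer(b"AC--" b"--GT", dtype=np.uint8).reshape(2, 4)
        with pytest.raises(ConfigurationError):
            distance_matrix((["a", "b"], matrix), "p_distance")


class TestNeighborJoining:
    def _additive_matrix(self):
        # ((a,b),(c,d),e) with known branch lengths
        newick = "((a:1,b:2):1,(c:1.5,d:1):2,e:3);"
        from io import StringIO

        from skbio import TreeNode
        tree = TreeNode.read(StringIO(newick))
        ids = sorted(t.name for t in tree.tips())
        dist = np.array([[tree.find(x).distance(tree.find(y)) for y in ids]
                         for x in ids])
        return ids, dist

    def test_recovers_additive_topology(self):
        ids, dist = self._additive_matrix()
        tree = nj_tree(ids, dist)
        # sides are anchor-normalized: {a,b} is encoded as its complement
        assert _tree_bipartitions(tree, ids) == {frozenset({"c", "d", "e"}),
                                                 frozenset({"c", "d"})}

    def test_taxon_order_invariance(self):
        ids, dist = self._additive_matrix()
        perm = [3, 1, 4, 0, 2]
        tree1 = nj_tree(ids, dist)
        tree2 = nj_tree([ids[i] for i in perm], dist[np.ix_(perm, perm)])
        assert _tree_bipartitions(tree1, ids) == _tree_bipartitions(tree2, ids)

    def test_matches_minimal_oracle_on_random_matrices(self, rng):
        for n in (5, 6, 7):
            for _ in range(5):
                ids = [f"t{i}" for i in range(n)]
                m = rng.uniform(0.1, 1.0, size=(n, n))
                dist = (m + m.T) / 2
                np.fill_diagonal(dist, 0.0)
                tree = nj_tree(ids, dist)
                assert _tree_bipartitions(tree, ids) == oracle_nj(ids, dist)

    def test_asymmetric_matrix_is_an_error(self):
        ids = ["a", "b", "c", "d"]
        dist = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ConfigurationError):
            nj_tree(ids, dist)

    def test_too_few_taxa_is_an_error(self):
        with pytest.raises(ConfigurationError):
            nj_tree(["a", "b", "c"], np.zeros((3, 3)))


class TestCompareTrees:
    def test_identical_trees(self):
        t = "((a,b),(c,d),e);"
        cmp_ = compare_trees(t, t)
        assert cmp_.nrf == 0.0 and cmp_.shared_branch_fraction == 1.0

    def test_disjoint_five_leaf_trees(self):
        cmp_ = compare_trees("((a,b),(c,d),e);", "((a,c),(b,e),d);")
        assert cmp_.nrf == 1.0 and cmp_.shared_branch_fraction == 0.0

    def test_leaf_set_mismatch_is_an_error(self):
        with pytest.raises(ConfigurationError):
            compare_trees("((a,b),(c,d),e);", "((a,b),(c,d),f);")

    def test_matches_exhaustive_bipartition_enumeration(self, rng):
        for n in (5, 6, 7):
            labels = [f"t{i}" for i in range(n)]
            for _ in range(8):
                t1 = _random_trees(rng, labels)
                t2 = _random_trees(rng, labels)
                cmp_ = compare_trees(t1, t2)
                b1 = _tree_bipartitions(t1, labels)
                b2 = _tree_bipartitions(t2, labels)
                assert cmp_.nrf == pytest.approx(len(b1 ^ b2) / (2 * (n - 3)))
                assert cmp_.shared_branch_fraction == pytest.approx(
                    len(b1 & b2) / len(b1))

    def test_invariant_to_rerooting_and_rotation(self, rng):
        from io import StringIO

        from skbio import TreeNode
        t1 = "((a,b),((c,d),e),(f,g));"
        t2 = "((a,c),((b,d),e),(f,g));"
        base = compare_trees(t1, t2)
        tree = TreeNode.read(StringIO(t1))
        rerooted = tree.root_at(tree.find("d").parent)
        cmp_ = compare_trees(str(rerooted).strip(), t2)
        assert cmp_.nrf == pytest.approx(base.nrf)
        assert cmp_.shared_branch_fraction == pytest.approx(
            base.shared_branch_fraction)

    def test_degradation_increases_distortion(self, small_genomes, genome_index):
        """More degradation -> larger median nRF to the original tree."""
        ref_calls = call_dataset(small_genomes, CallingParams("normal"),
                                 genome_index)
        ids = [g.genome_id for g in small_genomes]
        ref_pan = build_pangenome(ref_calls, ids, si=90, cg_threshold=100.0)
        ref_tree = nj_tree(*distance_matrix(
            build_core_alignment(ref_pan, ref_calls)))
        nrf = {"light": [], "heavy": []}
        for seed in range(4):
            for name, profile in (
                    ("light", DegradationProfile(fragmentation_level=4,
                                                 contamination_scope="none")),
                    ("heavy", DegradationProfile(fragmentation_level=12,
                                                 incompleteness_mean=0.03,
                                                 contamination_scope="none"))):
                mags, _ = simulate_dataset(small_genomes, profile, [], seed=50 + seed)
                calls = call_dataset(mags, CallingParams("normal"), genome_index,
                                     seed=seed)
                for c in calls:
                    c.assembly_id = c.assembly_id.replace("_mag", "")
                pan = build_pangenome(calls, ids, si=90, cg_threshold=100.0)
                tree = nj_tree(*distance_matrix(build_core_alignment(pan, calls)))
                nrf[name].append(compare_trees(ref_tree, tree).nrf)
        assert np.median(nrf["heavy"]) >= np.median(nrf["light"])


class TestEnrichment:
    @staticmethod
    def _fake_pan(categories_per_cluster, core_ids):
        cids = list(categories_per_cluster)
        matrix = pd.DataFrame(np.ones((len(cids), 4), dtype=int), index=cids,
                              columns=list("wxyz"))
        partition = {cid: ("core" if cid in core_ids else "shell") for cid in cids}
        return PanGenome(clusters=[], presence_matrix=matrix, si_threshold=90.0,
                         cg_threshold=100.0, partition=partition,
                         cluster_family={cid: cid for cid in cids},
                         representative_seqs={})

    def test_binomial_closed_form(self):
        # 2 of 2 core members in a category with background 0.5 -> p = 0.25
        pan = self._fake_pan({"c1": "J", "c2": "J", "c3": "K", "c4": "K"},
                             core_ids=["c1", "c2"])
        results = enrichment(pan, {"c1": "J", "c2": "J", "c3": "K", "c4": "K"},
                             "core")
        by_cat = {r.category: r for r in results}
        assert by_cat["J"].p_value == pytest.approx(0.25)
        assert by_cat["J"].observed == 2

    def test_single_category_bh_is_identity(self):
        pan = self._fake_pan({"c1": "J", "c2": "J", "c3": "J"}, ["c1"])
        results = enrichment(pan, {c: "J" for c in ("c1", "c2", "c3")}, "core")
        assert results[0].adjusted_p == results[0].p_value

    def test_matches_tail_sum_and_bh_oracle(self, rng):
        cats = list("JKLM")
        assignment = {f"c{i}": cats[int(rng.integers(4))] for i in range(60)}
        core = [f"c{i}" for i in range(0, 60, 3)]
        pan = self._fake_pan(assignment, core)
        results = enrichment(pan, assignment, "core")
        m = len(core)
        counts = pd.Series([assignment[c] for c in core]).value_counts()
        bg = pd.Series(list(assignment.values())).value_counts() / 60
        ps = {}
        for r in results:
            k = int(counts.get(r.category, 0))
            q = bg[r.category]
            tail = sum(binom.pmf(x, m, q) for x in range(k, m + 1))
            assert r.p_value == pytest.approx(tail, abs=1e-12)
            ps[r.category] = r.p_value
        # Benjamini-Hochberg step-up, computed directly
        items = sorted(ps.items(), key=lambda kv: kv[1])
        n = len(items)
        adj_sorted = [min(1.0, p * n / (i + 1)) for i, (_, p) in enumerate(items)]
        for i in range(n - 2, -1, -1):
            adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
        expected = {c: a for (c, _), a in zip(items, adj_sorted)}
        for r in results:
            assert r.adjusted_p == pytest.approx(expected[r.category], abs=1e-12)
            assert r.adjusted_p >= r.p_value

    def test_empty_gene_set_is_an_error(self):
        pan = self._fake_pan({"c1": "J"}, [])
        with pytest.raises(ConfigurationError):
            enrichment(pan, {"c1": "J"}, "core")

    def test_uncategorized_families_are_excluded(self):
        pan = self._fake_pan({"c1": "J", "c2": "SPURIOUS", "c3": "K"},
                             ["c1", "c2"])
        results = enrichment(pan, {"c1": "J", "c2": "SPURIOUS", "c3": "K"}, "core")
        cats = {r.category for r in results}
        assert cats == {"J", "K"}
        by_cat = {r.category: r for r in results}
        assert by_cat["J"].background_fraction == pytest.approx(0.5)
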