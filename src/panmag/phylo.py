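"""Trees from core-gene alignments or gene presence/absence, tree-distance
metrics, and COG-category enrichment.

The single-copy core-gene "alignment" is positional: the generator produces
substitution-only sequences, so every call is a codon-trimmed substring of
its family member and can be placed against the family's longest member by
its offset within the gene; missing ends of partial calls become gap
characters.  Trees are built by neighbour joining on p-distances (gaps
excluded pairwise) or on Jaccard distances of accessory-gene presence.
Topologies are compared with the normalized Robinson-Foulds distance and
the fraction of shared internal branches.

Enrichment of a functional category within a gene set (core, accessory or
unique clusters) uses a one-tailed (upper) binomial test against the
category's background share among all categorized clusters, with
Benjamini-Hochberg adjustment across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import binom
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from statsmodels.stats.multitest import multipletests

from .calling import GeneCall
from .errors import ConfigurationError
from .pangenome import PanGenome

_GAP = ord("-")


@dataclass(frozen=True)
class TreeComparison:
    nrf: float
    shared_branch_fraction: float


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    background_fraction: float
    p_value: float
    adjusted_p: float


# ---------------------------------------------------------------------------
# alignments and distances
# ---------------------------------------------------------------------------

def single_copy_core_clusters(pan: PanGenome,
                              calls: list[GeneCall]) -> dict[str, dict[str, GeneCall]]:
    """Core clusters with exactly one member in every assembly.

    Returns cluster_id -> {assembly_id: call}.
    """
    by_id = {c.call_id: c for c in calls}
    n = pan.n_assemblies
    out = {}
    for cluster in pan.clusters:
        if pan.partition.get(cluster.cluster_id) != "core":
            continue
        members = [by_id[m] for m in cluster.member_call_ids]
        per_assembly = {}
        ok = True
        for m in members:
            if m.assembly_id in per_assembly:
                ok = False
                break
            per_assembly[m.assembly_id] = m
        if ok and len(per_assembly) == n:
            out[cluster.cluster_id] = per_assembly
    return out


def build_core_alignment(pan: PanGenome,
                         calls: list[GeneCall]) -> tuple[list[str], np.ndarray]:
    """Concatenated positional alignment of the single-copy core families.

    Returns (assembly ids, uint8 character matrix); gap columns are ``-``.
    Families are concatenated in deterministic (cluster id) order.
    """
    sc = single_copy_core_clusters(pan, calls)
    if not sc:
        raise ConfigurationError("no single-copy core family to align")
    ids = list(pan.presence_matrix.columns)
    blocks = []
    for cid in sorted(sc):
        members = sc[cid]
        width = max(m.gene_offset + m.length for m in members.values())
        block = np.full((len(ids), width), _GAP, dtype=np.uint8)
        for r, asm in enumerate(ids):
            m = members[asm]
            seq = np.frombuffer(m.sequence.encode(), dtype=np.uint8)
            block[r, m.gene_offset:m.gene_offset + m.length] = seq
        blocks.append(block)
    return ids, np.concatenate(blocks, axis=1)


def distance_matrix(data, kind: str = "p_distance") -> tuple[list[str], np.ndarray]:
    """Symmetric distance matrix with zero diagonal.

    ``p_distance``: data is an (ids, character matrix) alignment; gap
    positions are excluded pairwise (zero overlap is an error).
    ``jaccard``: data is a clusters x assemblies presence/absence DataFrame;
    distances are between assemblies.
    """
    if kind == "p_distance":
        ids, matrix = data
        n = len(ids)
        valid = matrix != _GAP
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                m = int(both.sum())
                if m == 0:
                    raise ConfigurationError(
                        f"no overlapping columns for {ids[i]} vs {ids[j]}")
                d = float((matrix[i, both] != matrix[j, both]).mean())
                dist[i, j] = dist[j, i] = d
        return list(ids), dist
    if kind == "jaccard":
        if isinstance(data, pd.DataFrame):
            ids = list(data.columns)
            mat = data.to_numpy().T.astype(bool)
        else:
            ids, mat = data
            mat = np.asarray(mat, dtype=bool)
        n = len(ids)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                union = int((mat[i] | mat[j]).sum())
                if union == 0:
                    raise ConfigurationError(
                        f"no genes present for pair {ids[i]} vs {ids[j]}")
                inter = int((mat[i] & mat[j]).sum())
                dist[i, j] = dist[j, i] = 1.0 - inter / union
        return list(ids), dist
    raise ConfigurationError(f"unknown distance kind {kind!r}")


# ---------------------------------------------------------------------------
# neighbour joining and tree comparison
# ---------------------------------------------------------------------------

def nj_tree(ids: list[str], dist: np.ndarray) -> str:
    """Neighbour-joining tree (Newick).  Taxa are sorted lexicographically
    before the join loop so tie-breaking is deterministic."""
    dist = np.asarray(dist, dtype=float)
    if len(ids) < 4:
        raise ConfigurationError("neighbour joining needs >= 4 taxa")
    if dist.shape != (len(ids), len(ids)) or not np.allclose(dist, dist.T):
        raise ConfigurationError("distance matrix must be square and symmetric")
    order = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    dm = DistanceMatrix(dist[np.ix_(order, order)], ids_sorted)
    tree = nj(dm)
    return str(tree).strip()


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the leaf-name side not
    containing the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    full = frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def _as_tree(t) -> TreeNode:
    return t if isinstance(t, TreeNode) else TreeNode.read(StringIO(t))


def compare_trees(t1, t2) -> TreeComparison:
    """Normalized Robinson-Foulds distance and shared-branch fraction.

    nRF = |symmetric difference of non-trivial bipartitions| / (2(n-3)) for
    two fully resolved unrooted trees (otherwise the denominator is the
    total bipartition count of both trees); shared_branch_fraction is the
    fraction of the first tree's non-trivial bipartitions present in the
    second.  Both are invariant to leaf order and rooting.
    """
    tree1, tree2 = _as_tree(t1), _as_tree(t2)
    l1 = {t.name for t in tree1.tips()}
    l2 = {t.name for t in tree2.tips()}
    if l1 != l2:
        raise ConfigurationError("trees have different leaf sets")
    n = len(l1)
    b1, b2 = _bipartitions(tree1), _bipartitions(tree2)
    rf = len(b1 ^ b2)
    if len(b1) == len(b2) == n - 3:  # both fully resolved
        denom = 2 * (n - 3)
    else:
        denom = len(b1) + len(b2)
    nrf = rf / denom if denom else 0.0
    shared = len(b1 & b2) / len(b1) if b1 else 1.0
    return TreeComparison(nrf=nrf, shared_branch_fraction=shared)


# ---------------------------------------------------------------------------
# functional enrichment
# ---------------------------------------------------------------------------

_UNCATEGORIZED = {"SPURIOUS", "", None}


def _cluster_categories(pan: PanGenome, categories) -> dict[str, str]:
    out = {}
    for cid, fam in pan.cluster_family.items():
        cat = categories.get(fam)
        if cat not in _UNCATEGORIZED:
            out[cid] = cat
    return out


def gene_set_clusters(pan: PanGenome, gene_set: str) -> list[str]:
    """Cluster ids of the requested pan-genome gene set."""
    counts = pan.presence_matrix.sum(axis=1)
    if gene_set == "core":
        return pan.clusters_in("core")
    if gene_set == "unique":
        return [cid for cid in pan.presence_matrix.index if counts[cid] == 1]
    if gene_set == "accessory":
        core = set(pan.clusters_in("core"))
        return [cid for cid in pan.presence_matrix.index
                if cid not in core and counts[cid] > 1]
    raise ConfigurationError(f"unknown gene set {gene_set!r}")


def enrichment(pan: PanGenome, categories, gene_set: str = "core",
               cluster_ids: list[str] | None = None) -> list[EnrichmentResult]:
    """One-tailed binomial enrichment of each category in a gene set.

    For category c with background fraction q (its share among all
    categorized clusters of the pan-genome) and k of the set's m categorized
    members in c, p = P[Binomial(m, q) >= k]; Benjamini-Hochberg adjustment
    across categories.  ``cluster_ids`` overrides the built-in gene-set
    selection.
    """
    cluster_cat = _cluster_categories(pan, categories)
    if not cluster_cat:
        raise ConfigurationError("no categorized clusters in the pan-genome")
    members = cluster_ids if cluster_ids is not None else gene_set_clusters(pan, gene_set)
    if not members:
        raise ConfigurationError(f"gene set {gene_set!r} is empty")
    set_cats = [cluster_cat[cid] for cid in members if cid in cluster_cat]
    m = len(set_cats)
    if m == 0:
        raise ConfigurationError("gene set has no categorized members")
    background = pd.Series(list(cluster_cat.values())).value_counts()
    total = int(background.sum())
    observed = pd.Series(set_cats).value_counts()
    cats = sorted(background.index)
    ps, rows = [], []
    for c in cats:
        q = background[c] / total
        k = int(observed.get(c, 0))
        p = float(binom.sf(k - 1, m, q))
        ps.append(min(p, 1.0))
        rows.append((c, k, m * q, q))
    adj = multipletests(ps, method="fdr_bh")[1]
    return [EnrichmentResult(category=c, observed=k, expected=e,
                             background_fraction=q, p_value=p,
                             adjusted_p=float(min(max(ap, p), 1.0)))
            for (c, k, e, q), p, ap in zip(rows, ps, adj)]


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame([dict(category=r.category, observed=r.observed,
                       expected=round(r.expected, 3),
                       background_fraction=round(r.background_fraction, 5),
                       p_value=r.p_value, adjusted_p=r.adjusted_p)
                  for r in results]).to_csv(path, sep="\t", index=False)
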