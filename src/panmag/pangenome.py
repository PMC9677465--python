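"""Sequence-identity clustering of gene calls and core-genome classification.

Pairwise identity
-----------------
Identity between two nucleotide sequences is defined on the best end-free
alignment under unit match score with zero mismatch and gap penalties: the
alignment maximises the number of matched columns (ties broken by the
fewest aligned columns), terminal overhangs are free and excluded from the
alignment length, and

    identity = matches / aligned columns.

Excluding the overhangs is what lets a partial gene call (a codon-trimmed
substring of a family member) reach ~100% identity to its full-length
representative, which is exactly the behaviour real clustering tools show
for fragmented genes.  The whole objective is encoded into a single integer
score (``matches * 2^20 - columns``) so a standard local-alignment DP
maximises it directly; the production path decodes ``matches`` and
``columns`` from the optimal score alone.

Two implementations are provided: an exact full dynamic program (via
Biopython's ``PairwiseAligner``) and a seeded, banded dynamic program used
by clustering, which is exact whenever the optimal path stays within the
band around the k-mer-voted diagonal — always the case for the
substitution-only sequences the generator produces (verified against the
full DP in the test suite).  Set ``prefilter=False`` to force the full DP
everywhere.

Clustering and classification
-----------------------------
``greedy_besthit`` processes calls in deterministic order (decreasing
length, then id); each call joins the cluster whose representative it
matches best at or above the identity threshold, else founds a new cluster.
``single_linkage`` takes connected components of the match graph.  The
optional paralog-splitting pass reproduces the Roary-style artefact in
which a contaminant near-copy inside one assembly splits a core family into
sub-clusters that no longer span every assembly.  Clusters are classified
core / soft-core / shell / cloud with the usual prevalence bins (core at
``ceil(t * n / 100)`` assemblies, soft-core >= 95%, shell >= 15%, cloud
below).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from numba import njit

from .calling import GeneCall
from .errors import ConfigurationError
from .species import encode_seq

_B = 1 << 20  # score encoding base: score = matches * _B - columns

_aligner = Align.PairwiseAligner(mode="local", match_score=_B - 1,
                                 mismatch_score=-1, open_gap_score=-1,
                                 extend_gap_score=-1)


def _decode(score: int) -> float:
    if score <= 0:
        return 0.0
    m = -(-score // _B)
    c = m * _B - score
    return m / c if c else 1.0


def pairwise_identity(a: str, b: str) -> float:
    """Exact end-free identity of two sequences, in [0, 1]; symmetric."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    return _decode(int(_aligner.score(a, b)))


@njit(cache=True)
def _banded_score(a: np.ndarray, b: np.ndarray, diag: int, band: int) -> np.int64:
    """Best encoded local score over paths with ``|j - i - diag| <= band``.

    Cell (i, j) aligns a[i] with b[j]; within a row, band slot w corresponds
    to column j = i + diag - band + w.  A diagonal move keeps w, a gap in
    ``b`` (move down) goes to slot w+1 of the previous row, a gap in ``a``
    (move left) comes from slot w-1 of the current row.
    """
    n, m = a.size, b.size
    width = 2 * band + 1
    neg = np.int64(-(1 << 60))
    match = np.int64(_B - 1)
    prev = np.full(width, neg)
    cur = np.full(width, neg)
    best = np.int64(0)
    for i in range(n):
        for w in range(width):
            j = i + diag - band + w
            if j < 0 or j >= m:
                cur[w] = neg
                continue
            sc = np.int64(match if a[i] == b[j] else -1)  # restart (free overhang)
            if i > 0 and j > 0 and prev[w] > neg:
                v = prev[w] + (match if a[i] == b[j] else -1)
                if v > sc:
                    sc = v
            if i > 0 and w + 1 < width and prev[w + 1] > neg:
                v = prev[w + 1] - 1
                if v > sc:
                    sc = v
            if w - 1 >= 0 and cur[w - 1] > neg:
                v = cur[w - 1] - 1
                if v > sc:
                    sc = v
            cur[w] = sc
            if sc > best:
                best = sc
        prev, cur = cur, prev
    return best


def banded_identity(a_arr: np.ndarray, b_arr: np.ndarray, diag: int,
                    band: int = 16) -> float:
    """Identity via the banded DP around ``diag`` (= position in b - position in a)."""
    return _decode(int(_banded_score(a_arr, b_arr, diag, band)))


# ---------------------------------------------------------------------------
# k-mer index for candidate lookup and diagonal voting
# ---------------------------------------------------------------------------

_KMER = 12
_POWERS = (4 ** np.arange(_KMER - 1, -1, -1)).astype(np.int64)


def _kmer_codes(arr: np.ndarray) -> np.ndarray:
    if arr.size < _KMER:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr.astype(np.int64), _KMER)
    return windows @ _POWERS


class _RepIndex:
    """k-mer -> (representative, position) index over cluster representatives.

    Both the index and queries sample every third k-mer.  Because codon
    trimming keeps all call offsets at multiples of 3, a true hit between a
    call and its family representative always lands on positions congruent
    mod 3, so the stride-3 sampling never misses a matching pair.
    """

    def __init__(self, band: int):
        self.band = band
        self.kmers: dict[int, list[tuple[int, int]]] = defaultdict(list)
        self.seqs: list[np.ndarray] = []

    def add(self, arr: np.ndarray) -> int:
        idx = len(self.seqs)
        self.seqs.append(arr)
        kmers = self.kmers
        for i, code in enumerate(_kmer_codes(arr)[::3].tolist()):
            kmers[code].append((idx, 3 * i))
        return idx

    def candidates(self, arr: np.ndarray, min_votes: int = 2,
                   max_candidates: int = 5) -> list[tuple[int, int]]:
        """Representatives sharing k-mers, with the voted diagonal for each."""
        codes = _kmer_codes(arr)[::9]  # coarser query sampling; stays mod-3 aligned
        votes: dict[int, list[int]] = defaultdict(list)
        get = self.kmers.get
        for qpos, code in enumerate(codes.tolist()):
            hits = get(code)
            if hits:
                q9 = qpos * 9
                for idx, rpos in hits:
                    votes[idx].append(rpos - q9)
        ranked = sorted(((len(d), idx) for idx, d in votes.items()
                         if len(d) >= min_votes), reverse=True)
        return [(idx, int(np.median(votes[idx]))) for _, idx in ranked[:max_candidates]]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class GeneCluster:
    cluster_id: str
    representative_call_id: str
    member_call_ids: list[str]


def _sorted_calls(calls: list[GeneCall]) -> list[GeneCall]:
    return sorted(calls, key=lambda c: (-c.length, c.call_id))


def cluster_genes(calls: list[GeneCall], si: float,
                  method: str = "greedy_besthit",
                  prefilter: bool = True, band: int = 16) -> list[GeneCluster]:
    """Cluster calls at sequence-identity threshold ``si`` (percent)."""
    if not (50.0 <= si <= 100.0):
        raise ConfigurationError("si must be in [50,100]")
    threshold = si / 100.0 - 1e-9
    if method == "greedy_besthit":
        return _greedy_cluster(calls, threshold, prefilter, band)
    if method == "single_linkage":
        return _single_linkage(calls, threshold, prefilter, band)
    raise ConfigurationError(f"unknown clustering method {method!r}")


def _greedy_cluster(calls, threshold, prefilter, band) -> list[GeneCluster]:
    ordered = _sorted_calls(calls)
    clusters: list[GeneCluster] = []
    if prefilter:
        index = _RepIndex(band)
    rep_seqs: list[str] = []
    for call in ordered:
        arr = encode_seq(call.sequence)
        best_idx, best_ident = -1, threshold
        if prefilter:
            for idx, diag in index.candidates(arr):
                ident = banded_identity(arr, index.seqs[idx], diag, band)
                if ident > best_ident or (ident == best_ident and best_idx == -1):
                    best_idx, best_ident = idx, ident
        else:
            for idx, rep in enumerate(rep_seqs):
                ident = pairwise_identity(call.sequence, rep)
                if ident > best_ident or (ident == best_ident and best_idx == -1):
                    best_idx, best_ident = idx, ident
        if best_idx >= 0:
            clusters[best_idx].member_call_ids.append(call.call_id)
        else:
            clusters.append(GeneCluster(cluster_id=f"C{len(clusters):05d}",
                                        representative_call_id=call.call_id,
                                        member_call_ids=[call.call_id]))
            rep_seqs.append(call.sequence)
            if prefilter:
                index.add(arr)
    return clusters


def _single_linkage(calls, threshold, prefilter, band) -> list[GeneCluster]:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    ordered = _sorted_calls(calls)
    n = len(ordered)
    rows, cols = [], []
    if prefilter:
        index = _RepIndex(band)
        arrs = [encode_seq(c.sequence) for c in ordered]
        for arr in arrs:
            index.add(arr)
        for i, arr in enumerate(arrs):
            for j, diag in index.candidates(arr, max_candidates=50):
                if j >= i:
                    continue
                if banded_identity(arr, arrs[j], diag, band) >= threshold:
                    rows.append(i)
                    cols.append(j)
    else:
        for i in range(n):
            for j in range(i):
                if pairwise_identity(ordered[i].sequence, ordered[j].sequence) >= threshold:
                    rows.append(i)
                    cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups: dict[int, list[GeneCall]] = defaultdict(list)
    for call, lab in zip(ordered, labels):
        groups[int(lab)].append(call)
    clusters = []
    for members in sorted(groups.values(), key=lambda ms: ms[0].call_id):
        rep = min(members, key=lambda c: (-c.length, c.call_id))
        clusters.append(GeneCluster(cluster_id=f"C{len(clusters):05d}",
                                    representative_call_id=rep.call_id,
                                    member_call_ids=[m.call_id for m in members]))
    return clusters


# ---------------------------------------------------------------------------
# paralog splitting
# ---------------------------------------------------------------------------

def split_paralogs(clusters: list[GeneCluster], calls: list[GeneCall],
                   prefilter: bool = True, band: int = 16) -> list[GeneCluster]:
    """Split clusters that contain several members from one assembly.

    The assembly with the most paralogous members (ties: lexicographically
    first assembly id) seeds one sub-cluster per paralog; every other member
    joins the seed of highest identity (ties: first seed in deterministic
    order).  The pass recurses until no cluster has intra-assembly paralogs.
    It never merges clusters and never changes the multiset of member calls.
    """
    by_id = {c.call_id: c for c in calls}

    def _ident_to_seeds(member: GeneCall, seeds: list[GeneCall]) -> list[float]:
        if not prefilter:
            return [pairwise_identity(member.sequence, s.sequence) for s in seeds]
        index = _seed_index(tuple(s.call_id for s in seeds))
        arr = encode_seq(member.sequence)
        idents = [0.0] * len(seeds)
        for idx, diag in index.candidates(arr, max_candidates=len(seeds)):
            idents[idx] = banded_identity(arr, index.seqs[idx], diag, band)
        return idents

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def _seed_index(seed_ids: tuple[str, ...]) -> _RepIndex:
        index = _RepIndex(band)
        for sid in seed_ids:
            index.add(encode_seq(by_id[sid].sequence))
        return index

    out: list[GeneCluster] = []
    work = [(c.cluster_id, list(c.member_call_ids), c.representative_call_id)
            for c in clusters]
    while work:
        cid, member_ids, rep_id = work.pop(0)
        per_assembly: dict[str, list[str]] = defaultdict(list)
        for mid in member_ids:
            per_assembly[by_id[mid].assembly_id].append(mid)
        max_count = max(len(v) for v in per_assembly.values())
        if max_count <= 1:
            out.append(GeneCluster(cluster_id=cid, representative_call_id=rep_id,
                                   member_call_ids=member_ids))
            continue
        seed_assembly = min(a for a, v in per_assembly.items() if len(v) == max_count)
        seed_ids = sorted(per_assembly[seed_assembly])
        seed_calls = [by_id[s] for s in seed_ids]
        buckets: dict[str, list[str]] = {s: [s] for s in seed_ids}
        for mid in member_ids:
            if mid in buckets:
                continue
            idents = _ident_to_seeds(by_id[mid], seed_calls)
            best = int(np.argmax(idents))  # ties -> first seed in sorted order
            buckets[seed_ids[best]].append(mid)
        for i, s in enumerate(seed_ids):
            work.append((f"{cid}.{i}", buckets[s], s))
    out.sort(key=lambda c: c.cluster_id)
    return out


# ---------------------------------------------------------------------------
# presence/absence and classification
# ---------------------------------------------------------------------------

def build_presence_absence(clusters: list[GeneCluster], assembly_ids: list[str],
                           call_assembly: dict[str, str]) -> pd.DataFrame:
    """Binary clusters x assemblies matrix; cell = 1 iff the cluster has a
    member from the assembly.  Column order follows ``assembly_ids``."""
    col = {a: i for i, a in enumerate(assembly_ids)}
    mat = np.zeros((len(clusters), len(assembly_ids)), dtype=np.int8)
    for r, cluster in enumerate(clusters):
        for mid in cluster.member_call_ids:
            asm = call_assembly.get(mid)
            if asm is None or asm not in col:
                raise ConfigurationError(f"call {mid!r} maps to no known assembly")
            mat[r, col[asm]] = 1
    return pd.DataFrame(mat, index=[c.cluster_id for c in clusters],
                        columns=list(assembly_ids))


def classify_pangenome(matrix: pd.DataFrame, n_assemblies: int,
                       cg_threshold: float,
                       bins: tuple[float, float] = (95.0, 15.0)) -> dict[str, str]:
    """Partition clusters into core / soft_core / shell / cloud."""
    soft_bound, cloud_bound = bins
    if not (0.0 < cg_threshold <= 100.0):
        raise ConfigurationError("cg_threshold must be in (0,100]")
    if cg_threshold < cloud_bound:
        raise ConfigurationError(
            f"cg_threshold {cg_threshold} below the cloud bound {cloud_bound}")
    core_min = -(-cg_threshold * n_assemblies // 100)  # ceil
    counts = matrix.sum(axis=1)
    partition = {}
    for cid, count in counts.items():
        frac = count / n_assemblies
        if count >= core_min:
            partition[cid] = "core"
        elif frac >= soft_bound / 100.0:
            partition[cid] = "soft_core"
        elif frac >= cloud_bound / 100.0:
            partition[cid] = "shell"
        else:
            partition[cid] = "cloud"
    return partition


@dataclass
class PanGenome:
    clusters: list[GeneCluster]
    presence_matrix: pd.DataFrame  # clusters x assemblies, 0/1
    si_threshold: float
    cg_threshold: float
    partition: dict[str, str]
    params: dict = field(default_factory=dict)
    cluster_family: dict[str, str] = field(default_factory=dict)  # oracle labels
    representative_seqs: dict[str, str] = field(default_factory=dict)

    @property
    def n_assemblies(self) -> int:
        return self.presence_matrix.shape[1]

    def clusters_in(self, category: str) -> list[str]:
        return [cid for cid, cat in self.partition.items() if cat == category]

    @property
    def core_count(self) -> int:
        return sum(1 for cat in self.partition.values() if cat == "core")

    def counts(self) -> dict[str, int]:
        out = {"core": 0, "soft_core": 0, "shell": 0, "cloud": 0}
        for cat in self.partition.values():
            out[cat] += 1
        return out

    def reclassified(self, cg_threshold: float) -> "PanGenome":
        """Same clustering, new core-gene threshold."""
        partition = classify_pangenome(self.presence_matrix, self.n_assemblies,
                                       cg_threshold)
        return PanGenome(clusters=self.clusters, presence_matrix=self.presence_matrix,
                         si_threshold=self.si_threshold, cg_threshold=cg_threshold,
                         partition=partition, params=self.params,
                         cluster_family=self.cluster_family,
                         representative_seqs=self.representative_seqs)


def build_pangenome(calls: list[GeneCall], assembly_ids: list[str],
                    si: float = 90.0, cg_threshold: float = 100.0,
                    method: str = "greedy_besthit", paralog_split: bool = False,
                    prefilter: bool = True, band: int = 16) -> PanGenome:
    """Cluster calls, optionally split paralogs, and classify the clusters."""
    clusters = cluster_genes(calls, si, method=method, prefilter=prefilter, band=band)
    if paralog_split:
        clusters = split_paralogs(clusters, calls, prefilter=prefilter, band=band)
    by_id = {c.call_id: c for c in calls}
    call_assembly = {c.call_id: c.assembly_id for c in calls}
    matrix = build_presence_absence(clusters, assembly_ids, call_assembly)
    partition = classify_pangenome(matrix, len(assembly_ids), cg_threshold)
    return PanGenome(
        clusters=clusters, presence_matrix=matrix, si_threshold=si,
        cg_threshold=cg_threshold, partition=partition,
        params=dict(method=method, paralog_split=paralog_split, band=band,
                    prefilter=prefilter),
        cluster_family={c.cluster_id: by_id[c.representative_call_id].family_id
                        for c in clusters},
        representative_seqs={c.cluster_id: by_id[c.representative_call_id].sequence
                             for c in clusters})


def write_pangenome(pan: PanGenome, directory) -> None:
    """Rtab presence/absence, membership CSV, representative FASTA, summary TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pan.presence_matrix.to_csv(directory / "gene_presence_absence.Rtab", sep="\t")
    rows = [dict(cluster_id=c.cluster_id, representative=c.representative_call_id,
                 members=";".join(c.member_call_ids)) for c in pan.clusters]
    pd.DataFrame(rows).to_csv(directory / "clusters.csv", index=False)
    with open(directory / "representatives.fna", "w") as fh:
        for cid, seq in pan.representative_seqs.items():
            fh.write(f">{cid}\n{seq}\n")
    counts = pan.counts()
    pd.DataFrame([dict(category=k, clusters=v) for k, v in counts.items()]).to_csv(
        directory / "partition_summary.tsv", sep="\t", index=False)
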