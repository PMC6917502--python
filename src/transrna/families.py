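"""sRNA family and superfamily clustering, and its shuffle-based null model.

Two grouping levels are used:

* strict *families*: Levenshtein edit distance <= 1 (counting indels), used to
  ask whether the same sRNA is seen in multiple isolates;
* *superfamilies*: modified Hamming distance <= 5, barring indels. Because
  21-24-nt sRNAs of different lengths must cluster without gaps, the modified
  distance slides one sequence along the other and charges each overhanging
  nucleotide one substitution:

      d(a, b) = min over ungapped offsets of (mismatches in overlap
                                              + total overhang length)

Grouping is by single linkage: any chain of pairs within the cutoff merges.
The cutoff's chance-grouping rate is estimated by re-clustering dinucleotide-
preserving shuffles of the same sequences (Euler-path shuffle, which exactly
preserves the dinucleotide multiset and both end nucleotides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .discovery import levenshtein


def modified_hamming(a: str, b: str) -> int:
    """Best ungapped-offset alignment distance: mismatches + overhang length.

    Equal-length sequences at offset 0 reduce to plain Hamming distance.
    Symmetric; zero iff the sequences are identical.
    """
    if not a or not b:
        raise ValueError("modified_hamming requires non-empty sequences")
    m, n = len(a), len(b)
    best = m + n  # worse than any real alignment with overlap >= 1
    for offset in range(-(n - 1), m):
        lo, hi = max(0, offset), min(m, offset + n)
        overlap = hi - lo
        mismatches = sum(1 for i in range(lo, hi) if a[i] != b[i - offset])
        overhang = m + n - 2 * overlap
        best = min(best, mismatches + overhang)
    return best


def _best_offset(anchor: str, member: str, lo: int, hi: int) -> int:
    """Offset of ``member`` against ``anchor`` minimizing the modified-Hamming
    objective, restricted to offsets in [lo, hi] (ties -> smallest offset)."""
    best_offset, best_cost = lo, None
    m, n = len(anchor), len(member)
    for offset in range(lo, hi + 1):
        olo, ohi = max(0, offset), min(m, offset + n)
        mism = sum(1 for i in range(olo, ohi) if anchor[i] != member[i - offset])
        cost = mism + (m + n - 2 * (ohi - olo))
        if best_cost is None or cost < best_cost:
            best_offset, best_cost = offset, cost
    return best_offset


@dataclass
class Superfamily:
    """A single-linkage cluster of sRNAs with a gapless padded alignment."""

    id: str
    members: list[tuple[str, str]]  # (isolate_id, sequence)
    msa: list[str]  # one padded row per member, width = max member length
    size: int

    def isolate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for isolate, _ in self.members:
            counts[isolate] = counts.get(isolate, 0) + 1
        return counts


def _pad_members(seqs: Sequence[str]) -> list[str]:
    """Gapless end-padded alignment: the longest member anchors at offset 0,
    every other member sits at its best in-bounds ungapped offset."""
    width = max(len(s) for s in seqs)
    anchor = min((s for s in seqs if len(s) == width))
    rows = []
    for s in seqs:
        offset = 0 if s == anchor else _best_offset(anchor, s, 0, width - len(s))
        rows.append("-" * offset + s + "-" * (width - len(s) - offset))
    return rows


def cluster_families(
    srnas: Sequence[tuple[str, str]],
    max_dist: float = 5,
    metric: Callable[[str, str], float] = modified_hamming,
    id_prefix: str = "SupFam",
) -> list[Superfamily]:
    """Single-linkage clustering of (isolate, sequence) pairs under ``metric``.

    Components are reported in decreasing size, ties broken by the
    lexicographically smallest member sequence; ids are assigned in that
    order (``SupFam_1`` the largest). Duplicate sequences from different
    isolates count as distinct members but contribute one clustering node.
    """
    seqs = sorted({seq for _, seq in srnas})
    index = {s: i for i, s in enumerate(seqs)}
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if metric(seqs[i], seqs[j]) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[tuple[str, str]]] = {}
    for isolate, seq in srnas:
        groups.setdefault(find(index[seq]), []).append((isolate, seq))
    ordered = sorted(
        groups.values(), key=lambda members: (-len(members), min(s for _, s in members))
    )
    out = []
    for rank, members in enumerate(ordered, start=1):
        members = sorted(members)
        out.append(
            Superfamily(
                id=f"{id_prefix}_{rank}",
                members=members,
                msa=_pad_members([s for _, s in members]),
                size=len(members),
            )
        )
    return out


def cluster_strict_families(
    srnas: Sequence[tuple[str, str]], max_dist: int = 1
) -> list[Superfamily]:
    """Strict family grouping by Levenshtein edit distance (default <= 1)."""
    return cluster_families(
        srnas,
        max_dist=max_dist,
        metric=lambda a, b: levenshtein(a, b),
        id_prefix="Fam",
    )


def membership_table(clusters: Sequence[Superfamily]) -> "pd.DataFrame":
    """Cluster-by-isolate member-count matrix (upset-style bookkeeping)."""
    import pandas as pd

    isolates = sorted({iso for c in clusters for iso, _ in c.members})
    rows = [
        {"id": c.id, "size": c.size, **{iso: c.isolate_counts().get(iso, 0) for iso in isolates}}
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["id", "size", *isolates])


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Euler-path / Altschul-Erickson)


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide multiset and both end
    nucleotides, by randomizing the Eulerian path through the dinucleotide
    multigraph. Deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(seq) < 3:
        return seq
    chars = list(seq)
    vertices = list(dict.fromkeys(chars))
    if len(vertices) == 1:
        return seq
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(chars, chars[1:]):
        edges[a].append(b)
    first, last = chars[0], chars[-1]
    # choose a random final out-edge per non-terminal vertex such that every
    # vertex reaches `last` through the chosen edges (guarantees an Euler path)
    while True:
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices if v != last
        }
        if all(_reaches(v, last, last_edge) for v in vertices if v != last):
            break
    out_edges: dict[str, list[str]] = {}
    for v in vertices:
        pool = edges[v].copy()
        if v != last:
            pool.remove(last_edge[v])
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        if v != last:
            pool.append(last_edge[v])
        out_edges[v] = pool
    result = [first]
    cursor = {v: 0 for v in vertices}
    node = first
    for _ in range(len(chars) - 1):
        nxt = out_edges[node][cursor[node]]
        cursor[node] += 1
        result.append(nxt)
        node = nxt
    return "".join(result)


def _reaches(start: str, target: str, last_edge: dict[str, str]) -> bool:
    seen = set()
    node = start
    while node != target:
        if node in seen or node not in last_edge:
            return False
        seen.add(node)
        node = last_edge[node]
    return True


# ---------------------------------------------------------------------------
# Clustering-by-chance null


@dataclass
class ClusteringNull:
    """Observed vs shuffled grouping rates for the superfamily cutoff."""

    real_seq_fraction: float  # fraction of sequences in multi-member clusters
    real_cluster_fraction: float  # fraction of clusters with > 1 member
    null_seq_fractions: list[float]
    null_cluster_fractions: list[float]


def _grouping_rates(clusters: Sequence[Superfamily]) -> tuple[float, float]:
    n_seqs = sum(c.size for c in clusters)
    if not clusters or n_seqs == 0:
        return 0.0, 0.0
    grouped = sum(c.size for c in clusters if c.size > 1)
    multi = sum(1 for c in clusters if c.size > 1)
    return grouped / n_seqs, multi / len(clusters)


def clustering_null(
    srnas: Sequence[tuple[str, str]],
    max_dist: float = 5,
    n_reps: int = 10,
    seed: int = 0,
) -> ClusteringNull:
    """Estimate how often the superfamily cutoff groups sequences by chance.

    Each replicate dinucleotide-shuffles every sRNA and re-clusters; the
    summary reports, per replicate, the fraction of sequences landing in
    multi-member clusters (and the analogous per-cluster rate) alongside the
    same rates for the real sequences.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    real_seq, real_cluster = _grouping_rates(cluster_families(srnas, max_dist=max_dist))
    rng = np.random.default_rng(seed)
    null_seq, null_cluster = [], []
    for _ in range(n_reps):
        shuffled = [(iso, dinucleotide_shuffle(seq, rng)) for iso, seq in srnas]
        fs, fc = _grouping_rates(cluster_families(shuffled, max_dist=max_dist))
        null_seq.append(fs)
        null_cluster.append(fc)
    return ClusteringNull(real_seq, real_cluster, null_seq, null_cluster)
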