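"""Agglomerative hierarchical-clustering scaffolding from Hi-C contacts.

The flow mirrors proximity-ligation scaffolding practice: seed one cluster
per chromosome with large, mutually contact-poor contigs; grow clusters by
unique assignability (a contig joins only when its best normalized linkage
beats the runner-up by a margin); merge or split clusters on internal
signal; then order and orient each cluster by greedily chaining contig ends
through an end-window linkage graph.  The output is an AGP v2.1 layout and
a gapped scaffold FASTA.

All steps are deterministic: ties break by contig length, then identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import revcomp
from .hicmap import (ContactMatrix, MisjoinCall, bin_contacts, break_contigs,
                     default_bin_size, misjoin_scan, remap_pairs)


@dataclass
class Cluster:
    cluster_id: int
    members: list[str]


@dataclass
class ScaffoldConfig:
    n_seeds: int = 3
    bin_size: Optional[int] = None
    ratio: float = 3.0
    min_linkage: Optional[float] = None   # default: 5th pct of nonzero linkages
    end_window: int = 5
    merge_ratio: float = 0.5
    split_ratio: float = 0.1
    max_iter: int = 20
    misjoin_window: int = 5
    misjoin_threshold: float = 0.25
    gap_size: int = 100


# ---------------------------------------------------------------------------
# contig-level linkage helpers
# ---------------------------------------------------------------------------

def _contig_arrays(m: ContactMatrix):
    order = m.contig_order()
    lens = np.array([m.contig_lengths[c] for c in order], dtype=float)
    counts = m.contig_matrix()
    np.fill_diagonal(counts, 0.0)  # internal contacts are not linkage
    return order, lens, counts


def pair_linkage(counts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Length-normalized contig-pair linkage: contacts / (len_i * len_j)."""
    return counts / np.outer(lens, lens)


def bottleneck_linkage(link: np.ndarray) -> np.ndarray:
    """Minimax-path (bottleneck) linkage between all contig pairs.

    The strength of the best path between two contigs, where a path is as
    strong as its weakest edge.  Two contigs of one chromosome are joined by
    a chain of adjacent contigs with very strong direct linkage, so their
    bottleneck stays high even when their own contact count is zero; across
    chromosomes every path must traverse a background-level edge.  Minimax
    paths all run along the maximum spanning tree, so the matrix follows
    from one MST and a traversal per node.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import minimum_spanning_tree

    n = link.shape[0]
    mst = minimum_spanning_tree(csr_matrix(-link)).toarray()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j in zip(*np.nonzero(mst)):
        adj[i].append((j, -mst[i, j]))
        adj[j].append((i, -mst[i, j]))
    out = np.zeros((n, n))
    for s in range(n):
        stack = [(s, np.inf)]
        seen = {s}
        while stack:
            u, mn = stack.pop()
            if u != s:
                out[s, u] = mn
            for v, wt in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append((v, min(mn, wt)))
    return out


def seed_clusters(m: ContactMatrix, n_seeds: int,
                  pool_size: Optional[int] = None) -> list[Cluster]:
    """Pick ``n_seeds`` mutually contact-poor contigs from the longest ones.

    Greedy: start from the longest contig in the candidate pool (the
    ``pool_size`` longest, default max(3*n_seeds, 8)); repeatedly add the
    candidate whose maximum normalized linkage to the chosen set is
    smallest.  Ties break by length, then lexical id.

    Linkage here is the bottleneck (minimax-path) form of the normalized
    pair linkage: direct contact counts between distant parts of one
    chromosome fall to the trans background, but the chain of strongly
    linked neighbours connecting them does not, so the bottleneck keeps
    same-chromosome candidates apart from genuinely independent ones.
    """
    order, lens, counts = _contig_arrays(m)
    if n_seeds > len(order):
        raise ValueError("n_seeds exceeds number of contigs")
    if pool_size is None:
        pool_size = max(3 * n_seeds, 8)
    pool_size = min(pool_size, len(order))
    link = bottleneck_linkage(pair_linkage(counts, lens))

    by_len = sorted(range(len(order)),
                    key=lambda i: (-lens[i], order[i]))
    pool = by_len[:pool_size]
    chosen = [pool[0]]
    remaining = pool[1:]
    while len(chosen) < n_seeds:
        best = min(remaining,
                   key=lambda i: (max(link[i, j] for j in chosen),
                                  -lens[i], order[i]))
        chosen.append(best)
        remaining.remove(best)
    return [Cluster(k, [order[i]]) for k, i in enumerate(chosen)]


def _cluster_linkage(ci: int, members_idx: list[int], counts, lens) -> float:
    """Contig-to-cluster linkage: contact sum / (contig bp x cluster bp).

    Normalizing by the cluster's total length (rather than per member) keeps
    the background trans linkage flat as clusters grow, so the unique-
    assignability ratio compares a local cis signal against a size-stable
    noise floor.
    """
    s = sum(counts[ci, j] for j in members_idx)
    return s / (lens[ci] * sum(lens[j] for j in members_idx))


def assign_contigs(clusters: list[Cluster], m: ContactMatrix,
                   ratio: float = 3.0,
                   min_linkage: Optional[float] = None
                   ) -> tuple[list[Cluster], set[str]]:
    """Grow clusters by unique assignability, iterated to a fixpoint.

    A contig is assigned when its best cluster linkage is at least
    ``min_linkage`` and exceeds the second best by ``ratio``.  Assignments
    within a sweep are computed against the same cluster state, so the
    result does not depend on contig processing order.
    """
    order, lens, counts = _contig_arrays(m)
    idx = {c: i for i, c in enumerate(order)}
    link = pair_linkage(counts, lens)
    if min_linkage is None:
        nz = link[np.triu_indices_from(link, k=1)]
        nz = nz[nz > 0]
        min_linkage = float(np.percentile(nz, 5)) if nz.size else 0.0

    clusters = [Cluster(c.cluster_id, list(c.members)) for c in clusters]
    assigned = {cid for c in clusters for cid in c.members}
    unassigned = [c for c in order if c not in assigned]

    changed = True
    while changed and unassigned:
        changed = False
        member_idx = [[idx[cid] for cid in c.members] for c in clusters]
        decisions = []
        for cid in unassigned:
            ci = idx[cid]
            scores = [_cluster_linkage(ci, mi, counts, lens)
                      for mi in member_idx]
            ranked = sorted(range(len(scores)), key=lambda k: -scores[k])
            best, second = scores[ranked[0]], (
                scores[ranked[1]] if len(scores) > 1 else 0.0)
            if best >= min_linkage and (second == 0 or best / second >= ratio):
                decisions.append((cid, ranked[0]))
        for cid, k in decisions:
            clusters[k].members.append(cid)
            unassigned.remove(cid)
            changed = True
    return clusters, set(unassigned)


def evict_misfits(clusters: list[Cluster], m: ContactMatrix
                  ) -> tuple[list[Cluster], set[str]]:
    """Return wrongly assigned contigs to the pool.

    Re-checks every member of a multi-contig cluster against the current
    cluster state: if its linkage to some other cluster exceeds its
    leave-one-out linkage to its own, it is evicted.  All misfits are
    identified against the same state and removed together, so the result
    does not depend on member processing order.  Singleton clusters are
    exempt (a lone member has no within-cluster linkage to compare).
    """
    order, lens, counts = _contig_arrays(m)
    idx = {c: i for i, c in enumerate(order)}
    evicted: set[str] = set()
    for k, cl in enumerate(clusters):
        if len(cl.members) < 2:
            continue
        for cid in cl.members:
            ci = idx[cid]
            own = _cluster_linkage(
                ci, [idx[x] for x in cl.members if x != cid], counts, lens)
            for k2, other in enumerate(clusters):
                if k2 == k:
                    continue
                mx = [idx[x] for x in other.members]
                if _cluster_linkage(ci, mx, counts, lens) > own:
                    evicted.add(cid)
                    break
    if not evicted:
        return clusters, evicted
    out = [Cluster(c.cluster_id, [x for x in c.members if x not in evicted])
           for c in clusters]
    return [c for c in out if c.members], evicted


# ---------------------------------------------------------------------------
# merge / split
# ---------------------------------------------------------------------------

def _density(members: list[int], counts, lens) -> Optional[float]:
    if len(members) < 2:
        return None
    c = lp = 0.0
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            i, j = members[a], members[b]
            c += counts[i, j]
            lp += lens[i] * lens[j]
    return c / lp if lp > 0 else 0.0


def _between_density(ma: list[int], mb: list[int], counts, lens) -> float:
    c = lp = 0.0
    for i in ma:
        for j in mb:
            c += counts[i, j]
            lp += lens[i] * lens[j]
    return c / lp if lp > 0 else 0.0


def _best_spectral_cut(w: np.ndarray, members: list[int], counts, lens
                       ) -> Optional[tuple[np.ndarray, float]]:
    """Lowest-cross-density prefix cut along the sorted Fiedler vector.

    Orders the cluster's contigs by the second Laplacian eigenvector and
    evaluates every prefix/suffix bipartition, returning the one with the
    smallest between-density (and that density); None if degenerate.
    """
    n = w.shape[0]
    if n < 2:
        return None
    lap = np.diag(w.sum(axis=1)) - w
    _, vecs = np.linalg.eigh(lap)
    order = np.argsort(vecs[:, 1], kind="stable")
    best = None
    for cut in range(1, n):
        part = np.zeros(n, dtype=bool)
        part[order[:cut]] = True
        ga = [members[i] for i in range(n) if part[i]]
        gb = [members[i] for i in range(n) if not part[i]]
        cd = _between_density(ga, gb, counts, lens)
        if best is None or cd < best[1]:
            best = (part, cd)
    return best


def merge_split(clusters: list[Cluster], m: ContactMatrix,
                merge_ratio: float = 0.5, split_ratio: float = 0.1,
                max_iter: int = 20) -> list[Cluster]:
    """Merge clusters with strong mutual signal; split weakly-cut clusters.

    Merge when between-density >= merge_ratio * min(within-densities); a
    singleton (no within-density) adopts its partner's.  Split a cluster
    when a spectral bipartition has cross-density <= split_ratio * its
    within-density.  Iterates to a fixpoint or ``max_iter``.
    """
    order, lens, counts = _contig_arrays(m)
    idx = {c: i for i, c in enumerate(order)}
    link = pair_linkage(counts, lens)
    clusters = [Cluster(c.cluster_id, list(c.members)) for c in clusters]

    for _ in range(max_iter):
        changed = False
        # merges
        while True:
            mem = [[idx[c] for c in cl.members] for cl in clusters]
            within = [_density(mi, counts, lens) for mi in mem]
            best_pair, best_score = None, 0.0
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    bd = _between_density(mem[a], mem[b], counts, lens)
                    wa = within[a] if within[a] is not None else within[b]
                    wb = within[b] if within[b] is not None else within[a]
                    if wa is None:  # both singletons: no internal reference
                        continue
                    ref = min(wa, wb)
                    if ref <= 0:
                        continue
                    if bd >= merge_ratio * ref and bd > best_score:
                        best_pair, best_score = (a, b), bd
            if best_pair is None:
                break
            a, b = best_pair
            clusters[a].members.extend(clusters[b].members)
            del clusters[b]
            changed = True
        # splits
        new_clusters: list[Cluster] = []
        next_id = max((c.cluster_id for c in clusters), default=-1) + 1
        for cl in clusters:
            mi = [idx[c] for c in cl.members]
            wd = _density(mi, counts, lens)
            cut = None
            if wd is not None and wd > 0 and len(mi) >= 2:
                sub = link[np.ix_(mi, mi)].copy()
                np.fill_diagonal(sub, 0.0)
                cut = _best_spectral_cut(sub, mi, counts, lens)
            if cut is not None:
                part, cd = cut
                ga = [mi[i] for i in range(len(mi)) if part[i]]
                gb = [mi[i] for i in range(len(mi)) if not part[i]]
                if cd <= split_ratio * wd:
                    new_clusters.append(
                        Cluster(cl.cluster_id, [order[i] for i in ga]))
                    new_clusters.append(
                        Cluster(next_id, [order[i] for i in gb]))
                    next_id += 1
                    changed = True
                    continue
            new_clusters.append(cl)
        clusters = new_clusters
        if not changed:
            break
    return clusters


# ---------------------------------------------------------------------------
# order & orient
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldLayout:
    """Ordered, oriented contig placements: (contig_id, strand, gap_after)."""

    placements: list[tuple[str, str, int]] = field(default_factory=list)

    def contig_order(self) -> list[str]:
        return [cid for cid, _, _ in self.placements]


def _end_windows(m: ContactMatrix, contig: str, w: int):
    lo, hi = m.contig_bin_range(contig)
    n = hi - lo
    w = min(w, n)
    head = list(range(lo, lo + w))
    tail = list(range(hi - w, hi))
    return head, tail


def order_orient(cluster: Cluster, m: ContactMatrix,
                 end_window: int = 5, gap_size: int = 100) -> ScaffoldLayout:
    """Greedy end-to-end chaining of cluster members.

    Each contig contributes a head and a tail node (its first/last
    ``end_window`` bins); candidate joins are ranked by mean contact weight
    between end windows and accepted greedily when both ends are free and the
    join does not close a cycle.  A contig traversed head->tail is "+".
    The path direction is canonicalised (first id <= last id) so output is
    deterministic.
    """
    members = sorted(cluster.members,
                     key=lambda c: (-m.contig_lengths[c], c))
    if len(members) == 1:
        return ScaffoldLayout([(members[0], "+", 0)])

    dense = m.counts.toarray()
    wins = {c: _end_windows(m, c, end_window) for c in members}
    ends = [(c, e) for c in members for e in ("head", "tail")]

    def weight(e1, e2) -> float:
        c1, s1 = e1
        c2, s2 = e2
        b1 = wins[c1][0] if s1 == "head" else wins[c1][1]
        b2 = wins[c2][0] if s2 == "head" else wins[c2][1]
        return float(dense[np.ix_(b1, b2)].sum()) / (len(b1) * len(b2))

    cands = []
    for i in range(len(ends)):
        for j in range(i + 1, len(ends)):
            if ends[i][0] == ends[j][0]:
                continue
            cands.append((weight(ends[i], ends[j]), ends[i], ends[j]))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = {c: c for c in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used: set[tuple] = set()
    joins: dict[tuple, tuple] = {}
    for w_, e1, e2 in cands:
        if w_ <= 0:
            break
        if e1 in used or e2 in used:
            continue
        r1, r2 = find(e1[0]), find(e2[0])
        if r1 == r2:
            continue
        parent[r1] = r2
        used.update((e1, e2))
        joins[e1] = e2
        joins[e2] = e1

    # walk the path(s); with a connected cluster this is one path, but any
    # leftover components are appended deterministically
    layout: list[tuple[str, str]] = []
    visited: set[str] = set()

    def free_end(c):
        if (c, "head") not in joins:
            return (c, "head")
        if (c, "tail") not in joins:
            return (c, "tail")
        return None

    starts = [c for c in members if free_end(c) is not None]
    for start in starts:
        if start in visited:
            continue
        path: list[tuple[str, str]] = []
        cur_end = free_end(start)
        while True:
            c, entry = cur_end
            visited.add(c)
            orient = "+" if entry == "head" else "-"
            path.append((c, orient))
            exit_end = (c, "tail" if entry == "head" else "head")
            nxt = joins.get(exit_end)
            if nxt is None:
                break
            cur_end = nxt
        if path[-1][0] < path[0][0]:  # canonical direction
            path = [(c, "+" if o == "-" else "-") for c, o in reversed(path)]
        layout.extend(path)
    for c in members:  # isolated members (cycle-guard leftovers)
        if c not in visited:
            layout.append((c, "+"))

    placements = [(c, o, gap_size) for c, o in layout]
    if placements:
        placements[-1] = (placements[-1][0], placements[-1][1], 0)
    return ScaffoldLayout(placements)


# ---------------------------------------------------------------------------
# driver + output
# ---------------------------------------------------------------------------

def n50(lengths: Sequence[int]) -> int:
    """Largest L such that pieces >= L sum to at least half the total."""
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2.0
    acc = 0
    for x in arr:
        acc += x
        if acc >= half:
            return x
    return arr[-1]


def scaffold(pairs: pd.DataFrame, contigs: Mapping[str, str],
             config: ScaffoldConfig = ScaffoldConfig()
             ) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Full pipeline: bin -> misjoin-break -> seed -> assign -> merge/split
    -> order/orient.  Returns (AGP table, scaffold FASTA dict, report).
    """
    contigs = dict(contigs)
    genome_size = sum(len(s) for s in contigs.values())
    bin_size = config.bin_size or default_bin_size(genome_size)
    lengths = {c: len(s) for c, s in contigs.items()}

    m0 = bin_contacts(pairs, lengths, bin_size)
    calls = misjoin_scan(m0, window=config.misjoin_window,
                         threshold=config.misjoin_threshold)
    if calls:
        contigs, mapping = break_contigs(contigs, calls)
        pairs = remap_pairs(pairs, mapping)
        lengths = {c: len(s) for c, s in contigs.items()}
    m = bin_contacts(pairs, lengths, bin_size)

    if m.total_pairs() == 0:
        layouts = [ScaffoldLayout([(c, "+", 0)]) for c in sorted(contigs)]
        clusters, unassigned = [], set(contigs)
    else:
        clusters = seed_clusters(m, config.n_seeds)
        unassigned: set[str] = set()
        # alternate growth and refinement: a contig evicted or split off as
        # a contaminant returns to the pool and can be re-assigned, and
        # contigs whose ratio test was poisoned by a contaminated cluster
        # become assignable once the cluster is clean
        prev_state = None
        for _ in range(config.max_iter):
            clusters, unassigned = assign_contigs(
                clusters, m, ratio=config.ratio,
                min_linkage=config.min_linkage)
            clusters, _evicted = evict_misfits(clusters, m)
            clusters = merge_split(clusters, m,
                                   merge_ratio=config.merge_ratio,
                                   split_ratio=config.split_ratio,
                                   max_iter=config.max_iter)
            multis = [c for c in clusters if len(c.members) > 1]
            if multis:
                singles = [c.members[0] for c in clusters
                           if len(c.members) == 1]
                unassigned.update(singles)
                clusters = multis
            state = tuple(sorted(tuple(sorted(c.members))
                                 for c in clusters))
            if state == prev_state:
                break
            prev_state = state
        layouts = [order_orient(cl, m, config.end_window, config.gap_size)
                   for cl in clusters]
        layouts.extend(ScaffoldLayout([(c, "+", 0)])
                       for c in sorted(unassigned))

    agp = build_agp(layouts, lengths, gap_size=config.gap_size)
    fasta = build_scaffold_fasta(layouts, contigs, gap_size=config.gap_size)
    report = {
        "n_contigs": len(contigs),
        "n_scaffolds": len(layouts),
        "misjoins_broken": len(calls),
        "cluster_sizes": sorted((len(l.placements) for l in layouts),
                                reverse=True),
        "unassigned": sorted(unassigned),
        "n50_contigs": n50(list(lengths.values())),
        "n50_scaffolds": n50([len(s) for s in fasta.values()]),
    }
    return agp, fasta, report


def build_agp(layouts: Sequence[ScaffoldLayout], lengths: Mapping[str, int],
              gap_size: int = 100) -> pd.DataFrame:
    """AGP v2.1 rows (1-based inclusive coordinates)."""
    rows = []
    for si, layout in enumerate(layouts):
        sid = f"scaffold{si + 1:03d}"
        pos, part = 1, 1
        for i, (cid, strand, _) in enumerate(layout.placements):
            L = lengths[cid]
            rows.append((sid, pos, pos + L - 1, part, "W", cid, 1, L, strand))
            pos += L
            part += 1
            if i < len(layout.placements) - 1:
                rows.append((sid, pos, pos + gap_size - 1, part, "N", gap_size,
                             "scaffold", "yes", "proximity_ligation"))
                pos += gap_size
                part += 1
    return pd.DataFrame(rows, columns=[
        "object", "object_beg", "object_end", "part_number", "component_type",
        "component_id", "component_beg", "component_end", "orientation"])


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def build_scaffold_fasta(layouts: Sequence[ScaffoldLayout],
                         contigs: Mapping[str, str],
                         gap_size: int = 100) -> dict[str, str]:
    out = {}
    gap = "N" * gap_size
    for si, layout in enumerate(layouts):
        parts = []
        for cid, strand, _ in layout.placements:
            seq = contigs[cid]
            parts.append(seq if strand == "+" else revcomp(seq))
        out[f"scaffold{si + 1:03d}"] = gap.join(parts)
    return out
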