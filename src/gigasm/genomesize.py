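"""Genome-size estimation and genome-size evolution.

Three estimators of haploid genome size are provided: the k-mer spectrum
(total k-mers above the error trough divided by the coverage-peak
multiplicity), the alignment-fraction extrapolation (assembly size divided
by the fraction of reads it absorbs), and the classical c-value conversion
(1 pg = 978 Mb of double-stranded DNA).

Genome-size evolution on a time tree is modelled as Brownian motion.  The
ancestral states that maximise the joint BM likelihood coincide, for a
Gaussian process, with the conditional expectations given the tips, so they
solve a sparse linear system in the tree Laplacian weighted by inverse
branch lengths.  The BM rate sigma^2 is estimated by REML on the tip
contrasts; conditional variances give standard errors and 95% intervals.
Per-branch expansion rates are signed finite differences of the
reconstructed states over branch durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

BP_PER_PG = 978e6  # standard conversion, 1 pg ~ 978 Mb


# ---------------------------------------------------------------------------
# k-mer spectrum
# ---------------------------------------------------------------------------

@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]  # multiplicity -> number of distinct k-mers

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def kmer_histogram(reads: Mapping[str, str] | Sequence[str], k: int
                   ) -> KmerHistogram:
    """Histogram of canonical k-mer multiplicities over all reads.

    Canonical form is the lexicographic minimum of a k-mer and its reverse
    complement.  k must be odd (no self-complementary k-mers) and in
    [11, 31] so codes fit in 64 bits.  Reads shorter than k are skipped.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    seqs = reads.values() if isinstance(reads, Mapping) else reads
    powers = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    chunks = []
    for seq in seqs:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if codes.size < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        fwd = win.astype(np.uint64) @ powers
        rc = (np.uint64(3) - win[:, ::-1].astype(np.uint64)) @ powers
        chunks.append(np.minimum(fwd, rc))
    if not chunks:
        return KmerHistogram(k, {})
    _, mult = np.unique(np.concatenate(chunks), return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerHistogram(k, {int(m): int(c) for m, c in zip(ms, cs)})


def estimate_size_kmer(h: KmerHistogram, min_multiplicity: int = 2,
                       centroid_halfwidth: int = 12) -> float:
    """Genome size from a k-mer spectrum: total above the trough / peak depth.

    The error trough is the first multiplicity (>= ``min_multiplicity``)
    where counts start rising; the coverage peak is the modal multiplicity
    beyond it, located on a lightly smoothed spectrum (5-bin moving average).
    The peak depth used in the division is the count-weighted centroid of the
    ``centroid_halfwidth`` bins around the mode: adjacent k-mers share reads,
    so the spectrum has few independent samples and its raw mode jitters,
    while the peak centroid concentrates.  Narrow the window when a nearby
    repeat shoulder must be excluded.  A spectrum with no rise (flat or
    monotone decreasing) is inestimable and raises.
    """
    if not h.counts:
        raise ValueError("empty histogram: genome size inestimable")
    max_m = max(h.counts)
    counts = np.zeros(max_m + 2)
    for m, c in h.counts.items():
        counts[m] = c
    trough = None
    for m in range(max(1, min_multiplicity), max_m):
        if counts[m] < counts[m + 1]:
            trough = m
            break
    if trough is None:
        raise ValueError("no coverage peak above the error trough: "
                         "genome size inestimable")
    region = counts[trough + 1:max_m + 1]
    if region.size >= 5:
        kernel = np.ones(5) / 5.0
        smoothed = np.convolve(region, kernel, mode="same")
    else:
        smoothed = region
    mode = trough + 1 + int(np.argmax(smoothed))
    # refine the peak position by its local centroid: the mode of a sparse
    # histogram jitters between near-equal bins, the centroid does not
    lo = max(trough + 1, mode - centroid_halfwidth)
    hi = min(max_m, mode + centroid_halfwidth)
    ms = np.arange(lo, hi + 1)
    weights = counts[lo:hi + 1]
    peak = float((ms * weights).sum() / weights.sum())
    total = sum(m * c for m, c in h.counts.items() if m > trough)
    return total / peak


def estimate_size_alnfrac(assembly_size: float, aligned_fraction: float) -> float:
    """Total genome size implied by the read fraction an assembly absorbs."""
    if not 0.0 < aligned_fraction <= 1.0:
        raise ValueError("aligned_fraction must be in (0, 1]")
    return assembly_size / aligned_fraction


def cvalue_to_bp(c_value_pg: float) -> float:
    """Haploid DNA content in pg -> bp (978 Mb per pg)."""
    if c_value_pg <= 0:
        raise ValueError("c-value must be positive")
    return c_value_pg * BP_PER_PG


def bp_to_cvalue(bp: float) -> float:
    if bp <= 0:
        raise ValueError("genome size must be positive")
    return bp / BP_PER_PG


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

@dataclass
class SizeTree:
    """A time tree (branch lengths in Myr) with genome sizes at the tips (Gb).

    After :func:`asr_bm`, internal nodes carry ``states`` (and standard
    errors) keyed by a stable node label: tip taxon labels for leaves,
    ``nodeN`` for internal nodes in preorder.
    """

    tree: dendropy.Tree
    tip_sizes: dict[str, float]
    states: dict[str, float] = field(default_factory=dict)
    state_se: dict[str, float] = field(default_factory=dict)
    sigma2: Optional[float] = None

    @classmethod
    def from_newick(cls, newick: str, tip_sizes: Mapping[str, float]
                    ) -> "SizeTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree=tree, tip_sizes=dict(tip_sizes))

    def node_labels(self) -> dict:
        """Stable labels: taxon label for leaves, nodeN preorder otherwise."""
        labels, n = {}, 0
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                labels[nd] = nd.taxon.label
            else:
                labels[nd] = f"node{n}"
                n += 1
        return labels

    def to_newick(self) -> str:
        labels = self.node_labels()
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf() and labels[nd] in self.states:
                nd.label = f"{self.states[labels[nd]]:.6g}"
        return self.tree.as_string(schema="newick").strip()


def _edges(tree: dendropy.Tree, labels: dict):
    """(parent_label, child_label, length) for all non-root edges."""
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = nd.edge.length
            if bl is None or bl <= 0:
                raise ValueError("all branch lengths must be positive")
            out.append((labels[nd.parent_node], labels[nd], float(bl)))
    return out


def asr_bm(stree: SizeTree) -> SizeTree:
    """ML ancestral states under Brownian motion, with standard errors.

    Maximising the joint BM likelihood over internal states is a weighted
    least-squares problem on the tree graph: minimise
    sum over edges (x_child - x_parent)^2 / t with tips fixed, i.e. a
    Laplacian solve.  For a Gaussian process this joint mode equals the
    conditional mean given the tips (the GLS / empirical-Bayes estimate).
    sigma^2 is REML (n-1 denominator on the GLS residual quadratic form);
    standard errors come from the conditional covariance
    sigma^2 * inv(L_internal).
    """
    labels = stree.node_labels()
    tips = [labels[nd] for nd in stree.tree.leaf_node_iter()]
    internal = [labels[nd] for nd in stree.tree.preorder_node_iter()
                if not nd.is_leaf()]
    missing = [t for t in tips if t not in stree.tip_sizes]
    if missing:
        raise ValueError(f"tip sizes missing for {missing}")
    edges = _edges(stree.tree, labels)

    all_nodes = tips + internal
    pos = {n: i for i, n in enumerate(all_nodes)}
    n_all, n_tip = len(all_nodes), len(tips)
    lap = np.zeros((n_all, n_all))
    for pa, ch, t in edges:
        w = 1.0 / t
        i, j = pos[pa], pos[ch]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
    y = np.array([stree.tip_sizes[t] for t in tips])
    L_ii = lap[n_tip:, n_tip:]
    L_it = lap[n_tip:, :n_tip]
    x_int = np.linalg.solve(L_ii, -L_it @ y)

    # REML sigma^2 via the tip covariance (shared root-path lengths)
    C = _tip_covariance(stree.tree, labels, tips)
    Cinv = np.linalg.inv(C)
    one = np.ones(len(tips))
    mu = (one @ Cinv @ y) / (one @ Cinv @ one)
    resid = y - mu
    sigma2 = float(resid @ Cinv @ resid / (len(tips) - 1))

    cond_var = sigma2 * np.linalg.inv(L_ii).diagonal()
    states = dict(zip(tips, y.tolist()))
    states.update(zip(internal, x_int.tolist()))
    se = {n: 0.0 for n in tips}
    se.update(zip(internal, np.sqrt(np.maximum(cond_var, 0.0)).tolist()))
    return SizeTree(tree=stree.tree, tip_sizes=dict(stree.tip_sizes),
                    states=states, state_se=se, sigma2=sigma2)


def _tip_covariance(tree: dendropy.Tree, labels: dict, tips: list) -> np.ndarray:
    """BM tip covariance: C[i, j] = root-to-MRCA path length (one traversal)."""
    depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + float(nd.edge.length)
    pos = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = pos[labels[nd]]
            C[i, i] = depth[nd]
            below[nd] = [i]
        else:
            groups = [below[ch] for ch in nd.child_nodes()]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            C[i, j] = C[j, i] = depth[nd]
            below[nd] = [i for g in groups for i in g]
    return C


def branch_rates(stree: SizeTree) -> pd.DataFrame:
    """Signed per-branch rate of genome-size change: (child - parent)/t.

    With states in Gb and branch lengths in Myr, ``rate_mb_per_myr`` is the
    rate in Mb per million years (contractions negative).  Zero-duration
    branches are reported with NaN rates.
    """
    if not stree.states:
        raise ValueError("run asr_bm first: no ancestral states present")
    labels = stree.node_labels()
    rows = []
    for nd in stree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        pa, ch = labels[nd.parent_node], labels[nd]
        t = float(nd.edge.length or 0.0)
        dsize = stree.states[ch] - stree.states[pa]
        rate = dsize / t if t > 0 else float("nan")
        rows.append({"parent": pa, "child": ch, "length_myr": t,
                     "parent_gb": stree.states[pa], "child_gb": stree.states[ch],
                     "rate_gb_per_myr": rate,
                     "rate_mb_per_myr": rate * 1_000.0})
    return pd.DataFrame(rows)


def simulate_bm(tree: dendropy.Tree, root_state: float, sigma2: float,
                rng: np.random.Generator) -> tuple[dict, dict]:
    """Simulate BM along a tree; returns (tip values, all node true states)."""
    stree = SizeTree(tree=tree, tip_sizes={})
    labels = stree.node_labels()
    states = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[labels[nd]] = root_state
        else:
            t = float(nd.edge.length)
            states[labels[nd]] = states[labels[nd.parent_node]] + \
                rng.normal(0.0, np.sqrt(sigma2 * t))
    tips = {labels[nd]: states[labels[nd]] for nd in tree.leaf_node_iter()}
    return tips, states
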