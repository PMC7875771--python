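"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from gigasm.hicmap import ContactMatrix


def make_contact_matrix(contig_bins: dict[str, int], dense: np.ndarray,
                        bin_size: int = 1000) -> ContactMatrix:
    """Build a ContactMatrix from an explicit dense bin matrix.

    ``contig_bins`` maps contig id -> number of bins (contig length is
    n_bins * bin_size); bins are laid out in dict order.
    """
    rows, b = [], 0
    lengths = {}
    for cid, n in contig_bins.items():
        for i in range(n):
            rows.append((b, cid, i * bin_size, (i + 1) * bin_size))
            b += 1
        lengths[cid] = n * bin_size
    dense = np.asarray(dense, dtype=float)
    assert dense.shape == (b, b), "dense matrix does not match bin layout"
    assert np.allclose(dense, dense.T), "contact matrices must be symmetric"
    bins = pd.DataFrame(rows, columns=["bin", "contig", "start", "end"])
    return ContactMatrix(bin_size=bin_size, bins=bins,
                         counts=sp.csr_matrix(dense), contig_lengths=lengths)


def random_ultrametric_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random ultrametric tree by sequential coalescence (positive lengths)."""
    trees = [f"t{i}" for i in range(n_tips)]
    heights = [0.0] * n_tips
    while len(trees) > 1:
        i, j = sorted(rng.choice(len(trees), 2, replace=False))
        h = max(heights[i], heights[j]) + float(rng.uniform(1.0, 10.0))
        nw = f"({trees[i]}:{h - heights[i]:.6f},{trees[j]}:{h - heights[j]:.6f})"
        trees = [t for k, t in enumerate(trees) if k not in (i, j)] + [nw]
        heights = [x for k, x in enumerate(heights) if k not in (i, j)] + [h]
    return trees[0] + ";"


def masked_base_metrics(reads: dict[str, str], tracks: dict,
                        oracle: dict[str, list]) -> tuple[float, float]:
    """Per-base (recall, precision) of repeat tracks against truth intervals."""
    tp = fp = fn = 0
    for rid, seq in reads.items():
        L = len(seq)
        called = np.zeros(L, bool)
        track = tracks.get(rid)
        if track is not None:
            for s, e in track.intervals:
                called[s:e] = True
        true = np.zeros(L, bool)
        for s, e in oracle.get(rid, []):
            true[s:e] = True
        tp += int((called & true).sum())
        fp += int((called & ~true).sum())
        fn += int((~called & true).sum())
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return recall, precision
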