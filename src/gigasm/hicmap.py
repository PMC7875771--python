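"""Hi-C contact binning, normalization and misjoin detection.

Pairs are binned into a symmetric sparse contact matrix over a contig
layout.  Candidate misassemblies show up as points along the diagonal that
are depleted of contacts: a genuine chromosome-internal junction is crossed
by many short-range ligation products, a chimeric one only by background.
The depletion score of an intra-contig boundary is the number of contacts
crossing it within +-``window`` bins, divided by the median crossing count
over all scanned boundaries of that contig — a self-normalising,
insulation-style statistic, so scaling all counts leaves calls unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fixtures import read_pairs, write_pairs  # noqa: F401  (re-exported I/O)


@dataclass
class ContactMatrix:
    bin_size: int
    bins: pd.DataFrame          # columns: bin, contig, start, end
    counts: sp.csr_matrix       # symmetric, counts >= 0
    normalization: str = "raw"  # raw | VC | length
    contig_lengths: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def total_pairs(self) -> float:
        """Grand total counting each unordered bin pair once."""
        m = self.counts
        return float((m.sum() + m.diagonal().sum()) / 2.0)

    def contig_bin_range(self, contig: str) -> tuple[int, int]:
        sel = self.bins.index[self.bins["contig"] == contig]
        return int(sel.min()), int(sel.max()) + 1

    def contig_matrix(self) -> np.ndarray:
        """Dense contig x contig contact sums (order of ``contig_order``)."""
        order = self.contig_order()
        idx = {c: i for i, c in enumerate(order)}
        owner = self.bins["contig"].map(idx).to_numpy()
        coo = self.counts.tocoo()
        out = np.zeros((len(order), len(order)))
        np.add.at(out, (owner[coo.row], owner[coo.col]), coo.data)
        return out

    def contig_order(self) -> list[str]:
        return list(dict.fromkeys(self.bins["contig"]))


def bin_contacts(pairs: pd.DataFrame, contig_lengths: Mapping[str, int],
                 bin_size: int) -> ContactMatrix:
    """Bin ``.pairs`` records (1-based positions) into a symmetric matrix."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rows = []
    offsets: dict[str, int] = {}
    nxt = 0
    for contig in contig_lengths:
        L = int(contig_lengths[contig])
        n = max(1, -(-L // bin_size))
        offsets[contig] = nxt
        for b in range(n):
            rows.append((nxt + b, contig, b * bin_size,
                         min((b + 1) * bin_size, L)))
        nxt += n
    bins = pd.DataFrame(rows, columns=["bin", "contig", "start", "end"])

    def to_bin(chroms: pd.Series, pos: pd.Series) -> np.ndarray:
        out = np.empty(len(chroms), dtype=np.int64)
        pos0 = pos.to_numpy() - 1  # 1-based -> 0-based
        for contig, sel in chroms.groupby(chroms).groups.items():
            if contig not in offsets:
                raise ValueError(f"pair references unknown contig {contig!r}")
            p = pos0[chroms.index.get_indexer(sel)]
            L = contig_lengths[contig]
            if (p < 0).any() or (p >= L).any():
                bad = sel[np.flatnonzero((p < 0) | (p >= L))[0]]
                raise ValueError(f"pair record {bad} out of range on {contig}")
            out[chroms.index.get_indexer(sel)] = offsets[contig] + p // bin_size
        return out

    n_bins = len(bins)
    if len(pairs):
        b1 = to_bin(pairs["chrom1"], pairs["pos1"])
        b2 = to_bin(pairs["chrom2"], pairs["pos2"])
        data = np.ones(len(pairs))
        m = sp.coo_matrix((data, (b1, b2)), shape=(n_bins, n_bins))
        m = m + m.T  # symmetrise; diagonal pairs counted twice, halved below
        m = m.tolil()
        m.setdiag(m.diagonal() / 2.0)
        m = m.tocsr()
    else:
        m = sp.csr_matrix((n_bins, n_bins))
    return ContactMatrix(bin_size=bin_size, bins=bins, counts=m,
                         contig_lengths=dict(contig_lengths))


def normalize(m: ContactMatrix, method: str = "VC") -> ContactMatrix:
    """Return a normalized copy: none | VC | length.

    VC (vanilla coverage): cell / sqrt(rowsum_i * rowsum_j); zero-coverage
    bins are left untouched (flagged by a zero rowsum).  length: contig-level
    block sums divided by the product of contig lengths, returned at
    one-bin-per-contig resolution.
    """
    if m.normalization != "raw":
        raise ValueError("normalize expects a raw matrix")
    if method == "none":
        return m
    if method == "VC":
        rowsum = np.asarray(m.counts.sum(axis=1)).ravel()
        inv = np.zeros_like(rowsum)
        nz = rowsum > 0
        inv[nz] = 1.0 / np.sqrt(rowsum[nz])
        D = sp.diags(inv)
        counts = (D @ m.counts @ D).tocsr()
        return ContactMatrix(m.bin_size, m.bins.copy(), counts, "VC",
                             dict(m.contig_lengths))
    if method == "length":
        order = m.contig_order()
        block = m.contig_matrix()
        lens = np.array([m.contig_lengths[c] for c in order], dtype=float)
        block = block / np.outer(lens, lens)
        bins = pd.DataFrame({
            "bin": range(len(order)), "contig": order,
            "start": 0, "end": [int(x) for x in lens],
        })
        return ContactMatrix(0, bins, sp.csr_matrix(block), "length",
                             dict(m.contig_lengths))
    raise ValueError(f"unknown normalization {method!r}")


@dataclass(frozen=True)
class MisjoinCall:
    contig_id: str
    boundary_bin: int       # contig-local bin index; boundary before this bin
    position: int           # bp offset within the contig
    depletion_score: float


def crossing_sums(sub: np.ndarray, window: int, guard: int = 1) -> np.ndarray:
    """Contacts crossing each interior boundary within +-window bins.

    ``sub`` is the dense contig-local matrix; boundary b separates the left
    window [b-guard-window, b-guard) from the right window
    [b+guard, b+guard+window).  The ``guard`` bins immediately flanking the
    boundary are excluded so that a bin straddling a junction does not leak
    same-side contacts into the crossing count.  Only boundaries with full
    windows on both sides are scanned; others are NaN.
    """
    n = sub.shape[0]
    out = np.full(n + 1, np.nan)
    for b in range(window + guard, n - window - guard + 1):
        out[b] = sub[b - guard - window:b - guard, b + guard:b + guard + window].sum()
    return out


def misjoin_scan(m: ContactMatrix, window: int = 5,
                 threshold: float = 0.25, guard: int = 1,
                 alpha: float = 1e-5) -> list[MisjoinCall]:
    """Detect contact-depleted points along contig diagonals.

    Per contig, each interior boundary's crossing sum is divided by the
    median crossing sum of that contig; local minima scoring below
    ``threshold`` are called, at most one per 2*window boundaries.
    Contigs shorter than 2*(window+guard) bins are skipped.

    A candidate must additionally be significantly depleted under a
    Poisson null with the median as its mean (one-sided tail < ``alpha``):
    a low ratio between single-digit counts carries no evidence, so sparse
    data yields no calls rather than spurious ones, while a genuine
    depletion against a well-supported median always qualifies.
    """
    from scipy import stats

    if window < 1:
        raise ValueError("window must be >= 1")
    calls: list[MisjoinCall] = []
    dense = None
    for contig in m.contig_order():
        lo, hi = m.contig_bin_range(contig)
        n = hi - lo
        if n < 2 * (window + guard):
            continue
        if dense is None:
            dense = m.counts.toarray()
        sub = dense[lo:hi, lo:hi]
        cross = crossing_sums(sub, window, guard)
        valid = ~np.isnan(cross)
        med = float(np.median(cross[valid])) if valid.any() else 0.0
        if med <= 0:
            continue
        scores = cross / med
        # candidate boundaries: below threshold, significantly depleted,
        # and a local minimum
        cand = [b for b in np.flatnonzero(valid)
                if scores[b] < threshold and _is_local_min(scores, b)
                and stats.poisson.cdf(cross[b], med) < alpha]
        # one call per >= 2*window separation, lowest score first
        cand.sort(key=lambda b: scores[b])
        chosen: list[int] = []
        for b in cand:
            if all(abs(b - c) >= 2 * window for c in chosen):
                chosen.append(b)
        bin_start = m.bins.loc[lo, "start"]
        for b in sorted(chosen):
            pos = int(m.bins.loc[lo + b, "start"] - bin_start)
            calls.append(MisjoinCall(contig, int(b), pos, float(scores[b])))
    return calls


def _is_local_min(scores: np.ndarray, b: int) -> bool:
    left = scores[b - 1] if b - 1 >= 0 and not np.isnan(scores[b - 1]) else np.inf
    right = scores[b + 1] if b + 1 < scores.size and not np.isnan(scores[b + 1]) \
        else np.inf
    return scores[b] <= left and scores[b] <= right


def default_bin_size(genome_size: int) -> int:
    """genome_size / 2000, clamped to [1 kb, 1 Mb]."""
    return int(min(1_000_000, max(1_000, genome_size // 2_000)))


def break_contigs(contigs: Mapping[str, str], calls: list[MisjoinCall]
                  ) -> tuple[dict[str, str], dict]:
    """Split contig sequences at called misjoins.

    Returns (new contigs, mapping old_id -> list of (new_id, offset)) so
    that pair coordinates can be lifted onto the broken layout.
    """
    by_contig: dict[str, list[int]] = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c.position)
    out: dict[str, str] = {}
    mapping: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in contigs.items():
        cuts = sorted(p for p in by_contig.get(cid, []) if 0 < p < len(seq))
        if not cuts:
            out[cid] = seq
            mapping[cid] = [(cid, 0)]
            continue
        edges = [0] + cuts + [len(seq)]
        parts = []
        for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
            nid = f"{cid}.{i + 1}"
            out[nid] = seq[s:e]
            parts.append((nid, s))
        mapping[cid] = parts
    return out, mapping


def remap_pairs(pairs: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Lift pair coordinates through a :func:`break_contigs` mapping."""
    df = pairs.copy()
    for side in ("1", "2"):
        chrom = df[f"chrom{side}"].to_numpy(dtype=object)
        pos = df[f"pos{side}"].to_numpy()  # 1-based
        new_chrom = chrom.copy()
        new_pos = pos.copy()
        for cid, parts in mapping.items():
            if len(parts) == 1 and parts[0][0] == cid:
                continue
            sel = np.flatnonzero(chrom == cid)
            if not sel.size:
                continue
            starts = np.array([off for _, off in parts])
            ids = np.array([nid for nid, _ in parts], dtype=object)
            idx = np.searchsorted(starts, pos[sel] - 1, side="right") - 1
            new_chrom[sel] = ids[idx]
            new_pos[sel] = pos[sel] - starts[idx]
        df[f"chrom{side}"] = new_chrom
        df[f"pos{side}"] = new_pos
    return df


def write_matrix(m: ContactMatrix, prefix) -> None:
    """COO TSV (bin_i, bin_j, count) plus a bin table."""
    coo = sp.triu(m.counts).tocoo()
    pd.DataFrame({"bin_i": coo.row, "bin_j": coo.col, "count": coo.data}) \
        .to_csv(f"{prefix}.coo.tsv", sep="\t", index=False)
    m.bins.to_csv(f"{prefix}.bins.tsv", sep="\t", index=False)


def write_misjoins_bed(calls: list[MisjoinCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.contig_id}\t{c.position}\t{c.position + 1}\t"
                     f"{c.depletion_score:.4f}\n")
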