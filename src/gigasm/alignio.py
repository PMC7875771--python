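"""Alignment plumbing: local alignments, PAF I/O, interval liftover and a
toy exact-k-mer overlapper.

The central primitive is :func:`map_interval`, which lifts an interval on
one read through a local alignment onto the aligned read — the coordinate
mechanism that transitive repeat-annotation transfer relies on.  Alignments
carry only endpoint anchors by default; coordinates in between are linearly
interpolated, which is exact for the ungapped alignments the bundled
overlapper produces and accurate to a few bp otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open, 0-based interval [start, end)."""

    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        s, e = max(self.start, other.start), min(self.end, other.end)
        return Interval(s, e) if s < e else None


@dataclass(frozen=True)
class LocalAlignment:
    """A local correspondence between a query and a target sequence.

    Query spans ``[query_start, query_end)`` on the forward strand of the
    query; target spans ``[target_start, target_end)`` on the forward
    strand of the target.  ``strand`` is "+" when the query aligns to the
    forward target strand and "-" when it aligns to the reverse complement.
    ``anchors`` (optional) are (query_pos, target_pos) pairs, strictly
    monotonic (decreasing in target for "-"), used for piecewise mapping.
    """

    query_id: str
    query_start: int
    query_end: int
    query_length: int
    target_id: str
    target_start: int
    target_end: int
    target_length: int
    strand: str
    identity: float
    anchors: Optional[tuple] = field(default=None)

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError("invalid query span")
        if not (0 <= self.target_start < self.target_end <= self.target_length):
            raise ValueError("invalid target span")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")

    @property
    def query_span(self) -> Interval:
        return Interval(self.query_start, self.query_end)

    @property
    def target_span(self) -> Interval:
        return Interval(self.target_start, self.target_end)

    def inverse(self) -> "LocalAlignment":
        """The same correspondence read target -> query."""
        return LocalAlignment(
            query_id=self.target_id,
            query_start=self.target_start,
            query_end=self.target_end,
            query_length=self.target_length,
            target_id=self.query_id,
            target_start=self.query_start,
            target_end=self.query_end,
            target_length=self.query_length,
            strand=self.strand,
            identity=self.identity,
        )


def map_interval(aln: LocalAlignment, iv: Interval) -> Optional[Interval]:
    """Map ``iv`` (query coordinates) through ``aln`` to target coordinates.

    The interval is first clipped to the aligned query span; positions are
    then linearly interpolated between the alignment endpoints.  A "-"
    alignment reverses orientation.  Returns ``None`` when ``iv`` does not
    intersect the aligned span (an explicit "no overlap" result).
    """
    clipped = iv.intersect(aln.query_span)
    if clipped is None:
        return None
    a, b = aln.query_start, aln.query_end
    c, d = aln.target_start, aln.target_end
    scale = (d - c) / (b - a)
    if aln.strand == "+":
        ts = c + (clipped.start - a) * scale
        te = c + (clipped.end - a) * scale
    else:
        ts = c + (b - clipped.end) * scale
        te = c + (b - clipped.start) * scale
    s, e = int(round(ts)), int(round(te))
    if e <= s:  # degenerate after rounding; keep a 1-bp footprint
        e = s + 1
    return Interval(max(c, s), min(d, e))


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------

def write_paf(alignments: Iterable[LocalAlignment], path) -> None:
    """Write alignments as 12-column PAF with a ``dv:f:`` divergence tag."""
    with open(path, "w") as fh:
        for a in alignments:
            span = a.query_end - a.query_start
            matches = int(round(a.identity * span))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id, a.query_length, a.query_start, a.query_end,
                        a.strand,
                        a.target_id, a.target_length, a.target_start, a.target_end,
                        matches, span, 255, f"dv:f:{1.0 - a.identity:.6f}",
                    )
                )
                + "\n"
            )


def read_paf(path) -> list[LocalAlignment]:
    """Read PAF written by :func:`write_paf` (12 columns + optional tags)."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF line: {line!r}")
            identity = int(f[9]) / int(f[10]) if int(f[10]) else 0.0
            for tag in f[12:]:
                if tag.startswith("dv:f:"):
                    identity = 1.0 - float(tag[5:])
            out.append(
                LocalAlignment(
                    query_id=f[0], query_length=int(f[1]),
                    query_start=int(f[2]), query_end=int(f[3]),
                    strand=f[4],
                    target_id=f[5], target_length=int(f[6]),
                    target_start=int(f[7]), target_end=int(f[8]),
                    identity=min(1.0, identity),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Toy seed-and-extend overlapper
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of an encoded sequence (4^k numbering)."""
    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    return win @ powers


def _xdrop_extend(q: np.ndarray, t: np.ndarray, qpos: int, tpos: int,
                  match: int = 1, mismatch: int = -2, xdrop: int = 20):
    """Ungapped x-drop extension around a seed on one diagonal.

    Returns (q_start, q_end, matches) of the best-scoring extent.
    """
    # rightwards (inclusive of the seed start position)
    best = score = m_run = 0
    right_q, right_m = qpos, 0
    for off in range(min(len(q) - qpos, len(t) - tpos)):
        hit = q[qpos + off] == t[tpos + off]
        score += match if hit else mismatch
        m_run += int(hit)
        if score > best:
            best, right_q, right_m = score, qpos + off + 1, m_run
        elif best - score > xdrop:
            break
    # leftwards
    best = score = m_run = 0
    left_q, left_m = qpos, 0
    for off in range(1, min(qpos, tpos) + 1):
        hit = q[qpos - off] == t[tpos - off]
        score += match if hit else mismatch
        m_run += int(hit)
        if score > best:
            best, left_q, left_m = score, qpos - off, m_run
        elif best - score > xdrop:
            break
    return left_q, right_q, left_m + right_m


def overlap_reads(
    reads: Mapping[str, str],
    k: int = 15,
    min_len: int = 200,
    min_identity: float = 0.7,
    query_ids: Optional[Sequence[str]] = None,
    max_seed_hits: int = 2000,
) -> list[LocalAlignment]:
    """All-vs-subset local overlapper: exact k-mer seeds, ungapped extension.

    Queries (default: all reads) are indexed by their k-mers; every read is
    then scanned against the index on both strands.  Seed hits sharing a
    (query, target, strand, diagonal) are extended once with an x-drop
    ungapped extension.  Reports alignments of span >= ``min_len`` with
    identity >= ``min_identity``.  Self-hits are suppressed.  This exists to
    make fixtures self-contained; it is not a production aligner.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if not reads:
        raise ValueError("no reads supplied")
    if min(len(s) for s in reads.values()) < k:
        raise ValueError("k longer than shortest read")
    if query_ids is None:
        query_ids = list(reads)
    enc = {rid: _encode(seq) for rid, seq in reads.items()}

    index: dict[int, list] = {}
    for rid in query_ids:
        codes = _kmer_codes(enc[rid], k)
        for pos, code in enumerate(codes.tolist()):
            index.setdefault(code, []).append((rid, pos))
    # drop hyper-repetitive seeds to bound work
    index = {c: v for c, v in index.items() if len(v) <= max_seed_hits}

    out: list[LocalAlignment] = []
    for tid, tseq in reads.items():
        tenc = enc[tid]
        tlen = len(tenc)
        for strand in "+-":
            scan = tenc if strand == "+" else _encode(revcomp(tseq))
            codes = _kmer_codes(scan, k)
            groups: dict[tuple, list[int]] = {}
            for tpos, code in enumerate(codes.tolist()):
                hits = index.get(code)
                if not hits:
                    continue
                for qid, qpos in hits:
                    if qid == tid:
                        continue
                    groups.setdefault((qid, qpos - tpos), []).append(tpos)
            for (qid, diag), tpos_list in groups.items():
                qenc = enc[qid]
                done: list[tuple] = []
                for tpos in sorted(tpos_list):
                    qpos = tpos + diag
                    if any(s <= qpos < e for s, e in done):
                        continue
                    qs, qe, matches = _xdrop_extend(qenc, scan, qpos, tpos)
                    done.append((qs, qe))
                    span = qe - qs
                    if span < min_len:
                        continue
                    ident = matches / span
                    if ident < min_identity:
                        continue
                    ts, te = qs - diag, qe - diag
                    if strand == "+":
                        fts, fte = ts, te
                    else:  # positions were on the reverse complement
                        fts, fte = tlen - te, tlen - ts
                    out.append(
                        LocalAlignment(
                            query_id=qid, query_start=qs, query_end=qe,
                            query_length=len(qenc),
                            target_id=tid, target_start=fts, target_end=fte,
                            target_length=tlen,
                            strand=strand, identity=ident,
                        )
                    )
    # deduplicate identical spans found from multiple seeds
    seen = set()
    uniq = []
    for a in out:
        key = (a.query_id, a.target_id, a.strand, a.query_start, a.query_end,
               a.target_start, a.target_end)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    uniq.sort(key=lambda a: (a.query_id, a.target_id, a.query_start, a.strand))
    return uniq
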