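"""Read-level repeat annotation by alignment depth, with transitive transfer.

The strategy: align a small sample of reads against all reads; positions on
a sample read where the alignment pile-up depth strictly exceeds ``factor``
times the expected sequencing depth are called repetitive (a unique locus is
covered about ``coverage`` times, a repeat with n genomic copies about
``n x coverage`` times).  The sample's annotations are then propagated to
every aligned read in a single transitive step by lifting each repetitive
interval through the read-vs-read alignment, and merged per read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .alignio import Interval, LocalAlignment, map_interval


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a disjoint sorted list."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class RepeatTrack:
    """Disjoint, sorted repeat intervals on one read."""

    read_id: str
    intervals: list[tuple[int, int]]
    source: str = "depth-call"  # or "transferred"

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    def masked_bases(self) -> int:
        return sum(e - s for s, e in self.intervals)


def depth_profile(read_length: int,
                  spans: Iterable[tuple[int, int]]) -> np.ndarray:
    """Per-position alignment pile-up depth from query-side spans."""
    delta = np.zeros(read_length + 1, dtype=np.int64)
    for s, e in spans:
        if s < 0 or e > read_length:
            raise ValueError(f"alignment span ({s}, {e}) exceeds read length "
                             f"{read_length}")
        delta[s] += 1
        delta[e] -= 1
    return np.cumsum(delta[:-1])


def annotate_sample(
    sample_alignments: Sequence[LocalAlignment],
    read_lengths: Mapping[str, int],
    expected_depth: float,
    factor: float = 4.0,
    min_len: int = 100,
    sample_ids: Optional[Iterable[str]] = None,
) -> dict[str, RepeatTrack]:
    """Call repetitive intervals on sample reads from pile-up depth.

    A position is repetitive when its depth strictly exceeds
    ``factor * expected_depth`` ("exceeded", so depth exactly at the
    threshold is not called); maximal runs shorter than ``min_len`` are
    discarded.  Alignments are expected with the sample read on the query
    side.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be > 0")
    spans: dict[str, list[tuple[int, int]]] = {}
    for a in sample_alignments:
        if a.query_id not in read_lengths:
            raise ValueError(f"alignment references unknown read {a.query_id}")
        spans.setdefault(a.query_id, []).append((a.query_start, a.query_end))
    ids = list(sample_ids) if sample_ids is not None else sorted(spans)
    threshold = factor * expected_depth
    tracks: dict[str, RepeatTrack] = {}
    for rid in ids:
        depth = depth_profile(read_lengths[rid], spans.get(rid, ()))
        mask = depth > threshold
        ivs = _runs(mask, min_len)
        tracks[rid] = RepeatTrack(rid, ivs, source="depth-call")
    return tracks


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True runs of length >= min_len as half-open intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def transfer_annotations(
    sample_tracks: Mapping[str, RepeatTrack],
    all_alignments: Sequence[LocalAlignment],
    read_lengths: Mapping[str, int],
) -> dict[str, RepeatTrack]:
    """Propagate sample annotations to every aligned read (one transitive step).

    For each alignment from an annotated read A to read B, every repetitive
    interval of A intersecting the aligned span is lifted into B's
    coordinates and added to B's track; tracks are merged per read.  Original
    sample tracks are preserved (and may grow by transfers onto them).
    """
    collected: dict[str, list[tuple[int, int]]] = {
        rid: list(t.intervals) for rid, t in sample_tracks.items()
    }
    for a in all_alignments:
        if a.query_id not in read_lengths or a.target_id not in read_lengths:
            raise ValueError("alignment references unknown read "
                             f"{a.query_id} or {a.target_id}")
        track = sample_tracks.get(a.query_id)
        if track is None:
            continue
        for s, e in track.intervals:
            mapped = map_interval(a, Interval(s, e))
            if mapped is not None:
                collected.setdefault(a.target_id, []).append(
                    (mapped.start, mapped.end))
    out = {}
    for rid, ivs in collected.items():
        source = "depth-call" if rid in sample_tracks else "transferred"
        out[rid] = RepeatTrack(rid, ivs, source=source)
    return out


def mask_fraction(tracks: Mapping[str, RepeatTrack], total_bases: int) -> float:
    """Fraction of all read bases covered by the final masking track."""
    if total_bases <= 0:
        raise ValueError("total_bases must be > 0")
    masked = sum(t.masked_bases() for t in tracks.values())
    if masked > total_bases:
        raise ValueError("masked bases exceed total bases: invariant violated")
    return masked / total_bases


def select_sample(read_ids: Sequence[str], fraction: float = 0.01) -> list[str]:
    """Deterministic sample: every Nth read by file order (N = 1/fraction)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction outside (0, 1]")
    step = max(1, int(round(1.0 / fraction)))
    return list(read_ids)[::step]


def annotate_reads(
    reads: Mapping[str, str],
    genome_size_estimate: float,
    sample_fraction: float = 0.01,
    factor: float = 4.0,
    min_interval: int = 100,
    k: int = 15,
    min_aln_len: int = 200,
    min_identity: float = 0.8,
) -> tuple[dict[str, RepeatTrack], float]:
    """End-to-end pipeline: sample, overlap, depth-call, transfer, mask.

    ``expected_depth`` defaults to total read bases / genome-size estimate.
    Returns the final per-read tracks and the global masked fraction.
    """
    from .alignio import overlap_reads

    total_bases = sum(len(s) for s in reads.values())
    expected_depth = total_bases / genome_size_estimate
    sample = select_sample(list(reads), sample_fraction)
    lengths = {rid: len(s) for rid, s in reads.items()}
    alignments = overlap_reads(reads, k=k, min_len=min_aln_len,
                               min_identity=min_identity, query_ids=sample)
    tracks = annotate_sample(alignments, lengths, expected_depth,
                             factor=factor, min_len=min_interval,
                             sample_ids=sample)
    final = transfer_annotations(tracks, alignments, lengths)
    return final, mask_fraction(final, total_bases)


def write_bed(tracks: Mapping[str, RepeatTrack], path) -> None:
    """BED with the read id in the chromosome column."""
    with open(path, "w") as fh:
        for rid in sorted(tracks):
            for s, e in tracks[rid].intervals:
                fh.write(f"{rid}\t{s}\t{e}\t{tracks[rid].source}\n")
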