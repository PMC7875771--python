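"""Deterministic simulation fixtures.

Generates the inputs every downstream stage assumes, together with their
ground truth: chromosomes with planted, divergence-stratified repeat
families; long reads with configurable substitution error; contigs that
tile the genome, optionally with planted inter-chromosomal misjoins; and
Hi-C pairs with power-law intra-chromosomal distance decay plus a uniform
inter-chromosomal background.

All randomness is drawn from per-operation streams derived from
``(seed, operation)`` so that each stage is independently reproducible:
identical configuration gives byte-identical outputs.

Coordinates are 0-based half-open everywhere; ``.pairs`` emission converts
to the 1-based convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alignio import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream labels: one RNG stream per operation, derived from (seed, label)
_OP_GENOME, _OP_READS, _OP_CONTIGS, _OP_HIC = 11, 13, 17, 19


@dataclass(frozen=True)
class RepeatFamily:
    """A planted repeat family: consensus drawn once, copies mutated from it.

    ``divergence_mean`` is the mean of the exponential distribution the
    per-copy divergence (substitutions/site) is drawn from, giving the
    long-tailed age structure repeat landscapes show.
    """

    family_id: str
    consensus_length: int
    copy_number: int
    divergence_mean: float
    te_class: str = "LINE"

    def __post_init__(self):
        if self.consensus_length <= 0 or self.copy_number <= 0:
            raise ValueError("consensus_length and copy_number must be positive")
        if not 0.0 <= self.divergence_mean < 0.45:
            raise ValueError("divergence_mean outside [0, 0.45)")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chromosome_lengths: tuple = (100_000, 80_000)
    repeat_families: tuple = ()
    read_coverage: float = 10.0
    read_length_mean: float = 2_000.0
    read_length_sd: float = 500.0
    read_error_rate: float = 0.0
    contig_break_count: int = 0
    misjoin_count: int = 0
    min_segment_length: int = 10_000
    hic_pair_count: int = 10_000
    hic_decay_exponent: float = 1.0
    hic_trans_fraction: float = 0.05

    def __post_init__(self):
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.read_coverage <= 0 or self.read_length_mean <= 0:
            raise ValueError("coverage and read length must be positive")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate outside [0, 1]")
        if not 0.0 <= self.hic_trans_fraction <= 1.0:
            raise ValueError("hic_trans_fraction outside [0, 1]")
        if self.hic_decay_exponent <= 0:
            raise ValueError("hic_decay_exponent must be > 0")
        if self.contig_break_count < 0:
            raise ValueError("contig_break_count must be >= 0")
        if self.misjoin_count > self.contig_break_count:
            raise ValueError("misjoin_count exceeds contig_break_count")
        object.__setattr__(
            self, "repeat_families",
            tuple(f if isinstance(f, RepeatFamily) else RepeatFamily(*f)
                  for f in self.repeat_families),
        )
        object.__setattr__(self, "chromosome_lengths",
                           tuple(int(x) for x in self.chromosome_lengths))


@dataclass
class TruthTables:
    """Ground truth accompanying each simulated artefact (pandas tables)."""

    repeat_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "family_id", "te_class", "divergence"]))
    repeat_copies: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["copy_id", "family_id", "te_class", "length",
                     "identity", "p", "q"]))
    read_origins: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["read_id", "chrom", "start", "end", "strand"]))
    contig_origins: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["contig_id", "part_index", "chrom", "start", "end", "strand"]))
    misjoin_positions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["contig_id", "offset"]))


def _rng(config: SimConfig, op: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), op])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T
_TRANSVERSIONS = {65: (67, 84), 71: (67, 84), 67: (65, 71), 84: (65, 71)}


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float,
            ts_prob: float = 2 / 3):
    """Substitute a ``divergence`` fraction of distinct sites.

    Transitions are drawn with probability ``ts_prob`` (the familiar ~2:1
    transition bias).  Returns (mutated copy, p, q): realised transition and
    transversion proportions.
    """
    n_sub = int(round(divergence * seq.size))
    out = seq.copy()
    if n_sub == 0:
        return out, 0.0, 0.0
    sites = rng.choice(seq.size, size=n_sub, replace=False)
    is_ts = rng.random(n_sub) < ts_prob
    for pos, ts in zip(sites.tolist(), is_ts.tolist()):
        base = int(out[pos])
        if ts:
            out[pos] = _TRANSITION[base]
        else:
            out[pos] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    p = float(np.count_nonzero(is_ts)) / seq.size
    q = (n_sub - float(np.count_nonzero(is_ts))) / seq.size
    return out, p, q


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], TruthTables]:
    """Random chromosomes with planted repeat-family copies.

    Copies are inserted (not overwritten), so each chromosome ends up at its
    configured length plus the inserted repeat bases.  Every planted copy is
    recorded in ``truth.repeat_intervals`` (final coordinates) and
    ``truth.repeat_copies`` (realised divergence decomposition).
    """
    rng = _rng(config, _OP_GENOME)
    chrom_ids = [f"chr{i + 1}" for i in range(len(config.chromosome_lengths))]
    backbones = {cid: _random_seq(rng, L)
                 for cid, L in zip(chrom_ids, config.chromosome_lengths)}
    lengths = np.asarray(config.chromosome_lengths, dtype=float)

    insertions: dict[str, list] = {cid: [] for cid in chrom_ids}
    copy_rows, copy_id = [], 0
    for fam in config.repeat_families:
        consensus = _random_seq(rng, fam.consensus_length)
        for _ in range(fam.copy_number):
            ci = rng.choice(len(chrom_ids), p=lengths / lengths.sum())
            cid = chrom_ids[ci]
            pos = int(rng.integers(0, config.chromosome_lengths[ci] + 1))
            div = float(min(rng.exponential(fam.divergence_mean), 0.44)) \
                if fam.divergence_mean > 0 else 0.0
            copy, p, q = _mutate(rng, consensus, div)
            realised = p + q
            insertions[cid].append((pos, copy, fam, realised))
            copy_rows.append({
                "copy_id": f"{fam.family_id}_copy{copy_id}",
                "family_id": fam.family_id, "te_class": fam.te_class,
                "length": fam.consensus_length,
                "identity": 100.0 * (1.0 - realised), "p": p, "q": q,
            })
            copy_id += 1

    sequences: dict[str, str] = {}
    interval_rows = []
    for cid in chrom_ids:
        parts, cursor, offset = [], 0, 0
        backbone = backbones[cid]
        for pos, copy, fam, div in sorted(insertions[cid], key=lambda x: x[0]):
            parts.append(backbone[cursor:pos])
            start = pos + offset
            parts.append(copy)
            interval_rows.append({"chrom": cid, "start": start,
                                  "end": start + copy.size,
                                  "family_id": fam.family_id,
                                  "te_class": fam.te_class, "divergence": div})
            offset += copy.size
            cursor = pos
        parts.append(backbone[cursor:])
        sequences[cid] = np.concatenate(parts).tobytes().decode("ascii")

    truth = TruthTables(
        repeat_intervals=pd.DataFrame(
            interval_rows, columns=["chrom", "start", "end", "family_id",
                                    "te_class", "divergence"]),
        repeat_copies=pd.DataFrame(
            copy_rows, columns=["copy_id", "family_id", "te_class", "length",
                                "identity", "p", "q"]),
    )
    return sequences, truth


def simulate_reads(genome: dict[str, str], config: SimConfig,
                   truth: Optional[TruthTables] = None
                   ) -> tuple[dict[str, str], TruthTables]:
    """Sample reads uniformly over the genome to the configured coverage.

    Lengths are lognormal (moment-matched to ``read_length_mean/sd``),
    truncated at chromosome ends; strands are random; errors are i.i.d.
    substitutions at ``read_error_rate``.
    """
    if not genome or sum(len(s) for s in genome.values()) == 0:
        raise ValueError("empty genome")
    rng = _rng(config, _OP_READS)
    chrom_ids = list(genome)
    lengths = np.array([len(genome[c]) for c in chrom_ids], dtype=float)
    total_target = config.read_coverage * lengths.sum()

    mean, sd = config.read_length_mean, config.read_length_sd
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0

    reads, rows, total = {}, [], 0
    i = 0
    while total < total_target:
        ci = rng.choice(len(chrom_ids), p=lengths / lengths.sum())
        cid = chrom_ids[ci]
        L = int(lengths[ci])
        rlen = max(50, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))
        # keep a minimal footprint when truncating at the chromosome end
        floor = min(50, L)
        start = int(rng.integers(0, L - floor + 1))
        end = min(start + rlen, L)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[cid][start:end]
        if strand == "-":
            seq = revcomp(seq)
        if config.read_error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            n_err = rng.binomial(arr.size, config.read_error_rate)
            if n_err:
                sites = rng.choice(arr.size, size=n_err, replace=False)
                for pos in sites.tolist():
                    base = int(arr[pos])
                    choices = [b for b in (65, 67, 71, 84) if b != base]
                    arr[pos] = choices[rng.integers(0, 3)]
            seq = arr.tobytes().decode("ascii")
        rid = f"read{i:06d}"
        reads[rid] = seq
        rows.append({"read_id": rid, "chrom": cid, "start": start, "end": end,
                     "strand": strand})
        total += end - start
        i += 1

    out_truth = truth if truth is not None else TruthTables()
    out_truth = replace_read_origins(out_truth, pd.DataFrame(rows))
    return reads, out_truth


def replace_read_origins(truth: TruthTables, origins: pd.DataFrame) -> TruthTables:
    new = TruthTables(
        repeat_intervals=truth.repeat_intervals,
        repeat_copies=truth.repeat_copies,
        read_origins=origins,
        contig_origins=truth.contig_origins,
        misjoin_positions=truth.misjoin_positions,
    )
    return new


def _breakpoints(rng, L: int, n_breaks: int, min_seg: int) -> list[int]:
    """n_breaks interior cut positions with min segment spacing."""
    if n_breaks == 0:
        return []
    if (n_breaks + 1) * min_seg > L:
        raise ValueError("chromosome too short for requested breaks at "
                         f"min_segment_length={min_seg}")
    # stick-breaking with a floor: distribute the slack uniformly
    slack = L - (n_breaks + 1) * min_seg
    cuts = np.sort(rng.integers(0, slack + 1, size=n_breaks))
    return [int(c + (i + 1) * min_seg) for i, c in enumerate(cuts)]


def simulate_contigs(genome: dict[str, str], config: SimConfig,
                     truth: Optional[TruthTables] = None
                     ) -> tuple[dict[str, str], TruthTables]:
    """Cut the genome into contigs; optionally plant chimeric misjoins.

    ``contig_break_count`` interior breakpoints are spread across
    chromosomes in proportion to length (segments never shorter than
    ``min_segment_length``, so every junction is resolvable at mapping
    resolution).  Each misjoin concatenates two segments from *different*
    chromosomes, its junction offset recorded in ``truth.misjoin_positions``.
    Contigs tile the genome exactly.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = _rng(config, _OP_CONTIGS)
    chrom_ids = list(genome)
    lengths = np.array([len(genome[c]) for c in chrom_ids], dtype=float)

    # apportion breaks to chromosomes by length (largest remainder)
    raw = lengths / lengths.sum() * config.contig_break_count
    counts = np.floor(raw).astype(int)
    rem = config.contig_break_count - counts.sum()
    for idx in np.argsort(-(raw - counts))[:rem]:
        counts[idx] += 1

    segments = []  # (chrom, start, end)
    for cid, nb in zip(chrom_ids, counts.tolist()):
        L = len(genome[cid])
        cuts = [0] + _breakpoints(rng, L, nb, config.min_segment_length) + [L]
        for s, e in zip(cuts[:-1], cuts[1:]):
            segments.append((cid, s, e))

    # choose misjoin pairs: segments from different chromosomes, no reuse
    n_seg = len(segments)
    order = rng.permutation(n_seg).tolist()
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for a in order:
        if len(pairs) == config.misjoin_count:
            break
        if a in used:
            continue
        partner = next((b for b in order
                        if b not in used and b != a
                        and segments[b][0] != segments[a][0]), None)
        if partner is None:
            continue
        used.update((a, partner))
        pairs.append((a, partner))
    if len(pairs) < config.misjoin_count:
        raise ValueError("not enough cross-chromosome segment pairs for "
                         f"{config.misjoin_count} misjoins")

    contigs: dict[str, str] = {}
    origin_rows, misjoin_rows = [], []
    cidx = 0

    def emit(parts: list[int]):
        nonlocal cidx
        name = f"contig{cidx:04d}"
        cidx += 1
        seq_parts, offset = [], 0
        for pi, si in enumerate(parts):
            chrom, s, e = segments[si]
            seq_parts.append(genome[chrom][s:e])
            origin_rows.append({"contig_id": name, "part_index": pi,
                                "chrom": chrom, "start": s, "end": e,
                                "strand": "+"})
            if pi > 0:
                misjoin_rows.append({"contig_id": name, "offset": offset})
            offset += e - s
        contigs[name] = "".join(seq_parts)

    paired = {i for ab in pairs for i in ab}
    for a, b in pairs:
        emit([a, b])
    for i in range(n_seg):
        if i not in paired:
            emit([i])

    base = truth if truth is not None else TruthTables()
    out = TruthTables(
        repeat_intervals=base.repeat_intervals,
        repeat_copies=base.repeat_copies,
        read_origins=base.read_origins,
        contig_origins=pd.DataFrame(
            origin_rows, columns=["contig_id", "part_index", "chrom", "start",
                                  "end", "strand"]),
        misjoin_positions=pd.DataFrame(
            misjoin_rows, columns=["contig_id", "offset"]),
    )
    return contigs, out


def _sample_separations(rng, n: int, alpha: float, L: int) -> np.ndarray:
    """Separations s in [1, L-1] with density proportional to s^-alpha."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        s = np.exp(u * np.log(L - 1))
    else:
        a = 1.0 - alpha
        s = (1.0 + u * ((L - 1) ** a - 1.0)) ** (1.0 / a)
    return np.maximum(1, np.round(s)).astype(np.int64)


def simulate_hic(layout_sequences: dict[str, str], config: SimConfig,
                 truth: Optional[TruthTables] = None) -> pd.DataFrame:
    """Hi-C pairs over the genome, emitted in contig coordinates.

    Intra-chromosomal separations follow a power law with exponent
    ``hic_decay_exponent``; a ``hic_trans_fraction`` share of pairs joins two
    positions on different chromosomes uniformly.  When ``truth`` carries
    contig origins, genome positions are converted to (contig, offset); the
    depleted-contact signature at planted misjoins emerges from this mapping
    alone.  Returned positions are 1-based as in the 4DN ``.pairs`` format.
    """
    if config.hic_pair_count <= 0:
        raise ValueError("hic_pair_count must be > 0")
    rng = _rng(config, _OP_HIC)

    have_layout = truth is not None and len(truth.contig_origins) > 0
    if have_layout:
        chrom_ids = sorted(truth.contig_origins["chrom"].unique())
        chrom_len = {c: int(truth.contig_origins.query("chrom == @c")["end"].max())
                     for c in chrom_ids}
    else:
        chrom_ids = list(layout_sequences)
        chrom_len = {c: len(s) for c, s in layout_sequences.items()}
    lengths = np.array([chrom_len[c] for c in chrom_ids], dtype=float)
    probs = lengths / lengths.sum()

    n = config.hic_pair_count
    is_trans = rng.random(n) < config.hic_trans_fraction

    c1 = rng.choice(len(chrom_ids), size=n, p=probs)
    c2 = c1.copy()
    len_arr = lengths.astype(np.int64)
    p1 = (rng.random(n) * len_arr[c1]).astype(np.int64)
    p2 = np.empty(n, dtype=np.int64)

    # cis: separation sampled from the power law, direction random; draws
    # falling off the chromosome are redrawn (reflection-free rejection)
    for ci in range(len(chrom_ids)):
        idx = np.flatnonzero(~is_trans & (c1 == ci))
        L = int(len_arr[ci])
        while idx.size:
            s = _sample_separations(rng, idx.size, config.hic_decay_exponent, L)
            sign = np.where(rng.random(idx.size) < 0.5, 1, -1)
            pos = p1[idx] + sign * s
            ok = (pos >= 0) & (pos < L)
            p2[idx[ok]] = pos[ok]
            idx = idx[~ok]
    # trans: uniform position on a different chromosome
    t_idx = np.flatnonzero(is_trans)
    if t_idx.size and len(chrom_ids) < 2:
        raise ValueError("trans pairs require >= 2 chromosomes")
    while t_idx.size:
        cj = rng.choice(len(chrom_ids), size=t_idx.size, p=probs)
        ok = cj != c1[t_idx]
        sel = t_idx[ok]
        c2[sel] = cj[ok]
        p2[sel] = (rng.random(sel.size) * len_arr[cj[ok]]).astype(np.int64)
        t_idx = t_idx[~ok]

    names1 = [chrom_ids[i] for i in c1]
    names2 = [chrom_ids[i] for i in c2]

    if have_layout:
        mapper = genome_to_contig_mapper(truth)
        names1, p1 = mapper(names1, p1)
        names2, p2 = mapper(names2, p2)

    strands = np.where(rng.random((n, 2)) < 0.5, "+", "-")
    df = pd.DataFrame({
        "readID": [f"pair{i:07d}" for i in range(n)],
        "chrom1": names1, "pos1": np.asarray(p1) + 1,
        "chrom2": names2, "pos2": np.asarray(p2) + 1,
        "strand1": strands[:, 0], "strand2": strands[:, 1],
    })
    # upper-triangular ordering as the .pairs spec requires
    flip = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"]))
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        df.loc[flip, [a, b]] = df.loc[flip, [b, a]].values
    return df


def genome_to_contig_mapper(truth: TruthTables):
    """Return a vectorisable genome->(contig, offset) coordinate mapper."""
    per_chrom: dict[str, tuple] = {}
    for chrom, sub in truth.contig_origins.groupby("chrom"):
        sub = sub.sort_values("start")
        offsets = []
        for _, row in sub.iterrows():
            prior = truth.contig_origins.query(
                "contig_id == @row.contig_id and part_index < @row.part_index")
            offsets.append(int((prior["end"] - prior["start"]).sum()))
        per_chrom[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                            sub["contig_id"].tolist(), np.array(offsets))

    def mapper(chroms, positions):
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        names = np.empty(positions.size, dtype=object)
        offs = np.empty(positions.size, dtype=np.int64)
        for chrom in np.unique(chroms):
            starts, ends, cids, offsets = per_chrom[chrom]
            sel = np.flatnonzero(chroms == chrom)
            idx = np.searchsorted(starts, positions[sel], side="right") - 1
            if (idx < 0).any() or (positions[sel] >= ends[idx]).any():
                raise ValueError(f"positions on {chrom} not covered by layout")
            cid_arr = np.asarray(cids, dtype=object)
            names[sel] = cid_arr[idx]
            offs[sel] = positions[sel] - starts[idx] + offsets[idx]
        return names.tolist(), offs

    return mapper


def read_truth_tracks(truth: TruthTables) -> dict[str, list[tuple[int, int]]]:
    """Per-read repeat intervals (read coordinates) implied by the truth.

    Intersects each read's origin with the genomic repeat intervals and maps
    into read coordinates, flipping for minus-strand reads.  This is the
    oracle the masking recall/precision checks compare against.
    """
    by_chrom = {c: sub[["start", "end"]].to_numpy()
                for c, sub in truth.repeat_intervals.groupby("chrom")}
    tracks: dict[str, list[tuple[int, int]]] = {}
    for row in truth.read_origins.itertuples():
        ivs = []
        L = row.end - row.start
        for rs, re in by_chrom.get(row.chrom, ()):
            s, e = max(row.start, rs), min(row.end, re)
            if s < e:
                a, b = s - row.start, e - row.start
                if row.strand == "-":
                    a, b = L - b, L - a
                ivs.append((int(a), int(b)))
        tracks[row.read_id] = sorted(ivs)
    return tracks


# ---------------------------------------------------------------------------
# File emission helpers (plain-text formats only)
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_pairs(df: pd.DataFrame, path) -> None:
    """Write a minimal 4DN ``.pairs`` file (1-based positions)."""
    cols = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(cols) + "\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    cols = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols,
                     dtype={"chrom1": str, "chrom2": str})
    return df


def write_truth(truth: TruthTables, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.repeat_intervals.to_csv(outdir / "repeat_intervals.bed", sep="\t",
                                  header=False, index=False)
    truth.repeat_copies.to_csv(outdir / "repeat_copies.tsv", sep="\t", index=False)
    truth.read_origins.to_csv(outdir / "read_origins.tsv", sep="\t", index=False)
    truth.contig_origins.to_csv(outdir / "contig_origins.tsv", sep="\t", index=False)
    truth.misjoin_positions.to_csv(outdir / "misjoin_positions.tsv", sep="\t",
                                   index=False)
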