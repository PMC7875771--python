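"""Walkthrough: read-level repeat masking by alignment depth.

Plants one repeat family into a small genome, sequences it with error-free
long reads, and runs the sample-overlap-transfer masking pipeline. Because
the fixture carries ground truth, per-base recall and precision of the
masking can be computed exactly. Finishes with a Kimura divergence
landscape of the planted copies.

Run:  python examples/repeat_masking.py
"""

import numpy as np

from gigasm import fixtures, repeatreads, replandscape
from gigasm.fixtures import RepeatFamily, SimConfig

cfg = SimConfig(
    seed=7,
    chromosome_lengths=(200_000,),
    repeat_families=(RepeatFamily("line1", 300, 30, 0.03, te_class="LINE"),),
    read_coverage=10,
    read_error_rate=0.0,
)

genome, truth = fixtures.simulate_genome(cfg)
reads, truth = fixtures.simulate_reads(genome, cfg, truth)
genome_size = sum(len(s) for s in genome.values())
print(f"genome {genome_size:,} bp with {len(truth.repeat_intervals)} planted "
      f"copies; {len(reads)} reads")

tracks, fraction = repeatreads.annotate_reads(
    reads, genome_size, sample_fraction=0.02)
print(f"masked fraction of read bases: {fraction:.4f}")

# evaluate against the truth tracks
oracle = fixtures.read_truth_tracks(truth)
tp = fp = fn = 0
for rid, seq in reads.items():
    called = np.zeros(len(seq), bool)
    if rid in tracks:
        for s, e in tracks[rid].intervals:
            called[s:e] = True
    true = np.zeros(len(seq), bool)
    for s, e in oracle.get(rid, []):
        true[s:e] = True
    tp += int((called & true).sum())
    fp += int((called & ~true).sum())
    fn += int((~called & true).sum())
print(f"per-base recall {tp / (tp + fn):.3f}, "
      f"precision {tp / (tp + fp):.3f}")

# divergence landscape of the planted copies (from the truth table)
records = replandscape.copy_divergences(truth.repeat_copies)
records = replandscape.filter_8080(records)
table = replandscape.landscape_table(records)
occupied = table.loc[:, (table > 0).any()]
print(f"\nK2P landscape (bp per 1% divergence bin):\n{occupied}")
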