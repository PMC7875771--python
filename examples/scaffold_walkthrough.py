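"""Walkthrough: from chimeric contigs to chromosome-scale scaffolds.

Simulates a 3-chromosome genome, cuts it into contigs with two planted
cross-chromosome misjoins, simulates Hi-C pairs over that layout, and runs
the full scaffolding pipeline: misjoin detection/breaking, seeded
clustering, and ordering/orientation. Compares the result against the
simulation ground truth.

Run:  python examples/scaffold_walkthrough.py
"""

from gigasm import fixtures, scaffolder
from gigasm.fixtures import SimConfig

cfg = SimConfig(
    seed=42,
    chromosome_lengths=(600_000, 500_000, 400_000),
    contig_break_count=27,          # -> 30 segments over 3 chromosomes
    misjoin_count=2,                # two chimeric contigs planted
    min_segment_length=15_000,
    hic_pair_count=120_000,
    hic_decay_exponent=1.0,         # power-law contact decay
    hic_trans_fraction=0.05,        # inter-chromosomal background
)

genome, truth = fixtures.simulate_genome(cfg)
contigs, truth = fixtures.simulate_contigs(genome, cfg, truth)
pairs = fixtures.simulate_hic(genome, cfg, truth)
print(f"simulated {len(contigs)} contigs from {len(genome)} chromosomes, "
      f"{len(pairs)} Hi-C pairs")
print(f"planted misjoins:\n{truth.misjoin_positions}")

agp, fasta, report = scaffolder.scaffold(
    pairs, contigs, scaffolder.ScaffoldConfig(n_seeds=3, bin_size=1_500))

print(f"\nmisjoins broken: {report['misjoins_broken']}")
print(f"scaffolds: {report['n_scaffolds']}  "
      f"(sizes {report['cluster_sizes']}, unassigned {report['unassigned']})")
print(f"contig N50 {report['n50_contigs']:,} bp -> "
      f"scaffold N50 {report['n50_scaffolds']:,} bp")

# check cluster purity against the truth; pieces of a broken chimera are
# named "<parent>.<i>" and must be attributed to the chromosome of the
# parent segment their midpoint falls in
ct = truth.contig_origins
w = agp[agp["component_type"] == "W"]
lengths = dict(zip(w["component_id"], w["component_end"]))


def true_chrom(component_id: str) -> str:
    base, _, _ = component_id.partition(".")
    siblings = sorted((c for c in lengths if c.partition(".")[0] == base),
                      key=lambda c: int(c.partition(".")[2] or 0))
    offset = sum(lengths[c] for c in siblings[:siblings.index(component_id)])
    mid = offset + lengths[component_id] / 2
    edge = 0
    for part in ct[ct["contig_id"] == base].itertuples():
        edge += part.end - part.start
        if mid < edge:
            return part.chrom
    return part.chrom


print("\nscaffold composition (true chromosome of each member):")
for sid, grp in w.groupby("object"):
    chroms = sorted({true_chrom(c) for c in grp["component_id"]})
    print(f"  {sid}: {len(grp)} contigs, chromosomes {chroms}")
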