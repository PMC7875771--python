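"""Walkthrough: assigning scaffolds to ancestral linkage groups.

Builds a toy conserved-marker table for three scaffolds against three
ancestral chordate linkage groups (CLGs), tests each (scaffold, CLG) cell
for marker enrichment with the one-sided Fisher exact test, and produces
Oxford-grid dotplot coordinates.

Run:  python examples/synteny_enrichment.py
"""

import numpy as np
import pandas as pd

from gigasm import synteny

rng = np.random.default_rng(5)

# 60 markers: each scaffold is dominated by one CLG, with a few strays
rows = []
dominant = {"scafA": "CLG1", "scafB": "CLG2", "scafC": "CLG3"}
clgs = ["CLG1", "CLG2", "CLG3"]
for scaf, home in dominant.items():
    for i in range(20):
        clg = home if rng.random() < 0.85 else rng.choice(clgs)
        rows.append({"marker_id": f"{scaf}_m{i}", "scaffold_id": scaf,
                     "clg_label": clg, "position": int(rng.integers(1e6))})
markers = pd.DataFrame(rows)

table = synteny.contingency(markers)
print(f"contingency table ({table.to_numpy().sum()} markers):\n{table}\n")

enriched = synteny.fisher_enrichment(table, alpha=0.01, fdr=True)
hits = enriched[enriched["significant"]]
print("significant enrichments (BH-adjusted p <= 0.01):")
print(hits[["scaffold_id", "clg_label", "count", "expected", "p_value"]]
      .to_string(index=False))

dots = synteny.dotplot_data(markers, scaffold_order=sorted(dominant),
                            clg_order=clgs)
print(f"\ndotplot coordinates (first 5 of {len(dots)}):\n{dots.head()}")
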