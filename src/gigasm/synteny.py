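"""Macrosynteny analysis against chordate linkage groups (CLGs).

Ortholog markers, each labelled with an ancestral chordate linkage group,
are tabulated per assembly scaffold; a one-sided Fisher's exact test on the
2x2 collapse of each (scaffold, CLG) cell against the rest of the table
identifies enriched associations (default significance: raw p <= 0.01,
matching common macrosynteny practice; an optional Benjamini-Hochberg
correction is available but off by default).  Dot-plot coordinates for an
Oxford grid are exported from marker ranks.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MARKER_COLUMNS = ("marker_id", "clg_label", "scaffold_id", "position")


def contingency(markers: pd.DataFrame) -> pd.DataFrame:
    """Scaffold x CLG marker counts; grand total equals the marker count."""
    if len(markers) == 0:
        raise ValueError("empty marker table")
    if markers["marker_id"].duplicated().any():
        dup = markers.loc[markers["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id {dup!r}")
    table = pd.crosstab(markers["scaffold_id"], markers["clg_label"])
    return table


def fisher_enrichment(table: pd.DataFrame, alpha: float = 0.01,
                      fdr: bool = False) -> pd.DataFrame:
    """One-sided (enrichment) Fisher's exact test per (scaffold, CLG) cell.

    Each cell is collapsed to the 2x2 table [in-cell vs rest of row;
    rest of column vs remainder]; significance is p <= alpha (on raw p by
    default; on BH-adjusted p when ``fdr``).  Cells in all-zero rows or
    columns are skipped and reported with NaN p.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 scaffolds and 2 CLGs")
    counts = table.to_numpy(dtype=np.int64)
    total = int(counts.sum())
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    # one-sided Fisher on a 2x2 collapse is the hypergeometric upper tail:
    # P(X >= a) with X ~ Hypergeom(total; col_sum successes; row_sum draws)
    rs = np.repeat(row_sums, len(table.columns))
    cs = np.tile(col_sums, len(table.index))
    a = counts.ravel()
    valid = (rs > 0) & (cs > 0)
    p = np.full(a.shape, np.nan)
    p[valid] = stats.hypergeom.sf(a[valid] - 1, total, cs[valid], rs[valid])
    expected = np.where(valid, rs * cs / total, np.nan)
    out = pd.DataFrame({
        "scaffold_id": np.repeat(table.index.to_numpy(dtype=object),
                                 len(table.columns)),
        "clg_label": np.tile(table.columns.to_numpy(dtype=object),
                             len(table.index)),
        "count": a, "expected": expected, "p_value": p,
        "significant": False,
    })
    pvals = out["p_value"]
    if fdr:
        adjusted = _bh_adjust(pvals.to_numpy())
        out["p_adjusted"] = adjusted
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out["significant"] = pvals <= alpha
    out.loc[pvals.isna(), "significant"] = False
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    pv = p[mask]
    n = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    tmp = np.empty(n)
    tmp[order] = np.minimum(ranked, 1.0)
    adj[mask] = tmp
    return adj


def dotplot_data(markers: pd.DataFrame,
                 scaffold_order: Sequence[str],
                 clg_order: Sequence[str]) -> pd.DataFrame:
    """Oxford-grid coordinates: x = marker rank by (scaffold, position),
    y = CLG index."""
    unknown_s = set(markers["scaffold_id"]) - set(scaffold_order)
    unknown_g = set(markers["clg_label"]) - set(clg_order)
    if unknown_s or unknown_g:
        raise ValueError(f"labels missing from supplied orders: "
                         f"{sorted(unknown_s | unknown_g)}")
    s_rank = {s: i for i, s in enumerate(scaffold_order)}
    g_rank = {g: i for i, g in enumerate(clg_order)}
    df = markers.copy()
    df["_srank"] = df["scaffold_id"].map(s_rank)
    df = df.sort_values(["_srank", "position", "marker_id"],
                        kind="mergesort").reset_index(drop=True)
    out = pd.DataFrame({
        "marker_id": df["marker_id"],
        "x_index": np.arange(1, len(df) + 1),
        "y_index": df["clg_label"].map(g_rank) + 1,
        "scaffold_id": df["scaffold_id"],
        "clg_label": df["clg_label"],
    })
    return out
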