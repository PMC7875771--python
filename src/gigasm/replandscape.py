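"""Kimura-divergence repeat landscapes, the 80/80 filter, composition PCA
and TE-expression normalization.

Each repeat copy is summarised against its family consensus by the realised
transition proportion p and transversion proportion q; the Kimura
two-parameter distance K = -1/2 ln((1-2p-q) sqrt(1-2q)) corrects for
multiple hits and is the age proxy landscapes are binned by.  Copies are
optionally filtered by the 80/80 rule (length >= 80 bp and identity >= 80%)
before compositional analyses.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np
import pandas as pd

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA", "unknown")

REQUIRED_COLUMNS = ("copy_id", "family_id", "te_class", "length",
                    "identity", "p", "q")


def k2p_distance(p, q):
    """Kimura 2-parameter distance from transition/transversion proportions.

    K = -1/2 ln((1 - 2p - q) * sqrt(1 - 2q)).  Accepts scalars or arrays;
    raises naming the offending term when the log arguments leave their
    domain (saturated divergence).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("p and q must be non-negative")
    if (p + q > 1).any():
        raise ValueError("p + q exceeds 1")
    t1 = 1.0 - 2.0 * p - q
    t2 = 1.0 - 2.0 * q
    if (t1 <= 0).any():
        raise ValueError("domain violation: 1 - 2p - q must be > 0")
    if (t2 <= 0).any():
        raise ValueError("domain violation: 1 - 2q must be > 0")
    K = -0.5 * np.log(t1 * np.sqrt(t2))
    return float(K) if K.ndim == 0 else K


def copy_divergences(table: Union[pd.DataFrame, str]) -> pd.DataFrame:
    """Per-copy divergence records with the K2P distance appended.

    ``table`` is a DataFrame or a TSV path with columns
    copy_id, family_id, te_class, length, identity (percent), p, q.
    Malformed rows raise with their (1-based) line number.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = table.copy().reset_index(drop=True)
    K = np.empty(len(df))
    for i, row in enumerate(df.itertuples()):
        try:
            K[i] = k2p_distance(row.p, row.q)
        except ValueError as err:
            raise ValueError(f"row {i + 1} (copy {row.copy_id}): {err}") from err
    df["K"] = K
    return df


def filter_8080(records: pd.DataFrame) -> pd.DataFrame:
    """80/80 rule: keep copies >= 80 bp long and >= 80% identical."""
    return records[(records["length"] >= 80)
                   & (records["identity"] >= 80.0)].copy()


def landscape_table(records: pd.DataFrame, bin_width: float = 1.0,
                    max_percent: float = 50.0) -> pd.DataFrame:
    """Repeat landscape: bp per TE class per K2P bin (K in percent).

    Copy lengths are accumulated into ``bin_width``-percent divergence bins
    spanning [0, max_percent); anything beyond lands in a final overflow
    bin (with a warning).  Column totals conserve input bp exactly.
    """
    import warnings

    edges = np.arange(0.0, max_percent + bin_width, bin_width)
    n_bins = len(edges) - 1
    kpct = records["K"].to_numpy() * 100.0
    idx = np.minimum((kpct // bin_width).astype(int), n_bins)
    if (idx == n_bins).any():
        warnings.warn("copies with K beyond the last bin placed in the "
                      "overflow bin", stacklevel=2)
    classes = sorted(records["te_class"].unique())
    table = pd.DataFrame(0.0, index=classes,
                         columns=list(edges[:-1]) + ["overflow"])
    for cls, b, length in zip(records["te_class"], idx, records["length"]):
        col = table.columns[b]
        table.loc[cls, col] += length
    return table


def composition_vector(records: pd.DataFrame, genome_size: float) -> pd.Series:
    """Per-class masked fraction of the genome (records pre-filtered 80/80).

    Classes outside the canonical five (LTR, LINE, SINE, DNA, unknown) are
    ignored; fractions therefore sum to at most 1.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    out = pd.Series(0.0, index=list(TE_CLASSES))
    for cls, sub in records.groupby("te_class"):
        if cls in out.index:
            bp = float(sub["length"].sum())
            if bp > genome_size:
                raise ValueError(f"class {cls} masked bp exceeds genome size")
            out[cls] = bp / genome_size
    return out


def composition_pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame,
                                                   np.ndarray]:
    """PCA of a genomes x class-fractions matrix via covariance eigenvectors.

    Columns are centred; components are ordered by decreasing eigenvalue
    with a deterministic sign convention (the largest-magnitude loading of
    each component is positive).  Returns (scores, loadings,
    explained-variance ratio).
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 genomes")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Xc @ vecs
    pcs = [f"PC{i + 1}" for i in range(vecs.shape[1])]
    evr = vals / vals.sum() if vals.sum() > 0 else vals
    return (pd.DataFrame(scores, index=matrix.index, columns=pcs),
            pd.DataFrame(vecs, index=matrix.columns, columns=pcs),
            evr)


def normalize_te_expression(count: float, consensus_length: float,
                            library_size: float) -> float:
    """Length- and library-normalized TE-family expression.

    n = (count * 10^6 / consensus_length) / (library_size / 10^6):
    counts per consensus-length unit, per million sequenced reads.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if consensus_length <= 0 or library_size <= 0:
        raise ValueError("consensus_length and library_size must be positive")
    return (count * 1e6 / consensus_length) / (library_size / 1e6)
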