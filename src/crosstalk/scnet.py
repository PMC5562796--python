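"""Directed cell-type communication networks from single-cell expression.

Given an annotated genes x cells matrix with T cell types, a gene is called
*highly expressed* in a cell type when the type's mean expression exceeds a
per-gene threshold ``mean + k*sd`` (default k=3).  Where the ligand of a
curated pair is high in a sender type and the receptor high in a receiver
type, a directed communication edge sender -> receiver labeled by the pair
is emitted (self-edges model autocrine signaling).  Edges are counted per
ordered type pair, scored by an exclusiveness measure (a gene's mean in one
type divided by the unweighted mean of the per-type means), and the
top-scoring fraction is reported.

Threshold statistic scope
-------------------------
How the per-gene mean and sd are computed is configurable:

* ``"rest"`` (default) — over the cells *outside* the focal type.  A type
  is flagged when it is an outlier relative to the rest of the tissue; this
  is the only variant whose calls do not saturate for balanced type sizes
  (see below) and it recovers planted signal exactly.
* ``"pooled"`` — over all cells pooled.  Note the hard bound: a type
  holding a fraction p of all cells can never exceed the pooled mean by
  more than sqrt((1-p)/p) pooled sds, whatever the data; for 7 equal-sized
  types that is sqrt(6) < 3, so at k=3 this variant cannot call anything
  on a balanced dataset.  It is usable on real tissues only because cell
  type abundances there are very unbalanced.
* ``"type-means"`` — over the T per-type mean values themselves.  By the
  Samuelson inequality no value among T can exceed the mean by more than
  (T-1)/sqrt(T) sds (ddof=1); for T=7 that is about 2.27 < 3, so at k=3
  this variant never calls anything at all.  Kept for documentation.

A gene with zero threshold-scope sd is never called high.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .pairs import PairDB

__all__ = [
    "type_profiles",
    "call_high",
    "build_network",
    "edge_counts",
    "exclusiveness",
    "rank_edges",
    "filter_involving",
    "export_graphml",
    "max_standardized_deviation_bound",
]

STAT_SCOPES = ("rest", "pooled", "type-means")


def type_profiles(
    matrix: pd.DataFrame, annotations: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-type mean expression profiles.

    Returns ``(profiles, counts)`` where ``profiles`` is genes x types
    (arithmetic mean over the type's cells on the working scale) and
    ``counts`` the number of cells per type.  Every cell must be
    annotated.
    """
    missing = [c for c in matrix.columns if c not in annotations.index]
    if missing:
        raise ValueError(f"unannotated cells: {missing[:10]}")
    ann = annotations.loc[matrix.columns]
    types = sorted(ann.unique())
    profiles = pd.DataFrame(
        {t: matrix.loc[:, (ann == t).to_numpy()].mean(axis=1) for t in types}
    )
    counts = ann.value_counts().reindex(types)
    if (counts < 1).any():
        raise ValueError("every cell type needs at least one cell")
    return profiles, counts


def max_standardized_deviation_bound(n: int) -> float:
    """Samuelson bound: max (x_i - mean)/sd over n values, sd with ddof=1."""
    return (n - 1) / math.sqrt(n)


def call_high(
    matrix: pd.DataFrame,
    annotations: pd.Series,
    k: float = 3.0,
    stat_scope: str = "rest",
) -> pd.DataFrame:
    """Boolean genes x types matrix of high-expression calls.

    Type t is called high for gene i iff the type's mean expression
    exceeds ``mean_i + k * sd_i`` where the per-gene moments are taken over
    the scope selected by ``stat_scope`` (see module docstring).  The call
    is invariant under global rescaling of the matrix, and lowering ``k``
    never removes a call.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if stat_scope not in STAT_SCOPES:
        raise ValueError(f"stat_scope must be one of {STAT_SCOPES}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    profiles, counts = type_profiles(matrix, annotations)
    x = matrix.to_numpy(float)
    m = profiles.to_numpy()
    types = list(profiles.columns)
    eps = 0.0

    if stat_scope == "type-means":
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=1)
        high = m > (mu + k * sd)[:, None]
        high[sd == 0, :] = False
    elif stat_scope == "pooled":
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        high = m > (mu + k * sd)[:, None]
        high[sd == 0, :] = False
    else:  # rest: moments over cells outside the focal type
        ann = annotations.loc[matrix.columns].to_numpy()
        n_tot = x.shape[1]
        s_tot = x.sum(axis=1)
        ss_tot = (x * x).sum(axis=1)
        high = np.zeros((x.shape[0], len(types)), dtype=bool)
        for j, t in enumerate(types):
            mask = ann == t
            n_t = int(mask.sum())
            n_o = n_tot - n_t
            if n_o < 2:
                raise ValueError(
                    f"fewer than 2 cells outside type {t!r}; cannot form a threshold"
                )
            s_o = s_tot - x[:, mask].sum(axis=1)
            ss_o = ss_tot - (x[:, mask] ** 2).sum(axis=1)
            mu_o = s_o / n_o
            var_o = np.maximum(ss_o - n_o * mu_o**2, 0.0) / (n_o - 1)
            sd_o = np.sqrt(var_o)
            col = m[:, j] > mu_o + k * sd_o
            col[sd_o <= eps] = False
            high[:, j] = col
    calls = pd.DataFrame(high, index=profiles.index, columns=types)
    calls.attrs["k"] = float(k)
    calls.attrs["stat_scope"] = stat_scope
    return calls


def build_network(calls: pd.DataFrame, db: PairDB) -> pd.DataFrame:
    """Directed communication edges from high-expression calls.

    For every curated pair (L, R) and every ordered type pair (s, r) with
    L high in s and R high in r, one edge ``s -> r`` labeled (L, R) is
    emitted; s == r (autocrine) is allowed.  Receptor groups are expanded
    to individual pair records — no receptor summation at this stage.
    """
    genes = set(calls.index)
    rows = []
    for p in db.pairs:
        if p.ligand not in genes or p.receptor not in genes:
            continue
        senders = list(calls.columns[calls.loc[p.ligand]])
        receivers = list(calls.columns[calls.loc[p.receptor]])
        for s in senders:
            for r in receivers:
                rows.append((s, r, p.ligand, p.receptor))
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor"])


def edge_counts(edges: pd.DataFrame, types: list[str] | None = None) -> pd.DataFrame:
    """Sender x receiver integer count matrix; its total equals len(edges)."""
    if types is None:
        types = sorted(set(edges["sender"]) | set(edges["receiver"]))
    counts = pd.DataFrame(0, index=types, columns=types, dtype=int)
    for s, r in zip(edges["sender"], edges["receiver"]):
        counts.loc[s, r] += 1
    return counts


def exclusiveness(profiles: pd.DataFrame, cell_type: str, gene: str) -> float:
    """How exclusive a gene's expression is to one cell type.

    The type's mean expression divided by the unweighted mean of the
    per-type means: 1 for a uniformly expressed gene, T for a gene
    expressed in exactly one of T types.  NaN with a warning when the gene
    is silent in every type.
    """
    row = profiles.loc[gene]
    denom = float(row.mean())
    if denom <= 0:
        warnings.warn(f"gene {gene!r} has zero mean across all types")
        return float("nan")
    return float(row[cell_type]) / denom


def rank_edges(
    edges: pd.DataFrame, profiles: pd.DataFrame, top_fraction: float = 0.02
) -> pd.DataFrame:
    """Score, sort and keep the top fraction of edges.

    Each edge is scored by the geometric mean of the sender-ligand and
    receiver-receptor exclusiveness (zero whenever either side is
    non-exclusive); ties are broken lexicographically by (ligand,
    receptor, sender, receiver).  The top ``ceil(top_fraction * N)`` edges
    are returned with a ``score`` column.
    """
    if edges.empty:
        raise ValueError("edge collection is empty")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    scores = []
    for s, r, lig, rec in zip(
        edges["sender"], edges["receiver"], edges["ligand"], edges["receptor"]
    ):
        es = exclusiveness(profiles, s, lig)
        er = exclusiveness(profiles, r, rec)
        scores.append(math.sqrt(max(es, 0.0) * max(er, 0.0)))
    scored = edges.copy()
    scored["score"] = scores
    scored = scored.sort_values(
        by=["score", "ligand", "receptor", "sender", "receiver"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n_keep = math.ceil(top_fraction * len(scored))
    return scored.head(n_keep)


def filter_involving(edges: pd.DataFrame, focal_type: str) -> pd.DataFrame:
    """Edges where the focal type is sender or receiver (autocrine kept)."""
    mask = (edges["sender"] == focal_type) | (edges["receiver"] == focal_type)
    return edges[mask].reset_index(drop=True)


def export_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    """Write the directed multigraph (typed nodes, pair-labeled edges)."""
    g = nx.MultiDiGraph()
    for row in edges.itertuples(index=False):
        attrs = {"ligand": row.ligand, "receptor": row.receptor}
        if hasattr(row, "score"):
            attrs["score"] = float(row.score)
        g.add_edge(row.sender, row.receiver, **attrs)
    nx.write_graphml(g, str(path))
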