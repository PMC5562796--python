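"""Classification of normal-to-cancer correlation shifts.

A pair's (rho_normal, rho_cancer) point is assigned to one of three areas
of the scatter plane, away from the diagonal:

* **I**   — uncorrelated in normal (strictly inside the +/-0.25 band) but
  positively correlated in cancer (> 0.5): gained correlation.
* **II**  — negatively correlated in normal (< -0.5) but uncorrelated in
  cancer: lost negative correlation.
* **III** — positively correlated in normal (> 0.5) but uncorrelated in
  cancer: lost positive correlation.

Everything else (including boundary values, the inequalities being strict)
is ``none``.  The +/-0.25 "uncorrelated" band is the documented default,
motivated by the fluctuation of correlation estimates between randomized
half-cohorts; :func:`estimate_noise_band` recalibrates it on any cohort.
Pairs recurrently falling in the same area across cohorts are ranked by
:func:`recurrence_rank`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import pair_correlations, pairwise_spearman, _pair_matrices
from .pairs import PairDB
from .simulate import BulkCohort

__all__ = [
    "ShiftThresholds",
    "classify_shift",
    "shift_table",
    "estimate_noise_band",
    "recurrence_rank",
]

CATEGORIES = ("I", "II", "III", "none")


@dataclass(frozen=True)
class ShiftThresholds:
    """Cut points defining the uncorrelated band and the correlated tails."""

    uncorrelated_low: float = -0.25
    uncorrelated_high: float = 0.25
    correlated: float = 0.5
    anticorrelated: float = -0.5

    def __post_init__(self) -> None:
        if not (self.uncorrelated_low < 0 < self.uncorrelated_high):
            raise ValueError("uncorrelated band must straddle 0")
        if self.correlated <= self.uncorrelated_high:
            raise ValueError("correlated cut must exceed the band")
        if self.anticorrelated >= self.uncorrelated_low:
            raise ValueError("anticorrelated cut must fall below the band")

    def uncorrelated(self, rho: float) -> bool:
        return self.uncorrelated_low < rho < self.uncorrelated_high


def classify_shift(
    rho_normal: float,
    rho_cancer: float,
    thresholds: ShiftThresholds = ShiftThresholds(),
) -> str:
    """Assign one shift category to a (rho_normal, rho_cancer) point.

    Missing values map to ``none``.  The three areas are mutually
    exclusive by construction, so the assignment partitions [-1, 1]^2.
    """
    if not (np.isfinite(rho_normal) and np.isfinite(rho_cancer)):
        return "none"
    for rho in (rho_normal, rho_cancer):
        if abs(rho) > 1:
            raise ValueError(f"correlation out of range: {rho}")
    t = thresholds
    if t.uncorrelated(rho_normal) and rho_cancer > t.correlated:
        return "I"
    if rho_normal < t.anticorrelated and t.uncorrelated(rho_cancer):
        return "II"
    if rho_normal > t.correlated and t.uncorrelated(rho_cancer):
        return "III"
    return "none"


def shift_table(
    normal_records: pd.DataFrame,
    cancer_records: pd.DataFrame,
    thresholds: ShiftThresholds = ShiftThresholds(),
) -> pd.DataFrame:
    """Join per-condition correlation records and classify each pair.

    Expects the output of :func:`crosstalk.correlation.pair_correlations`
    for the two conditions; pairs are matched on (ligand, receptors).
    Adds a ``missing`` flag for pairs with an undefined rho on either side.
    """
    merged = normal_records.merge(
        cancer_records,
        on=["ligand", "receptors"],
        suffixes=("_normal", "_cancer"),
    )
    cats = [
        classify_shift(rn, rc, thresholds)
        for rn, rc in zip(merged["rho_normal"], merged["rho_cancer"])
    ]
    out = merged[["ligand", "receptors", "rho_normal", "rho_cancer"]].copy()
    out["category"] = cats
    out["missing"] = ~(
        np.isfinite(out["rho_normal"]) & np.isfinite(out["rho_cancer"])
    )
    return out


def estimate_noise_band(
    cohort: BulkCohort,
    db: PairDB,
    group_size: int,
    n_reps: int = 1000,
    seed: int | None = None,
    condition: str = "normal",
    percentile: float = 95.0,
) -> float:
    """Calibrate the uncorrelated band width by randomized cohort splits.

    For each repetition two random subsets of ``group_size`` samples are
    drawn (independently, so they may overlap — drawing 2x65 from 112
    normal samples forces overlap) and the per-pair correlation difference
    between them recorded; the returned band half-width is the given
    percentile of |delta rho| pooled over pairs and repetitions.
    """
    if group_size < 3:
        raise ValueError("group_size must be >= 3")
    if seed is None:
        raise ValueError("a seed is mandatory for the randomized split")
    cols = cohort.samples(condition)
    if len(cols) < group_size + 1:
        raise ValueError("cohort must have more samples than group_size")
    a, b, _, _ = _pair_matrices(cohort.expression[cols], db)
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_reps):
        idx1 = rng.choice(len(cols), size=group_size, replace=False)
        idx2 = rng.choice(len(cols), size=group_size, replace=False)
        rho1 = pairwise_spearman(a[:, idx1], b[:, idx1])
        rho2 = pairwise_spearman(a[:, idx2], b[:, idx2])
        d = np.abs(rho1 - rho2)
        deltas.append(d[np.isfinite(d)])
    pooled = np.concatenate(deltas)
    if pooled.size == 0:
        raise ValueError("no finite correlation differences")
    return float(np.percentile(pooled, percentile))


def recurrence_rank(
    tables: list[pd.DataFrame], top_k: int = 15
) -> dict[str, pd.DataFrame]:
    """Rank pairs by how often they fall in each shift area across cohorts.

    Sort key per category: number of cohorts in the category (desc), then
    mean |rho_cancer - rho_normal| across those cohorts (desc), then the
    pair name (asc) to make ties deterministic.  Returns the top ``top_k``
    pairs per category.
    """
    if not tables:
        raise ValueError("need at least one shift table")
    stacked = pd.concat(tables, ignore_index=True)
    stacked["pair"] = stacked["ligand"] + "|" + stacked["receptors"]
    stacked["abs_shift"] = (stacked["rho_cancer"] - stacked["rho_normal"]).abs()
    out: dict[str, pd.DataFrame] = {}
    for cat in ("I", "II", "III"):
        sub = stacked[stacked["category"] == cat]
        if sub.empty:
            out[cat] = pd.DataFrame(
                columns=["pair", "n_cohorts", "mean_abs_shift"]
            )
            continue
        agg = (
            sub.groupby("pair")
            .agg(n_cohorts=("pair", "size"), mean_abs_shift=("abs_shift", "mean"))
            .reset_index()
        )
        agg = agg.sort_values(
            by=["n_cohorts", "mean_abs_shift", "pair"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        out[cat] = agg.head(top_k)
    return out
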