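"""Per-pair Spearman correlation, random-pair nulls and K-S comparisons.

Within each condition, the Spearman correlation between a ligand's
expression and the expression of its cognate receptor(s) across samples is
the working proxy for co-regulated cell-cell signaling.  For non-bijective
relations (one ligand, several receptors) the correlation is computed
between the ligand and the element-wise sum of its receptors' expression on
the linear abundance scale.  Random non-interacting (ligand, receptor)
pairs provide a background distribution; distributions are compared with
the two-sample Kolmogorov-Smirnov statistic and summarized by mean,
standard deviation and coefficient of variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import PairDB, sample_random_pairs
from .simulate import BulkCohort

__all__ = [
    "spearman",
    "pairwise_spearman",
    "pair_correlations",
    "random_null",
    "summarize_distribution",
    "ks_compare",
    "CorrDistributionSummary",
    "KSResult",
]

logger = logging.getLogger(__name__)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (midranks for ties).

    Returns NaN with a warning when either vector is constant; inputs must
    have equal length >= 3.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pairwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation between paired rows of ``a`` and ``b``.

    Vectorized over pairs: ranks (midranks for ties) along axis 1, then a
    row-wise Pearson correlation of the rank vectors.  Rows where either
    side is constant yield NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be 2-D arrays of identical shape")
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _pair_matrices(
    expr: pd.DataFrame, db: PairDB
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]], int]:
    """Ligand rows and receptor-sum rows for every measurable ligand group.

    Returns (ligand matrix, receptor-sum matrix, (ligand, receptor-label)
    list, number of skipped groups).  A group is skipped when the ligand or
    every one of its receptors is absent from the matrix.
    """
    index = set(expr.index)
    lig_rows, rec_rows, labels = [], [], []
    skipped = 0
    for lig in sorted(db.receptor_groups):
        recs = sorted(r for r in db.receptor_group(lig) if r in index)
        if lig not in index or not recs:
            skipped += 1
            continue
        lig_rows.append(expr.loc[lig].to_numpy(float))
        rec_rows.append(expr.loc[recs].to_numpy(float).sum(axis=0))
        labels.append((lig, "+".join(recs)))
    if not labels:
        raise ValueError("no ligand-receptor pair has both sides measured")
    return np.array(lig_rows), np.array(rec_rows), labels, skipped


def pair_correlations(
    cohort: BulkCohort,
    db: PairDB,
    condition: str,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation per ligand group within one condition.

    One record per ligand with at least one measured receptor: the
    correlation between the ligand and the linear-scale sum of its
    receptors across that condition's samples (optionally restricted to
    ``samples``).  Returns a DataFrame with columns ``ligand, receptors,
    rho, n, condition, pair_class``; the number of skipped ligand groups is
    recorded in ``.attrs["n_skipped"]``.
    """
    cols = cohort.samples(condition) if samples is None else list(samples)
    if len(cols) < 3:
        raise ValueError(f"condition {condition!r} has fewer than 3 samples")
    expr = cohort.expression[cols]
    a, b, labels, skipped = _pair_matrices(expr, db)
    if skipped:
        logger.info("pair_correlations: skipped %d ligand groups with missing genes", skipped)
    rho = pairwise_spearman(a, b)
    out = pd.DataFrame(
        {
            "ligand": [l for l, _ in labels],
            "receptors": [r for _, r in labels],
            "rho": rho,
            "n": len(cols),
            "condition": condition,
            "pair_class": "specific",
        }
    )
    out.attrs["n_skipped"] = skipped
    return out


def random_null(
    cohort: BulkCohort,
    db: PairDB,
    n_sample: int,
    seed: int,
    condition: str,
) -> pd.DataFrame:
    """Spearman correlations of random non-interacting (ligand, receptor) pairs.

    No receptor summation is applied — a random pair has no cognate group.
    Pairs whose genes are absent from the matrix are skipped.
    """
    cols = cohort.samples(condition)
    if len(cols) < 3:
        raise ValueError(f"condition {condition!r} has fewer than 3 samples")
    expr = cohort.expression[cols]
    index = set(expr.index)
    pairs = sample_random_pairs(db, n_sample, seed, exclude_known=True)
    kept = [(l, r) for l, r in pairs if l in index and r in index]
    if not kept:
        raise ValueError("no random pair has both genes measured")
    a = expr.loc[[l for l, _ in kept]].to_numpy(float)
    b = expr.loc[[r for _, r in kept]].to_numpy(float)
    rho = pairwise_spearman(a, b)
    out = pd.DataFrame(
        {
            "ligand": [l for l, _ in kept],
            "receptors": [r for _, r in kept],
            "rho": rho,
            "n": len(cols),
            "condition": condition,
            "pair_class": "random",
        }
    )
    out.attrs["n_skipped"] = len(pairs) - len(kept)
    return out


@dataclass(frozen=True)
class CorrDistributionSummary:
    """Location and dispersion of a correlation-coefficient collection."""

    condition: str
    pair_class: str
    mean: float
    sd: float
    cv: float | None  # sd / |mean|; None when the mean is ~0
    n: int


def summarize_distribution(records: pd.DataFrame) -> CorrDistributionSummary:
    """Mean, sd (ddof=1) and coefficient of variation of the rho values.

    The CV is ``sd / |mean|`` and reported as missing (None) when the mean
    is numerically zero.  Requires at least 2 finite records.
    """
    rho = records["rho"].to_numpy(float)
    rho = rho[np.isfinite(rho)]
    if rho.size < 2:
        raise ValueError("need at least 2 finite correlation records")
    mean = float(rho.mean())
    sd = float(rho.std(ddof=1))
    cv = None if abs(mean) < 1e-12 else sd / abs(mean)
    cond = records["condition"].iloc[0] if "condition" in records else ""
    klass = records["pair_class"].iloc[0] if "pair_class" in records else ""
    return CorrDistributionSummary(
        condition=str(cond), pair_class=str(klass), mean=mean, sd=sd, cv=cv, n=rho.size
    )


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    d: float
    pvalue: float
    n_a: int
    n_b: int


def ks_compare(a, b) -> KSResult:
    """Two-sample K-S test: D = sup |ECDF_a - ECDF_b|, asymptotic P."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(d=float(res.statistic), pvalue=float(res.pvalue), n_a=a.size, n_b=b.size)
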