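"""Moderated-t differential expression and pair regulation scenarios.

Per gene j, expression (log2 with pseudocount) is modeled as
``E[y_j] = X a_j`` with an indicator design (0 = normal, 1 = cancer), so the
contrast coefficient is the cancer-minus-normal difference of group means in
log2 units.  Per-gene residual variances are shrunk toward a global prior by
empirical Bayes: the posterior variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with prior df ``d0`` and scale ``s0^2`` estimated by moment matching on
log s^2 (the classical moderated-t construction), and the moderated
t-statistic ``coef / (s~ * u)`` is referred to a t distribution with
``d0 + d`` degrees of freedom.  Genes are then gated at a fold-change and
P-value threshold and ligand-receptor pairs classified by the joint
direction of their two members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .pairs import PairDB
from .simulate import BulkCohort

__all__ = [
    "LinearFit",
    "fit_linear_model",
    "moderate",
    "select_de",
    "classify_pairs",
    "trigamma_inverse",
    "SCENARIOS",
]

#: pair regulation scenarios: joint direction of (ligand, receptor)
SCENARIOS = ("both_up", "one_up", "both_down", "one_down", "discordant", "none")


@dataclass
class LinearFit:
    """Per-gene OLS fit of the two-group linear model."""

    genes: pd.Index
    coef: np.ndarray  # contrast coefficient (log2 cancer - normal)
    sigma2: np.ndarray  # residual variance s^2
    df_residual: float  # residual df d
    stdev_unscaled: float  # sqrt of contrast entry of (X'X)^-1


def _design_from_condition(condition: pd.Series) -> np.ndarray:
    ind = (condition == "cancer").to_numpy(dtype=float)
    return np.column_stack([np.ones_like(ind), ind])


def fit_linear_model(
    cohort: BulkCohort,
    design: np.ndarray | None = None,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    contrast_index: int = -1,
) -> LinearFit:
    """Ordinary least squares per gene on the (log2) expression matrix.

    With the default indicator design the contrast coefficient equals the
    difference of group means.  A custom ``design`` (samples x columns) may
    be supplied; the contrast is its ``contrast_index`` column.
    """
    n_norm = len(cohort.samples("normal"))
    n_canc = len(cohort.samples("cancer"))
    if min(n_norm, n_canc) < 2:
        raise ValueError("each condition needs at least 2 samples")
    y = cohort.expression.to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + pseudocount)
    x = _design_from_condition(cohort.condition) if design is None else np.asarray(design, float)
    if x.shape[0] != y.shape[1]:
        raise ValueError("design row count must equal sample count")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv  # genes x m
    resid = y - beta @ x.T
    d = x.shape[0] - x.shape[1]
    sigma2 = (resid**2).sum(axis=1) / d
    c = contrast_index % x.shape[1]
    return LinearFit(
        genes=cohort.expression.index,
        coef=beta[:, c],
        sigma2=sigma2,
        df_residual=float(d),
        stdev_unscaled=float(np.sqrt(xtx_inv[c, c])),
    )


def trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by bisection.

    trigamma is strictly decreasing from +inf to 0 on (0, inf), so the
    root is unique; brackets are widened geometrically before bisecting to
    relative tolerance ``tol``.
    """
    if y <= 0:
        raise ValueError("trigamma is positive; target must be > 0")
    lo, hi = 1e-9, 1.0
    while special.polygamma(1, hi) > y:
        hi *= 2.0
        if hi > 1e12:
            return hi
    while special.polygamma(1, lo) < y:
        lo /= 2.0
    while (hi - lo) > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(sigma2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the first two moments of ``log s^2`` against the scaled-F
    sampling model: ``e = log s^2 - digamma(d/2) + log(d/2)`` has mean
    ``log s0^2 - digamma(d0/2) + log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond ``trigamma(d/2)``.  A non-positive excess
    yields an infinite prior df (complete shrinkage).
    """
    s2 = np.asarray(sigma2, float)
    ok = s2 > 1e-24  # exact fits leave fp dust in the residuals
    if not ok.any():
        raise ValueError("all residual variances are zero")
    if (~ok).any():
        warnings.warn(f"dropping {(~ok).sum()} zero residual variances from prior fit")
        s2 = s2[ok]
    if s2.size < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    d = df_residual
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (e.size - 1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        half_d0 = trigamma_inverse(float(evar))
        d0 = 2.0 * half_d0
        s0_2 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def moderate(
    fit: LinearFit,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-statistics for a :class:`LinearFit`.

    ``d0``/``s0_2`` may be forced (``d0=0`` reproduces the ordinary t;
    ``d0=inf`` uses the prior variance alone); by default they are
    estimated from the data.  Returns a DataFrame with columns
    ``log2fc, t, pvalue, fdr`` indexed by gene; FDR is Benjamini-Hochberg.
    """
    if d0 is None:
        d0, s0_est = estimate_prior(fit.sigma2, fit.df_residual)
        if s0_2 is None:
            s0_2 = s0_est
    elif s0_2 is None and d0 > 0:
        _, s0_2 = estimate_prior(fit.sigma2, fit.df_residual)
    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = fit.sigma2
        df_total = d
    else:
        s2_post = (d0 * s0_2 + d * fit.sigma2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef / (np.sqrt(s2_post) * fit.stdev_unscaled)
    df_p = min(df_total, 1e300) if np.isfinite(df_total) else np.inf
    if np.isinf(df_p):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_p)
    p = np.where(np.isnan(t), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": fit.coef, "t": t, "pvalue": p, "fdr": fdr}, index=fit.genes
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2) if s0_2 is not None else None
    out.attrs["df_residual"] = d
    return out


def select_de(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_fdr: bool = False,
) -> tuple[set[str], set[str]]:
    """Gate genes into up / down sets at a fold-change and P threshold.

    Thresholds are inclusive (``log2fc >= log2(fc)`` and ``P <= p``); the
    default gate uses the raw P-value, ``use_fdr`` switches to the BH
    adjusted one.
    """
    if results.empty:
        raise ValueError("empty DE results")
    lfc_cut = np.log2(fc_threshold)
    p = results["fdr"] if use_fdr else results["pvalue"]
    sig = p <= p_threshold
    up = set(results.index[sig & (results["log2fc"] >= lfc_cut)])
    down = set(results.index[sig & (results["log2fc"] <= -lfc_cut)])
    return up, down


def _direction(gene: str, up: set[str], down: set[str]) -> str:
    if gene in up:
        return "up"
    if gene in down:
        return "down"
    return "unchanged"


def classify_pairs(
    up: set[str], down: set[str], db: PairDB
) -> pd.DataFrame:
    """Assign each curated pair one regulation scenario.

    The joint (ligand, receptor) direction grid maps onto: both members up
    -> ``both_up``; exactly one up, other unchanged -> ``one_up``; both
    down -> ``both_down``; exactly one down, other unchanged ->
    ``one_down``; one up and one down -> ``discordant``; neither changed
    -> ``none``.  The assignment is exhaustive and mutually exclusive.
    """
    if up & down:
        raise ValueError(f"up and down sets overlap: {sorted(up & down)[:5]}")
    rows = []
    for p in db.pairs:
        dl = _direction(p.ligand, up, down)
        dr = _direction(p.receptor, up, down)
        n_up = (dl == "up") + (dr == "up")
        n_down = (dl == "down") + (dr == "down")
        if n_up == 2:
            scen = "both_up"
        elif n_down == 2:
            scen = "both_down"
        elif n_up == 1 and n_down == 1:
            scen = "discordant"
        elif n_up == 1:
            scen = "one_up"
        elif n_down == 1:
            scen = "one_down"
        else:
            scen = "none"
        rows.append((p.ligand, p.receptor, dl, dr, scen))
    return pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "ligand_direction", "receptor_direction", "scenario"],
    )
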