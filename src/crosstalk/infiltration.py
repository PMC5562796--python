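"""Stratification of tumors by non-neoplastic cell infiltration.

Bulk tumor samples carry admixed lymphocytes, monocytes, neutrophils and
stromal cells.  If that infiltrate drove the ligand-receptor co-expression
signal, tumors rich in infiltrating cells should show a different
correlation distribution than infiltrate-poor tumors.  The test: split the
cancer samples at the 25% quantiles of an admixture fraction, recompute the
per-pair correlations within the high and low groups, and compare the two
rho distributions by Q-Q matching and a two-sample K-S test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .correlation import KSResult, ks_compare, pair_correlations
from .pairs import PairDB
from .simulate import ADMIXTURE_TYPES, BulkCohort

__all__ = ["quantile_split", "compare_infiltration_groups", "ADMIXTURE_TYPES"]


def quantile_split(
    table: pd.DataFrame, cell_type: str, q: float = 0.25
) -> tuple[list[str], list[str]]:
    """Split samples into high- and low-infiltration groups at quantile ``q``.

    ``high`` holds samples whose fraction is >= the (1-q) empirical
    quantile, ``low`` those <= the q quantile (midpoint interpolation;
    ties are included on both boundaries, so groups can exceed ceil(q*n)).
    Requires >= 8 samples with a non-missing fraction.  When every fraction
    is identical both groups contain all samples and a degeneracy warning
    is raised.
    """
    if cell_type not in table.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    if not (0 < q < 0.5):
        raise ValueError("q must lie in (0, 0.5)")
    frac = table[cell_type].dropna()
    if len(frac) < 8:
        raise ValueError("need at least 8 samples with a measured fraction")
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    values = frac.to_numpy(float)
    if np.ptp(values) == 0:
        warnings.warn("all fractions identical: degenerate quantile split")
        all_samples = list(frac.index)
        return all_samples, all_samples
    hi_cut = float(np.quantile(values, 1 - q, method="midpoint"))
    lo_cut = float(np.quantile(values, q, method="midpoint"))
    high = list(frac.index[frac >= hi_cut])
    low = list(frac.index[frac <= lo_cut])
    return high, low


def compare_infiltration_groups(
    cohort: BulkCohort,
    db: PairDB,
    split: tuple[list[str], list[str]],
    n_quantiles: int = 99,
) -> tuple[pd.DataFrame, KSResult]:
    """Compare the pair-correlation distribution between two sample groups.

    Per-pair correlations are recomputed within each group; the Q-Q points
    match the two rho distributions on a grid of ``n_quantiles`` equally
    spaced percentiles and the K-S test compares the full collections.
    """
    high, low = split
    if len(high) < 3 or len(low) < 3:
        raise ValueError("each group needs at least 3 samples")
    rho_high = pair_correlations(cohort, db, "cancer", samples=high)["rho"]
    rho_low = pair_correlations(cohort, db, "cancer", samples=low)["rho"]
    grid = np.linspace(1, 99, n_quantiles)
    qq = pd.DataFrame(
        {
            "percentile": grid,
            "rho_high": np.nanpercentile(rho_high.to_numpy(float), grid),
            "rho_low": np.nanpercentile(rho_low.to_numpy(float), grid),
        }
    )
    ks = ks_compare(rho_high, rho_low)
    return qq, ks
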