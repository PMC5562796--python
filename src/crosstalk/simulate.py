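"""Synthetic cohorts with known planted structure.

Every downstream stage of the pipeline (differential expression, pair
correlation, correlation-shift classification, infiltration stratification,
single-cell network extraction) is validated against data generated here,
where the ground truth is known exactly:

* **Bulk cohorts** — two-condition (normal / cancer) expression matrices.
  Marginals are log-normal by default (mimicking normalized RNA-seq
  abundance estimates) or negative binomial on counts.  Differential
  expression is planted by scaling a gene's cancer-condition mean by
  ``2**log2fc``.  Pair correlation is planted through a Gaussian copula:
  the latent bivariate-normal correlation ``r`` is chosen so that the
  normal-score Spearman ``(6/pi)*arcsin(r/2)`` equals the target; because
  the marginal transform is monotone, continuous marginals carry the
  Spearman correlation through unchanged.
* **Infiltration fractions** — per-cancer-sample proportions of four
  non-neoplastic admixture cell types (lymphocyte, monocyte, neutrophil,
  stromal), drawn from a Dirichlet together with a tumor-purity component
  so the four fractions are each in [0, 1] and sum below 1.  An optional
  association mode couples one pair's correlation strength to a chosen
  fraction, to probe the sensitivity of the quantile stratification.
* **Single cells** — negative-binomial counts per (cell type, gene), the
  standard model for scRNA-seq count noise.  A planted communication edge
  multiplies the ligand's mean in the sender type and the receptor's mean
  in the receiver type by an elevation factor.

Seeds are mandatory: a spec without a seed does not construct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BulkCohortSpec",
    "SingleCellSpec",
    "PlantedEdge",
    "BulkCohort",
    "TruthRecord",
    "InfiltrationAssociation",
    "simulate_bulk",
    "simulate_infiltration",
    "simulate_single_cells",
    "latent_correlation",
]

#: cell types used for infiltration fraction tables
ADMIXTURE_TYPES = ("lymphocyte", "monocyte", "neutrophil", "stromal")

MAX_TARGET_RHO = 0.95


def latent_correlation(rho_s: float) -> float:
    """Latent bivariate-normal correlation giving Spearman ``rho_s``.

    Inverts ``rho_s = (6/pi) * arcsin(r/2)``, the classical relation between
    the Pearson correlation of a bivariate Gaussian and the Spearman
    correlation of any monotone transform of its margins.
    """
    if abs(rho_s) > MAX_TARGET_RHO:
        raise ValueError(
            f"target Spearman {rho_s} outside the feasible band "
            f"[-{MAX_TARGET_RHO}, {MAX_TARGET_RHO}]"
        )
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


@dataclass
class BulkCohort:
    """Genes x samples expression with per-sample condition labels."""

    expression: pd.DataFrame  # genes x samples, non-negative, no missing
    condition: pd.Series  # sample -> {"normal", "cancer"}
    infiltration: pd.DataFrame | None = None  # cancer samples x 4 fractions

    def __post_init__(self) -> None:
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        labels = set(self.condition.unique())
        if not {"normal", "cancer"} <= labels:
            raise ValueError("condition labels must cover both normal and cancer")
        if list(self.condition.index) != list(self.expression.columns):
            raise ValueError("condition index must match expression columns")

    def samples(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset(self, samples: Sequence[str]) -> "BulkCohort":
        samples = list(samples)
        return BulkCohort(
            expression=self.expression[samples],
            condition=self.condition.loc[samples],
            infiltration=None
            if self.infiltration is None
            else self.infiltration.reindex(
                [s for s in samples if s in self.infiltration.index]
            ),
        )


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a simulated dataset."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2fc
    pair_corr: dict[str, tuple[float, float]] = field(default_factory=dict)
    # "LIG|REC" -> (rho_normal, rho_cancer)
    edges: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (sender, receiver, ligand, receptor)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "pair_corr": {k: list(v) for k, v in self.pair_corr.items()},
            "edges": [list(e) for e in self.edges],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes={k: float(v) for k, v in payload["de_genes"].items()},
            pair_corr={
                k: (float(v[0]), float(v[1]))
                for k, v in payload["pair_corr"].items()
            },
            edges=[tuple(e) for e in payload["edges"]],
        )


@dataclass
class BulkCohortSpec:
    """Recipe for a two-condition bulk cohort.

    Parameters
    ----------
    genes
        Gene symbols of the matrix rows.
    n_normal, n_cancer
        Sample counts per condition (each >= 2).
    seed
        Mandatory RNG seed.
    baseline_mean
        Scalar or per-gene linear-scale mean abundance.
    sigma_log
        Log-normal shape parameter (natural-log sd) for the default
        marginal; 0.5 gives a coefficient of variation of ~53%, typical of
        moderately expressed genes across patients.
    nb_dispersion
        Size parameter of the negative-binomial marginal (``marginal="nb"``).
    planted_de
        gene -> log2 fold-change applied to the cancer mean.
    planted_corr
        (ligand, receptor) -> (target Spearman in normal, in cancer).
        Pairs must not share genes with one another (joint copula planting
        across overlapping pairs is infeasible in general and rejected).
    """

    genes: Sequence[str]
    n_normal: int
    n_cancer: int
    seed: int
    baseline_mean: float | Mapping[str, float] = 100.0
    sigma_log: float = 0.5
    nb_dispersion: float = 10.0
    marginal: str = "lognormal"
    planted_de: Mapping[str, float] = field(default_factory=dict)
    planted_corr: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for a simulation spec")
        if self.n_normal < 2 or self.n_cancer < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.marginal not in ("lognormal", "nb"):
            raise ValueError(f"unknown marginal: {self.marginal!r}")
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene symbols in spec")
        for g in self.planted_de:
            if g not in gene_set:
                raise ValueError(f"planted DE gene {g!r} not in gene list")
        used: set[str] = set()
        for (lig, rec), (rn, rc) in self.planted_corr.items():
            for g in (lig, rec):
                if g not in gene_set:
                    raise ValueError(f"planted pair gene {g!r} not in gene list")
                if g in used:
                    raise ValueError(
                        f"gene {g!r} appears in more than one planted pair; "
                        "overlapping pairs cannot be jointly planted"
                    )
                used.add(g)
            for rho in (rn, rc):
                if abs(rho) > MAX_TARGET_RHO:
                    raise ValueError(
                        f"target Spearman {rho} for pair ({lig},{rec}) "
                        f"exceeds |{MAX_TARGET_RHO}|"
                    )


def _mean_vector(spec: BulkCohortSpec) -> np.ndarray:
    if isinstance(spec.baseline_mean, Mapping):
        return np.array([float(spec.baseline_mean[g]) for g in spec.genes])
    return np.full(len(spec.genes), float(spec.baseline_mean))


def simulate_bulk(spec: BulkCohortSpec) -> tuple[BulkCohort, TruthRecord]:
    """Draw a bulk cohort with the planted structure of ``spec``.

    Per condition, a latent standard-normal matrix is drawn; for each
    planted pair the receptor's latent row is replaced by a mixture with
    the ligand's row at the copula correlation for that condition's target
    Spearman.  Latent scores are then pushed through the marginal: the
    log-normal marginal ``mean * exp(sigma*z - sigma^2/2)`` has expectation
    exactly ``mean``; the negative-binomial marginal maps the normal CDF
    through the NB quantile function.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    gi = {g: i for i, g in enumerate(genes)}
    base = _mean_vector(spec)

    blocks: list[pd.DataFrame] = []
    labels: list[str] = []
    names: list[str] = []
    for cond, n, prefix in (
        ("normal", spec.n_normal, "N"),
        ("cancer", spec.n_cancer, "C"),
    ):
        z = rng.standard_normal((len(genes), n))
        for (lig, rec), (rho_n, rho_c) in spec.planted_corr.items():
            rho = rho_n if cond == "normal" else rho_c
            r = latent_correlation(rho)
            li, ri = gi[lig], gi[rec]
            z[ri] = r * z[li] + np.sqrt(1.0 - r * r) * z[ri]
        mean = base.copy()
        if cond == "cancer":
            for g, lfc in spec.planted_de.items():
                mean[gi[g]] *= 2.0 ** float(lfc)
        if spec.marginal == "lognormal":
            s = spec.sigma_log
            x = mean[:, None] * np.exp(s * z - 0.5 * s * s)
        else:
            size = spec.nb_dispersion
            p = size / (size + mean)
            u = stats.norm.cdf(z)
            x = stats.nbinom.ppf(u, size, p[:, None])
        blocks.append(pd.DataFrame(x, index=genes))
        labels += [cond] * n
        names += [f"{prefix}{i + 1}" for i in range(n)]

    expr = pd.concat(blocks, axis=1)
    expr.columns = names
    expr.index.name = "gene"
    condition = pd.Series(labels, index=names, name="condition")
    truth = TruthRecord(
        de_genes=dict(spec.planted_de),
        pair_corr={
            f"{lig}|{rec}": (float(rn), float(rc))
            for (lig, rec), (rn, rc) in spec.planted_corr.items()
        },
    )
    return BulkCohort(expression=expr, condition=condition), truth


@dataclass
class InfiltrationAssociation:
    """Couple one pair's correlation strength to an admixture fraction.

    Cancer samples with the fraction above its median get the pair
    re-planted at ``rho_high``; those below at ``rho_low``.  The cohort's
    expression for the two genes is regenerated in place.
    """

    pair: tuple[str, str]
    cell_type: str = "lymphocyte"
    rho_high: float = 0.8
    rho_low: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_type not in ADMIXTURE_TYPES:
            raise ValueError(f"unknown admixture type {self.cell_type!r}")


def simulate_infiltration(
    cohort: BulkCohort,
    association: InfiltrationAssociation | None = None,
    seed: int | None = None,
    sigma_log: float = 0.5,
) -> pd.DataFrame:
    """Draw infiltration fractions for the cohort's cancer samples.

    Fractions for the four admixture types come from a Dirichlet prior with
    a dominant tumor-purity component (means ~12% lymphocyte, 8% monocyte,
    4% neutrophil, 16% stromal).  With ``association`` set, the named
    pair's two genes are regenerated so that their Spearman correlation
    differs between samples above and below the median fraction; the
    cohort's expression matrix is modified in place and the table is
    attached as ``cohort.infiltration``.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for infiltration simulation")
    rng = np.random.default_rng(seed)
    cancer = cohort.samples("cancer")
    alpha = np.array([1.5, 1.0, 0.5, 2.0, 7.0])
    draws = rng.dirichlet(alpha, size=len(cancer))[:, :4]
    table = pd.DataFrame(draws, index=cancer, columns=list(ADMIXTURE_TYPES))
    table.index.name = "sample"

    if association is not None:
        lig, rec = association.pair
        for g in (lig, rec):
            if g not in cohort.expression.index:
                raise ValueError(f"association gene {g!r} not in cohort")
        frac = table[association.cell_type]
        high = frac >= frac.median()
        base = cohort.expression.loc[[lig, rec], cancer].mean(axis=1).to_numpy()
        for mask, rho in ((high, association.rho_high), (~high, association.rho_low)):
            cols = list(frac.index[mask])
            if not cols:
                continue
            r = latent_correlation(rho)
            zl = rng.standard_normal(len(cols))
            zr = r * zl + np.sqrt(1 - r * r) * rng.standard_normal(len(cols))
            s = sigma_log
            cohort.expression.loc[lig, cols] = base[0] * np.exp(s * zl - s * s / 2)
            cohort.expression.loc[rec, cols] = base[1] * np.exp(s * zr - s * s / 2)
    cohort.infiltration = table
    return table


@dataclass(frozen=True)
class PlantedEdge:
    """A ground-truth communication edge for single-cell simulation."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    elevation: float = 20.0

    def __post_init__(self) -> None:
        if self.elevation <= 1.0:
            raise ValueError("elevation factor must exceed 1")


@dataclass
class SingleCellSpec:
    """Recipe for an annotated single-cell count matrix.

    Counts are negative binomial per (cell type, gene) with a common
    dispersion (size) parameter; a planted edge multiplies the ligand mean
    in the sender type and the receptor mean in the receiver type by the
    edge's elevation factor.
    """

    cell_types: Sequence[tuple[str, int]]  # (type name, cell count)
    genes: Sequence[str]
    seed: int
    baseline_mean: float | Mapping[str, float] = 1.0
    dispersion: float = 10.0
    planted_edges: Sequence[PlantedEdge] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for a simulation spec")
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        names = [t for t, _ in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        gene_set = set(self.genes)
        type_set = set(names)
        for e in self.planted_edges:
            for g in (e.ligand, e.receptor):
                if g not in gene_set:
                    raise ValueError(f"planted gene {g!r} not in gene list")
            for t in (e.sender, e.receiver):
                if t not in type_set:
                    raise ValueError(f"planted cell type {t!r} not in spec")


def simulate_single_cells(
    spec: SingleCellSpec,
) -> tuple[pd.DataFrame, pd.Series, TruthRecord]:
    """Draw an annotated genes x cells NB count matrix from ``spec``.

    Returns the count matrix, a cell -> cell-type annotation series and the
    :class:`TruthRecord` listing the planted edges.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    gi = {g: i for i, g in enumerate(genes)}
    if isinstance(spec.baseline_mean, Mapping):
        base = np.array([float(spec.baseline_mean[g]) for g in genes])
    else:
        base = np.full(len(genes), float(spec.baseline_mean))

    blocks: list[np.ndarray] = []
    ann: list[str] = []
    cells: list[str] = []
    for tname, n_cells in spec.cell_types:
        mean = base.copy()
        for e in spec.planted_edges:
            if e.sender == tname:
                mean[gi[e.ligand]] *= e.elevation
            if e.receiver == tname:
                mean[gi[e.receptor]] *= e.elevation
        size = spec.dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p[:, None], size=(len(genes), n_cells))
        blocks.append(counts)
        ann += [tname] * n_cells
        cells += [f"{tname}_{i + 1}" for i in range(n_cells)]

    matrix = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=genes, columns=cells
    )
    matrix.index.name = "gene"
    annotations = pd.Series(ann, index=cells, name="cell_type")
    truth = TruthRecord(
        edges=[(e.sender, e.receiver, e.ligand, e.receptor) for e in spec.planted_edges]
    )
    return matrix, annotations, truth
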