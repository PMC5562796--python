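"""Shared fixtures: a small curated-style pair database and simulated data.

All fixtures are generated programmatically; nothing is read from disk
except through tmp_path round trips inside the tests themselves.
"""

import pandas as pd
import pytest

import crosstalk as ct

# 12-pair demo database: 3 ligands sharing one receptor, one ligand with 3
# receptors, 6 bijective pairs -> 12 pairs, 10 ligands, 10 receptors.
DEMO_PAIRS = (
    [("LS1", "RSHARED"), ("LS2", "RSHARED"), ("LS3", "RSHARED")]
    + [("LMULTI", "RM1"), ("LMULTI", "RM2"), ("LMULTI", "RM3")]
    + [(f"LB{i}", f"RB{i}") for i in range(1, 7)]
)


@pytest.fixture(scope="session")
def demo_db() -> ct.PairDB:
    return ct.PairDB(DEMO_PAIRS)


@pytest.fixture()
def demo_pair_file(tmp_path):
    path = tmp_path / "pairs.tsv"
    lines = ["ligand\treceptor"] + [f"{l}\t{r}" for l, r in DEMO_PAIRS]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def bijective_db() -> ct.PairDB:
    """30 bijective pairs over 60 distinct genes."""
    return ct.PairDB([(f"L{i:02d}", f"R{i:02d}") for i in range(30)])


@pytest.fixture(scope="session")
def planted_cohort(bijective_db):
    """Bulk cohort: first 10 pairs at Spearman 0.6 in normal, 0 in cancer."""
    pairs = [(p.ligand, p.receptor) for p in bijective_db.pairs]
    genes = [g for p in pairs for g in p] + [f"F{i}" for i in range(20)]
    spec = ct.BulkCohortSpec(
        genes=genes,
        n_normal=150,
        n_cancer=150,
        seed=424242,
        planted_corr={p: (0.6, 0.0) for p in pairs[:10]},
        planted_de={"F0": 2.0, "F1": -2.0},
    )
    cohort, truth = ct.simulate_bulk(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def sc_dataset(bijective_db):
    """7 balanced cell types, 5 planted communication edges, elevation 20."""
    pairs = [(p.ligand, p.receptor) for p in bijective_db.pairs[:12]]
    genes = [g for p in pairs for g in p] + [f"F{i}" for i in range(20)]
    edges = [
        ct.PlantedEdge("T0", "T1", "L00", "R00"),
        ct.PlantedEdge("T2", "T3", "L01", "R01"),
        ct.PlantedEdge("T4", "T5", "L02", "R02"),
        ct.PlantedEdge("T6", "T0", "L03", "R03"),
        ct.PlantedEdge("T1", "T1", "L04", "R04"),  # autocrine
    ]
    spec = ct.SingleCellSpec(
        cell_types=[(f"T{i}", 200) for i in range(7)],
        genes=genes,
        seed=99,
        planted_edges=edges,
    )
    matrix, annotations, truth = ct.simulate_single_cells(spec)
    return matrix, annotations, truth


def tiny_cohort(values_normal, values_cancer, genes=None) -> ct.BulkCohort:
    """Hand-built cohort from explicit per-gene sample values."""
    n_n = len(values_normal[0])
    n_c = len(values_cancer[0])
    genes = genes or [f"g{i}" for i in range(len(values_normal))]
    cols = [f"N{i}" for i in range(n_n)] + [f"C{i}" for i in range(n_c)]
    data = [list(vn) + list(vc) for vn, vc in zip(values_normal, values_cancer)]
    expr = pd.DataFrame(data, index=genes, columns=cols)
    cond = pd.Series(["normal"] * n_n + ["cancer"] * n_c, index=cols)
    return ct.BulkCohort(expression=expr, condition=cond)
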