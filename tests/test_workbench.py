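"""Matrix I/O, pipeline orchestration, manifest reproducibility, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import crosstalk as ct
from crosstalk.cli import main as cli_main
from crosstalk.io import (
    read_annotations,
    read_conditions,
    read_expression_matrix,
    read_infiltration,
    write_expression_matrix,
)
from crosstalk.pipeline import PipelineConfig, PipelineError, run_pipeline


class TestMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        m = pd.DataFrame(
            [[1.0, 2.0], [3.5, 0.0], [0.1, 9.0]],
            index=["A", "B", "C"], columns=["s1", "s2"],
        )
        m.index.name = "gene"
        path = tmp_path / "m.tsv"
        write_expression_matrix(m, path)
        back = read_expression_matrix(path)
        pd.testing.assert_frame_equal(m, back)

    def test_mtx_equals_tsv_twin(self, tmp_path):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.poisson(2, size=(5, 4)).astype(float),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(4)],
        )
        m.index.name = "gene"
        write_expression_matrix(m, tmp_path / "m.tsv")
        write_expression_matrix(m, tmp_path / "m.mtx", fmt="mtx")
        dense = read_expression_matrix(tmp_path / "m.tsv")
        sparse = read_expression_matrix(tmp_path / "m.mtx")
        pd.testing.assert_frame_equal(dense, sparse)

    def test_transpose_flag(self, tmp_path):
        m = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        m.T.to_csv(tmp_path / "t.tsv", sep="\t")
        back = read_expression_matrix(tmp_path / "t.tsv", transpose=True)
        assert list(back.index) == ["g"]

    @pytest.mark.parametrize(
        "payload, match",
        [
            ("gene\ts1\nA\t-1.0\n", "negative"),
            ("gene\ts1\nA\tnan\n", "NaN"),
            ("gene\ts1\nA\t1.0\nA\t2.0\n", "duplicate gene"),
        ],
    )
    def test_invalid_matrices_rejected(self, tmp_path, payload, match):
        path = tmp_path / "bad.tsv"
        path.write_text(payload)
        with pytest.raises(ValueError, match=match):
            read_expression_matrix(path)

    def test_side_tables(self, tmp_path):
        (tmp_path / "cond.tsv").write_text("s1\tnormal\ns2\tcancer\n")
        cond = read_conditions(tmp_path / "cond.tsv")
        assert cond["s2"] == "cancer"
        (tmp_path / "bad.tsv").write_text("s1\ttumor\n")
        with pytest.raises(ValueError, match="unknown condition"):
            read_conditions(tmp_path / "bad.tsv")
        (tmp_path / "ann.tsv").write_text("c1\tTcell\nc2\tCAF\n")
        assert read_annotations(tmp_path / "ann.tsv")["c2"] == "CAF"
        (tmp_path / "inf.tsv").write_text("sample\tlymphocyte\ns1\t0.2\ns2\t1.7\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            read_infiltration(tmp_path / "inf.tsv")


@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory, bijective_db):
    """Write a complete synthetic input set for the pipeline."""
    root = tmp_path_factory.mktemp("pipeline")
    bijective_db.write(root / "pairs.tsv")

    pairs = [(p.ligand, p.receptor) for p in bijective_db.pairs]
    genes = [g for p in pairs for g in p] + [f"F{i}" for i in range(10)]
    spec = ct.BulkCohortSpec(
        genes=genes, n_normal=40, n_cancer=40, seed=17,
        planted_corr={p: (0.7, 0.0) for p in pairs[:5]},
        planted_de={"F0": 2.0},
    )
    cohort, _ = ct.simulate_bulk(spec)
    table = ct.simulate_infiltration(cohort, seed=18)
    write_expression_matrix(cohort.expression, root / "bulk.tsv")
    cohort.condition.rename_axis("sample").to_csv(
        root / "conditions.tsv", sep="\t", header=False
    )
    table.to_csv(root / "infiltration.tsv", sep="\t")

    sc_spec = ct.SingleCellSpec(
        cell_types=[(f"T{i}", 60) for i in range(4)],
        genes=genes,
        seed=19,
        planted_edges=[ct.PlantedEdge("T0", "T1", "L00", "R00")],
    )
    matrix, ann, _ = ct.simulate_single_cells(sc_spec)
    write_expression_matrix(matrix, root / "sc.tsv")
    ann.rename_axis("cell").to_csv(root / "sc_ann.tsv", sep="\t", header=False)
    return root


class TestPipeline:
    def _config(self, root, outdir, **kw):
        base = dict(
            pairs=str(root / "pairs.tsv"),
            outdir=str(outdir),
            bulk_matrix=str(root / "bulk.tsv"),
            conditions=str(root / "conditions.tsv"),
            infiltration=str(root / "infiltration.tsv"),
            sc_matrix=str(root / "sc.tsv"),
            sc_annotations=str(root / "sc_ann.tsv"),
            n_random=200,
            seed=23,
        )
        base.update(kw)
        return PipelineConfig(**base)

    def test_end_to_end_manifest_and_determinism(self, pipeline_inputs, tmp_path):
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        m1 = run_pipeline(self._config(pipeline_inputs, out1))
        m2 = run_pipeline(self._config(pipeline_inputs, out2))
        assert set(m1["outputs"]) >= {
            "de.tsv", "pair_scenarios.tsv", "correlations.tsv", "random_null.tsv",
            "summary.json", "shift.tsv", "infiltration.json", "edges.tsv",
            "edge_counts.tsv", "top_edges.tsv", "network.graphml",
        }
        for name in m1["outputs"]:
            if name.endswith(".tsv"):
                assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 23
        assert manifest["skipped"] == []
        # the planted communication edge comes out of the sc branch
        edges = pd.read_csv(out1 / "edges.tsv", sep="\t")
        assert ("T0", "T1", "L00", "R00") in set(map(tuple, edges.to_numpy()))

    def test_bulk_only_skips_single_cell(self, pipeline_inputs, tmp_path):
        cfg = self._config(
            pipeline_inputs, tmp_path / "bulk_only", sc_matrix=None, sc_annotations=None
        )
        manifest = run_pipeline(cfg)
        assert manifest["skipped"] == ["single_cell"]
        assert not any(n.startswith("edges") for n in manifest["outputs"])

    def test_missing_seed_for_stochastic_stage_rejected(self, pipeline_inputs, tmp_path):
        with pytest.raises(ValueError, match="seed"):
            self._config(pipeline_inputs, tmp_path / "x", seed=None)

    def test_stage_error_names_stage(self, pipeline_inputs, tmp_path):
        cfg = self._config(
            pipeline_inputs, tmp_path / "broken",
            conditions=str(pipeline_inputs / "sc_ann.tsv"),  # wrong file
        )
        with pytest.raises(PipelineError, match="bulk"):
            run_pipeline(cfg)


class TestCLI:
    def test_pairs_summary(self, demo_pair_file):
        result = CliRunner().invoke(cli_main, ["pairs", str(demo_pair_file)])
        assert result.exit_code == 0
        assert json.loads(result.output) == {
            "n_pairs": 12, "n_ligands": 10, "n_receptors": 10,
        }

    def test_simulate_then_run_all(self, tmp_path, bijective_db):
        bijective_db.write(tmp_path / "pairs.tsv")
        pairs = [(p.ligand, p.receptor) for p in bijective_db.pairs]
        genes = [g for p in pairs for g in p]
        sim_spec = {
            "bulk": {
                "genes": genes,
                "n_normal": 20,
                "n_cancer": 20,
                "seed": 5,
                "planted_corr": {"L00|R00": [0.7, 0.0]},
            },
            "single_cell": {
                "cell_types": [["A", 40], ["B", 40]],
                "genes": genes,
                "seed": 6,
                "planted_edges": [
                    {"sender": "A", "receiver": "B", "ligand": "L01", "receptor": "R01"}
                ],
            },
        }
        (tmp_path / "sim.yaml").write_text(yaml.safe_dump(sim_spec))
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", str(tmp_path / "sim.yaml"), "--outdir", str(tmp_path / "data")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            [
                "run-all",
                "--pairs", str(tmp_path / "pairs.tsv"),
                "--outdir", str(tmp_path / "out"),
                "--bulk-matrix", str(tmp_path / "data" / "bulk_matrix.tsv"),
                "--conditions", str(tmp_path / "data" / "conditions.tsv"),
                "--sc-matrix", str(tmp_path / "data" / "sc_matrix.tsv"),
                "--sc-annotations", str(tmp_path / "data" / "sc_annotations.tsv"),
                "--seed", "7",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "manifest.json").exists()
        edges = pd.read_csv(tmp_path / "out" / "edges.tsv", sep="\t")
        assert ("A", "B", "L01", "R01") in set(map(tuple, edges.to_numpy()))
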