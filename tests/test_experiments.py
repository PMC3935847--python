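import numpy as np
import pandas as pd
import pytest

from ctrlcascade import (
    ExperimentConfig,
    GeneratorSpec,
    aggregate_realizations,
    assign_capacities,
    classify_edges,
    compute_loads,
    critical_fraction,
    driver_report,
    failed_edge_census,
    fraction_sweep,
    run_cascade,
    single_trigger_experiment,
    toy_fixture,
    write_edge_list,
)
from ctrlcascade.graph_core import DirectedGraph


@pytest.fixture
def small_config():
    return ExperimentConfig(
        generator=GeneratorSpec("er", 60, 3.0),
        alpha=0.3,
        f_grid=(0.0, 0.2, 1.0),
        n_realizations=4,
        master_seed=11,
    )


class TestExperimentConfig:
    def test_exactly_one_input_source(self):
        with pytest.raises(ValueError, match="exactly one"):
            ExperimentConfig()
        with pytest.raises(ValueError, match="exactly one"):
            ExperimentConfig(
                generator=GeneratorSpec("er", 10, 1.0), input_path="x.txt"
            )

    def test_dict_roundtrip(self, small_config):
        assert ExperimentConfig.from_dict(small_config.to_dict()) == small_config

    def test_yaml_roundtrip(self, small_config, tmp_path):
        import yaml

        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(small_config.to_dict()))
        assert ExperimentConfig.from_yaml(p) == small_config


class TestSingleTrigger:
    def test_edgeless_graph_rejected(self, tmp_path):
        g = DirectedGraph(4, ())
        p = tmp_path / "g.txt"
        write_edge_list(g, p)
        cfg = ExperimentConfig(input_path=str(p), n_realizations=1)
        with pytest.raises(ValueError, match="no edges"):
            single_trigger_experiment(cfg)

    def test_huge_alpha_gives_single_stage_traces(self):
        cfg = ExperimentConfig(
            generator=GeneratorSpec("er", 50, 3.0),
            alpha=1e6,
            n_realizations=3,
            master_seed=5,
        )
        res = single_trigger_experiment(cfg)
        assert (res.records["n_stages"] == 1).all()
        assert (res.records["total_failed"] == 0).all()
        assert len(res.trace) == 1

    def test_trace_padding_uses_terminal_values(self):
        cfg = ExperimentConfig(
            generator=GeneratorSpec("er", 60, 4.0),
            alpha=0.1,
            n_realizations=5,
            master_seed=6,
        )
        res = single_trigger_experiment(cfg)
        # final averaged stage equals the mean of the per-realization finals
        assert res.trace.iloc[-1]["n_drivers_mean"] == pytest.approx(
            res.records["final_n_drivers"].mean()
        )

    def test_reproducible(self):
        cfg = ExperimentConfig(
            generator=GeneratorSpec("er", 40, 3.0), n_realizations=3, master_seed=7
        )
        a = single_trigger_experiment(cfg)
        b = single_trigger_experiment(cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.trace, b.trace)


class TestFailedEdgeCensus:
    def test_all_failed_critical(self):
        g = DirectedGraph(2, ((0, 1),))
        cls = classify_edges(g)
        caps = assign_capacities(compute_loads(g), 0.3)
        trace = run_cascade(g, caps, [(0, 1)])
        census = failed_edge_census(cls, trace)
        assert census.defined
        assert census.as_tuple() == (1.0, 0.0, 0.0)

    def test_zero_failed_edges_flagged_undefined(self, matching_demo):
        cls = classify_edges(matching_demo)
        caps = assign_capacities(compute_loads(matching_demo), 10.0)
        trace = run_cascade(matching_demo, caps, [])
        census = failed_edge_census(cls, trace)
        assert not census.defined
        assert np.isnan(census.critical)

    def test_densities_sum_to_one(self, matching_demo):
        cls = classify_edges(matching_demo)
        caps = assign_capacities(compute_loads(matching_demo), 0.0)
        trace = run_cascade(matching_demo, caps, [(1, 2), (2, 3)])
        census = failed_edge_census(cls, trace)
        assert sum(census.as_tuple()) == pytest.approx(1.0)


class TestFractionSweep:
    def test_endpoint_cells(self, small_config):
        sweep = fraction_sweep(small_config, classify=False)
        rec = sweep.records
        for r in range(small_config.n_realizations):
            mine = rec[rec.realization == r]
            intact_nd = mine[mine.f == 0.0]["n_drivers_final"].unique()
            assert len(intact_nd) == 1  # both strategies agree at f=0
            assert (mine[mine.f == 1.0]["n_drivers_final"] == 60).all()
            assert (intact_nd[0] <= mine["n_drivers_final"]).all()

    def test_summary_shape_and_errors(self, small_config):
        sweep = fraction_sweep(small_config)
        assert len(sweep.summary) == len(small_config.f_grid) * 2
        assert (sweep.summary["n_realizations"] == 4).all()
        assert (sweep.summary["n_drivers_final_se"] >= 0).all()

    def test_byte_identical_outputs(self, small_config, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        fraction_sweep(small_config).to_tsv(out1)
        fraction_sweep(small_config).to_tsv(out2)
        for name in ("sweep_summary.tsv", "sweep_records.tsv", "manifest.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_critical_fraction_detection(self):
        records = pd.DataFrame(
            [
                {"realization": 0, "strategy": s, "f": f, "n_drivers_final": 1,
                 "total_failed": tf}
                for s in ("RA", "IA")
                for f, tf in [(0.2, 3), (0.4, 0), (0.6, 0)]
            ]
        )
        sweep = aggregate_realizations(records)
        assert critical_fraction(sweep) == 0.4


class TestAggregateRealizations:
    def test_single_record_flagged(self):
        rec = pd.DataFrame(
            [{"realization": 0, "strategy": "RA", "f": 0.1,
              "n_drivers_final": 5, "total_failed": 2}]
        )
        out = aggregate_realizations(rec).summary
        assert out.loc[0, "single_sample"]
        assert out.loc[0, "n_drivers_final_mean"] == 5
        assert out.loc[0, "n_drivers_final_se"] == 0.0

    def test_known_mean_and_se(self):
        rec = pd.DataFrame(
            [
                {"realization": i, "strategy": "RA", "f": 0.1,
                 "n_drivers_final": v, "total_failed": 0}
                for i, v in enumerate((1, 2, 3))
            ]
        )
        out = aggregate_realizations(rec).summary
        assert out.loc[0, "n_drivers_final_mean"] == pytest.approx(2.0)
        assert out.loc[0, "n_drivers_final_se"] == pytest.approx(0.5774, abs=1e-4)

    def test_constant_records_zero_se(self):
        rec = pd.DataFrame(
            [
                {"realization": i, "strategy": "IA", "f": 0.2,
                 "n_drivers_final": 4, "total_failed": 1}
                for i in range(5)
            ]
        )
        out = aggregate_realizations(rec).summary
        assert out.loc[0, "n_drivers_final_se"] == 0.0

    def test_undefined_censuses_excluded_from_average(self):
        rec = pd.DataFrame(
            [
                {"realization": 0, "strategy": "RA", "f": 0.1, "n_drivers_final": 3,
                 "total_failed": 1, "census_defined": True,
                 "density_critical": 1.0, "density_ordinary": 0.0,
                 "density_redundant": 0.0},
                {"realization": 1, "strategy": "RA", "f": 0.1, "n_drivers_final": 3,
                 "total_failed": 0, "census_defined": False,
                 "density_critical": np.nan, "density_ordinary": np.nan,
                 "density_redundant": np.nan},
            ]
        )
        out = aggregate_realizations(rec).summary
        assert out.loc[0, "n_census_defined"] == 1
        assert out.loc[0, "density_critical_mean"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            aggregate_realizations(pd.DataFrame())


class TestFixedInputGraph:
    def test_input_file_used_for_every_realization(self, tmp_path):
        g = toy_fixture("matching_demo")
        p = tmp_path / "g.txt"
        write_edge_list(g, p)
        cfg = ExperimentConfig(
            input_path=str(p), alpha=0.3, n_realizations=3, master_seed=2
        )
        res = single_trigger_experiment(cfg)
        assert (res.records["n_nodes"] == 8).all()
        assert (res.records["intact_n_drivers"] == driver_report(g).n_drivers).all()
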