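"""Model/results surface, workflow runs, p-curve export, CLI and plots."""

import json

import matplotlib
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from vasca import ASCA, PermutationPlan, RunConfig, export_pcurve, run_analysis
from vasca.cli import main as cli_main
from vasca.simulate import generate_scenario

matplotlib.use("Agg")


def eq3_frames(seed=0, n_vars=5):
    rng = np.random.default_rng(seed)
    design = pd.DataFrame(
        {"temp": [10, 10, 20, 20, 30, 30] * 2, "pH": [4.0] * 6 + [6.0] * 6}
    )
    data = pd.DataFrame(
        rng.standard_normal((12, n_vars)),
        columns=[f"v{i}" for i in range(n_vars)],
    )
    return data, design


class TestModel:
    def test_from_formula_and_summary(self):
        data, design = eq3_frames()
        res = ASCA.from_formula("~ temp + pH + temp:pH", data, design).fit()
        assert res.terms == ("temp", "pH", "temp:pH")
        text = str(res.summary())
        for token in ("temp:pH", "residual", "SSQ"):
            assert token in text

    def test_default_terms_are_main_effects(self):
        data, design = eq3_frames()
        res = ASCA(data, design).fit()
        assert res.terms == ("temp", "pH")

    def test_ssq_statistic_requires_autoscale(self):
        data, design = eq3_frames()
        with pytest.raises(ValueError, match="autoscale"):
            ASCA(data, design, statistic="ssq", scaling="center")
        ASCA(data, design, statistic="ssq")  # defaults to autoscale

    def test_row_mismatch_rejected(self):
        data, design = eq3_frames()
        with pytest.raises(ValueError, match="rows"):
            ASCA(data.iloc[:10], design)

    def test_non_numeric_data_rejected(self):
        data, design = eq3_frames()
        data = data.astype(object)
        data.iloc[0, 0] = "oops"
        with pytest.raises(ValueError, match="non-numeric"):
            ASCA(data, design)

    def test_methods_share_cached_permutations(self):
        data, design = eq3_frames(n_vars=4)
        res = ASCA(data, design, scaling="autoscale").fit()
        plan = PermutationPlan(80, seed=1)
        a = res.permutation_test("temp", plan=plan)
        v = res.vasca("temp", plan=plan)
        assert v.p_curve[-1] == a.p_value
        # summary picks up the cached p-value
        assert f"{a.p_value:.4g}" in str(res.summary())

    def test_asca_genes_via_results(self):
        data, design = eq3_frames(n_vars=6)
        res = ASCA(data, design).fit()
        g = res.asca_genes("temp", n_perms=30, alpha=0.5)
        assert g.leverage.shape == (6,)

    def test_component_and_bootstrap_roundtrip(self):
        data, design = eq3_frames(n_vars=4)
        res = ASCA(data, design).fit()
        cm = res.components("temp", variables=[0, 1, 2])
        assert cm.loadings.shape[0] == 3
        boot = res.bootstrap_loadings("temp", variables=[0, 1, 2], n_boot=120)
        assert boot.significant.shape == (3,)
        apca = res.apca_components("temp", variables=[0, 1, 2])
        assert apca.projected_scores is None

    def test_term_disambiguation_required(self):
        data, design = eq3_frames()
        res = ASCA(data, design).fit()
        with pytest.raises(ValueError, match="specify"):
            res.permutation_test(n_perms=5)
        with pytest.raises(KeyError):
            res.vasca("nope", n_perms=5)


class TestExportPcurve:
    def _results(self):
        data, design = eq3_frames(n_vars=4)
        res = ASCA(data, design, scaling="autoscale").fit()
        plan = PermutationPlan(40, seed=2)
        return (
            res.vasca("temp", plan=plan),
            res.univariate_fdr("temp", plan=plan),
            res.permutation_test("temp", plan=plan),
        )

    def test_vasca_rows_per_rank(self):
        v, f, a = self._results()
        frame = export_pcurve(vasca=v)
        assert (frame["method"] == "vasca").sum() == 4
        assert frame.attrs["alpha_lines"] == [0.05, 0.01]

    def test_fdr_rows_sorted_and_clamped(self):
        v, f, a = self._results()
        f.p_adjusted = np.array([1.3, 0.2, 0.9, 0.4])
        frame = export_pcurve(fdr=f)
        p = frame.loc[frame["method"] == "fdr", "p_value"].to_numpy()
        np.testing.assert_allclose(p, [0.2, 0.4, 0.9, 1.0])

    def test_combined_stable_sort(self):
        v, f, a = self._results()
        frame = export_pcurve(vasca=v, fdr=f, asca=a)
        assert frame["method"].tolist() == ["asca"] + ["fdr"] * 4 + ["vasca"] * 4
        assert frame.groupby("method")["m"].apply(
            lambda s: s.is_monotonic_increasing
        ).all()

    def test_empty_export_rejected(self):
        with pytest.raises(ValueError):
            export_pcurve()


@pytest.fixture
def csv_pair(tmp_path):
    """A small generated dataset with a known informative-variable set."""
    X, design, truth, terms = generate_scenario("ex2", seed=12)
    X = X[:, :200]  # 3 informative + 197 background: quick but non-trivial
    data = tmp_path / "data.csv"
    pd.DataFrame(X, columns=[f"x{i}" for i in range(200)]).to_csv(data, index=False)
    dpath = tmp_path / "design.csv"
    design.to_frame().to_csv(dpath, index=False)
    return data, dpath


class TestRunAnalysis:
    def test_bundle_structure_three_terms(self, tmp_path):
        data, design = eq3_frames(n_vars=4)
        dpath, gpath = tmp_path / "d.csv", tmp_path / "g.csv"
        data.to_csv(dpath, index=False)
        design.to_csv(gpath, index=False)
        config = RunConfig(
            data=str(dpath), design=str(gpath), out=str(tmp_path / "out"),
            terms="temp + pH + temp:pH", n_perms=30, seed=3,
        )
        bundle = run_analysis(config)
        assert set(bundle["terms"]) == {"temp", "pH", "temp:pH"}
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert set(summary["terms"]) == {"temp", "pH", "temp:pH"}
        assert (tmp_path / "out" / "pcurve_temp.csv").exists()
        assert (tmp_path / "out" / "config.yaml").exists()

    def test_end_to_end_detects_informative_variables(self, csv_pair, tmp_path):
        data, design = csv_pair
        config = RunConfig(
            data=str(data), design=str(design), out=str(tmp_path / "out"),
            scaling="autoscale", n_perms=200, alpha=0.01, seed=1, n_boot=150,
            methods=("asca", "vasca", "fdr"),
        )
        bundle = run_analysis(config)
        v = bundle["terms"]["class"]["vasca"]
        assert set(v.order[:3]) == {0, 1, 2}
        assert v.selected_m >= 3
        a = bundle["terms"]["class"]["asca"]
        assert a.p_value > 0.05  # holistic test misses the 3-variable signal

    def test_rerun_from_embedded_config_reproduces(self, csv_pair, tmp_path):
        data, design = csv_pair
        out = tmp_path / "out"
        config = RunConfig(
            data=str(data), design=str(design), out=str(out),
            scaling="autoscale", n_perms=100, seed=5,
        )
        run_analysis(config)
        first = (out / "summary.json").read_text()
        rerun_cfg = RunConfig.from_yaml(out / "config.yaml")
        run_analysis(rerun_cfg)
        assert (out / "summary.json").read_text() == first

    def test_missing_design_file(self, tmp_path, csv_pair):
        data, _ = csv_pair
        config = RunConfig(data=str(data), design=str(tmp_path / "nope.csv"),
                           out=str(tmp_path / "o"))
        with pytest.raises(FileNotFoundError, match="nope"):
            run_analysis(config)

    def test_config_validation_and_roundtrip(self, tmp_path):
        with pytest.raises(ValueError, match="autoscale"):
            RunConfig(data="a", design="b", statistic="ssq", scaling="center")
        config = RunConfig(data="a", design="b", methods=("vasca",), alpha=0.2)
        path = tmp_path / "c.yaml"
        config.to_yaml(path)
        assert RunConfig.from_yaml(path) == config


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(
            cli_main,
            ["simulate", "--scenario", "ex1", "--seed", "4", "--out", str(sim_dir)],
        )
        assert result.exit_code == 0, result.output
        truth = json.loads((sim_dir / "truth.json").read_text())
        assert truth["informative"] == []
        # analyse a small slice of the simulated data through the CLI
        data = pd.read_csv(sim_dir / "data.csv").iloc[:, :6]
        data.to_csv(sim_dir / "small.csv", index=False)
        out = tmp_path / "run"
        result = runner.invoke(
            cli_main,
            ["run", "--data", str(sim_dir / "small.csv"),
             "--design", str(sim_dir / "design.csv"),
             "--perms", "50", "--seed", "2", "--out", str(out), "--fdr"],
        )
        assert result.exit_code == 0, result.output
        assert "ASCA p=" in result.output
        assert (out / "fdr_class.csv").exists()

    def test_bench_smoke(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "bench"
        result = runner.invoke(
            cli_main,
            ["bench", "--scenario", "ex1", "--reps", "1", "--perms", "1",
             "--seed", "0", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        report = json.loads((out / "report.json").read_text())
        assert report["reps"] == 1

    def test_run_requires_inputs(self):
        result = CliRunner().invoke(cli_main, ["run"])
        assert result.exit_code != 0


class TestViz:
    def test_plot_smoke(self):
        import matplotlib.pyplot as plt

        from vasca.viz import plot_loadings, plot_pcurve, plot_scores

        data, design = eq3_frames(n_vars=4)
        res = ASCA(data, design, scaling="autoscale").fit()
        plan = PermutationPlan(30, seed=1)
        v = res.vasca("temp", plan=plan)
        f = res.univariate_fdr("temp", plan=plan)
        a = res.permutation_test("temp", plan=plan)
        ax = plot_pcurve(export_pcurve(vasca=v, fdr=f, asca=a))
        assert ax.get_ylabel() == "p-value"
        cm = res.components("temp")
        ax = plot_scores(cm, design=res.model.design, factor="temp")
        assert ax is not None
        boot = res.bootstrap_loadings("temp", variables=[0, 1], n_boot=120)
        ax = plot_loadings(boot, var_names=res.var_names)
        assert ax is not None
        plt.close("all")
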