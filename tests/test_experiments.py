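"""Generational loop composition, replicate runs, experiment presets, CLI."""

import numpy as np
import pandas as pd
import pytest

from phenomate import (Cohort, FEMALE, MALE, base_config, build_covariances,
                       child_seed, experiment_spec, init_founders,
                       run_experiment, run_generation, run_iteration,
                       run_replicates, summaries_to_frame)


@pytest.fixture
def small_config():
    return base_config(nc_initial=60, generations=3, iterations=4)


class TestRunGeneration:
    def test_next_size_equals_female_rs_exp_sum(self, small_config, rng):
        covs = build_covariances(small_config)
        cohort = init_founders(small_config, rng, P=covs.P)
        nxt, summary = run_generation(cohort, small_config, covs, rng,
                                      id_start=cohort.size)
        expected = int(cohort.rs_exp[cohort.is_female].sum())
        # reproductive failure aside, the recruit pool is fully assigned
        assert nxt.size == expected
        assert summary.nc == cohort.size
        assert np.isfinite(summary.ne) or expected == 0

    def test_single_sex_cohort_terminates(self, small_config, rng):
        covs = build_covariances(small_config)
        cohort = init_founders(small_config, rng, P=covs.P)
        cohort.sex[:] = MALE
        nxt, summary = run_generation(cohort, small_config, covs, rng)
        assert nxt.size == 0

    def test_selection_off_limit(self, rng):
        """A nearly flat fitness landscape with no environmental noise:
        every raw weight sits near 1, so rs_exp lands in the top Poisson
        quantiles and the recruit pool is the female rs_exp sum."""
        from phenomate import expected_rs

        cfg = base_config(nc_initial=100, var_theta_return_day=0.0,
                          var_theta_rls=0.0, omega_scalar=200.0,
                          mating_mode="random_uniform",
                          fitness_scaling="none")
        covs = build_covariances(cfg)
        cohort = init_founders(cfg, rng, P=covs.P)
        nxt, _ = run_generation(cohort, cfg, covs, rng, id_start=cohort.size)
        assert cohort.rs_exp.min() >= expected_rs(0.95, cfg.lambda_rs)
        assert nxt.size == int(cohort.rs_exp[cohort.is_female].sum())


class TestRunIteration:
    def test_stream_length_and_generations(self, small_config):
        stream = run_iteration(small_config, seed=5)
        assert len(stream) == small_config.generations + 1
        assert [s.generation for s in stream] == [0, 1, 2, 3]

    def test_same_seed_identical(self, small_config):
        a = summaries_to_frame([run_iteration(small_config, seed=9)])
        b = summaries_to_frame([run_iteration(small_config, seed=9)])
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, small_config):
        a = run_iteration(small_config, seed=1)
        b = run_iteration(small_config, seed=2)
        assert any(x.nc != y.nc for x, y in zip(a, b))

    def test_collapse_records_zero_census(self):
        # omega tiny and far-off optimum: population cannot persist
        cfg = base_config(nc_initial=6, generations=5, iterations=2,
                          var_theta_return_day=400.0)
        streams = [run_iteration(cfg, seed=s) for s in range(8)]
        collapsed = [s for s in streams if s[-1].nc == 0]
        for stream in collapsed:
            ncs = [x.nc for x in stream]
            # once zero, stays zero and remains recorded to the final generation
            first_zero = ncs.index(0)
            assert all(v == 0 for v in ncs[first_zero:])
            assert len(ncs) == cfg.generations + 1

    def test_pedigree_closure(self, small_config):
        _, ped = run_iteration(small_config, seed=3, collect_pedigree=True)
        by_id = ped.set_index("animal")
        offspring = ped[ped.generation > 0]
        for _, row in offspring.iterrows():
            assert by_id.loc[row.dam, "sex"] == "female"
            assert by_id.loc[row.sire, "sex"] == "male"
            assert by_id.loc[row.dam, "generation"] == row.generation - 1


class TestExperimentPresets:
    def test_exp1_crosses_variance_and_mating(self):
        spec = experiment_spec("exp1")
        labels = [label for label, _ in spec.levels]
        assert len(labels) == 6
        cfgs = dict(spec.configs())
        assert cfgs["var_rd=10_assortative"].var_return_day == 10
        assert cfgs["var_rd=20_random"].mating_mode == "random_uniform"

    @pytest.mark.parametrize("name,param,values", [
        ("exp2", "rho", [-0.6, -0.3, 0.0]),
        ("exp3", "var_theta_return_day", [10.0, 20.0, 30.0]),
        ("exp4", "omega_scalar", [1.0, 2.0, 3.0]),
    ])
    def test_single_parameter_sweeps(self, name, param, values):
        spec = experiment_spec(name)
        swept = [getattr(cfg, param) for _, cfg in spec.configs()]
        assert swept == values
        # everything else stays at the base values
        for _, cfg in spec.configs():
            assert cfg.nc_initial == 500
            assert cfg.iterations == 100
            assert cfg.generations == 10

    def test_unknown_experiment(self):
        with pytest.raises(ValueError, match="exp1..exp4"):
            experiment_spec("exp9")

    def test_run_experiment_tables(self):
        spec = experiment_spec("exp4", master_seed=1,
                               nc_initial=40, generations=2, iterations=3)
        raw, agg = run_experiment(spec)
        assert set(raw["level"]) == {"omega=1.0", "omega=2.0", "omega=3.0"}
        assert len(raw) == 3 * 3 * 3  # levels x iterations x generations 0..2
        assert {"nc_mean", "nc_lo", "nc_hi"} <= set(agg.columns)

    def test_replicates_deterministic_in_master_seed(self, small_config):
        a = run_replicates(small_config, master_seed=4, iterations=3)
        b = run_replicates(small_config, master_seed=4, iterations=3)
        pd.testing.assert_frame_equal(a, b)
        c = run_replicates(small_config, master_seed=5, iterations=3)
        assert not a["nc"].equals(c["nc"])

    def test_child_seed_stable(self):
        s1 = child_seed(42, 1, 7)
        s2 = child_seed(42, 1, 7)
        assert (np.random.default_rng(s1).integers(1 << 30)
                == np.random.default_rng(s2).integers(1 << 30))


class TestCLI:
    def test_simulate_writes_outputs(self, tmp_path):
        import yaml
        from click.testing import CliRunner

        from phenomate.cli import main
        from tests.conftest import TABLE_DEFAULTS

        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(yaml.safe_dump(
            dict(TABLE_DEFAULTS, nc_initial=40, generations=2, iterations=3)))
        out = tmp_path / "out"
        result = CliRunner().invoke(main, [
            "simulate", "--config", str(cfg_file), "--seed", "1",
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        for name in ("pedigree.tsv", "summary_raw.csv", "summary_agg.csv",
                     "config_resolved.yaml", "run.log"):
            assert (out / name).exists()

    def test_experiment_command(self, tmp_path):
        from click.testing import CliRunner

        from phenomate.cli import main

        out = tmp_path / "exp"
        result = CliRunner().invoke(main, [
            "experiment", "--name", "exp2", "--seed", "3",
            "--override", "nc_initial=30", "--override", "generations=2",
            "--override", "iterations=2", "--out", str(out)])
        assert result.exit_code == 0, result.output
        agg = pd.read_csv(out / "summary_agg.csv")
        assert set(agg["level"]) == {"rho=-0.6", "rho=-0.3", "rho=0.0"}
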