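"""Multi-generation breed wrapper, scenario runner, case studies, CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import breedsim as bs
from breedsim.cli import main as cli_main
from breedsim.exceptions import ConfigError, ValidationError
from breedsim.program import bundled_scenario_path


def fresh_sim(seed):
    genome = bs.build_genome(n_chr=1, n_loci=30)
    phenome = bs.build_phenome(genome, 5, vg=1.0, h2=0.5, seed=seed)
    return bs.Simulation(genome, phenome, seed=seed)


BREED_ARGS = dict(nA=10, nB_per_A=5, replace_A=False, replace_B=True,
                  n_per_mate=1, ratio_malefemale=1.0,
                  criteria="EBV", methods="GBLUP")


class TestBreed:
    def test_rotational_args_maintain_cohort_sizes(self):
        sim = fresh_sim(1)
        A, B = sim.founders(60), sim.founders(600)
        sires, dams = bs.breed(A, B, nA=50, nB_per_A=10, replace_B=True,
                               n_per_mate=2, ratio_malefemale=1,
                               criteria="random", n_gens=3,
                               n_select_A=50, n_select_B=500)
        assert sires.n == 50 and dams.n == 500
        assert all(m.sex == "male" for m in sires.members)

    def test_single_generation_random_breed_equals_mate(self):
        sim = fresh_sim(2)
        A, B = sim.founders(10), sim.founders(50)
        males, females = bs.breed(A, B, nA=10, nB_per_A=5, replace_B=True,
                                  n_per_mate=1, ratio_malefemale=1,
                                  criteria="random", n_gens=1)
        assert males.n + females.n == 50

    def test_breed_equals_explicit_mate_select_loop(self):
        """Given the same seed, breed() must reproduce the hand-written
        mate/select iteration bit for bit."""
        sim1 = fresh_sim(3)
        A1, B1 = sim1.founders(10), sim1.founders(50)
        sires1, dams1 = bs.breed(A1, B1, n_gens=3, n_select_A=10,
                                 **BREED_ARGS)

        sim2 = fresh_sim(3)
        A2, B2 = sim2.founders(10), sim2.founders(50)
        for _ in range(3):
            males, females = bs.mate(A2, B2, **BREED_ARGS)
            A2 = bs.select(males, 10, **{k: v for k, v in BREED_ARGS.items()
                                         if k in ("criteria", "methods")})
            B2 = females
        np.testing.assert_array_equal(sires1.ids, A2.ids)
        np.testing.assert_array_equal(dams1.ids, B2.ids)
        np.testing.assert_array_equal(sires1.get_genotypes(),
                                      A2.get_genotypes())

    def test_breed_is_reproducible_for_a_fixed_seed(self):
        runs = []
        for _ in range(2):
            sim = fresh_sim(4)
            A, B = sim.founders(8), sim.founders(24)
            out = bs.breed(A, B, nA=8, nB_per_A=3, replace_B=True,
                           n_per_mate=1, ratio_malefemale=1,
                           criteria="phenotypes", n_gens=2, n_select_A=8)
            runs.append(out)
        np.testing.assert_array_equal(runs[0][0].ids, runs[1][0].ids)
        np.testing.assert_array_equal(runs[0][0].get_genotypes(),
                                      runs[1][0].get_genotypes())

    def test_directional_selection_raises_mean_bv(self):
        ok = 0
        for rep in range(10):
            sim = fresh_sim(50 + rep)
            A, B = sim.founders(20), sim.founders(100)
            base = (A + B).get_BVs().mean()
            sires, dams = bs.breed(A, B, nA=20, nB_per_A=5, replace_B=True,
                                   n_per_mate=1, ratio_malefemale=1,
                                   criteria="phenotypes", n_gens=3,
                                   n_select_A=20)
            final = (sires + dams).get_BVs().mean()
            if final >= base:
                ok += 1
        assert ok >= 9

    def test_selection_exceeding_sex_group_rejected(self):
        sim = fresh_sim(5)
        A, B = sim.founders(4), sim.founders(8)
        with pytest.raises(ValidationError):
            bs.breed(A, B, nA=4, nB_per_A=2, replace_B=True, n_per_mate=1,
                     ratio_malefemale=1, criteria="random", n_gens=1,
                     n_select_A=100)


class TestCaseStudies:
    def test_nam_panel_family_structure(self):
        out = bs.run_nam_panel(seed=6, n_loci=60, n_rils_per_family=5,
                               ssd_gens=2)
        assert len(out["families"]) == 25
        assert all(f.n == 5 for f in out["families"])
        assert out["NAM"].n == 125
        het = (out["NAM"].get_genotypes() == 1).mean()
        assert het < 0.25  # three selfing meioses from the F1

    def test_rotational_cross_counts_are_burn_in_independent(self):
        out = bs.run_rotational_cross(seed=7, burn_in=2, post_bottleneck=1,
                                      purebred_gens=1, n_rotations=1)
        assert out["sires_A"].n == 50 and out["dams_A"].n == 500
        assert out["sires_B"].n == 100 and out["dams_B"].n == 2000
        males, females = out["crosses"][0]
        assert males.n + females.n == 2000


class TestScenarios:
    def test_empty_step_list_writes_header_only_log(self, tmp_path):
        cfg = {"genome": {"n_chr": 1, "n_loci": 4}, "steps": []}
        bs.run_scenario(cfg, outdir=tmp_path, seed=0)
        log = pd.read_csv(tmp_path / "generations.csv")
        assert log.empty and "step" in log.columns

    def test_generic_step_scenario(self, tmp_path):
        cfg = {
            "genome": {"n_chr": 1, "n_loci": 10},
            "phenome": {"n_qtl": 3, "vg": 1.0, "h2": 0.5},
            "steps": [
                {"op": "founders", "out": "base", "n": 20},
                {"op": "repeat", "times": 2,
                 "steps": [{"op": "mate", "a": "base", "out": "base"}]},
                {"op": "subset", "a": "base", "range": [1, 10], "out": "base"},
                {"op": "mate", "a": "base", "out": ["m", "f"],
                 "ratio_malefemale": 1},
                {"op": "select", "a": "f", "n": 3, "out": "best",
                 "criteria": "phenotypes"},
                {"op": "dh", "a": "best", "out": "dhs"},
                {"op": "save", "a": "dhs", "prefix": "dhs"},
            ],
        }
        result = bs.run_scenario(cfg, outdir=tmp_path, seed=1)
        assert result["cohorts"]["dhs"].n == 3
        assert (tmp_path / "dhs_pedigree.csv").exists()
        log = pd.read_csv(tmp_path / "generations.csv")
        assert (log["step"] == "base").sum() == 4  # founders + 2 repeats + subset

    def test_scenario_pedigree_is_self_consistent(self, tmp_path):
        cfg = {
            "genome": {"n_chr": 1, "n_loci": 8},
            "phenome": {"n_qtl": 2},
            "steps": [
                {"op": "founders", "out": "base", "n": 10},
                {"op": "mate", "a": "base", "out": "g1"},
                {"op": "mate", "a": "g1", "out": "g2"},
                {"op": "save", "a": "g2", "prefix": "g2"},
            ],
        }
        bs.run_scenario(cfg, outdir=tmp_path, seed=2)
        ped = pd.read_csv(tmp_path / "g2_pedigree.csv")
        pos = {r.id: i for i, r in enumerate(ped.itertuples())}
        for r in ped.itertuples():
            for p in (r.sire, r.dam):
                assert p == 0 or pos[p] < pos[r.id]

    def test_unknown_step_keyword_rejected(self, tmp_path):
        cfg = {"genome": {"n_chr": 1, "n_loci": 4},
               "steps": [{"op": "teleport", "out": "x"}]}
        with pytest.raises(ConfigError):
            bs.run_scenario(cfg, outdir=tmp_path)

    def test_unknown_argument_rejected(self, tmp_path):
        cfg = {"genome": {"n_chr": 1, "n_loci": 4},
               "steps": [{"op": "founders", "out": "a", "n": 2},
                         {"op": "mate", "a": "a", "out": "b",
                          "wrong_arg": 1}]}
        with pytest.raises(ConfigError):
            bs.run_scenario(cfg, outdir=tmp_path)

    def test_bundled_scenarios_exist_and_parse(self):
        for name in ("rotational_cross", "nam_panel"):
            cfg = bs.program.load_scenario(bundled_scenario_path(name))
            assert cfg["case_study"] == name

    def test_cli_simulate_runs_a_scenario(self, tmp_path):
        scenario = tmp_path / "tiny.yml"
        scenario.write_text(yaml.safe_dump({
            "genome": {"n_chr": 1, "n_loci": 6},
            "phenome": {"n_qtl": 2},
            "steps": [{"op": "founders", "out": "base", "n": 5},
                      {"op": "mate", "a": "base", "out": "g1"},
                      {"op": "save", "a": "g1", "prefix": "g1"}],
        }))
        runner = CliRunner()
        result = runner.invoke(cli_main, ["simulate", str(scenario),
                                          "--seed", "3",
                                          "--outdir", str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "generations.csv").exists()
        assert (tmp_path / "out" / "g1_bv.csv").exists()
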