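"""Summary statistics, reference tables, model choice and estimation."""

import numpy as np
import pandas as pd
import pytest

from invabc import abc as iabc
from invabc.coalsim import LocusDesign, SimulatedDataset


def dataset_from(matrices, populations, design):
    return SimulatedDataset(matrices=matrices, populations=populations,
                            design=design)


def seq_matrix(rows):
    return np.vstack([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


class TestSummarize:
    def test_identical_sequences_zero_everything(self):
        design = [LocusDesign("L", "mitochondrial", 4, {"A": 2, "B": 2})]
        ds = dataset_from(
            {"L": seq_matrix(["ACGT"] * 4)}, {"L": ["A", "A", "B", "B"]}, design
        )
        vec = iabc.summarize(ds)
        names = iabc.summary_names(design)
        d = dict(zip(names, vec))
        assert d["L:A:H"] == 1 and d["L:B:H"] == 1
        assert d["L:A:S"] == 0 and d["L:A:k"] == 0
        assert d["L:A-B:W"] == 0 and d["L:A-B:B"] == 0

    def test_two_population_within_between(self):
        # within diffs 0; all four cross pairs differ at 3 sites
        design = [LocusDesign("L", "mitochondrial", 6, {"A": 2, "B": 2})]
        ds = dataset_from(
            {"L": seq_matrix(["AAAAAA", "AAAAAA", "TTTAAA", "TTTAAA"])},
            {"L": ["A", "A", "B", "B"]},
            design,
        )
        d = dict(zip(iabc.summary_names(design), iabc.summarize(ds)))
        assert d["L:A-B:W"] == 0.0
        assert d["L:A-B:B"] == 3.0
        assert d["L:A:H"] == 1 and d["L:B:S"] == 0

    def test_vector_length_two_loci_three_pops(self):
        sizes = {"A": 2, "B": 2, "C": 2}
        design = [
            LocusDesign("L1", "mitochondrial", 4, dict(sizes)),
            LocusDesign("L2", "x_linked", 4, dict(sizes)),
        ]
        assert len(iabc.summary_names(design)) == 2 * (3 * 3) + 2 * (3 * 2)

    def test_single_sequence_population_masked_to_zero(self):
        design = [LocusDesign("L", "mitochondrial", 4, {"A": 1, "B": 2})]
        ds = dataset_from(
            {"L": seq_matrix(["ACGT", "ACGA", "ACGA"])},
            {"L": ["A", "B", "B"]},
            design,
        )
        d = dict(zip(iabc.summary_names(design), iabc.summarize(ds)))
        assert d["L:A:k"] == 0.0 and d["L:A:S"] == 0.0 and d["L:A:H"] == 1


def toy_table(n_per=50, gap=100.0, seed=0):
    """Two scenarios with well-separated Gaussian summary clouds."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 3))
    b = rng.normal(gap, 1.0, size=(n_per, 3))
    summaries = np.vstack([a, b])
    params = pd.DataFrame({"N": rng.uniform(10, 20, size=2 * n_per)})
    return iabc.ReferenceTable(
        scenario_names=["A", "B"],
        scenario_ids=np.array([0] * n_per + [1] * n_per),
        params=params,
        summaries=summaries,
        stat_names=["s1", "s2", "s3"],
        mad=iabc._mad(summaries),
    )


class TestChooseModel:
    def test_single_scenario_table_always_certain(self):
        ref = toy_table()
        ref_single = iabc.ReferenceTable(
            ["A"], np.zeros(100, dtype=int), ref.params, ref.summaries,
            ref.stat_names, ref.mad,
        )
        res = iabc.choose_model_direct(ref_single, np.array([5.0, 5.0, 5.0]),
                                       n_closest=100)
        assert res.posterior["A"] == 1.0

    def test_disjoint_clouds_give_certain_choice(self):
        ref = toy_table()
        res = iabc.choose_model_direct(ref, np.zeros(3), n_closest=40)
        assert res.posterior["A"] == 1.0 and res.posterior["B"] == 0.0

    def test_uniform_limit_with_all_rows(self):
        ref = toy_table()
        res = iabc.choose_model_direct(ref, np.zeros(3), n_closest=100)
        assert res.posterior["A"] == pytest.approx(0.5)
        assert res.posterior["B"] == pytest.approx(0.5)

    def test_posterior_sums_to_one_and_ci_contains_pp(self):
        ref = toy_table(gap=2.0)
        for obs in (np.zeros(3), np.full(3, 1.0), np.full(3, 3.0)):
            res = iabc.choose_model_direct(ref, obs, n_closest=30)
            assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-12)
            for s, pp in res.posterior.items():
                lo, hi = res.ci[s]
                assert 0.0 <= lo <= pp <= hi <= 1.0

    def test_mad_normalization_unit_scale(self):
        ref = toy_table()
        z = ref.normalized()
        mad = np.median(np.abs(z - np.median(z, axis=0)), axis=0)
        assert np.allclose(mad, 1.0, atol=1e-12)

    def test_reference_table_round_trip(self, tmp_path):
        ref = toy_table()
        path = tmp_path / "ref.tsv"
        ref.write(path)
        back = iabc.ReferenceTable.read(path)
        assert back.scenario_names == ref.scenario_names
        assert np.allclose(back.summaries, ref.summaries)
        assert np.allclose(back.mad, ref.mad)
        assert np.array_equal(back.scenario_ids, ref.scenario_ids)


class TestEstimateParameters:
    def test_constant_parameter_recovered_exactly(self):
        rng = np.random.default_rng(1)
        summaries = rng.normal(size=(60, 2))
        ref = iabc.ReferenceTable(
            ["A"], np.zeros(60, dtype=int),
            pd.DataFrame({"N": np.full(60, 7.5)}), summaries,
            ["s1", "s2"], iabc._mad(summaries),
        )
        post = iabc.estimate_parameters(ref, np.zeros(2), n_closest=60)
        assert post.median["N"] == pytest.approx(7.5, abs=1e-9)
        assert post.lower95["N"] == pytest.approx(7.5, abs=1e-9)

    def test_noiseless_linear_relation_collapses_to_truth(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(1.0, 5.0, size=(80, 1))
        params = pd.DataFrame({"N": 2.0 * s[:, 0]})
        ref = iabc.ReferenceTable(
            ["A"], np.zeros(80, dtype=int), params, s, ["s1"], iabc._mad(s)
        )
        obs = np.array([3.0])
        post = iabc.estimate_parameters(ref, obs, n_closest=80, log_scale=False)
        assert post.median["N"] == pytest.approx(6.0, abs=1e-8)
        assert post.upper95["N"] - post.lower95["N"] < 1e-6

    def test_singular_design_falls_back_to_rejection(self):
        # constant summaries make the regression design rank deficient
        summaries = np.ones((40, 2))
        params = pd.DataFrame({"N": np.linspace(1, 2, 40)})
        ref = iabc.ReferenceTable(
            ["A"], np.zeros(40, dtype=int), params, summaries, ["s1", "s2"],
            iabc._mad(summaries),
        )
        post = iabc.estimate_parameters(ref, np.ones(2), n_closest=40)
        assert post.lower95["N"] <= np.median(params["N"]) <= post.upper95["N"]


class TestPcaPriorCheck:
    def test_mean_observation_projects_to_origin(self):
        ref = toy_table(gap=1.0)
        obs = ref.summaries.mean(axis=0)
        check = iabc.pca_prior_check(ref, obs, n_components=2)
        assert np.linalg.norm(check.observed) < 1.5
        assert check.ok

    def test_far_observation_flagged(self):
        ref = toy_table(gap=1.0)
        obs = ref.summaries.mean(axis=0) + 100.0 * ref.mad
        check = iabc.pca_prior_check(ref, obs, n_components=2)
        assert not check.ok

    def test_rank_bounded_by_inputs(self):
        ref = toy_table()
        check = iabc.pca_prior_check(ref, ref.summaries[0], n_components=10)
        assert check.coordinates.shape[1] - 1 <= min(*ref.summaries.shape)
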