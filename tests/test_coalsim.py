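"""Scenario parsing, prior sampling, and the coalescent simulator."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from invabc.coalsim import (
    LocusDesign,
    MutationModel,
    ParameterDraw,
    Prior,
    ScenarioModel,
    FoundingEvent,
    apply_mutations,
    parse_scenario,
    sample_parameters,
    simulate_dataset,
    simulate_genealogy,
)
from invabc.seq_io import InputError

FIG3A_YAML = """
name: ghost_origin_trio
populations: {LA: N1, Sa: N2, NJ: N3, anc: N4}
sampled: [LA, Sa, NJ]
events:
  - {time: t1, source: Sa, target: NJ, founder: Nf3, duration: db}
  - {time: t2, source: anc, target: Sa, founder: Nf2, duration: db}
  - {time: t3, source: anc, target: LA, founder: Nf1, duration: db}
order: [t1, t2, t3]
"""


def constant_model(N=5000.0, name="single"):
    return ScenarioModel(
        name=name, populations={"P": "N"}, sampled=["P"], events=[],
        priors={"N": Prior(N, N)}, order=[],
    )


def fixed_draw(**values):
    defaults = {"mu": 1e-6, "kappa": 2.0, "p_inv": 0.1}
    mu = values.pop("mu", defaults["mu"])
    kappa = values.pop("kappa", defaults["kappa"])
    p_inv = values.pop("p_inv", defaults["p_inv"])
    return ParameterDraw(values=values, mu=mu, kappa=kappa, p_inv=p_inv)


def mrca_time(tree, a, b):
    anc_a = set()
    node = a
    while node >= 0:
        anc_a.add(node)
        node = tree.parent[node]
    node = b
    while node not in anc_a:
        node = tree.parent[node]
    return tree.time[node]


class TestParseScenario:
    def test_fig3a_topology_parses(self):
        model = parse_scenario(FIG3A_YAML)
        assert len(model.populations) == 4
        assert model.ghosts == ["anc"]
        assert [e.target for e in model.events] == ["NJ", "Sa", "LA"]
        # default priors filled in by parameter-name prefix
        assert model.priors["t1"].low == 1.0 and model.priors["t1"].high == 100.0
        assert model.priors["db"].low == 5.0
        assert model.priors["Nf3"].high == 10_000.0
        assert model.priors["N1"].high == 1_000_000.0

    def test_cycle_in_founding_events_rejected(self):
        with pytest.raises(InputError, match="cycle"):
            ScenarioModel(
                name="bad", populations={"A": "N1", "B": "N2"},
                sampled=["A", "B"],
                events=[
                    FoundingEvent("t1", "A", "B", "Nf1", "db"),
                    FoundingEvent("t2", "B", "A", "Nf2", "db"),
                ],
                priors={
                    "N1": Prior(1e3, 1e4), "N2": Prior(1e3, 1e4),
                    "t1": Prior(1, 50), "t2": Prior(1, 50),
                    "Nf1": Prior(1, 100), "Nf2": Prior(1, 100),
                    "db": Prior(5, 25),
                },
            )

    def test_disconnected_population_rejected(self):
        with pytest.raises(InputError, match="common ancestor"):
            ScenarioModel(
                name="bad", populations={"A": "N1", "B": "N2"},
                sampled=["A", "B"], events=[],
                priors={"N1": Prior(1e3, 1e4), "N2": Prior(1e3, 1e4)},
            )

    def test_ordered_parameter_without_prior_rejected(self):
        with pytest.raises(InputError):
            ScenarioModel(
                name="bad", populations={"A": "N1"}, sampled=["A"], events=[],
                priors={"N1": Prior(1e3, 1e4)}, order=["t9"],
            )


class TestSampleParameters:
    def test_draws_respect_support_and_ordering(self):
        model = parse_scenario(FIG3A_YAML)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            d = sample_parameters(model, rng)
            assert 5.0 < d["db"] < 25.0
            assert 1.0 < d["t1"] < d["t2"] < d["t3"] < 100.0
            assert 1e-9 <= d.mu <= 1e-7
            assert 0.05 <= d.kappa <= 20.0

    def test_ordered_marginal_matches_rejection_oracle(self):
        model = parse_scenario(FIG3A_YAML)
        rng = np.random.default_rng(1)
        mine = np.array([sample_parameters(model, rng)["t1"]
                         for _ in range(3000)])
        # brute-force rejection oracle, independent code path
        oracle_rng = np.random.default_rng(2)
        oracle = []
        while len(oracle) < 3000:
            t = oracle_rng.uniform(1, 100, size=3)
            if t[0] < t[1] < t[2]:
                oracle.append(t[0])
        assert ks_2samp(mine, np.array(oracle)).pvalue > 0.01

    def test_infeasible_constraints_raise(self):
        model = constant_model()
        model.priors["t1"] = Prior(10, 20)
        model.priors["t2"] = Prior(30, 40)
        model.order = ["t2", "t1"]  # impossible: t2 < t1 has empty support
        with pytest.raises(InputError, match="ordering"):
            sample_parameters(model, np.random.default_rng(0), max_attempts=200)


class TestGenealogy:
    def test_pair_tmrca_matches_msprime_oracle(self):
        """Mean TMRCA for two copies equals the gene-copy number; msprime
        run at the same haploid size is the independent check."""
        import msprime

        G = 1000.0
        model = constant_model(N=2 * G)  # mitochondrial scaling: G = N/2
        draw = fixed_draw(N=2 * G)
        rng = np.random.default_rng(3)
        mine = [
            simulate_genealogy(model, draw, {"P": 2}, "mitochondrial", rng)
            .time.max()
            for _ in range(2000)
        ]
        other = [
            msprime.sim_ancestry(
                samples=2, ploidy=1, population_size=G, random_seed=s
            ).max_root_time
            for s in range(1, 2001)
        ]
        assert np.mean(mine) == pytest.approx(G, rel=0.1)
        assert np.mean(mine) == pytest.approx(np.mean(other), rel=0.1)

    def test_no_cross_population_coalescence_before_split(self):
        model = ScenarioModel(
            name="split", populations={"A": "N1", "B": "N2"}, sampled=["A", "B"],
            events=[FoundingEvent("t1", "A", "B", "Nf", "db")],
            priors={
                "N1": Prior(500, 500), "N2": Prior(500, 500),
                "t1": Prior(50, 50), "Nf": Prior(500, 500), "db": Prior(5, 5),
            },
        )
        draw = fixed_draw(N1=500.0, N2=500.0, t1=50.0, Nf=500.0, db=5.0)
        rng = np.random.default_rng(4)
        for _ in range(50):
            tree = simulate_genealogy(model, draw, {"A": 3, "B": 3},
                                      "autosomal", rng)
            pops = tree.leaf_populations
            for i in range(6):
                for j in range(i + 1, 6):
                    if pops[i] != pops[j]:
                        assert mrca_time(tree, i, j) >= 50.0

    def test_founder_bottleneck_reduces_target_diversity(self):
        def scenario(nf):
            return (
                ScenarioModel(
                    name="b", populations={"S": "N1", "T": "N2"},
                    sampled=["S", "T"],
                    events=[FoundingEvent("t1", "S", "T", "Nf", "db")],
                    priors={
                        "N1": Prior(20_000, 20_000), "N2": Prior(20_000, 20_000),
                        "t1": Prior(50, 50), "Nf": Prior(nf, nf),
                        "db": Prior(25, 25),
                    },
                ),
                fixed_draw(N1=20_000.0, N2=20_000.0, t1=50.0, Nf=float(nf),
                           db=25.0, mu=5e-6),
            )

        def mean_target_k(nf, seed):
            model, draw = scenario(nf)
            rng = np.random.default_rng(seed)
            ks = []
            for _ in range(200):
                ds = simulate_dataset(
                    model, draw,
                    [LocusDesign("L", "autosomal", 200, {"S": 2, "T": 6})],
                    rng,
                )
                mat = ds.matrices["L"]
                rows = [i for i, p in enumerate(ds.populations["L"]) if p == "T"]
                sub = mat[rows]
                diffs = [
                    np.sum(sub[a] != sub[b])
                    for a in range(len(rows)) for b in range(a + 1, len(rows))
                ]
                ks.append(np.mean(diffs))
            return np.mean(ks)

        assert mean_target_k(5, seed=5) < mean_target_k(20_000, seed=6)


class TestMutations:
    def test_zero_rate_gives_identical_sequences(self):
        model = constant_model()
        draw = fixed_draw(N=5000.0, mu=0.0)
        rng = np.random.default_rng(7)
        tree = simulate_genealogy(model, draw, {"P": 6}, "mitochondrial", rng)
        mat = apply_mutations(tree, MutationModel(0.0, 2.0, 0.1, 100), rng)
        assert np.all(mat == mat[0])

    def test_invariant_fraction_never_mutates(self):
        model = constant_model(N=50_000)
        draw = fixed_draw(N=50_000.0, mu=1e-4, p_inv=0.5)
        rng = np.random.default_rng(8)
        tree = simulate_genealogy(model, draw, {"P": 8}, "mitochondrial", rng)
        mat = apply_mutations(tree, MutationModel(1e-4, 2.0, 0.5, 100), rng)
        n_varying = int(np.sum(np.any(mat != mat[0], axis=0)))
        assert n_varying <= 50  # floor(0.5 * 100) sites are frozen

    def test_large_kappa_suppresses_transversions(self):
        model = constant_model(N=100_000)
        draw = fixed_draw(N=100_000.0, mu=2e-5, kappa=2.0)
        rng = np.random.default_rng(9)
        tree = simulate_genealogy(model, draw, {"P": 2}, "mitochondrial", rng)
        mat = apply_mutations(
            tree, MutationModel(2e-5, 1e6, 0.0, 400), rng
        )
        a, b = mat
        diff = a != b
        assert diff.sum() > 10
        purine = np.isin(a, [ord("A"), ord("G")])
        b_purine = np.isin(b, [ord("A"), ord("G")])
        transversions = diff & (purine != b_purine)
        assert transversions.sum() == 0  # kappa -> inf: transitions only


class TestSimulateDataset:
    def _trio(self):
        return [
            LocusDesign("mt", "mitochondrial", 120, {"P": 5}),
            LocusDesign("nuc", "autosomal", 80, {"P": 5}),
        ]

    def test_fixed_seed_reproducible(self):
        model = constant_model()
        draw = fixed_draw(N=5000.0)
        d1 = simulate_dataset(model, draw, self._trio(),
                              np.random.default_rng(42))
        d2 = simulate_dataset(model, draw, self._trio(),
                              np.random.default_rng(42))
        for name in ("mt", "nuc"):
            assert np.array_equal(d1.matrices[name], d2.matrices[name])

    def test_loci_have_independent_genealogies(self):
        model = constant_model(N=200_000)
        draw = fixed_draw(N=200_000.0, mu=1e-5)
        ds = simulate_dataset(model, draw, self._trio(),
                              np.random.default_rng(43))
        assert not np.array_equal(ds.matrices["mt"][:, :80], ds.matrices["nuc"])

    def test_time_rescaling_preserves_diversity(self):
        """Doubling N and halving mu leaves E[k] unchanged."""
        def mean_k(N, mu, seed):
            model = constant_model(N=N)
            draw = fixed_draw(N=float(N), mu=mu)
            rng = np.random.default_rng(seed)
            ks = []
            for _ in range(1500):
                tree = simulate_genealogy(model, draw, {"P": 4},
                                          "mitochondrial", rng)
                mat = apply_mutations(
                    tree, MutationModel(mu, 2.0, 0.1, 150), rng
                )
                diffs = [
                    np.sum(mat[a] != mat[b])
                    for a in range(4) for b in range(a + 1, 4)
                ]
                ks.append(np.mean(diffs))
            return np.mean(ks)

        k1 = mean_k(4000, 2e-6, seed=10)
        k2 = mean_k(8000, 1e-6, seed=11)
        assert k1 == pytest.approx(k2, rel=0.1)

    def test_alignment_round_trip(self):
        model = constant_model()
        draw = fixed_draw(N=5000.0)
        ds = simulate_dataset(model, draw, self._trio(),
                              np.random.default_rng(44))
        alns, popmap = ds.to_alignments()
        assert alns["mt"].n == 5 and alns["mt"].length == 120
        assert alns["mt"].inheritance == "mitochondrial"
        for sid in alns["mt"].sample_ids:
            assert popmap.population_of(sid) == "P"
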