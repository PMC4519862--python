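"""Shared fixtures: small alignments plus session-scoped ABC tables.

The ABC reference tables are expensive (tens of thousands of coalescent
datasets), so they are built once per session and shared between the
recovery, error-rate and calibration tests.
"""

from __future__ import annotations

import copy

import numpy as np
import pytest

from invabc import abc as iabc
from invabc.coalsim import Prior
from invabc.seq_io import Alignment, PopulationMap
from invabc.synthetic_data import StudyDesign, scenario_library

# deliberately separable scenario pair for machinery-validation tests:
# same locus design, disjoint effective-size priors and a fixed mutation
# rate, so the summary distributions barely overlap
SEPARABLE_MUTATION_PRIORS = {"mu": (1e-8, 1e-8), "kappa": (2.0, 2.0)}


def make_alignment(seqs, inheritance="mitochondrial", locus="locus"):
    return Alignment(locus, inheritance, [(f"s{i}", s) for i, s in enumerate(seqs)])


def single_population_map(aln: Alignment, pop="P1") -> PopulationMap:
    return PopulationMap({sid: pop for sid in aln.sample_ids})


@pytest.fixture(scope="session")
def trio_loci():
    """Desk-scale two-locus design over the LA / Sa / NJ entry-point trio."""
    design = StudyDesign.default()
    return design.locus_designs(design.cluster1_groups())


@pytest.fixture(scope="session")
def separable_models():
    lib = scenario_library()

    def with_n_prior(model, lo, hi, name):
        m = copy.deepcopy(model)
        for p in set(m.populations.values()):
            m.priors[p] = Prior(lo, hi)
        m.name = name
        return m

    a = with_n_prior(lib["cluster1_scenario5"], 1e3, 3e4, "low_n_ghost_origin")
    b = with_n_prior(lib["cluster1_usa_origin"], 3e5, 1e6, "high_n_usa_origin")
    return a, b


@pytest.fixture(scope="session")
def separable_reference(separable_models, trio_loci):
    a, b = separable_models
    return iabc.build_reference_table(
        [a, b], 10_000, trio_loci, seed=101,
        mutation_priors=SEPARABLE_MUTATION_PRIORS,
    )


@pytest.fixture(scope="session")
def separable_pods(separable_models, trio_loci):
    a, _ = separable_models
    rng = np.random.default_rng(202)
    return iabc.simulate_pods(a, trio_loci, 100, rng,
                              mutation_priors=SEPARABLE_MUTATION_PRIORS)


@pytest.fixture(scope="session")
def study_scenario5():
    return scenario_library()["cluster1_scenario5"]


@pytest.fixture(scope="session")
def study_reference(study_scenario5, trio_loci):
    """Single-scenario table under the study priors (parameter recovery)."""
    return iabc.build_reference_table([study_scenario5], 10_000, trio_loci,
                                      seed=404)


@pytest.fixture(scope="session")
def study_pods(study_scenario5, trio_loci):
    rng = np.random.default_rng(505)
    return iabc.simulate_pods(study_scenario5, trio_loci, 100, rng)
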