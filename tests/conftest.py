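"""Shared fixtures: small deterministic cohorts built by the generator."""

import warnings

import numpy as np
import pandas as pd
import pytest

from poegwas.assoc import Whitener
from poegwas.kinship import partition_clusters, pedigree_kinship
from poegwas.phenotype import adjust_and_standardize
from poegwas.synthetic import (
    ArchitectureSpec,
    CausalVariant,
    SimulatedCohort,
    founder_pedigree,
    simulate_cohort,
    simulate_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    trio_pedigree,
)


def standardize_quiet(phenotypes: pd.DataFrame) -> pd.Series:
    """Standardized trait indexed by iid, silencing small-stratum warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = adjust_and_standardize(phenotypes)
    return std.set_index("iid")["y"]


@pytest.fixture(scope="session")
def three_generation_pedigree():
    return simulate_pedigree(8, 3, mating_rate=1.0, seed=11)


@pytest.fixture(scope="session")
def founder_cohort():
    """2,000 unrelated samples, 20 independent variants, one additive causal."""
    ped = founder_pedigree(2000)
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "additive", a=0.25),), background_h2=0.0
    )
    cohort = simulate_cohort(ped, spec, n_variants=20, seed=5)
    kin = pedigree_kinship(ped)
    part = partition_clusters(ped)
    y = standardize_quiet(cohort.phenotypes["height"])
    return cohort, kin, part, y


@pytest.fixture(scope="session")
def trio_cohort():
    """300 independent trios with an opposing-effect causal variant."""
    ped = trio_pedigree(300)
    spec = ArchitectureSpec(
        causal=(CausalVariant("var1", "opposing", a_p=-0.4, a_m=0.2),),
        background_h2=0.4,
    )
    cohort = simulate_cohort(
        ped, spec, n_variants=10, maf_range=(0.2, 0.5), seed=13
    )
    kin = pedigree_kinship(ped)
    part = partition_clusters(ped)
    y = standardize_quiet(cohort.phenotypes["height"])
    return cohort, kin, part, y
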