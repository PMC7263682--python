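import numpy as np
import pytest

import bpsim


@pytest.fixture
def small_genome():
    return bpsim.build_genome(2, 1.0, 200)


@pytest.fixture
def founder_pop(small_genome):
    return bpsim.create_founder_population(small_genome, 20, seed=7, freq_spec=0.5)


def example_scenario_config(n_sires: int, seed: int = 1, reps: int = 1) -> dict:
    """The two-scenario truncation-selection experiment: 100 founders,
    10,000 SNPs on 5 x 2 Morgan chromosomes, one trait with 50 additive and
    10 dominant QTL scaled to founder variance 1, phenotypes at h2 = 0.5,
    GBLUP EBVs with VanRaden G, top n_sires males / top 20 females selected,
    100 offspring by uniform random mating with replacement."""
    return {
        "seed": seed,
        "replicates": reps,
        "genome": {"n_chr": 5, "chr_length_morgan": 2.0, "n_snp": 10000},
        "founders": {"n": 100, "cohort": "Founder"},
        "traits": {"n_additive": 50, "n_dominant": 10, "var_target": 1.0},
        "actions": [
            {
                "name": "Offspring",
                "phenotyping": {"heritability": 0.5},
                "evaluation": {"kind": "G", "h2": 0.5},
                "breeding_size": 100,
                "selection_size": [n_sires, 20],
                "selection_criterion": "bve",
                "selection_m": {"cohorts": ["Founder_M"]},
                "selection_f": {"cohorts": ["Founder_F"]},
            }
        ],
    }


@pytest.fixture
def scenario_config():
    return example_scenario_config
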