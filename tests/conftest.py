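import numpy as np
import pandas as pd
import pytest

from epicross import simulate
from epicross.pipeline import species_consensus


@pytest.fixture(scope="session")
def strong_species():
    """10-chromosome species with strong CHH-recombination coupling."""
    return simulate.simulate_species(
        10, seed=11, chrom_length=20_000_000, n_individuals=2, chh_coupling=0.9
    )


@pytest.fixture(scope="session")
def strong_consensus(strong_species):
    return species_consensus(strong_species, use_truth_rates=True)


@pytest.fixture(scope="session")
def null_species():
    """Species with every methylation-recombination coupling switched off."""
    return simulate.simulate_species(
        10, seed=23, chrom_length=20_000_000, n_individuals=2,
        chh_coupling=0.0, cg_peri_enrich=1.0, chg_peri_enrich=1.0,
    )


@pytest.fixture(scope="session")
def null_consensus(null_species):
    return species_consensus(null_species, use_truth_rates=True)


def make_records(rows):
    """Cytosine report frame from (chrom, pos, strand, n_meth, n_unmeth, context, tri)."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"],
    )


def single_feature_consensus(seed=0, n_chrom=4, n_per_chrom=150):
    """Consensus-shaped table whose target depends only on chh_s."""
    rng = np.random.default_rng(seed)
    n = n_chrom * n_per_chrom
    df = pd.DataFrame(
        {
            "chrom": np.repeat([f"chr{i + 1}" for i in range(n_chrom)], n_per_chrom),
            "window_index": np.tile(np.arange(n_per_chrom), n_chrom),
            "cg_s": rng.normal(size=n),
            "chg_s": rng.normal(size=n),
            "chh_s": rng.normal(size=n),
        }
    )
    df["rate_s"] = np.sin(df["chh_s"]) * 2.0
    return df
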