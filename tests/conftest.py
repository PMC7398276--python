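import numpy as np
import pandas as pd
import pytest

from methkit.pipeline import (Dataset, recovery_report, run_dmr_stage,
                              run_domain_stage, simulate_dataset)


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """A sub-megabase synthetic dataset shared across the suite."""
    return simulate_dataset("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_results(tiny_dataset):
    """DMR and domain calls on the tiny dataset, plus recovery scores."""
    dmr_res = run_dmr_stage(tiny_dataset, n_permutations=500, seed=11)
    dom_res = run_domain_stage(tiny_dataset, pmd_trees=200, seed=11)
    report = recovery_report(tiny_dataset, dmr_res, dom_res)
    return dmr_res, dom_res, report


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_allc(rows):
    """Helper: build an allc frame from (chrom, pos, strand, context, mc, cov)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "cov"])
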