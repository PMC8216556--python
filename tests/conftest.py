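import numpy as np
import pytest

from thermoglyco.io_formats import ExperimentDesign, PeptideRecord
from thermoglyco.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return ExperimentDesign.default()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic experiment shared across tests (seeded)."""
    cfg = SimulationConfig(seed=7, n_proteins=80, n_glycoproteins=30,
                           n_categories=12, frac_shared_peptides=0.1)
    return generate(cfg)


def make_peptide(design, seq, accessions, levels, base=1e6):
    """PeptideRecord whose intensity in each channel is base*levels[condition]:
    every replicate ratio for comparison (A, B) equals levels[A]/levels[B]."""
    intens = {ch: base * levels[design.condition_of[ch]] for ch in design.channels}
    return PeptideRecord(seq, tuple(accessions), intens)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
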