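"""Shared fixtures: a pore model, the barcode set, and small simulated
libraries.  Everything is generated at test time from fixed seeds."""

import numpy as np
import pytest

from squigglebin import simulator as sim


@pytest.fixture(scope="session")
def pore_model():
    return sim.build_pore_model()


@pytest.fixture(scope="session")
def barcodes():
    return sim.make_barcodes()


@pytest.fixture(scope="session")
def toy_model():
    """A k=1 pore model with hand-set levels A=-1, C=0, G=1, T=2."""
    return sim.PoreModel(k=1, means=np.array([-1.0, 0.0, 1.0, 2.0]),
                         level_sd=0.1, seed=0)


@pytest.fixture(scope="session")
def small_library(pore_model):
    """60 clean reads (no barcode-less, no chimeras, quality-independent
    noise), with truth."""
    cfg = sim.SimConfig(n_reads=60, no_barcode_rate=0.0, chimera_rate=0.0,
                        link_quality_to_noise=False)
    squiggles, truths, fastq = sim.simulate_library(pore_model, cfg, seed=7)
    return squiggles, truths, fastq, cfg


@pytest.fixture(scope="session")
def mixed_library(pore_model):
    """80 reads with default barcode-less and chimera rates."""
    cfg = sim.SimConfig(n_reads=80)
    squiggles, truths, fastq = sim.simulate_library(pore_model, cfg, seed=11)
    return squiggles, truths, fastq, cfg
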