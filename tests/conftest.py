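import numpy as np
import pandas as pd
import pytest

import lettersim as ls
from lettersim.design import generate_categ_designs, generate_search_designs

ALPHABET6 = "abcdef"


@pytest.fixture(scope="session")
def glyphs6():
    return ls.render_glyphs(ALPHABET6, n_fonts=6, seed=0)


@pytest.fixture(scope="session")
def truth6(glyphs6):
    return ls.GroundTruth(ls.truth_rdm_from_glyphs(glyphs6))


@pytest.fixture(scope="session")
def search_dataset(truth6, glyphs6):
    """Simulated search experiment at the reduced test scale (60 HITs)."""
    hits = generate_search_designs(5, glyphs6.fonts, 2, seed=1, alphabet=ALPHABET6)
    trials = ls.simulate_search(truth6, hits, seed=2)
    return hits, trials


@pytest.fixture(scope="session")
def categ_dataset(truth6, glyphs6):
    """Simulated categorization experiment at the reduced test scale."""
    hits = generate_categ_designs(
        ALPHABET6, 8, 60, seed=0, pairs_per_block=3, fonts=glyphs6.fonts
    )
    trials = ls.simulate_categ(truth6, hits, seed=1)
    return hits, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_noiseless_truth(n_letters=4, seed=0):
    """Ground truth with every stochastic RT component switched off."""
    truth = ls.default_truth(seed=seed, n_letters=n_letters, n_fonts=3)
    truth.search = ls.SearchParams(
        hit_offset_sd=0.0, residual_sd=0.0, lapse_rate=0.0,
        error_base=0.0, error_slope=0.0,
    )
    truth.categ = ls.CategParams(
        hit_intercept_sd=0.0, residual_sd_ms=0.0, error_base=0.0, error_slope=0.0
    )
    return truth
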