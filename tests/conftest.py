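import numpy as np
import pytest

from selcontrast.genetics import CodonAlignment, universal_code
from selcontrast.model import (CodonFrequencies, CodonModelParams, QFactory,
                               fit_global_model, hky_exchangeabilities)
from selcontrast.simulate import (SiteOmegaSpec, default_params,
                                  scale_to_mean_pairwise, simulate_alignment,
                                  simulate_tree)


@pytest.fixture(scope="session")
def code():
    return universal_code()


@pytest.fixture(scope="session")
def params(code):
    freqs = CodonFrequencies.f3x4(
        np.array([[0.3, 0.2, 0.2, 0.3],
                  [0.25, 0.25, 0.25, 0.25],
                  [0.28, 0.22, 0.20, 0.30]]), code)
    return CodonModelParams(hky_exchangeabilities(2.0), freqs,
                            alpha=1.0, beta=0.7)


@pytest.fixture(scope="session")
def small_tree():
    """16-taxon coalescent tree at moderate depth."""
    return scale_to_mean_pairwise(
        simulate_tree(16, "coalescent", 1.0, seed=42), 0.9)


@pytest.fixture(scope="session")
def small_aln(small_tree):
    """Neutral 40-codon alignment on the small tree."""
    return simulate_alignment(small_tree, SiteOmegaSpec.constant(40, 1.0, 1.0),
                              default_params(), seed=7)


@pytest.fixture(scope="session")
def small_fit(small_aln, small_tree):
    return fit_global_model(small_aln, small_tree, nuc_model="HKY")
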