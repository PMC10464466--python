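import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from sensescale import published_loadings
from sensescale.synth import BifactorSpec, default_thresholds, simulate_responses


@pytest.fixture(scope="session")
def hypo_loadings():
    return published_loadings("HYPO")


@pytest.fixture(scope="session")
def hypo_spec(hypo_loadings):
    return BifactorSpec(hypo_loadings, default_thresholds(hypo_loadings.n_items))


@pytest.fixture(scope="session")
def hypo_sample_3000(hypo_spec):
    """One n=3000 sample from the published HYPO generating model."""
    return simulate_responses(hypo_spec, 3000, seed=20260921)


@pytest.fixture(scope="session")
def hypo_fit_3000(hypo_sample_3000, hypo_loadings):
    """Bifactor GRM fitted to the shared n=3000 HYPO sample (slow; shared)."""
    from sensescale.grm import fit_grm

    structure = {i: s for i, s in zip(hypo_loadings.item_ids, hypo_loadings.subscale)}
    return fit_grm(hypo_sample_3000, structure, tol=1e-5, max_iter=500)
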