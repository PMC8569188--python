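import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clonebench as cb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_ref():
    return cb.toy_reference(cb.FixtureSpec(n_contigs=2, contig_length=50_000, seed=7))


@pytest.fixture(scope="session")
def eight_clone_tree():
    return cb.parse_structure(cb.EIGHT_CLONE_STRUCTURE)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def diploid_config(**overrides):
    """All copy-number machinery off: every somatic variant is het diploid."""
    base = dict(
        snvgermline=0.0, indgermline=0.0,
        snvsomatic_total=400, indsomatic_total=40,
        aneuploid=0, wgdprob=0.0,
        cnvrepgermline=0, cnvdelgermline=0,
        cnvsomatic_rep=0, cnvsomatic_del=0,
        dbsnpsnvproportion=0.0, dbsnpindelproportion=0.0,
    )
    base.update(overrides)
    return cb.SimulationConfig(**base)


@pytest.fixture(scope="session")
def diploid_profiles(toy_ref, eight_clone_tree):
    """A noise-free diploid tumour over the eight-clone architecture."""
    rng = np.random.default_rng(11)
    cfg = diploid_config()
    events = cb.simulate_somatic_events(cfg, eight_clone_tree, toy_ref, rng)
    return cb.build_clone_profiles(eight_clone_tree, [], events, toy_ref, rng)


@pytest.fixture(scope="session")
def diploid_bulk(toy_ref, eight_clone_tree, diploid_profiles):
    comp = cb.BulkComposition.from_weights(
        {c: 1.0 for c in eight_clone_tree.clones}, purity=1.0)
    rng = np.random.default_rng(21)
    sample, truth = cb.compose_bulk(diploid_profiles, eight_clone_tree, comp,
                                    target_depth=250, rng=rng)
    return sample, truth, comp
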