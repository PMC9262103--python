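import numpy as np
import pytest

from ddrcca import (
    ConfoundSpec,
    ConnectomeSpec,
    DomainSpec,
    LinkSpec,
    SubjectTable,
    make_linked_dataset,
    preprocess_pipeline,
    stack_to_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    values = rng.standard_normal((30, 6))
    return SubjectTable(
        values=values,
        variable_names=[f"v{i}" for i in range(6)],
        subject_ids=[f"s{i}" for i in range(30)],
    )


def small_linked(n_subjects=400, rho=0.7, seed=7, n_patterns=3):
    """Small linked behaviour table + connectivity stack with one mode."""
    sm_specs = [
        DomainSpec("alpha", 8, 2, signal_sd=(3.0, 2.0), noise_sd=0.5),
        DomainSpec("beta", 8, 2, signal_sd=(3.0, 2.0), noise_sd=0.5),
    ]
    bm_spec = ConnectomeSpec(n_regions=10, n_patterns=n_patterns, noise_sd=0.3)
    link = LinkSpec(canonical_rhos=(rho,), sm_factors=(0,), bm_factors=(0,))
    return make_linked_dataset(
        sm_specs,
        bm_spec,
        link,
        n_subjects=n_subjects,
        confound_spec=ConfoundSpec(),
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def linked_preprocessed():
    """Preprocessed linked dataset shared by stability/CCA tests."""
    sm, stack, conf, fam, truth = small_linked(n_subjects=400, seed=7)
    bm, part_bm = stack_to_table(stack)
    smp, _ = preprocess_pipeline(sm, confounds=conf)
    bmp, _ = preprocess_pipeline(bm, confounds=conf)
    return {
        "sm": smp,
        "bm": bmp,
        "part_sm": truth["partition_sm"].restrict(smp.variable_names),
        "part_bm": part_bm.restrict(bmp.variable_names),
        "truth": truth,
    }
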