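import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rsapred.feature_encoding import PhysChemScales, WindowSpec, load_physchem_scales
from rsapred.io_formats import (
    ChainRecord,
    DisorderProfile,
    PssmProfile,
    RsaTrack,
    Ss3Profile,
)
from rsapred.synthetic_data import SyntheticSpec, generate_chain_set


@pytest.fixture(scope="session")
def scales() -> PhysChemScales:
    return load_physchem_scales()


@pytest.fixture(scope="session")
def spec9() -> WindowSpec:
    return WindowSpec(9)


@pytest.fixture(scope="session")
def small_chains(scales):
    """Eight feature-linked chains, lengths 30-40, fully populated."""
    return generate_chain_set(
        SyntheticSpec(n_chains=8, min_length=30, max_length=40, rng_seed=7), scales
    )


def make_chain(
    sequence: str,
    states: str | None = None,
    pssm_scores=None,
    p_disorder=None,
    rsa=None,
    chain_id: str = "c1",
) -> ChainRecord:
    """Hand-built chain with deterministic simple profiles for unit tests."""
    L = len(sequence)
    if pssm_scores is None:
        pssm_scores = np.zeros((L, 20))
    if states is None:
        states = "C" * L
    probs = np.zeros((L, 3))
    for i, s in enumerate(states):
        probs[i, "CHE".index(s)] = 1.0
    if p_disorder is None:
        p_disorder = np.zeros(L)
    p_disorder = np.asarray(p_disorder, dtype=float)
    return ChainRecord(
        chain_id=chain_id,
        sequence=sequence,
        pssm=PssmProfile(np.asarray(pssm_scores, dtype=float)),
        ss3=Ss3Profile(states, probs),
        disorder=DisorderProfile(
            p_disorder=p_disorder,
            p_order=1.0 - p_disorder,
            state=(p_disorder >= 0.5).astype(int),
        ),
        rsa=None if rsa is None else RsaTrack(np.asarray(rsa, dtype=float)),
    )
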