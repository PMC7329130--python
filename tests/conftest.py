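import pytest

from kstardesign.synthgen import GeneratorParams, generate_problem, toy1_state, toy2_problem

#: Small generator profile whose per-sequence conformation spaces stay well
#: under 1e4 (4 complex positions, <= 3 rotamers each), so the brute-force
#: oracles remain exhaustive and fast.
SMALL_PROFILE = dict(
    n_protein_pos=2,
    n_ligand_pos=2,
    n_mutable=2,
    types_per_mutable=3,
    rotamers_min=2,
    rotamers_max=3,
)


def small_problem(seed: int):
    return generate_problem(GeneratorParams(seed=seed, **SMALL_PROFILE))


@pytest.fixture(scope="session")
def toy1():
    return toy1_state()


@pytest.fixture(scope="session")
def toy2():
    return toy2_problem()
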