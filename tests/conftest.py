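import numpy as np
import pytest

from fieldqsar import (
    AlignedMolecule,
    Atom,
    SeriesSpec,
    SplitSpec,
    assign_atom_params,
    build_grid,
    generate_series,
    split_train_test,
)


@pytest.fixture(scope="session")
def series35():
    """Default 35-compound synthetic series (seed 7) with ground truth."""
    return generate_series(SeriesSpec(seed=7))


@pytest.fixture(scope="session")
def small_series():
    """A 12-compound series for cheaper matrix-level tests."""
    return generate_series(SeriesSpec(n_compounds=12, seed=3))


@pytest.fixture(scope="session")
def split35(series35):
    _, activities, _ = series35
    return split_train_test(activities, SplitSpec(seed=7))


@pytest.fixture()
def methane():
    """A methane-like molecule with explicit charges, parameters assigned."""
    atoms = [
        Atom("C", (0.0, 0.0, 0.0), -0.24),
        Atom("H", (0.63, 0.63, 0.63), 0.06),
        Atom("H", (-0.63, -0.63, 0.63), 0.06),
        Atom("H", (-0.63, 0.63, -0.63), 0.06),
        Atom("H", (0.63, -0.63, -0.63), 0.06),
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4)]
    return assign_atom_params(AlignedMolecule("methane", atoms, bonds))


@pytest.fixture()
def single_carbon():
    mol = AlignedMolecule("c1", [Atom("C", (0.0, 0.0, 0.0), 0.0)])
    return assign_atom_params(mol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241007)
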