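"""Shared fixtures: toy structures and small synthetic window sets."""

import numpy as np
import pandas as pd
import pytest

from tmdassoc import (SamplerConfig, StructureEnsemble, default_bias_specs,
                      generate_helix_dimer_ensemble, make_landscape,
                      simulate_umbrella_series)

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}


def build_ensemble(frames, atom_rows):
    """Hand-crafted ensemble: atom_rows are (chain, res_id, res_name,
    atom_name, element) tuples; frames is (n_frames, n_atoms, 3)."""
    atoms = pd.DataFrame(atom_rows, columns=["chain_id", "res_id", "res_name",
                                             "atom_name", "element"])
    atoms["mass"] = [_MASS[e] for e in atoms["element"]]
    return StructureEnsemble(np.asarray(frames, dtype=float), atoms)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def toy_dimer():
    """5-frame helix dimer at growing separations, with the lipid plane."""
    return generate_helix_dimer_ensemble([9.0, 10.0, 12.0, 15.0, 20.0], seed=0)


@pytest.fixture(scope="session")
def small_window_run():
    """Cheap 20-window umbrella run on the double-well landscape plus the
    landscape itself (shared across WHAM/reweight tests)."""
    land = make_landscape("double_well")
    cfg = SamplerConfig(n_steps=8000, seed=42)
    windows = simulate_umbrella_series(land, default_bias_specs(), cfg)
    return land, windows
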