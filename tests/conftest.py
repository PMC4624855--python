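import numpy as np
import pytest

from pcnmd import FixtureSpec, make_backbone, make_ensemble, select
from pcnmd.structure import AtomRecord, Ensemble, Structure


def make_atom(serial, name, element, chain, res_seq, xyz, res_name="ALA",
              occupancy=1.0, hetero=False):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc="", chain=chain,
        res_seq=res_seq, i_code="", res_name=res_name,
        coords=np.asarray(xyz, dtype=float), occupancy=occupancy, hetero=hetero,
    )


def ca_only_structure(coords, chain="A"):
    """Structure with one CA atom per residue at the given coordinates."""
    return Structure(
        [
            make_atom(i + 1, "CA", "C", chain, i + 1, xyz)
            for i, xyz in enumerate(np.asarray(coords, dtype=float))
        ]
    )


def static_ensemble(structure, n_frames=3, stride=10.0):
    frames = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    return Ensemble(structure, frames, stride * np.arange(n_frames))


@pytest.fixture
def helix20():
    return make_backbone(FixtureSpec(kind="helix", n_residues=20))


@pytest.fixture
def helix20_ca(helix20):
    return select(helix20, "name CA")


@pytest.fixture
def gaussian_ensemble(helix20):
    spec = FixtureSpec(kind="helix", n_residues=20, motion="gaussian",
                       n_frames=200, noise_sigma=0.2, seed=11)
    return make_ensemble(helix20, spec)


@pytest.fixture
def harmonic_ensemble(helix20):
    spec = FixtureSpec(kind="helix", n_residues=20, motion="harmonic",
                       n_frames=100, noise_sigma=0.5, seed=5)
    return make_ensemble(helix20, spec)


@pytest.fixture
def diffusive_ensemble(helix20):
    spec = FixtureSpec(kind="helix", n_residues=20, motion="diffusive",
                       n_frames=100, noise_sigma=0.3, seed=3)
    return make_ensemble(helix20, spec)
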