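import numpy as np
import pytest

from memanchor import synthetic_data as synth
from memanchor import traj_core as core


def point_topology(n, name="X", element="C", resname="PNT", segid="SYS"):
    """Minimal n-atom topology for hand-built geometric test frames."""
    return core.Topology(
        names=np.array([name] * n, dtype=object),
        elements=np.array([element] * n, dtype=object),
        masses=np.full(n, 12.011),
        resnames=np.array([resname] * n, dtype=object),
        resids=np.arange(1, n + 1),
        segids=np.array([segid] * n, dtype=object),
        molecule_ids=np.arange(n),
        molecule_labels={i: resname for i in range(n)},
    )


def make_frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return core.Frame(np.asarray(coords, dtype=float), np.asarray(box, dtype=float), time)


@pytest.fixture(scope="session")
def popc_bilayer():
    """Pure-POPC pseudo-bilayer planted at the reported pure-POPC values."""
    spec = synth.BilayerSpec(
        n_lipids_per_leaflet=64, thickness=3.87, area_per_lipid=0.662,
        target_order=0.176, species_fractions={"POPC": 1.0},
        jitter_sd=0.02, n_frames=10, seed=11)
    return spec, synth.make_bilayer(spec)


@pytest.fixture(scope="session")
def anchored_system():
    """Six-component-style bilayer with a doubly anchored pseudo-protein."""
    bspec = synth.BilayerSpec(n_lipids_per_leaflet=36, n_frames=5, seed=2)
    bilayer = synth.make_bilayer(bspec)
    aspec = synth.AnchorSpec(n_frames=300, seed=7)
    return aspec, synth.make_anchored_protein(aspec, bilayer)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
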