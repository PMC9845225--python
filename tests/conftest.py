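import numpy as np
import pytest

from oxmembrane import synthetic_data as syn
from oxmembrane.containers import BilayerTrajectory


@pytest.fixture(scope="session")
def mixing_traj() -> BilayerTrajectory:
    """Ideal-mixing two-species bilayer (no attraction)."""
    spec = syn.BilayerSimSpec(
        n_per_leaflet=200,
        box_lengths=(115.0, 115.0),
        species_fractions={"POPC": 0.5, "POPC-OOH": 0.5},
        n_frames=100,
        seed=11,
    )
    return syn.gen_bilayer_traj(spec)


@pytest.fixture(scope="session")
def rim_stack():
    """Two-population vesicle rim FLIM stack (2.0 / 2.4 ns, 50:50)."""
    geom = syn.RimGeometry(shape=(40, 40), radius=13.0, rim_width=3.0)
    dspec = syn.DecaySimSpec(
        lifetimes=[2.0], amplitudes=[1.0], peak_counts=500, background_rate=0.2, seed=5
    )
    return syn.gen_flim_stack(geom, [(2.0, 0.5, None), (2.4, 0.5, None)], dspec)


def make_traj(
    coords: np.ndarray,
    species=None,
    leaflet=None,
    role=None,
    mol_id=None,
    box=(100.0, 100.0),
    dt=1.0,
) -> BilayerTrajectory:
    """Hand-built trajectory helper for constructed fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return BilayerTrajectory(
        coords=coords,
        species=np.array(species if species is not None else ["A"] * n),
        leaflet=np.array(leaflet if leaflet is not None else ["upper"] * n),
        role=np.array(role if role is not None else ["phosphate"] * n),
        mol_id=np.array(mol_id if mol_id is not None else np.arange(n)),
        box=box,
        dt=dt,
    )
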