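"""Shared fixtures and tiny in-code system builders for the test suite.

All fixtures are generated programmatically; no data files are stored.
"""
from __future__ import annotations

import numpy as np
import pytest

from lidmap.model_io import BeadTopology, Frame, Role, Trajectory


def build_topology(
    n_protein_res: int = 0,
    lipid_species: tuple[str, ...] = (),
    residue_start: int = 1,
) -> BeadTopology:
    """Protein backbone chain (one BB bead per residue) followed by 3-bead
    lipids (PO4 + C1A + C2A), one per entry of ``lipid_species``.

    Bead layout: protein bead for residue i is index i; lipid l occupies
    indices n_protein_res + 3*l (head), +1 and +2 (acyl).
    """
    names, resids, resnames, mids, roles, species = [], [], [], [], [], []
    for i in range(n_protein_res):
        names.append("BB")
        resids.append(residue_start + i)
        resnames.append("ALA")
        mids.append(0)
        roles.append(Role.PROTEIN_BACKBONE)
        species.append("PROT")
    mol = 1 if n_protein_res else 0
    resid = residue_start + n_protein_res
    for sp in lipid_species:
        for name, role in (
            ("PO4", Role.LIPID_HEAD),
            ("C1A", Role.LIPID_ACYL),
            ("C2A", Role.LIPID_ACYL),
        ):
            names.append(name)
            resids.append(resid)
            resnames.append(sp)
            mids.append(mol)
            roles.append(role)
            species.append(sp)
        mol += 1
        resid += 1
    return BeadTopology(
        bead_names=np.array(names, dtype=object),
        residue_seq=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_id=np.array(mids),
        roles=np.array(roles, dtype=object),
        species=np.array(species, dtype=object),
    )


def lipid_head_index(top: BeadTopology, lipid: int) -> int:
    heads = np.flatnonzero(top.role_mask(Role.LIPID_HEAD))
    return int(heads[lipid])


def make_trajectory(top: BeadTopology, coords_per_frame, box=(50.0, 50.0, 50.0)) -> Trajectory:
    frames = [
        Frame(coords=np.asarray(c, dtype=float), box=np.asarray(box, dtype=float), time=float(i))
        for i, c in enumerate(coords_per_frame)
    ]
    return Trajectory(top, frames=frames)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bilayer():
    """~100 lipids per leaflet at exactly 80:10:10 in the lower leaflet."""
    from lidmap.synthetic import BilayerSpec, make_bilayer

    spec = BilayerSpec(box_xy=(80.0, 80.0), area_per_lipid=64.0)
    top, frame = make_bilayer(spec, seed=11)
    return spec, top, frame


@pytest.fixture(scope="session")
def bound_protein_traj(small_bilayer):
    """Always-bound synthetic trajectory with one planted orientation state."""
    from lidmap.synthetic import ProteinScheduleSpec, make_protein_trajectory

    spec, top, frame = small_bilayer
    pspec = ProteinScheduleSpec(bound_fraction=1.0)
    traj, truth = make_protein_trajectory(top, frame, pspec, n_frames=120, seed=7,
                                          bilayer_spec=spec)
    return traj, truth
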