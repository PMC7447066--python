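"""Shared fixtures: toy systems built atom-by-atom and small synthetic specs."""

from __future__ import annotations

import numpy as np
import pytest

from psitraj.core import ELEMENT_MASSES, Residue, Topology, Trajectory


def toy_topology(entries, **kwargs) -> Topology:
    """Build a Topology from (chain, resid, resname, atomname) tuples.

    Elements are inferred from the first letter of the atom name unless the
    tuple carries an explicit fifth element field.
    """
    residues: list[Residue] = []
    key_to_idx: dict[tuple[str, int], int] = {}
    names, elements, resindex = [], [], []
    for entry in entries:
        chain, resid, resname, atomname = entry[:4]
        element = entry[4] if len(entry) > 4 else atomname[0]
        key = (chain, resid)
        if key not in key_to_idx:
            key_to_idx[key] = len(residues)
            residues.append(Residue(index=resid, name=resname, chain=chain))
        names.append(atomname)
        elements.append(element)
        resindex.append(key_to_idx[key])
    return Topology(
        residues=residues,
        atom_names=np.array(names, dtype=object),
        atom_elements=np.array(elements, dtype=object),
        atom_masses=np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements]),
        atom_resindex=np.array(resindex, dtype=int),
        **kwargs,
    )


def toy_trajectory(topology: Topology, frames, times=None) -> Trajectory:
    coords = np.asarray(frames, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(topology=topology, times=times, coords=coords)


@pytest.fixture(scope="session")
def dimer_spec():
    from psitraj.synthetic import spec_for_condition

    return spec_for_condition(3.0, "AI", seed=11, n_frames=41)


@pytest.fixture(scope="session")
def dimer_trajectory(dimer_spec):
    from psitraj.synthetic import make_trajectory

    return make_trajectory(dimer_spec)
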