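import numpy as np
import pytest

from reinet import Atom, Frame, Residue, Topology, Trajectory
from reinet.structure_io import build_exclusions


def point_system(
    positions,
    charges=None,
    eps=0.0,
    rmin_half=1.0,
    bonds=(),
    masses=None,
    n_frames=1,
):
    """In-memory system with one atom per position.

    ``positions`` is a list per residue of lists of xyz triples; each
    residue owns its positions' atoms in order.
    """
    atoms, residues, coords = [], [], []
    flat_idx = 0
    for ri, pos_list in enumerate(positions):
        atom_ids = []
        for pos in pos_list:
            q = 0.0 if charges is None else charges[flat_idx]
            atoms.append(
                Atom(
                    atom_id=flat_idx,
                    name=f"C{len(atom_ids) + 1}",
                    type_name="STD",
                    residue_key=f"A:{ri + 1}",
                    charge=float(q),
                    lj_eps=float(eps),
                    lj_rmin_half=float(rmin_half),
                    mass=12.0 if masses is None else float(masses[flat_idx]),
                )
            )
            atom_ids.append(flat_idx)
            coords.append(pos)
            flat_idx += 1
        residues.append(Residue(ri, f"A:{ri + 1}", "ALA", tuple(atom_ids)))
    excluded, special = build_exclusions(flat_idx, bonds)
    topo = Topology(
        atoms=atoms,
        residues=residues,
        bonds=list(bonds),
        excluded_pairs=excluded,
        special14_pairs=special,
    )
    frames = [Frame(k, np.array(coords, float)) for k in range(n_frames)]
    return topo, Trajectory(topo, frames)


@pytest.fixture
def toy_files(tmp_path):
    """A small written-to-disk toy system plus its sidecar."""
    from reinet import FixtureSpec, make_toy_system

    spec = FixtureSpec(n_residues=4, seed=42)
    topo, traj, sidecar = make_toy_system(spec, tmp_path)
    return tmp_path, topo, traj, sidecar
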