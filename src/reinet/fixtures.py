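"""Synthetic systems with known ground truth.

Everything downstream of the file readers is testable against these
generators: toy topologies written as real PDB/PSF/CHARMM-parameter/XYZ
files (so the production readers are exercised end to end), seeded random
graphs for shortest-path cross-checks, and "hub" systems where designated
residues are given deliberately strong interactions so that pipeline-level
properties (the hub must surface as the best-connected residue) can be
asserted.

Fixture residues are simplified 2–8-atom bodies, not chemistry: trajectory
frames add isotropic Gaussian jitter per atom, no dynamics is claimed.
All randomness flows through the single seed in :class:`FixtureSpec`, and
a given seed reproduces the generated files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .energy import NonbondedParams, elec_pair_energy, lj_pair_energy
from .networks import Network
from .structure_io import (
    Atom,
    Frame,
    Residue,
    Topology,
    Trajectory,
    build_exclusions,
    read_topology,
    read_trajectory,
)

_RESNAMES = ["ALA", "GLY", "SER", "VAL", "LEU", "THR", "ASP", "LYS"]
_MIN_ATOM_SEPARATION = 0.5  # Å; closer than this is an infeasible geometry
# nonbonded (non-1-2/1-3) pairs closer than this are a steric clash: real
# structures keep such atoms near van der Waals contact, and r^-12 terms at
# sub-Å separations would produce meaninglessly huge energies
_MIN_NONBONDED_SEPARATION = 1.6
_MAX_RETRIES = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated toy system.

    ``geometry`` is one of ``linear-chain`` (residues strung along x and
    bonded together, so inter-residue 1-2/1-3/1-4 exclusions exist),
    ``globule`` (residue centers packed in a sphere) or ``two-body`` (two
    residues at a fixed separation). ``jitter_sd`` is the per-atom
    Gaussian displacement between frames, in Å.
    """

    n_residues: int = 4
    atoms_per_residue: tuple[int, int] = (2, 4)
    charge_range: tuple[float, float] = (-0.4, 0.4)
    eps_range: tuple[float, float] = (0.02, 0.2)
    rmin_half_range: tuple[float, float] = (1.0, 2.0)
    geometry: str = "linear-chain"
    separation: float = 5.0
    jitter_sd: float = 0.1
    n_frames: int = 3
    seed: int = 0
    n_types: int = 6

    def __post_init__(self) -> None:
        if self.geometry not in ("linear-chain", "globule", "two-body"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "two-body" and self.n_residues != 2:
            object.__setattr__(self, "n_residues", 2)
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValidationError("need at least one residue and one frame")


# ---------------------------------------------------------------------------
# scalar brute-force energy oracle (ground truth for sidecars)
# ---------------------------------------------------------------------------

def oracle_residue_pair_energy(
    topology: Topology,
    frame: Frame,
    res_a: int,
    res_b: int,
    params: NonbondedParams,
) -> float:
    """Naive double loop over atom pairs, one scalar term at a time.

    Deliberately kept free of array code so it is an independent check on
    the vectorized pipeline path.
    """
    total = 0.0
    for i in topology.residues[res_a].atom_ids:
        for j in topology.residues[res_b].atom_ids:
            key = (min(i, j), max(i, j))
            if key in topology.excluded_pairs:
                continue
            ai, aj = topology.atoms[i], topology.atoms[j]
            dx = frame.coords[i] - frame.coords[j]
            r = float(np.sqrt(dx @ dx))
            eps_i, rmh_i = ai.lj_eps, ai.lj_rmin_half
            eps_j, rmh_j = aj.lj_eps, aj.lj_rmin_half
            if key in topology.special14_pairs:
                if ai.type_name in topology.nb14_overrides:
                    eps_i, rmh_i = topology.nb14_overrides[ai.type_name]
                if aj.type_name in topology.nb14_overrides:
                    eps_j, rmh_j = topology.nb14_overrides[aj.type_name]
            eps_ij = (eps_i * eps_j) ** 0.5
            rmin_ij = rmh_i + rmh_j
            fix = topology.nbfix.get(tuple(sorted((ai.type_name, aj.type_name))))
            if fix is not None:
                eps_ij, rmin_ij = fix
            e = lj_pair_energy(eps_ij, rmin_ij, r, params)
            e_el = elec_pair_energy(ai.charge, aj.charge, r, params)
            if key in topology.special14_pairs:
                e_el *= params.scale14_elec
            total += e + e_el
    return total


def oracle_energy_tables(
    topology: Topology, trajectory: Trajectory, params: NonbondedParams
) -> tuple[dict, np.ndarray]:
    """Per-frame signed pair energies and the mean-|E| matrix, both from
    the scalar oracle."""
    n = topology.n_residues
    per_frame: dict = {}
    mean_abs = np.zeros((n, n))
    for frame in trajectory.frames:
        table = {}
        for i in range(n):
            for j in range(i + 1, n):
                e = oracle_residue_pair_energy(topology, frame, i, j, params)
                table[f"{i},{j}"] = e
                mean_abs[i, j] += abs(e)
        per_frame[str(frame.frame_index)] = table
    mean_abs /= trajectory.n_frames
    mean_abs = mean_abs + mean_abs.T
    return per_frame, mean_abs


# ---------------------------------------------------------------------------
# geometry + parameter generation
# ---------------------------------------------------------------------------

def _draw_types(rng: np.random.Generator, spec: FixtureSpec) -> dict[str, tuple]:
    """Atom-type table: type -> (eps, rmin/2, eps14 | None, rmin14/2 | None).

    Every other type also carries 1-4 override columns so that code path
    is exercised by default.
    """
    types = {}
    for k in range(spec.n_types):
        eps = rng.uniform(*spec.eps_range)
        rmh = rng.uniform(*spec.rmin_half_range)
        if k % 2 == 0:
            types[f"T{k:02d}"] = (eps, rmh, eps * 0.5, rmh * 0.9)
        else:
            types[f"T{k:02d}"] = (eps, rmh, None, None)
    return types


def _residue_centers(
    rng: np.random.Generator, spec: FixtureSpec, inflate: float = 1.0
) -> np.ndarray:
    n = spec.n_residues
    max_extent = 1.3 * (spec.atoms_per_residue[1] - 1)  # rod length per residue
    if spec.geometry == "two-body":
        return np.array([[0.0, 0.0, 0.0], [spec.separation, 0.0, 0.0]])
    if spec.geometry == "linear-chain":
        spacing = max(spec.separation, max_extent + 3.0)
        return np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    # globule: centers packed in a sphere; compact enough that residues stay
    # within the nonbonded cutoff of most others, inflated on regeneration
    # attempts until the packing is clash-free
    radius = inflate * max(4.0, (0.5 * max_extent + 2.2) * n ** (1 / 3))
    min_gap = 3.0
    centers = np.empty((n, 3))
    for i in range(n):
        for _ in range(500):
            p = rng.uniform(-radius, radius, 3)
            if p @ p > radius**2:
                continue
            if i == 0 or np.min(np.linalg.norm(centers[:i] - p, axis=1)) > min_gap:
                centers[i] = p
                break
        else:
            centers[i] = rng.uniform(-radius, radius, 3)
    return centers


def _build_system(spec: FixtureSpec, rng: np.random.Generator, inflate: float = 1.0):
    """One attempt at generating atoms/bonds/coordinates; may be infeasible."""
    types = _draw_types(rng, spec)
    type_names = list(types)
    centers = _residue_centers(rng, spec, inflate)

    atoms: list[Atom] = []
    residues: list[Residue] = []
    bonds: list[tuple[int, int]] = []
    base_coords: list[np.ndarray] = []
    for ri in range(spec.n_residues):
        n_atoms_res = int(rng.integers(spec.atoms_per_residue[0], spec.atoms_per_residue[1] + 1))
        label = f"A:{2 * ri + 1}"  # deliberately non-sequential author numbers
        atom_ids = []
        first = len(atoms)
        direction = _unit(rng)  # each residue is a short rod along one axis
        for ai in range(n_atoms_res):
            tname = type_names[int(rng.integers(len(type_names)))]
            eps, rmh, _, _ = types[tname]
            atoms.append(
                Atom(
                    atom_id=len(atoms),
                    name=f"C{ai + 1}",
                    type_name=tname,
                    residue_key=label,
                    charge=float(np.round(rng.uniform(*spec.charge_range), 4)),
                    lj_eps=eps,
                    lj_rmin_half=rmh,
                    mass=float(np.round(rng.uniform(10.0, 16.0), 3)),
                )
            )
            atom_ids.append(atoms[-1].atom_id)
            base_coords.append(centers[ri] + ai * 1.3 * direction + rng.normal(0, 0.1, 3))
            if ai > 0:
                bonds.append((atom_ids[ai - 1], atom_ids[ai]))
        residues.append(Residue(ri, label, _RESNAMES[ri % len(_RESNAMES)], tuple(atom_ids)))
        if spec.geometry == "linear-chain" and ri > 0:
            bonds.append((first - 1, first))  # peptide-like inter-residue bond
    coords = np.array(base_coords)
    return atoms, residues, bonds, coords, types


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _geometry_feasible(coords: np.ndarray, excluded) -> bool:
    """No overlaps anywhere; no steric clash between nonbonded pairs."""
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(d, np.inf)
    if d.min() < _MIN_ATOM_SEPARATION:
        return False
    for i, j in excluded:
        d[i, j] = d[j, i] = np.inf
    return d.min() >= _MIN_NONBONDED_SEPARATION


# ---------------------------------------------------------------------------
# file writers (toy dialects of the production formats)
# ---------------------------------------------------------------------------

def _write_pdb(path: Path, atoms, residues, coords) -> None:
    lines = []
    res_of = {}
    for res in residues:
        for aid in res.atom_ids:
            res_of[aid] = res
    for atom in atoms:
        res = res_of[atom.atom_id]
        resid = int(res.label.split(":")[1])
        x, y, z = coords[atom.atom_id]
        lines.append(
            f"ATOM  {atom.atom_id + 1:5d} {atom.name:<4s} {res.name:<3s} "
            f"A{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_psf(path: Path, atoms, residues, bonds) -> None:
    res_of = {}
    for res in residues:
        for aid in res.atom_ids:
            res_of[aid] = res
    out = ["PSF NAMD", "", "       1 !NTITLE", " REMARKS reinet toy fixture", ""]
    out.append(f"{len(atoms):8d} !NATOM")
    for atom in atoms:
        res = res_of[atom.atom_id]
        resid = int(res.label.split(":")[1])
        out.append(
            f"{atom.atom_id + 1:8d} A    {resid:<4d} {res.name:<4s} "
            f"{atom.name:<4s} {atom.type_name:<4s} {atom.charge:12.6f}  "
            f"{atom.mass:10.4f}           0"
        )
    out.append("")
    out.append(f"{len(bonds):8d} !NBOND: bonds")
    row = []
    for a, b in bonds:
        row.extend([a + 1, b + 1])
        if len(row) == 8:
            out.append("".join(f"{x:8d}" for x in row))
            row = []
    if row:
        out.append("".join(f"{x:8d}" for x in row))
    out.extend(["", "       0 !NTHETA: angles", ""])
    path.write_text("\n".join(out) + "\n")


def _write_params(path: Path, types: dict[str, tuple]) -> None:
    out = ["! reinet toy nonbonded parameter table (CHARMM-style)", "NONBONDED"]
    for tname, (eps, rmh, eps14, rmh14) in types.items():
        if eps14 is not None:
            out.append(
                f"{tname:<6s} 0.0 {-eps:10.6f} {rmh:10.6f} 0.0 {-eps14:10.6f} {rmh14:10.6f}"
            )
        else:
            out.append(f"{tname:<6s} 0.0 {-eps:10.6f} {rmh:10.6f}")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


def _write_xyz(path: Path, atoms, frames: list[np.ndarray]) -> None:
    out = []
    for k, coords in enumerate(frames):
        out.append(str(len(atoms)))
        out.append(f"frame {k}")
        for atom, (x, y, z) in zip(atoms, coords):
            out.append(f"C {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def make_toy_system(
    spec: FixtureSpec,
    out_dir: str | Path,
    params: NonbondedParams | None = None,
    prefix: str = "toy",
) -> tuple[Topology, Trajectory, dict]:
    """Write a toy PDB+PSF+parameter+XYZ set and its ground-truth sidecar.

    The returned topology/trajectory are the files *read back* through the
    production readers, and the sidecar's per-frame pair energies come from
    the scalar brute-force oracle evaluated on exactly those objects — so
    pipeline results must agree with the sidecar to float precision.
    Geometries whose closest atoms fall under 0.5 Å are regenerated from
    the same seed lineage, with bounded retries.
    """
    if params is None:
        params = NonbondedParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng((spec.seed, attempt))
        atoms, residues, bonds, coords, types = _build_system(
            spec, rng, inflate=1.0 + 0.25 * attempt
        )
        frames = [
            np.round(coords + (rng.normal(0, spec.jitter_sd, coords.shape) if spec.jitter_sd > 0 else 0.0), 6)
            for _ in range(spec.n_frames)
        ]
        excluded, _ = build_exclusions(len(atoms), bonds)
        if all(_geometry_feasible(f, excluded) for f in frames):
            break
    else:
        raise ValidationError(
            f"could not generate non-overlapping geometry after {_MAX_RETRIES} tries"
        )

    pdb, psf = out / f"{prefix}.pdb", out / f"{prefix}.psf"
    prm, xyz = out / f"{prefix}.prm", out / f"{prefix}.xyz"
    _write_pdb(pdb, atoms, residues, frames[0])
    _write_psf(psf, atoms, residues, bonds)
    _write_params(prm, types)
    _write_xyz(xyz, atoms, frames)

    topology = read_topology(psf, prm)
    trajectory = read_trajectory(topology, xyz, stride=1)
    per_frame, mean_abs = oracle_energy_tables(topology, trajectory, params)
    sidecar = {
        "spec": asdict(spec),
        "params": params.to_dict(),
        "labels": topology.residue_labels,
        "per_frame_pair_energy_kcal_mol": per_frame,
        "mean_abs_energy_kcal_mol": mean_abs.tolist(),
        "files": {"pdb": pdb.name, "psf": psf.name, "params": prm.name, "trajectory": xyz.name},
    }
    (out / f"{prefix}_sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return topology, trajectory, sidecar


def write_system_files(
    topology: Topology,
    trajectory: Trajectory,
    out_dir: str | Path,
    prefix: str = "system",
) -> dict[str, str]:
    """Serialize an in-memory system to PDB+PSF+parameter+XYZ files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    types: dict[str, tuple] = {}
    for a in topology.atoms:
        ov = topology.nb14_overrides.get(a.type_name, (None, None))
        types.setdefault(a.type_name, (a.lj_eps, a.lj_rmin_half, ov[0], ov[1]))
    frames = [f.coords for f in trajectory.frames]
    _write_pdb(out / f"{prefix}.pdb", topology.atoms, topology.residues, frames[0])
    _write_psf(out / f"{prefix}.psf", topology.atoms, topology.residues, topology.bonds)
    _write_params(out / f"{prefix}.prm", types)
    _write_xyz(out / f"{prefix}.xyz", topology.atoms, frames)
    return {
        "pdb": f"{prefix}.pdb",
        "psf": f"{prefix}.psf",
        "params": f"{prefix}.prm",
        "trajectory": f"{prefix}.xyz",
    }


def make_random_graph(
    n_nodes: int,
    edge_prob: float,
    cost_range: tuple[float, float] = (0.5, 5.0),
    seed: int = 0,
    directed: bool = False,
) -> Network:
    """Seeded Erdős–Rényi-style weighted graph for shortest-path tests."""
    rng = np.random.default_rng(seed)
    costs = np.full((n_nodes, n_nodes), np.inf)
    draw = rng.random((n_nodes, n_nodes))
    weights = rng.uniform(*cost_range, (n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if directed:
                if draw[i, j] < edge_prob:
                    costs[i, j] = weights[i, j]
            elif j > i and draw[i, j] < edge_prob:
                costs[i, j] = costs[j, i] = weights[i, j]
    return Network(
        costs=costs,
        labels=[str(i) for i in range(n_nodes)],
        directed=directed,
        semantics="inv_energy",
        params={"edge_prob": edge_prob, "seed": seed},
    )


def make_hub_system(
    n_residues: int = 10,
    hub_strength_factor: float = 10.0,
    seed: int = 0,
    n_hubs: int = 1,
    atoms_per_residue: int = 3,
    n_frames: int = 2,
    params: NonbondedParams | None = None,
) -> tuple[Topology, Trajectory, list[int]]:
    """Compact in-memory system whose first ``n_hubs`` residues interact
    deliberately strongly with everything else.

    Hub charges are calibrated (linearly, since the Coulomb term dominates
    by construction) so every hub pair's mean |E| is at least
    ``hub_strength_factor`` times the largest — hence also the median —
    non-hub pair energy. With a large factor the hubs must surface as the
    minimum of the average shortest-path profile of the energy network.
    """
    from .energy import pair_energy_matrix  # local import to avoid cycle at module load

    if params is None:
        params = NonbondedParams()
    if not 1 <= n_hubs < n_residues:
        raise ValidationError("need 1 <= n_hubs < n_residues")
    rng = np.random.default_rng(seed)
    hubs = list(range(n_hubs))

    # compact ball: every residue pair well inside the cutoff
    radius = 4.0
    centers = np.empty((n_residues, 3))
    for i in range(n_residues):
        for _ in range(500):
            p = rng.uniform(-radius, radius, 3)
            if p @ p > radius**2:
                continue
            if i == 0 or np.min(np.linalg.norm(centers[:i] - p, axis=1)) > 1.8:
                centers[i] = p
                break
        else:
            centers[i] = p

    atoms: list[Atom] = []
    residues: list[Residue] = []
    bonds: list[tuple[int, int]] = []
    coords = []
    signs = rng.choice([-1.0, 1.0], n_residues)
    for ri in range(n_residues):
        label = f"A:{ri + 1}"
        atom_ids = []
        for ai in range(atoms_per_residue):
            q = signs[ri] * rng.uniform(0.08, 0.12)
            atoms.append(
                Atom(
                    atom_id=len(atoms),
                    name=f"C{ai + 1}",
                    type_name="HUB" if ri in hubs else "STD",
                    residue_key=label,
                    charge=float(q),
                    lj_eps=1e-3,
                    lj_rmin_half=0.8,
                    mass=12.0,
                )
            )
            atom_ids.append(atoms[-1].atom_id)
            coords.append(centers[ri] + 0.6 * ai * _unit(rng) + rng.normal(0, 0.1, 3))
            if ai:
                bonds.append((atom_ids[-2], atom_ids[-1]))
        residues.append(Residue(ri, label, _RESNAMES[ri % len(_RESNAMES)], tuple(atom_ids)))
    excluded, special = build_exclusions(len(atoms), bonds)
    coords = np.array(coords)

    def build_topology(atom_list):
        return Topology(
            atoms=atom_list,
            residues=residues,
            bonds=bonds,
            excluded_pairs=excluded,
            special14_pairs=special,
        )

    frames = [
        Frame(k, coords + rng.normal(0, 0.05, coords.shape)) for k in range(n_frames)
    ]
    topology = build_topology(atoms)
    trajectory = Trajectory(topology, frames)

    hub_atom_ids = {a for h in hubs for a in residues[h].atom_ids}
    for _ in range(6):
        matrix = pair_energy_matrix(topology, trajectory, params)
        iu = np.triu_indices(n_residues, k=1)
        is_hub_pair = np.zeros((n_residues, n_residues), bool)
        for h in hubs:
            is_hub_pair[h, :] = is_hub_pair[:, h] = True
        hub_vals = matrix.values[iu][is_hub_pair[iu]]
        other_vals = matrix.values[iu][~is_hub_pair[iu]]
        target = hub_strength_factor * other_vals.max()
        if hub_vals.min() >= target:
            break
        scale = 1.3 * target / hub_vals.min()
        atoms = [
            Atom(
                a.atom_id, a.name, a.type_name, a.residue_key,
                a.charge * (scale if a.atom_id in hub_atom_ids else 1.0),
                a.lj_eps, a.lj_rmin_half, a.mass,
            )
            for a in atoms
        ]
        topology = build_topology(atoms)
        trajectory = Trajectory(topology, frames)
    return topology, trajectory, hubs
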