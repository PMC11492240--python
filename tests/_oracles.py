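"""Independent oracles used to cross-check the package.

Kept deliberately naive and separate from the implementation: energies
are evaluated one scalar atom pair at a time straight from the formulas,
bond-path classification goes through networkx, all-pairs shortest paths
through a triple-loop Floyd–Warshall, and alignments through exhaustive
recursion over all gapped alignments.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

COULOMB = 332.0636


def switch_factor(r: float, ron: float, rc: float) -> float:
    if r <= ron:
        return 1.0
    if r >= rc:
        return 0.0
    rc2, ron2, r2 = rc * rc, ron * ron, r * r
    return (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2) / (rc2 - ron2) ** 3


def bond_distances(n_atoms: int, bonds) -> dict:
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from(bonds)
    return dict(nx.all_pairs_shortest_path_length(g, cutoff=3))


def naive_residue_pair_energy(topology, coords, res_a: int, res_b: int, params) -> float:
    """Double loop over atom pairs, formulas written out longhand."""
    dists = bond_distances(topology.n_atoms, topology.bonds)
    rc, ron = params.cutoff, params.switch_on
    total = 0.0
    for i in topology.residues[res_a].atom_ids:
        for j in topology.residues[res_b].atom_ids:
            sep = dists.get(i, {}).get(j)
            if sep in (1, 2):
                continue
            ai, aj = topology.atoms[i], topology.atoms[j]
            r = math.dist(coords[i], coords[j])
            if r >= rc:
                continue
            eps_i, rmh_i = ai.lj_eps, ai.lj_rmin_half
            eps_j, rmh_j = aj.lj_eps, aj.lj_rmin_half
            if sep == 3:
                eps_i, rmh_i = topology.nb14_overrides.get(ai.type_name, (eps_i, rmh_i))
                eps_j, rmh_j = topology.nb14_overrides.get(aj.type_name, (eps_j, rmh_j))
            eps_ij = math.sqrt(eps_i * eps_j)
            rmin_ij = rmh_i + rmh_j
            fix = topology.nbfix.get(tuple(sorted((ai.type_name, aj.type_name))))
            if fix is not None:
                eps_ij, rmin_ij = fix
            s6 = (rmin_ij / r) ** 6
            e_lj = eps_ij * (s6 * s6 - 2 * s6) * switch_factor(r, ron, rc)
            e_el = COULOMB * ai.charge * aj.charge / (params.dielectric * r)
            if params.elec_scheme == "shifted":
                e_el *= (1 - (r / rc) ** 2) ** 2
            elif params.elec_scheme == "switched":
                e_el *= switch_factor(r, ron, rc)
            if sep == 3:
                e_el *= params.scale14_elec
            total += e_lj + e_el
    return total


def naive_mean_abs_matrix(topology, trajectory, params) -> np.ndarray:
    n = topology.n_residues
    acc = np.zeros((n, n))
    for frame in trajectory.frames:
        for i in range(n):
            for j in range(i + 1, n):
                acc[i, j] += abs(
                    naive_residue_pair_energy(topology, frame.coords, i, j, params)
                )
    acc /= trajectory.n_frames
    return acc + acc.T


def floyd_warshall(costs: np.ndarray, directed: bool) -> np.ndarray:
    n = costs.shape[0]
    d = np.array(costs, dtype=float)
    if not directed:
        d = np.minimum(d, d.T)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def enumerate_alignment_score(seq_a: str, seq_b: str, match: float,
                              mismatch: float, gap: float) -> float:
    """Optimal global alignment score by exhaustive recursion (linear gaps)."""

    def best(i: int, j: int) -> float:
        if i == len(seq_a):
            return -gap * (len(seq_b) - j)
        if j == len(seq_b):
            return -gap * (len(seq_a) - i)
        sub = match if seq_a[i] == seq_b[j] else mismatch
        return max(
            best(i + 1, j + 1) + sub,
            best(i + 1, j) - gap,
            best(i, j + 1) - gap,
        )

    return best(0, 0)
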