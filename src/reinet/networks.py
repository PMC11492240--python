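"""Residue-graph construction.

Three graph flavors over the same residue nodes:

* **residue COM network** — undirected; residues linked when their
  trajectory-averaged center-of-mass distance is ≤ 8 Å; edge cost is 1
  (binary variant) or the averaged distance in Å (weighted variant);
* **atom contact network** — directed, built from a single snapshot;
  c = number of atom pairs closer than 3.5 Å between residues A (I atoms)
  and B (J atoms); connectivity A→B = c/I, so cost(A→B) = I/c and
  cost(B→A) = J/c (higher connectivity, cheaper edge);
* **energy network** — undirected; edge cost is the inverse of the mean
  absolute interaction energy, 1/mean|E| in mol/kcal, so that strongly
  interacting residues are close in shortest-path terms. Attractive and
  repulsive interactions count alike. No distance threshold is needed.

Absent edges are stored as +inf in the cost matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .energy import PairEnergyMatrix
from .structure_io import Frame, Topology, Trajectory

SEMANTICS = ("binary", "com_distance", "inv_connectivity", "inv_energy")


@dataclass
class Network:
    """Weighted residue graph.

    ``costs`` is the N×N nonnegative edge-cost matrix with +inf marking
    absent edges (including the diagonal: no self-edges). ``semantics``
    tags what the costs mean so downstream comparisons can refuse to mix
    units.
    """

    costs: np.ndarray
    labels: list[str]
    directed: bool
    semantics: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, dtype=float)
        n = self.costs.shape[0]
        if self.costs.shape != (n, n) or len(self.labels) != n:
            raise ValidationError("network cost matrix/label mismatch")
        if self.semantics not in SEMANTICS:
            raise ValidationError(f"unknown semantics {self.semantics!r}")
        if np.any(np.isfinite(np.diag(self.costs))):
            raise ValidationError("self-edges are not allowed")
        finite = self.costs[np.isfinite(self.costs)]
        if np.any(finite <= 0):
            raise ValidationError("finite edge costs must be positive")
        if not self.directed and not np.array_equal(
            self.costs, self.costs.T
        ):
            raise ValidationError("undirected network has asymmetric costs")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        finite = np.isfinite(self.costs).sum()
        return int(finite if self.directed else finite // 2)

    # serialization ---------------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source_label\ttarget_label\tcost\n")
            for i in range(self.n_nodes):
                js = range(self.n_nodes) if self.directed else range(i + 1, self.n_nodes)
                for j in js:
                    if i != j and np.isfinite(self.costs[i, j]):
                        fh.write(f"{self.labels[i]}\t{self.labels[j]}\t{self.costs[i, j]:.12g}\n")

    def to_adjacency_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.costs, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    def sidecar(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "semantics": self.semantics,
                    "directed": self.directed,
                    "n_nodes": self.n_nodes,
                    "n_edges": self.n_edges,
                    "params": self.params,
                },
                indent=2,
            )
        )

    @classmethod
    def from_adjacency_tsv(cls, path: str | Path, sidecar: str | Path) -> "Network":
        import pandas as pd

        meta = json.loads(Path(sidecar).read_text())
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            costs=df.to_numpy(float),
            labels=[str(c) for c in df.columns],
            directed=bool(meta["directed"]),
            semantics=str(meta["semantics"]),
            params=dict(meta.get("params", {})),
        )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def average_com_distances(topology: Topology, trajectory: Trajectory) -> np.ndarray:
    """Mass-weighted residue center-of-mass distances averaged over frames."""
    n = topology.n_residues
    masses = topology.masses
    acc = np.zeros((n, n), dtype=float)
    for frame in trajectory.frames:
        coms = np.empty((n, 3))
        for i in range(n):
            idx = topology.residue_atom_indices(i)
            w = masses[idx]
            coms[i] = (frame.coords[idx] * w[:, None]).sum(axis=0) / w.sum()
        diff = coms[:, None, :] - coms[None, :, :]
        acc += np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return acc / trajectory.n_frames


def build_residue_com_network(
    topology: Topology,
    trajectory: Trajectory,
    cutoff: float = 8.0,
    mode: str = "binary",
) -> Network:
    """Residue network from trajectory-averaged COM distances.

    Edge iff averaged distance ≤ ``cutoff`` (boundary inclusive); cost 1
    in ``binary`` mode, the averaged distance (Å) in ``weighted`` mode.
    """
    if mode not in ("binary", "weighted"):
        raise ValidationError(f"mode must be binary|weighted, got {mode!r}")
    dist = average_com_distances(topology, trajectory)
    costs = np.full_like(dist, np.inf)
    edge = dist <= cutoff
    np.fill_diagonal(edge, False)
    costs[edge] = 1.0 if mode == "binary" else dist[edge]
    return Network(
        costs=costs,
        labels=topology.residue_labels,
        directed=False,
        semantics="binary" if mode == "binary" else "com_distance",
        params={"cutoff_A": cutoff, "mode": mode, "n_frames": trajectory.n_frames},
    )


def build_atom_contact_network(
    topology: Topology, frame: Frame, atom_cutoff: float = 3.5
) -> Network:
    """Directed contact network from a single snapshot.

    c counts atom pairs strictly closer than ``atom_cutoff``; the edge
    cost A→B is I/c (source residue atom count over contact count), B→A
    is J/c. c = 0 means no edge in either direction.
    """
    n = topology.n_residues
    idx = [topology.residue_atom_indices(i) for i in range(n)]
    sizes = np.array([len(ix) for ix in idx])
    costs = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            diff = frame.coords[idx[i], None, :] - frame.coords[None, idx[j], :]
            d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
            c = int(np.count_nonzero(d < atom_cutoff))
            if c > 0:
                costs[i, j] = sizes[i] / c
                costs[j, i] = sizes[j] / c
    return Network(
        costs=costs,
        labels=topology.residue_labels,
        directed=True,
        semantics="inv_connectivity",
        params={"atom_cutoff_A": atom_cutoff, "frame_index": frame.frame_index},
    )


def build_energy_network(
    matrix: PairEnergyMatrix, min_energy: float = 1e-8
) -> Network:
    """Undirected network with cost 1/mean|E| per residue pair.

    Pairs with mean|E| ≤ ``min_energy`` (kcal/mol) get no edge; the small
    default floor only suppresses numerically-zero interactions whose
    inverse would be float noise.
    """
    values = matrix.values
    costs = np.full_like(values, np.inf)
    edge = values > min_energy
    np.fill_diagonal(edge, False)
    costs[edge] = 1.0 / values[edge]
    return Network(
        costs=costs,
        labels=list(matrix.labels),
        directed=False,
        semantics="inv_energy",
        params={
            "min_energy_kcal_mol": min_energy,
            "n_frames": matrix.n_frames,
            "energy_params": matrix.params.to_dict(),
        },
    )
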