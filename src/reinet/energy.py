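"""Pairwise residue nonbonded interaction energies.

For a residue pair (A, B) the interaction energy in one snapshot is the
sum over all atom pairs (i ∈ A, j ∈ B) of a 12-6 Lennard-Jones term

    E_LJ(r) = ε_ij [ (r_min,ij / r)^12 − 2 (r_min,ij / r)^6 ] · S(r)

and a Coulomb term  E_el(r) = C q_i q_j / (ε_r r)  under a cutoff scheme,
with C = 332.0636 kcal·Å/(mol·e²). S(r) is the CHARMM switching function
taking the van der Waals term smoothly from full strength at ``switch_on``
(default 10 Å) to zero at the ``cutoff`` (default 12 Å). Atom pairs one
or two bonds apart are excluded; pairs three bonds apart (1-4) use the
force field's 1-4 LJ overrides. Combining rules are CHARMM's:
ε_ij = sqrt(ε_i ε_j), r_min,ij = r_min,i/2 + r_min,j/2, unless an NBFIX
entry overrides the pair.

Electrostatics cannot use a lattice sum when the energy must decompose
per residue pair, so a cutoff scheme is applied instead; the default is
the shifted potential E·(1 − (r/r_c)²)², with plain switched and
truncated variants selectable. The scheme used is recorded in outputs.

The trajectory-level summary is the mean over snapshots of |E_AB|: the
sign of the interaction (attractive vs repulsive) is deliberately
discarded, only its strength is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import SingularityError, ValidationError
from .structure_io import Frame, Topology, Trajectory

#: Coulomb constant in kcal·Å/(mol·e²) (CHARMM/NAMD convention)
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class NonbondedParams:
    """Cutoff scheme for the pair-energy evaluation.

    ``elec_scheme`` is one of ``shifted`` (default), ``switched``,
    ``truncated``; ``scale14_elec`` multiplies electrostatics of 1-4
    pairs (1.0 = unscaled, the CHARMM convention).
    """

    cutoff: float = 12.0
    switch_on: float = 10.0
    coulomb_const: float = COULOMB_CONSTANT
    dielectric: float = 1.0
    elec_scheme: str = "shifted"
    scale14_elec: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.switch_on < self.cutoff:
            raise ValidationError(
                f"need 0 < switch_on < cutoff, got {self.switch_on}, {self.cutoff}"
            )
        if self.coulomb_const <= 0:
            raise ValidationError("coulomb_const must be positive")
        if self.elec_scheme not in ("shifted", "switched", "truncated"):
            raise ValidationError(f"unknown elec_scheme {self.elec_scheme!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def vdw_switch_factor(r, params: NonbondedParams):
    """CHARMM van der Waals switching function S(r).

    1 for r ≤ switch_on, 0 for r ≥ cutoff, and the cubic-in-r² polynomial
    (r_c² − r²)² (r_c² + 2r² − 3 r_on²) / (r_c² − r_on²)³ in between;
    C¹-continuous at both boundaries. Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    rc2, ron2 = params.cutoff**2, params.switch_on**2
    r2 = r * r
    mid = (rc2 - r2) ** 2 * (rc2 + 2.0 * r2 - 3.0 * ron2) / (rc2 - ron2) ** 3
    out = np.where(r2 <= ron2, 1.0, np.where(r2 >= rc2, 0.0, mid))
    return out if out.ndim else float(out)


def lj_pair_energy(eps_ij, rmin_ij, r, params: NonbondedParams):
    """Switched 12-6 Lennard-Jones energy (kcal/mol) for one atom pair.

    Minimum value −ε_ij at r = r_min,ij; zero crossing at r_min·2^(−1/6);
    identically zero at and beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularityError("Lennard-Jones energy requested at r <= 0")
    ratio6 = (np.asarray(rmin_ij, float) / r) ** 6
    raw = np.asarray(eps_ij, float) * (ratio6 * ratio6 - 2.0 * ratio6)
    out = np.where(r >= params.cutoff, 0.0, raw * vdw_switch_factor(r, params))
    return out if out.ndim else float(out)


def elec_pair_energy(qi, qj, r, params: NonbondedParams):
    """Coulomb energy (kcal/mol) for one atom pair under the cutoff scheme.

    shifted:   C q_i q_j/(ε_r r) · (1 − (r/r_c)²)²   (default)
    switched:  C q_i q_j/(ε_r r) · S(r)
    truncated: C q_i q_j/(ε_r r)
    All are identically zero at and beyond the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularityError("Coulomb energy requested at r <= 0")
    raw = params.coulomb_const * np.asarray(qi, float) * np.asarray(qj, float) / (
        params.dielectric * r
    )
    if params.elec_scheme == "shifted":
        raw = raw * (1.0 - (r / params.cutoff) ** 2) ** 2
    elif params.elec_scheme == "switched":
        raw = raw * vdw_switch_factor(r, params)
    out = np.where(r >= params.cutoff, 0.0, raw)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# residue-pair sums
# ---------------------------------------------------------------------------

def _pair_masks(
    topology: Topology, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (|A|,|B|) masks of excluded (1-2/1-3) and special 1-4 pairs."""
    shape = (idx_a.size, idx_b.size)
    excluded = np.zeros(shape, dtype=bool)
    special = np.zeros(shape, dtype=bool)
    if topology.excluded_pairs or topology.special14_pairs:
        pos_a = {int(a): i for i, a in enumerate(idx_a)}
        pos_b = {int(b): j for j, b in enumerate(idx_b)}
        for pairs, mask in ((topology.excluded_pairs, excluded), (topology.special14_pairs, special)):
            for p, q in pairs:
                if p in pos_a and q in pos_b:
                    mask[pos_a[p], pos_b[q]] = True
                if q in pos_a and p in pos_b:
                    mask[pos_a[q], pos_b[p]] = True
    return excluded, special


def residue_pair_energy(
    topology: Topology,
    frame: Frame,
    res_a: int,
    res_b: int,
    params: NonbondedParams | None = None,
) -> float:
    """Signed nonbonded interaction energy (kcal/mol) between two residues
    in one frame: LJ + electrostatics summed over all atom pairs, honoring
    exclusions, 1-4 overrides and NBFIX. Symmetric in (res_a, res_b)."""
    if params is None:
        params = NonbondedParams()
    if res_a == res_b:
        raise ValidationError("residue paired with itself")
    idx_a = topology.residue_atom_indices(res_a)
    idx_b = topology.residue_atom_indices(res_b)
    for idx in (idx_a, idx_b):
        if np.any(np.isnan(topology.charges[idx])) or np.any(
            np.isnan(topology.lj_eps[idx])
        ):
            bad = topology.residues[res_a if idx is idx_a else res_b].label
            raise ValidationError(
                f"residue {bad} has atoms without charges/LJ parameters; "
                "load a PSF + parameter table first"
            )

    diff = frame.coords[idx_a, None, :] - frame.coords[None, idx_b, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r == 0):
        raise SingularityError(
            f"coincident atoms between residues {res_a} and {res_b}"
        )
    excluded, special = _pair_masks(topology, idx_a, idx_b)

    eps_a, eps_b = topology.lj_eps[idx_a], topology.lj_eps[idx_b]
    rmh_a, rmh_b = topology.lj_rmin_half[idx_a], topology.lj_rmin_half[idx_b]
    eps_ij = np.sqrt(eps_a[:, None] * eps_b[None, :])
    rmin_ij = rmh_a[:, None] + rmh_b[None, :]

    # 1-4 LJ overrides: substitute per-type 1-4 parameters where provided
    if np.any(special) and topology.nb14_overrides:
        ov = topology.nb14_overrides
        eps14_a = np.array([ov.get(topology.atoms[i].type_name, (eps_a[k], rmh_a[k]))[0] for k, i in enumerate(idx_a)])
        rmh14_a = np.array([ov.get(topology.atoms[i].type_name, (eps_a[k], rmh_a[k]))[1] for k, i in enumerate(idx_a)])
        eps14_b = np.array([ov.get(topology.atoms[j].type_name, (eps_b[k], rmh_b[k]))[0] for k, j in enumerate(idx_b)])
        rmh14_b = np.array([ov.get(topology.atoms[j].type_name, (eps_b[k], rmh_b[k]))[1] for k, j in enumerate(idx_b)])
        eps14_ij = np.sqrt(eps14_a[:, None] * eps14_b[None, :])
        rmin14_ij = rmh14_a[:, None] + rmh14_b[None, :]
        eps_ij = np.where(special, eps14_ij, eps_ij)
        rmin_ij = np.where(special, rmin14_ij, rmin_ij)

    # NBFIX pair overrides supersede combining rules
    if topology.nbfix:
        for (t1, t2), (eps_fix, rmin_fix) in topology.nbfix.items():
            ta = np.array([topology.atoms[i].type_name for i in idx_a])
            tb = np.array([topology.atoms[j].type_name for j in idx_b])
            hit = ((ta[:, None] == t1) & (tb[None, :] == t2)) | (
                (ta[:, None] == t2) & (tb[None, :] == t1)
            )
            eps_ij = np.where(hit, eps_fix, eps_ij)
            rmin_ij = np.where(hit, rmin_fix, rmin_ij)

    e_lj = lj_pair_energy(eps_ij, rmin_ij, r, params)
    e_el = elec_pair_energy(
        topology.charges[idx_a][:, None], topology.charges[idx_b][None, :], r, params
    )
    if params.scale14_elec != 1.0 and np.any(special):
        e_el = np.where(special, params.scale14_elec * e_el, e_el)
    include = ~excluded
    return float(np.sum(np.where(include, e_lj + e_el, 0.0)))


def candidate_pairs(
    topology: Topology,
    trajectory: Trajectory,
    params: NonbondedParams | None = None,
    margin: float = 2.0,
) -> set[tuple[int, int]]:
    """Residue pairs whose minimum atom–atom distance comes within
    ``cutoff + margin`` in at least one retained frame.

    The margin keeps the prefilter superset-safe: a pair it drops has all
    atom pairs beyond the cutoff in every frame, hence exactly zero energy.
    """
    if params is None:
        params = NonbondedParams()
    limit = params.cutoff + margin
    n = topology.n_residues
    idx = [topology.residue_atom_indices(i) for i in range(n)]
    pairs: set[tuple[int, int]] = set()
    for frame in trajectory.frames:
        coords = frame.coords
        # residue bounding-sphere prescreen, then exact min distance
        centers = np.array([coords[ix].mean(axis=0) for ix in idx])
        radii = np.array(
            [np.max(np.linalg.norm(coords[ix] - centers[i], axis=1)) for i, ix in enumerate(idx)]
        )
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in pairs:
                    continue
                center_gap = np.linalg.norm(centers[i] - centers[j])
                if center_gap - radii[i] - radii[j] > limit:
                    continue
                diff = coords[idx[i], None, :] - coords[None, idx[j], :]
                dmin = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).min())
                if dmin <= limit:
                    pairs.add((i, j))
    return pairs


@dataclass
class PairEnergyMatrix:
    """N×N mean |E| (kcal/mol) over frames, with residue labels attached.

    Symmetric, zero diagonal, all entries ≥ 0; ``params`` records the
    cutoff scheme the energies were computed with.
    """

    values: np.ndarray
    labels: list[str]
    n_frames: int
    params: NonbondedParams = field(default_factory=NonbondedParams)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.labels):
            raise ValidationError("pair-energy matrix shape/label mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("pair-energy matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("pair-energy diagonal must be zero")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("mean |E| entries must be finite and >= 0")

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    def mean_offdiagonal(self, nonzero_only: bool = True) -> float:
        """Mean |E| over residue pairs (upper triangle); by default over
        interacting pairs only (entries > 0)."""
        iu = np.triu_indices(self.n_residues, k=1)
        vals = self.values[iu]
        if nonzero_only:
            vals = vals[vals > 0]
        return float(vals.mean()) if vals.size else 0.0

    # serialization ---------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    def to_long_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for i in range(self.n_residues):
            for j in range(i + 1, self.n_residues):
                if self.values[i, j] > 0:
                    rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        pd.DataFrame(
            rows, columns=["resA", "resB", "mean_abs_energy_kcal_mol"]
        ).to_csv(path, index=False)

    def params_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"params": self.params.to_dict(), "n_frames": self.n_frames},
                indent=2,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "PairEnergyMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        params, n_frames = NonbondedParams(), 1
        if sidecar is not None and Path(sidecar).exists():
            meta = json.loads(Path(sidecar).read_text())
            params = NonbondedParams(**meta["params"])
            n_frames = int(meta["n_frames"])
        return cls(
            values=df.to_numpy(float),
            labels=[str(c) for c in df.columns],
            n_frames=n_frames,
            params=params,
        )


def pair_energy_matrix(
    topology: Topology,
    trajectory: Trajectory,
    params: NonbondedParams | None = None,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> PairEnergyMatrix:
    """Mean absolute residue-pair interaction energy over all frames.

    Entry (A,B) = (1/n_frames) Σ_frames |E_AB(frame)|. Pairs outside the
    ``candidate_pairs`` prefilter are zero by construction (their energy is
    zero in every frame).
    """
    if params is None:
        params = NonbondedParams()
    if pairs is None:
        pairs = candidate_pairs(topology, trajectory, params)
    n = topology.n_residues
    acc = np.zeros((n, n), dtype=float)
    for frame in trajectory.frames:
        for i, j in pairs:
            e = residue_pair_energy(topology, frame, i, j, params)
            acc[i, j] += abs(e)
    acc /= trajectory.n_frames
    acc = acc + acc.T
    return PairEnergyMatrix(
        values=acc,
        labels=topology.residue_labels,
        n_frames=trajectory.n_frames,
        params=params,
    )
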