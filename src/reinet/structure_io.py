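"""Structures, topologies, trajectories and sequences.

This module is the file-format boundary of the package. Heavy lifting
(PDB/PSF/XYZ/DCD parsing, PDB writing) is delegated to MDAnalysis; what
is added here is the package's own light data model — :class:`Atom`,
:class:`Residue`, :class:`Topology`, :class:`Frame`, :class:`Trajectory` —
plus a parser for CHARMM-style nonbonded parameter tables and the
bond-graph exclusion builder (1-2/1-3 pairs excluded from nonbonded sums,
1-4 pairs flagged for special treatment).

Units: coordinates and distances in Å, charges in elementary charges,
Lennard-Jones well depths in kcal/mol, masses in amu.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    ParameterLookupError,
    ParseError,
    ShapeError,
    ValidationError,
)

# three-letter -> one-letter amino acid codes; anything absent maps to 'X'
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common CHARMM histidine tautomer names
    "HSD": "H", "HSE": "H", "HSP": "H",
}

#: opt-in mapping for modified residues (disabled by default so that no
#: silent chemistry assumption is made; pass to :func:`extract_sequence`)
MODIFIED_RESIDUE_MAP: dict[str, str] = {"MSE": "M", "SEC": "U", "PYL": "O"}

_BFACTOR_SENTINEL = 999.99


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom with its nonbonded parameters.

    ``lj_eps`` is the potential-well depth ε (kcal/mol, stored positive)
    and ``lj_rmin_half`` is r_min/2 (Å); the pairwise equilibrium distance
    is r_min(i,j) = lj_rmin_half(i) + lj_rmin_half(j). ``charge`` is q in
    elementary charges. Parameters not yet assigned are NaN.
    """

    atom_id: int
    name: str
    type_name: str
    residue_key: str
    charge: float
    lj_eps: float
    lj_rmin_half: float
    mass: float

    def has_parameters(self) -> bool:
        return not (
            np.isnan(self.charge)
            or np.isnan(self.lj_eps)
            or np.isnan(self.lj_rmin_half)
        )


@dataclass(frozen=True)
class Residue:
    """A residue: 0-based ordinal ``index``, verbatim author ``label``
    (chain:number+insertion-code, e.g. ``A:57``), 3-letter ``name`` and the
    ordered ``atom_ids`` it owns."""

    index: int
    label: str
    name: str
    atom_ids: tuple[int, ...]


@dataclass
class Topology:
    """Atoms grouped into residues plus the bond graph and its exclusions.

    ``excluded_pairs`` holds 1-2 and 1-3 atom pairs (as sorted tuples);
    ``special14_pairs`` holds 1-4 pairs. ``nb14_overrides`` maps an atom
    type to its (eps, rmin/2) pair used for 1-4 Lennard-Jones terms.
    ``nbfix`` maps a sorted type pair to an explicit (eps, rmin_full)
    override of the combining rules.
    """

    atoms: list[Atom]
    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    excluded_pairs: frozenset[tuple[int, int]] = frozenset()
    special14_pairs: frozenset[tuple[int, int]] = frozenset()
    nb14_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    nbfix: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    source_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise EmptyInputError("topology contains no residues")
        seen: set[int] = set()
        for res in self.residues:
            if not res.atom_ids:
                raise ValidationError(f"residue {res.label} owns no atoms")
            overlap = seen.intersection(res.atom_ids)
            if overlap:
                raise ValidationError(f"atoms {sorted(overlap)} claimed twice")
            seen.update(res.atom_ids)
        for a, b in self.bonds:
            if a >= len(self.atoms) or b >= len(self.atoms):
                raise ValidationError(f"bond ({a},{b}) references unknown atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def residue_labels(self) -> list[str]:
        return [r.label for r in self.residues]

    # cached per-atom arrays -------------------------------------------------
    def _array(self, attr: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_arrays", {})
        if attr not in cache:
            cache[attr] = np.array([getattr(a, attr) for a in self.atoms], float)
        return cache[attr]

    @property
    def charges(self) -> np.ndarray:
        return self._array("charge")

    @property
    def lj_eps(self) -> np.ndarray:
        return self._array("lj_eps")

    @property
    def lj_rmin_half(self) -> np.ndarray:
        return self._array("lj_rmin_half")

    @property
    def masses(self) -> np.ndarray:
        return self._array("mass")

    def residue_atom_indices(self, index: int) -> np.ndarray:
        return np.asarray(self.residues[index].atom_ids, dtype=int)

    def residue_by_label(self, label: str) -> Residue:
        for res in self.residues:
            if res.label == label:
                return res
        raise ValidationError(f"no residue labelled {label!r}")


@dataclass
class Frame:
    """Coordinates (Å) of every atom at one trajectory snapshot."""

    frame_index: int
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (n,3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates in frame {self.frame_index}")


@dataclass
class Trajectory:
    """An ordered series of frames over one topology."""

    topology: Topology
    frames: list[Frame]
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("trajectory has no frames")
        n = self.topology.n_atoms
        for fr in self.frames:
            if fr.coords.shape[0] != n:
                raise ShapeError(
                    f"frame {fr.frame_index} has {fr.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _mda():
    """Import MDAnalysis lazily (it is slow to import and noisy)."""
    import logging

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    logging.getLogger("MDAnalysis").setLevel(logging.WARNING)
    return mda


def _residue_key(segid: str, chain: str, resid: int, icode: str) -> str:
    ch = (chain or segid or "").strip() or "_"
    return f"{ch}:{resid}{(icode or '').strip()}"


def _group_residues(
    resnames: Sequence[str],
    keys: Sequence[str],
    atom_resindex: Sequence[int],
) -> list[Residue]:
    residues: list[Residue] = []
    for ordinal in range(len(resnames)):
        atom_ids = tuple(int(i) for i in np.flatnonzero(np.asarray(atom_resindex) == ordinal))
        label = keys[ordinal]
        residues.append(Residue(ordinal, label, resnames[ordinal], atom_ids))
    return residues


def build_exclusions(
    n_atoms: int, bonds: Iterable[tuple[int, int]]
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Classify atom pairs by shortest bond-path length.

    Pairs one or two bonds apart (1-2, 1-3) are excluded from nonbonded
    sums; pairs exactly three bonds apart (1-4) get special treatment.
    A pair reachable both ways is classified by its shortest path.
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    excluded: set[tuple[int, int]] = set()
    special: set[tuple[int, int]] = set()
    for start in range(n_atoms):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            if dist[cur] == 3:
                continue
            for nxt in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    queue.append(nxt)
        for other, d in dist.items():
            if other <= start:
                continue
            if d in (1, 2):
                excluded.add((start, other))
            elif d == 3:
                special.add((start, other))
    special -= excluded
    return frozenset(excluded), frozenset(special)


# ---------------------------------------------------------------------------
# CHARMM-style nonbonded parameter tables
# ---------------------------------------------------------------------------

@dataclass
class ParameterTable:
    """Per-atom-type nonbonded parameters.

    ``entries`` maps atom type -> (eps, rmin_half); ``entries14`` holds the
    optional 1-4 overrides; ``nbfix`` maps sorted type pairs to explicit
    (eps, rmin_full) values superseding the combining rules.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    entries14: dict[str, tuple[float, float]] = field(default_factory=dict)
    nbfix: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


def read_parameter_table(path: str | Path) -> ParameterTable:
    """Parse a CHARMM-style nonbonded parameter table.

    Two dialects are accepted per atom-type line:

    * full CHARMM: ``TYPE ignored -eps rmin/2 [ignored -eps14 rmin14/2]``
      (eps stored negative by CHARMM convention; absolute value is taken);
    * simplified:  ``TYPE eps rmin/2``.

    An optional ``NBFIX`` section holds ``TYPE1 TYPE2 -eps rmin`` pair
    overrides (rmin is the full equilibrium distance). ``!`` and ``*``
    start comments; ``NONBONDED``/``cutnb``/``END`` lines are ignored.
    """
    table = ParameterTable()
    section = "NONBONDED"
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("!")[0].strip()
        if not line or line.startswith("*"):
            continue
        upper = line.upper()
        if upper.startswith("NONBONDED") or upper.startswith("CUTNB"):
            section = "NONBONDED"
            continue
        if upper.startswith("NBFIX"):
            section = "NBFIX"
            continue
        if upper == "END":
            break
        tokens = line.split()
        try:
            if section == "NBFIX":
                t1, t2 = tokens[0], tokens[1]
                eps, rmin = abs(float(tokens[2])), float(tokens[3])
                table.nbfix[tuple(sorted((t1, t2)))] = (eps, rmin)
                continue
            type_name = tokens[0]
            nums = [float(t) for t in tokens[1:]]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: cannot parse parameter line {raw!r}") from exc
        if len(nums) == 2:
            table.entries[type_name] = (abs(nums[0]), nums[1])
        elif len(nums) >= 3:
            table.entries[type_name] = (abs(nums[1]), nums[2])
            if len(nums) >= 6:
                table.entries14[type_name] = (abs(nums[4]), nums[5])
        else:
            raise ParseError(f"{path}:{lineno}: expected 2+ numeric columns in {raw!r}")
    return table


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: str | Path) -> None:
    """Cheap pre-scan so malformed ATOM records fail with a line number."""
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParseError(f"{path}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparseable coordinates in {line!r}"
                ) from exc


def read_structure(
    path: str | Path, chain: str | None = None
) -> tuple[Topology, Frame]:
    """Read a PDB file into a parameter-less topology skeleton plus one frame.

    Only protein residues are kept (waters/ligands dropped); author residue
    numbers and insertion codes are preserved verbatim in the labels.
    ``chain`` restricts to one chain identifier. Charges and LJ parameters
    are NaN until :func:`read_topology` supplies them.
    """
    _validate_pdb_text(path)
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
        protein = universe.select_atoms("protein")
        if chain is not None:
            protein = protein.select_atoms(f"chainID {chain}")
    if len(protein) == 0:
        raise EmptyInputError(f"{path}: no protein residues" + (f" in chain {chain}" if chain else ""))

    atoms: list[Atom] = []
    keys: list[str] = []
    resnames: list[str] = []
    atom_resindex: list[int] = []
    for ordinal, res in enumerate(protein.residues):
        icode = getattr(res, "icode", "") or ""
        chain_id = res.atoms.chainIDs[0] if hasattr(res.atoms, "chainIDs") else ""
        key = _residue_key(res.segid, chain_id, int(res.resid), icode)
        keys.append(key)
        resnames.append(str(res.resname))
        for atom in res.atoms:
            atoms.append(
                Atom(
                    atom_id=len(atoms),
                    name=str(atom.name),
                    type_name=str(getattr(atom, "type", atom.name)),
                    residue_key=key,
                    charge=float("nan"),
                    lj_eps=float("nan"),
                    lj_rmin_half=float("nan"),
                    mass=float(atom.mass) if atom.mass > 0 else 1.0,
                )
            )
            atom_resindex.append(ordinal)

    residues = _group_residues(resnames, keys, atom_resindex)
    topology = Topology(atoms=atoms, residues=residues, source_path=str(path))
    coords = protein.positions.astype(float)
    return topology, Frame(frame_index=0, coords=coords)


def read_topology(
    psf_path: str | Path,
    param_source: str | Path,
    chain: str | None = None,
) -> Topology:
    """Read a PSF (X-PLOR/NAMD dialect) and attach nonbonded parameters.

    Every atom receives its charge and mass from the PSF and its
    Lennard-Jones (eps, r_min/2) from the parameter table keyed by atom
    type; 1-2/1-3 exclusions and 1-4 special pairs are derived from the
    PSF bond list. An atom type absent from the table raises
    :class:`ParameterLookupError` naming the type.
    """
    mda = _mda()
    table = read_parameter_table(param_source)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(psf_path))
        group = universe.atoms
        if chain is not None:
            group = group.select_atoms(f"segid {chain}")
    if len(group) == 0:
        raise EmptyInputError(f"{psf_path}: no atoms" + (f" in segment {chain}" if chain else ""))

    atoms: list[Atom] = []
    keys: list[str] = []
    resnames: list[str] = []
    atom_resindex: list[int] = []
    index_of = {atom.ix: i for i, atom in enumerate(group)}
    for ordinal, res in enumerate(group.residues):
        key = _residue_key(str(res.segid), "", int(res.resid), "")
        keys.append(key)
        resnames.append(str(res.resname))
        for atom in res.atoms:
            type_name = str(atom.type)
            if type_name not in table.entries:
                raise ParameterLookupError(
                    f"atom type {type_name!r} (atom {atom.ix + 1}, {atom.name}) "
                    f"missing from parameter table {param_source}"
                )
            eps, rmin_half = table.entries[type_name]
            atoms.append(
                Atom(
                    atom_id=len(atoms),
                    name=str(atom.name),
                    type_name=type_name,
                    residue_key=key,
                    charge=float(atom.charge),
                    lj_eps=eps,
                    lj_rmin_half=rmin_half,
                    mass=float(atom.mass),
                )
            )
            atom_resindex.append(ordinal)

    bonds = []
    if hasattr(universe, "bonds"):
        for a_ix, b_ix in universe.bonds.indices:
            if a_ix in index_of and b_ix in index_of:
                bonds.append((index_of[int(a_ix)], index_of[int(b_ix)]))
    excluded, special = build_exclusions(len(atoms), bonds)
    residues = _group_residues(resnames, keys, atom_resindex)
    return Topology(
        atoms=atoms,
        residues=residues,
        bonds=bonds,
        excluded_pairs=excluded,
        special14_pairs=special,
        nb14_overrides=dict(table.entries14),
        nbfix=dict(table.nbfix),
        source_path=str(psf_path),
    )


def read_trajectory(
    topology: Topology, path: str | Path, stride: int = 1
) -> Trajectory:
    """Read trajectory frames (multi-frame XYZ, DCD, or any coordinate
    format MDAnalysis recognises), keeping every ``stride``-th frame."""
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology.source_path and Path(topology.source_path).suffix.lower() in (".psf", ".pdb"):
                universe = mda.Universe(topology.source_path, str(path))
            else:
                universe = mda.Universe(str(path))
    except ValueError as exc:
        if "number of atoms" in str(exc):
            raise ShapeError(f"{path}: {exc}") from exc
        raise ParseError(f"{path}: {exc}") from exc
    if len(universe.atoms) != topology.n_atoms:
        raise ShapeError(
            f"{path}: {len(universe.atoms)} atoms per frame, "
            f"topology has {topology.n_atoms}"
        )
    frames = [
        Frame(frame_index=ts.frame, coords=universe.atoms.positions.astype(float))
        for ts in universe.trajectory[::stride]
    ]
    return Trajectory(topology=topology, frames=frames, stride=stride)


# ---------------------------------------------------------------------------
# sequence + profile-annotated structure output
# ---------------------------------------------------------------------------

def extract_sequence(
    topology: Topology, modified_map: Mapping[str, str] | None = None
) -> str:
    """One-letter sequence over the topology's residues, in ordinal order.

    Non-standard residues map to ``'X'`` unless ``modified_map`` (e.g.
    :data:`MODIFIED_RESIDUE_MAP` for MSE→M) supplies a letter.
    """
    out = []
    for res in topology.residues:
        name = res.name.upper()
        if modified_map and name in modified_map:
            out.append(modified_map[name])
        else:
            out.append(THREE_TO_ONE.get(name, "X"))
    return "".join(out)


def write_fasta(sequence: str, identifier: str, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write([SeqRecord(Seq(sequence), id=identifier, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_profile_structure(
    frame: Frame,
    topology: Topology,
    profile_values: Sequence[float],
    path: str | Path,
) -> None:
    """Write a PDB whose B-factor column carries each residue's profile value.

    Values are clamped to the fixed-width column range [-99.99, 999.99];
    non-finite values (isolated residues) become the 999.99 sentinel with a
    warning, so unreachable residues stand out in structure viewers.
    """
    values = np.asarray(list(profile_values), dtype=float)
    if values.shape[0] != topology.n_residues:
        raise ValidationError(
            f"profile length {values.shape[0]} != {topology.n_residues} residues"
        )
    if not np.all(np.isfinite(values)):
        warnings.warn(
            "non-finite profile values written as sentinel 999.99", stacklevel=2
        )
        values = np.where(np.isfinite(values), values, _BFACTOR_SENTINEL)
    values = np.clip(values, -99.99, 999.99)

    mda = _mda()
    n_atoms, n_res = topology.n_atoms, topology.n_residues
    atom_resindex = np.empty(n_atoms, dtype=int)
    for res in topology.residues:
        atom_resindex[list(res.atom_ids)] = res.index
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(
            n_atoms, n_residues=n_res, atom_resindex=atom_resindex, trajectory=True
        )
        universe.add_TopologyAttr("names", [a.name for a in topology.atoms])
        universe.add_TopologyAttr("resnames", [r.name for r in topology.residues])
        universe.add_TopologyAttr(
            "resids", [_label_number(r.label) for r in topology.residues]
        )
        universe.add_TopologyAttr("tempfactors", values[atom_resindex])
        universe.atoms.positions = frame.coords
        universe.atoms.write(str(path))


def _label_number(label: str) -> int:
    """Best-effort numeric part of a residue label for the PDB resid field."""
    tail = label.split(":", 1)[-1]
    digits = "".join(ch for ch in tail if ch.isdigit() or ch == "-")
    try:
        return int(digits)
    except ValueError:
        return 0
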