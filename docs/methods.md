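# Methods

## Model

`reinet` treats a protein as a weighted graph over residues and asks which
residues are cheap to reach from everywhere else. The physical core is the
pairwise nonbonded interaction energy between residues A and B in a single
trajectory snapshot:

- **Lennard-Jones**: ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶], with the CHARMM
  combining rules ε_ij = √(ε_i ε_j) and r_min,ij = r_min,i/2 + r_min,j/2,
  multiplied by the CHARMM switching polynomial
  S(r) = (r_c²−r²)²(r_c²+2r²−3r_on²)/(r_c²−r_on²)³ between r_on = 10 Å and
  r_c = 12 Å (S ≡ 1 below r_on, ≡ 0 above r_c; C¹-continuous at both ends).
- **Electrostatics**: C·q_i q_j/(ε_r r) with C = 332.0636 kcal·Å/(mol·e²),
  under a cutoff scheme (below).
- **Exclusions**: atom pairs one or two bonds apart contribute nothing;
  pairs exactly three bonds apart (1-4) use the force field's 1-4
  Lennard-Jones override parameters where the parameter table provides them,
  and their electrostatics can be scaled (default scale 1.0, the CHARMM
  convention). Bond-path classes come from a breadth-first search of the
  bond graph; a pair reachable at several depths takes its shortest path.
  NBFIX entries override the combining rules for specific type pairs.

The trajectory-level statistic per pair is the mean over snapshots of the
*absolute* energy. Discarding the sign is deliberate: a strong repulsive
contact constrains the structure as much as a strong attractive one, and it
keeps the derived edge costs positive.

### Why a cutoff scheme for the electrostatics

Lattice-sum (PME) electrostatics cannot be decomposed into per-residue-pair
contributions, so pair energies use a real-space cutoff scheme. The default
is the shifted potential, E·(1 − (r/r_c)²)², which goes smoothly to zero at
the cutoff and matches common NAMD cutoff practice; plain `switched`
(multiplying by S(r)) and `truncated` variants are selectable. The scheme in
force is recorded in every output's JSON sidecar, so downstream numbers are
always attributable to a stated convention. Because a solvated simulation
box is larger than the protein, no periodic minimum image is applied to
protein-internal pairs at ≤ 12 Å.

### Assumptions

- Only protein residues enter the analysis; solvent and ions are assumed
  stripped from the trajectory before evaluation.
- The topology's charges and the parameter table's (ε, r_min/2) per atom
  type are taken as given; bonded, angular, dihedral and CMAP terms are out
  of scope since only *inter*-residue nonbonded interactions enter the
  network.
- Multi-chain selection is the user's responsibility (a `chain`/segment
  argument on the readers); no chain is chosen silently.

## Networks

Three constructions over the same residue nodes, each tagged with a
`semantics` label so profiles from different cost units cannot be mixed:

1. **Residue COM** (undirected): mass-weighted centers of mass per residue
   per frame; pair distance averaged over frames; edge iff the average is
   ≤ 8 Å (boundary inclusive). Costs are 1 (binary variant) or the average
   distance in Å (weighted variant). Averaging precedes thresholding.
2. **Atom contact** (directed, final snapshot only): c counts atom pairs
   strictly closer than 3.5 Å; connectivity A→B is c/I with I the atom
   count of the *source* residue, so cost(A→B) = I/c and cost(B→A) = J/c.
   Dividing by the source residue's size is a documented normalization
   choice; both directions recover the same raw count c, and equal-sized
   residues get symmetric costs. Hydrogens count like any other atom.
3. **Energy** (undirected): cost = 1/mean|E|. Pairs with mean|E| below a
   floor of 1e-8 kcal/mol get no edge — the floor only suppresses
   numerically-zero interactions whose inverse would be float noise, it is
   not a physical threshold. No distance cutoff enters beyond the one inside
   the energy terms themselves.

A prefilter skips residue pairs whose minimum atom-atom distance stays
beyond cutoff + 2 Å in every retained frame; the 2 Å margin makes the
prefilter a pure cost optimization (a skipped pair has exactly zero energy
in every frame), never a result change.

## Shortest-path analysis

All-pairs shortest paths are computed with Dijkstra's algorithm (via
scipy's sparse-graph routines; edge costs are validated strictly positive).
A residue's profile value is the mean of its column — paths *into* the
residue, which differs from the row mean only for the directed contact
network; a flag exposes row averaging. Self-distances are excluded from the
mean. Unreachable pairs are excluded and counted per residue; a residue
unreachable from everywhere gets +∞ with a warning, and if more than 10% of
all ordered pairs are unreachable the profile raises instead — the energy
networks this package targets are dense, so heavy fragmentation signals a
broken input rather than a sparse protein.

Normalization divides by the mean of the finite values (profile mean = 1);
min-max mapping onto [0, 1] is available but degenerate (constant) profiles
are refused. The **peak/mean ratio** — a residue's value over the profile
mean — is invariant both to uniform edge-cost scaling and to
mean-normalization, which is what makes it comparable across the three
network types despite their different units.

## Cross-structure comparison

Homologous structures with different residue counts are paired by
Needleman–Wunsch global alignment with affine gaps (Biopython's
`PairwiseAligner`; defaults BLOSUM62, gap open 10, gap extend 0.5 — a
widely used global-alignment default, fully configurable and echoed in the
output). Tie-breaking among co-optimal alignments is fixed by the aligner's
deterministic enumeration order. Only aligned pairs are compared —
|Δ normalized value| per column, gap columns reported empty — and the
comparison refuses raw (unnormalized) profiles or profiles from different
network semantics, to prevent unit mixing. The mean absolute difference is
taken over exactly the paired columns.

## Synthetic systems

The fixture generators exist so every pipeline stage is testable without
external data, and they write the *production* formats (PDB, X-PLOR/NAMD
PSF, CHARMM-style parameter table, multi-frame XYZ), so the readers are
exercised end to end.

- **Toy systems** (`make_toy_system`): 1–8-atom residues as short rods,
  arranged in a bonded linear chain (producing genuine inter-residue
  1-2/1-3/1-4 pairs), a compact globule, or a fixed-separation two-body
  layout. Charges ±0.4 e, well depths 0.02–0.2 kcal/mol, r_min/2 1–2 Å —
  ranges typical of heavy-atom force-field parameters. Every other atom
  type carries 1-4 override columns so that code path always runs. Frames
  add isotropic Gaussian jitter (default 0.1 Å); no dynamics is claimed.
  Geometries placing non-excluded atom pairs closer than 1.6 Å are
  regenerated (same seed lineage, bounded retries, globule radius inflating
  per retry): real structures keep nonbonded atoms near van der Waals
  contact, and sub-Å contacts would put r⁻¹² energies at meaningless
  magnitudes. Overlaps below 0.5 Å are rejected unconditionally. Each
  system ships a JSON sidecar holding per-frame pair energies from a scalar
  brute-force oracle evaluated on the files *as read back*, making
  sidecar-vs-pipeline agreement a float-precision statement. Under these
  conditions toy mean |E| per interacting pair sits near 1 kcal/mol, the
  same order as real protein residue pairs.
- **Hub systems** (`make_hub_system`): a compact in-memory globule where
  designated residues' charges are calibrated (linearly — the Coulomb term
  dominates by construction, ε = 10⁻³ kcal/mol) until every hub pair's
  mean|E| is at least the strength factor times the largest non-hub pair
  energy. With factor 10 the hub must surface as the profile minimum — the
  synthetic analog of an active-site residue. For a 10-residue single-hub
  system in this strong-hub limit the hub's peak/mean ratio has the closed
  form 5/9 ≈ 0.556, independent of the drawn charges.
- **Random graphs** (`make_random_graph`): seeded weighted Erdős–Rényi
  graphs for cross-checking Dijkstra against an independent Floyd–Warshall.

What passing tests on these fixtures do *not* show: behavior on real
force-field chemistry (aromatics, salt bridges, waters), conformational
dynamics beyond Gaussian jitter, or the statistical stability of profiles
over long trajectories. They do show that every formula, threshold,
exclusion rule and graph operation is implemented exactly.

## Numerical choices

- Energies in kcal/mol, distances in Å, charges in elementary charges.
- All array math in float64; coordinates/charges read from text formats are
  promoted from the reader's float32.
- Energy terms are *identically* zero at and beyond the cutoff (enforced by
  masking, not left to the switch polynomial's rounding).
- The LJ and Coulomb primitives raise on r ≤ 0 rather than returning ±inf.
- Problem sizes in the test suite and acceptance script (≤ 50-atom
  fixtures, ≤ 50-node graphs, 100 hub replicates, 20 oracle fixtures) keep
  the full verification run in seconds while covering every code path; the
  pipeline itself scales to real proteins, where the N²/2 pair-energy loop
  dominates cost and the candidate-pair prefilter prunes it.
- Determinism: a fixture seed reproduces files byte-for-byte; identical
  CLI inputs give byte-identical numeric outputs.

## Known limitations

- The per-pair electrostatic cutoff scheme is a stated substitution for the
  lattice-sum electrostatics of production MD; absolute pair energies
  therefore differ from any PME-consistent decomposition, though relative
  network structure is robust to the scheme choice (it is configurable).
- The atom-contact normalization (divide by source residue's atom count) is
  one of several defensible conventions; it is recorded in every output.
- B-factor annotation clamps values to the PDB fixed-width column range
  [−99.99, 999.99] and writes 999.99 for non-finite values.
- CIF/mmCIF, multi-model NMR ensembles beyond the first model, and bonded
  or CMAP energy terms are out of scope.
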