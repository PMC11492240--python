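"""Pair-energy terms, cutoff/switching behavior, and oracle equivalence."""

import numpy as np
import pytest

from reinet import (
    FixtureSpec,
    NonbondedParams,
    SingularityError,
    ValidationError,
    candidate_pairs,
    elec_pair_energy,
    lj_pair_energy,
    make_toy_system,
    pair_energy_matrix,
    residue_pair_energy,
    vdw_switch_factor,
)
from conftest import point_system
from _oracles import naive_mean_abs_matrix, naive_residue_pair_energy

PARAMS = NonbondedParams()


class TestAnalyticValues:
    def test_lj_minimum_is_minus_eps(self):
        assert lj_pair_energy(0.1, 3.0, 3.0, PARAMS) == pytest.approx(-0.1, abs=1e-14)

    def test_lj_zero_crossing(self):
        r0 = 3.0 * 2 ** (-1 / 6)
        assert lj_pair_energy(0.1, 3.0, r0, PARAMS) == pytest.approx(0.0, abs=1e-14)

    def test_lj_hand_value_inside_switch(self):
        # 0.1 * ((3/4)^12 - 2 (3/4)^6), switch factor 1 below 10 Å
        assert lj_pair_energy(0.1, 3.0, 4.0, PARAMS) == pytest.approx(-0.03242807, abs=1e-7)

    @pytest.mark.parametrize("r,expected", [(9.0, 1.0), (10.0, 1.0), (12.0, 0.0), (13.0, 0.0)])
    def test_switch_plateaus(self, r, expected):
        assert vdw_switch_factor(r, PARAMS) == expected

    def test_switch_hand_value_at_11(self):
        # (144-121)^2 (144+242-300) / (144-100)^3
        assert vdw_switch_factor(11.0, PARAMS) == pytest.approx(529 * 86 / 44**3, abs=1e-12)
        assert vdw_switch_factor(11.0, PARAMS) == pytest.approx(0.5341, abs=1e-4)

    def test_elec_shifted_hand_value(self):
        assert elec_pair_energy(1.0, 1.0, 10.0, PARAMS) == pytest.approx(
            332.0636 / 10 * (1 - (10 / 12) ** 2) ** 2, abs=1e-12
        )
        assert elec_pair_energy(1.0, 1.0, 10.0, PARAMS) == pytest.approx(3.100, abs=1e-3)

    def test_elec_zero_charge_and_beyond_cutoff(self):
        assert elec_pair_energy(0.0, 1.0, 5.0, PARAMS) == 0.0
        assert elec_pair_energy(1.0, 1.0, 13.0, PARAMS) == 0.0
        assert lj_pair_energy(0.2, 2.0, 12.0, PARAMS) == 0.0

    def test_singularity_at_zero_distance(self):
        with pytest.raises(SingularityError):
            lj_pair_energy(0.1, 3.0, 0.0, PARAMS)
        with pytest.raises(SingularityError):
            elec_pair_energy(1.0, 1.0, 0.0, PARAMS)

    @pytest.mark.parametrize("scheme", ["shifted", "switched", "truncated"])
    def test_all_schemes_vanish_at_cutoff(self, scheme):
        p = NonbondedParams(elec_scheme=scheme)
        assert elec_pair_energy(1.0, -1.0, 12.0, p) == 0.0

    def test_continuity_at_switch_and_cutoff(self):
        h = 1e-7
        for r0 in (10.0, 12.0):
            below = lj_pair_energy(0.1, 3.0, r0 - h, PARAMS)
            above = lj_pair_energy(0.1, 3.0, r0 + h, PARAMS)
            assert abs(below - above) < 1e-9
        # shifted electrostatics is also continuous at the cutoff
        assert abs(elec_pair_energy(1, 1, 12 - h, PARAMS)) < 1e-9

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            NonbondedParams(cutoff=10.0, switch_on=12.0)
        with pytest.raises(ValidationError):
            NonbondedParams(elec_scheme="pme")


class TestResiduePairEnergy:
    def test_two_point_charges_hand_sum(self):
        # single-atom residues 5 Å apart, charges only
        topo, traj = point_system(
            [[(0.0, 0.0, 0.0)], [(5.0, 0.0, 0.0)]], charges=[0.3, -0.2]
        )
        expected = 332.0636 * 0.3 * -0.2 / 5.0 * (1 - (5 / 12) ** 2) ** 2
        assert residue_pair_energy(topo, traj.frames[0], 0, 1, PARAMS) == pytest.approx(
            expected, abs=1e-12
        )

    def test_beyond_cutoff_is_zero(self):
        topo, traj = point_system([[(0, 0, 0)], [(30, 0, 0)]], charges=[0.5, 0.5], eps=0.1)
        assert residue_pair_energy(topo, traj.frames[0], 0, 1, PARAMS) == 0.0

    def test_symmetric_in_pair_order(self, toy_files):
        _, topo, traj, _ = toy_files
        e_ab = residue_pair_energy(topo, traj.frames[0], 0, 2, PARAMS)
        e_ba = residue_pair_energy(topo, traj.frames[0], 2, 0, PARAMS)
        assert e_ab == pytest.approx(e_ba, abs=1e-12)

    def test_bonded_residues_honor_exclusions(self, toy_files):
        # adjacent residues in the chain fixture share 1-2/1-3/1-4 pairs
        _, topo, traj, _ = toy_files
        inter = [
            (i, j)
            for (i, j) in topo.excluded_pairs | topo.special14_pairs
            if topo.atoms[i].residue_key != topo.atoms[j].residue_key
        ]
        assert inter, "chain fixture must have inter-residue bonded pairs"
        for frame in traj.frames:
            got = residue_pair_energy(topo, frame, 0, 1, PARAMS)
            want = naive_residue_pair_energy(topo, frame.coords, 0, 1, PARAMS)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_parameters_rejected(self, tmp_path):
        from reinet import read_structure, FixtureSpec, make_toy_system

        make_toy_system(FixtureSpec(n_residues=2, seed=1), tmp_path)
        skeleton, frame = read_structure(tmp_path / "toy.pdb")
        with pytest.raises(ValidationError, match="parameters"):
            residue_pair_energy(skeleton, frame, 0, 1, PARAMS)


class TestCandidatePairs:
    def test_collinear_geometry(self):
        topo, traj = point_system([[(0, 0, 0)], [(5, 0, 0)], [(50, 0, 0)]])
        assert candidate_pairs(topo, traj, PARAMS) == {(0, 1)}

    def test_all_far_apart(self):
        topo, traj = point_system([[(0, 0, 0)], [(40, 0, 0)], [(80, 0, 0)]])
        assert candidate_pairs(topo, traj, PARAMS) == set()

    def test_matches_brute_force_min_distance(self, toy_files):
        _, topo, traj, _ = toy_files
        got = candidate_pairs(topo, traj, PARAMS, margin=2.0)
        limit = PARAMS.cutoff + 2.0
        brute = set()
        within_cutoff = set()
        for frame in traj.frames:
            for i in range(topo.n_residues):
                for j in range(i + 1, topo.n_residues):
                    d = min(
                        np.linalg.norm(frame.coords[a] - frame.coords[b])
                        for a in topo.residues[i].atom_ids
                        for b in topo.residues[j].atom_ids
                    )
                    if d <= limit:
                        brute.add((i, j))
                    if d <= PARAMS.cutoff:
                        within_cutoff.add((i, j))
        assert got == brute
        assert got >= within_cutoff  # superset-safe


class TestPairEnergyMatrix:
    def test_single_frame_is_abs_energy(self):
        topo, traj = point_system([[(0, 0, 0)], [(4, 0, 0)]], charges=[0.3, 0.3])
        m = pair_energy_matrix(topo, traj, PARAMS)
        e = residue_pair_energy(topo, traj.frames[0], 0, 1, PARAMS)
        assert m.values[0, 1] == pytest.approx(abs(e), abs=1e-12)

    def test_absolute_value_taken_before_mean(self):
        # LJ sign flips between frames: repulsive inside r_min 2^(-1/6), attractive outside
        from reinet import Frame, Trajectory

        topo, traj = point_system([[(0, 0, 0)], [(1.5, 0, 0)]], eps=0.3, rmin_half=1.0)
        frames = [Frame(0, np.array([[0, 0, 0], [1.5, 0, 0]], float)),
                  Frame(1, np.array([[0, 0, 0], [2.5, 0, 0]], float))]
        traj2 = Trajectory(topo, frames)
        e0 = residue_pair_energy(topo, frames[0], 0, 1, PARAMS)
        e1 = residue_pair_energy(topo, frames[1], 0, 1, PARAMS)
        assert e0 > 0 > e1  # signs genuinely differ
        m = pair_energy_matrix(topo, traj2, PARAMS)
        assert m.values[0, 1] == pytest.approx((abs(e0) + abs(e1)) / 2, abs=1e-12)
        assert m.values[0, 1] > abs((e0 + e1) / 2)

    def test_matrix_invariants(self, toy_files):
        _, topo, traj, _ = toy_files
        m = pair_energy_matrix(topo, traj, PARAMS)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert np.all(m.values >= 0) and np.all(np.isfinite(m.values))

    def test_matches_naive_oracle_on_random_fixture(self, tmp_path):
        spec = FixtureSpec(n_residues=5, geometry="globule", n_frames=5, seed=99)
        topo, traj, _ = make_toy_system(spec, tmp_path)
        m = pair_energy_matrix(topo, traj, PARAMS)
        oracle = naive_mean_abs_matrix(topo, traj, PARAMS)
        np.testing.assert_allclose(m.values, oracle, atol=1e-10)

    def test_tsv_round_trip(self, toy_files, tmp_path):
        from reinet import PairEnergyMatrix

        _, topo, traj, _ = toy_files
        m = pair_energy_matrix(topo, traj, PARAMS)
        m.to_tsv(tmp_path / "m.tsv")
        m.params_sidecar(tmp_path / "m.json")
        back = PairEnergyMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "m.json")
        np.testing.assert_allclose(back.values, m.values, rtol=1e-10)
        assert back.labels == m.labels
        assert back.params == m.params
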