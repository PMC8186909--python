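"""Structure/trajectory parsing, selections and centers of mass."""

import numpy as np
import pytest

from mechanotraj import synthetic as syn
from mechanotraj.errors import AnalysisError, ParseError, SelectionError
from mechanotraj.structure import (
    DomainMap,
    Structure,
    Trajectory,
    center_of_mass,
    load_frames,
    read_structure,
    read_trajectory,
    save_frames,
    select,
    write_structure,
    write_trajectory_pdb,
)

ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00"
    "           C  \n"
)


class TestReadStructure:
    def test_single_atom_identity_parse(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(ONE_ATOM_PDB)
        s = read_structure(path)
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504])
        assert s.atom_name[0] == "CA" and s.chain_id[0] == "A"

    def test_write_read_round_trip_preserves_fields(self, tmp_path, channel_model):
        path = tmp_path / "chan.pdb"
        write_structure(channel_model, path)
        back = read_structure(path)
        # PDB prints 3 decimals: coordinates agree to the printed precision
        np.testing.assert_allclose(back.coords, channel_model.coords, atol=5e-4)
        assert (back.chain_id == channel_model.chain_id).all()
        assert (back.res_id == channel_model.res_id).all()
        assert (back.atom_name == channel_model.atom_name).all()
        # idempotence: a second round trip is exact
        path2 = tmp_path / "chan2.pdb"
        write_structure(back, path2)
        again = read_structure(path2)
        np.testing.assert_array_equal(again.coords, back.coords)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.30  0.00"
            "           C  \n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.70  0.00"
            "           C  \n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        s = read_structure(path)
        assert s.n_atoms == 1
        assert s.coords[0, 0] == pytest.approx(2.0)


class TestTrajectory:
    def test_multi_model_frame_count_and_concatenation(self, tmp_path):
        model = syn.SpringModel(n_chains=1, n_beads_per_chain=4)
        run = syn.simulate_overdamped(model, n_steps=100, record_every=20, seed=0)
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        traj = run.trajectory
        write_trajectory_pdb(
            Trajectory(traj.topology, traj.coords[:2], traj.times[:2]), p1
        )
        write_trajectory_pdb(
            Trajectory(traj.topology, traj.coords[2:], traj.times[2:] - traj.times[2]),
            p2,
        )
        merged = read_trajectory([p1, p2], traj.topology)
        assert merged.n_frames == traj.n_frames
        assert np.all(np.diff(merged.times) > 0)

    def test_atom_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "t.pdb"
        path.write_text(ONE_ATOM_PDB)
        big = syn.make_channel_model()
        with pytest.raises(ParseError):
            read_trajectory(path, big)

    def test_non_monotone_times_rejected(self, channel_model):
        coords = np.stack([channel_model.coords] * 3)
        with pytest.raises(ParseError):
            Trajectory(channel_model, coords, times=[0.0, 2.0, 1.0])

    def test_frame_store_round_trip(self, tmp_path):
        model = syn.SpringModel(n_chains=2, n_beads_per_chain=6)
        run = syn.simulate_overdamped(model, n_steps=200, record_every=50, seed=1)
        path = tmp_path / "frames.npz"
        save_frames(run.trajectory, path)
        back = load_frames(path, run.trajectory.topology)
        assert back.n_frames == run.trajectory.n_frames
        assert np.abs(back.coords - run.trajectory.coords).max() < 1e-3
        np.testing.assert_array_equal(back.times, run.trajectory.times)


class TestSelect:
    def test_gate_residue_selects_all_four_chains(
        self, channel_model, channel_domain_map
    ):
        idx = select(channel_model, channel_domain_map, "gate_residue")
        assert set(channel_model.chain_id[idx]) == {"A", "B", "C", "D"}
        assert set(channel_model.res_id[idx]) == {1554}

    def test_backbone_flag_restricts_to_backbone_atoms(self, channel_model):
        dmap = DomainMap.from_dict(
            {"gate_bb": [{"chain": "*", "start": 1554, "stop": 1554,
                          "backbone_only": True}]}
        )
        idx = select(channel_model, dmap, "gate_bb")
        assert set(channel_model.atom_name[idx]) <= {"N", "CA", "C", "O"}

    def test_union_of_ar_repeats_equals_full_ar_selection(
        self, channel_model, channel_domain_map
    ):
        full = set(select(channel_model, channel_domain_map, "AR"))
        union = set()
        for i in range(1, 30):
            union |= set(select(channel_model, channel_domain_map, f"AR{i}"))
        assert union == full

    def test_unknown_and_empty_selections_raise(self, channel_model):
        dmap = DomainMap.from_dict(
            {"nowhere": [{"chain": "Z", "start": 1, "stop": 2}]}
        )
        with pytest.raises(SelectionError):
            select(channel_model, dmap, "missing")
        with pytest.raises(SelectionError):
            select(channel_model, dmap, "nowhere")

    def test_select_is_deterministic_and_sorted(
        self, channel_model, channel_domain_map
    ):
        a = select(channel_model, channel_domain_map, "TM")
        b = select(channel_model, channel_domain_map, "TM")
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)

    def test_domain_map_yaml_round_trip(self, tmp_path, channel_domain_map):
        path = tmp_path / "dmap.yaml"
        channel_domain_map.to_yaml(path)
        back = DomainMap.from_yaml(path)
        assert back.regions == channel_domain_map.regions


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        n = 2
        s = Structure(
            chain_id=np.full(n, "A"),
            res_id=np.arange(n),
            ins_code=np.full(n, ""),
            res_name=np.full(n, "X"),
            atom_name=np.array(["C1", "C2"]),
            element=np.full(n, "C"),
            occupancy=np.ones(n),
            coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]]),
        )
        np.testing.assert_allclose(center_of_mass(s), [0.0, 0.0, 1.0])

    def test_translation_equivariance(self, channel_model):
        t = np.array([1.5, -2.0, 3.25])
        shifted = channel_model.with_coords(channel_model.coords + t)
        np.testing.assert_allclose(
            center_of_mass(shifted), center_of_mass(channel_model) + t, atol=1e-9
        )

    def test_matches_brute_force_weighted_mean(self, channel_model):
        rng = np.random.default_rng(0)
        sel = rng.choice(channel_model.n_atoms, size=50, replace=False)
        com = center_of_mass(channel_model, sel)
        sub = channel_model.subset(sel)
        m = sub.masses()
        expected = sum(m[i] * sub.coords[i] for i in range(50)) / m.sum()
        np.testing.assert_allclose(com, expected, atol=1e-12)

    def test_union_com_is_mass_weighted_combination(self, channel_model):
        a = np.arange(0, 40)
        b = np.arange(40, 100)
        ma = channel_model.subset(a).masses().sum()
        mb = channel_model.subset(b).masses().sum()
        com_union = center_of_mass(channel_model, np.concatenate([a, b]))
        expected = (
            ma * center_of_mass(channel_model, a) + mb * center_of_mass(channel_model, b)
        ) / (ma + mb)
        np.testing.assert_allclose(com_union, expected, atol=1e-12)

    def test_empty_selection_rejected(self, channel_model):
        with pytest.raises(AnalysisError):
            center_of_mass(channel_model, np.array([], dtype=int))
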