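"""Geometric detectors vs brute-force oracles, plus occupancy bookkeeping."""

import numpy as np
import pytest

from oracles import brute_contacts, brute_hbonds, brute_saltbridges
from conftest import make_ion
from ppikit import synthetic_data as sd
from ppikit.interface_geometry import (GeometryCriteria,
                                       detect_contacts_frame,
                                       detect_hbonds_frame,
                                       detect_saltbridges_frame,
                                       occupancy_over_ensemble)
from ppikit.structure_io import (AtomRecord, Structure, TrajectoryEnsemble,
                                 infer_chem_roles)


def two_atom_structure(distance):
    return Structure([make_ion(1, "C1", "C", 1, "A", (0, 0, 0), 0.0),
                      make_ion(2, "C2", "C", 1, "B", (distance, 0, 0), 0.0)],
                     {"A": "A", "B": "B"})


def hbond_fixture(d_to_a, angle_deg):
    """Ser OG-HG donor on A, carbonyl-like O acceptor on B."""
    og = np.zeros(3)
    # hydrogen at 1.0 A from OG along +x
    hg = np.array([1.0, 0.0, 0.0])
    ang = np.deg2rad(angle_deg)
    acc = d_to_a * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms = [
        AtomRecord(1, "OG", "O", "SER", 1, "A", og, 16.0),
        AtomRecord(2, "HG", "H", "SER", 1, "A", hg, 1.0),
        AtomRecord(3, "O", "O", "GLY", 9, "B", acc, 16.0),
    ]
    return Structure(atoms, {"A": "A", "B": "B"})


class TestContactDetector:
    @pytest.mark.parametrize("d,expected", [(3.4, 1), (3.5, 1), (3.6, 0)])
    def test_cutoff_boundary(self, d, expected):
        s = two_atom_structure(d)
        recs = detect_contacts_frame(s.coords, s)
        assert len(recs) == expected

    def test_minimum_distance_reported_per_residue_pair(self):
        atoms = [make_ion(1, "C1", "C", 1, "A", (0, 0, 0), 0.0),
                 make_ion(2, "C2", "C", 1, "A", (0, 0, 1.5), 0.0),
                 make_ion(3, "C1", "C", 5, "B", (3.0, 0, 0), 0.0),
                 make_ion(4, "C2", "C", 5, "B", (3.2, 0, 1.5), 0.0)]
        s = Structure(atoms, {"A": "A", "B": "B"})
        recs = detect_contacts_frame(s.coords, s)
        assert len(recs) == 1
        assert recs[0].geometry_distance == pytest.approx(3.0, abs=1e-12)

    def test_hydrogens_excluded(self):
        atoms = [make_ion(1, "C1", "C", 1, "A", (0, 0, 0), 0.0),
                 AtomRecord(2, "H1", "H", "ION", 2, "B",
                            np.array([2.0, 0, 0]), 1.0),
                 make_ion(3, "C2", "C", 2, "B", (9.0, 0, 0), 0.0)]
        s = Structure(atoms, {"A": "A", "B": "B"})
        assert detect_contacts_frame(s.coords, s) == []


class TestHbondDetector:
    def test_collinear_ideal_geometry(self):
        s = hbond_fixture(2.9, 0.0)
        recs = detect_hbonds_frame(s.coords, s, infer_chem_roles(s))
        assert len(recs) == 1
        assert recs[0].geometry_distance == pytest.approx(2.9)
        assert recs[0].geometry_angle == pytest.approx(0.0, abs=1e-9)
        assert recs[0].atomsA == ("OG", "HG")
        assert recs[0].atomsB == ("O",)

    @pytest.mark.parametrize("angle,found", [(25.0, True), (29.9, True),
                                             (35.0, False)])
    def test_angle_cutoff(self, angle, found):
        s = hbond_fixture(2.9, angle)
        recs = detect_hbonds_frame(s.coords, s, infer_chem_roles(s))
        assert bool(recs) is found

    def test_distance_cutoff(self):
        s = hbond_fixture(3.6, 0.0)
        assert detect_hbonds_frame(s.coords, s, infer_chem_roles(s)) == []


class TestSaltBridgeDetector:
    @pytest.mark.parametrize("d,found", [(3.0, True), (3.7, False)])
    def test_asp_lys_boundary(self, d, found):
        recipe = sd.EnsembleRecipe(
            chain_a_start=1, chain_a_len=4, chain_b_start=50, chain_b_len=4,
            planted=(sd.PlantedInteraction("saltbridge", 2, 51,
                                           target_distance=min(d, 3.3)),))
        s, _ = sd.build_toy_complex(recipe)
        coords = s.coords
        if d > 3.3:  # push the planted bridge past the cutoff
            nz = [i for i, a in enumerate(s.atoms) if a.name == "NZ"]
            od = [i for i, a in enumerate(s.atoms) if a.name == "OD1"]
            shift = (d - 3.3) * (coords[nz[0]] - coords[od[0]]) \
                / np.linalg.norm(coords[nz[0]] - coords[od[0]])
            lys = [i for i, a in enumerate(s.atoms)
                   if a.resid == 51 and a.name not in
                   ("N", "CA", "C", "O", "HN")]
            coords[lys] += shift
        recs = detect_saltbridges_frame(coords, s, infer_chem_roles(s))
        assert bool(recs) is found

    def test_planted_asp_lys_and_arg_glu_pairs_found_exactly(self):
        recipe = sd.EnsembleRecipe(
            chain_a_start=1, chain_a_len=8, chain_b_start=50, chain_b_len=8,
            planted=(
                sd.PlantedInteraction("saltbridge", 2, 51, "ASP", "LYS"),
                sd.PlantedInteraction("saltbridge", 6, 55, "ARG", "GLU"),
            ))
        s, _ = sd.build_toy_complex(recipe)
        roles = infer_chem_roles(s)
        recs = detect_saltbridges_frame(s.coords, s, roles)
        got = {(r.resA[1], r.resB[1]) for r in recs}
        assert got == {(2, 51), (6, 55)}
        assert {r.pair_key for r in recs} == brute_saltbridges(
            s.coords, s, roles, 3.5)


class TestOracleEquivalence:
    @pytest.mark.parametrize("sigma", [0.3, 1.0, 3.0])
    def test_all_detectors_match_brute_force(self, sigma, default_complex):
        structure, _ = default_complex
        roles = infer_chem_roles(structure)
        crit = GeometryCriteria()
        rng = np.random.default_rng(int(sigma * 10))
        base = structure.coords
        for _ in range(5):
            frame = base + rng.normal(0, sigma, base.shape)
            contacts = detect_contacts_frame(frame, structure, crit)
            oracle = brute_contacts(frame, structure, crit.contact_cutoff)
            assert {r.pair_key[1:] for r in contacts} == set(oracle)
            for r in contacts:
                assert r.geometry_distance == pytest.approx(
                    oracle[(r.resA, r.resB)], abs=1e-10)
            hbonds = detect_hbonds_frame(frame, structure, roles, crit)
            assert {r.pair_key for r in hbonds} == brute_hbonds(
                frame, structure, roles, crit.hbond_dist_cutoff,
                crit.hbond_angle_cutoff)
            salts = detect_saltbridges_frame(frame, structure, roles, crit)
            assert {r.pair_key for r in salts} == brute_saltbridges(
                frame, structure, roles, crit.saltbridge_cutoff)

    def test_rigid_motion_and_permutation_invariance(self, default_complex):
        from test_trajectory_metrics import random_rotation
        structure, _ = default_complex
        roles = infer_chem_roles(structure)
        rng = np.random.default_rng(11)
        frame = structure.coords + rng.normal(0, 0.5, (len(structure), 3))
        rot = random_rotation(rng)
        moved = frame @ rot.T + np.array([100.0, -50.0, 7.0])
        for f in (frame, moved):
            keys = {r.pair_key
                    for r in detect_contacts_frame(f, structure)}
            if f is frame:
                ref_keys = keys
        assert keys == ref_keys

    def test_monotone_in_cutoff(self, default_complex):
        structure, _ = default_complex
        rng = np.random.default_rng(12)
        frame = structure.coords + rng.normal(0, 1.0, (len(structure), 3))
        roles = infer_chem_roles(structure)
        prev: set = set()
        for cutoff in (2.5, 3.0, 3.5, 4.5, 6.0):
            crit = GeometryCriteria(contact_cutoff=cutoff,
                                    hbond_dist_cutoff=cutoff,
                                    saltbridge_cutoff=cutoff)
            keys = {r.pair_key for r in
                    detect_contacts_frame(frame, structure, crit)}
            keys |= {r.pair_key for r in
                     detect_saltbridges_frame(frame, structure, roles, crit)}
            assert prev <= keys
            prev = keys

    def test_saltbridges_are_contacts_at_equal_cutoffs(self, default_complex):
        structure, _ = default_complex
        roles = infer_chem_roles(structure)
        rng = np.random.default_rng(13)
        frame = structure.coords + rng.normal(0, 0.8, (len(structure), 3))
        contacts = {r.pair_key[1:]
                    for r in detect_contacts_frame(frame, structure)}
        salts = {r.pair_key[1:]
                 for r in detect_saltbridges_frame(frame, structure, roles)}
        assert salts <= contacts


class TestOccupancy:
    def make_blinking_ensemble(self, n_on, n_total):
        s = two_atom_structure(3.0)
        near, far = s.coords, s.coords + np.array([[0, 0, 0], [10, 0, 0]])
        frames = np.stack([near] * n_on + [far] * (n_total - n_on))
        return TrajectoryEnsemble(s, [frames])

    @pytest.mark.parametrize("n_on,expected", [(10, 1.0), (5, 0.5), (0, None)])
    def test_count_ratios(self, n_on, expected):
        ens = self.make_blinking_ensemble(n_on, 10)
        with pytest.warns(UserWarning):  # fixture has no hydrogens
            roles = infer_chem_roles(ens.topology)
        occ = occupancy_over_ensemble(ens, roles)
        if expected is None:
            assert occ.occupancy == {}
        else:
            (key, vals), = occ.occupancy.items()
            assert vals[0] == pytest.approx(expected)

    def test_analysis_window_restricts_denominator(self):
        ens = self.make_blinking_ensemble(5, 10)  # on for first 5 frames
        with pytest.warns(UserWarning):
            roles = infer_chem_roles(ens.topology)
        occ = occupancy_over_ensemble(ens, roles,
                                      analysis_window=slice(5, None))
        assert occ.occupancy == {}
        occ = occupancy_over_ensemble(ens, roles,
                                      analysis_window=slice(0, 5))
        (key, vals), = occ.occupancy.items()
        assert vals[0] == pytest.approx(1.0)

    def test_empty_window_raises(self):
        ens = self.make_blinking_ensemble(5, 10)
        with pytest.warns(UserWarning):
            roles = infer_chem_roles(ens.topology)
        with pytest.raises(ValueError, match="empty analysis window"):
            occupancy_over_ensemble(ens, roles,
                                    analysis_window=slice(10, 10))

    def test_planted_persistence_recovered_within_tolerance(self):
        # 80%-persistent salt bridge under 0.1 A jitter: occupancy within
        # +/-0.1 of the plant over 10 seeds
        errs = []
        for seed in range(10):
            recipe = sd.EnsembleRecipe(
                n_replicas=1, n_frames=50, jitter_sigma=0.1,
                chain_a_start=1, chain_a_len=4, chain_b_start=50,
                chain_b_len=4,
                planted=(sd.PlantedInteraction(
                    "saltbridge", 2, 51, persistence=0.8,
                    replicas_present=(0,)),),
                seed=seed)
            ens, _ = sd.generate_ensemble(recipe)
            roles = infer_chem_roles(ens.topology)
            occ = occupancy_over_ensemble(ens, roles)
            key = [k for k in occ.occupancy if k[0] == "saltbridge"]
            assert len(key) == 1
            errs.append(occ.occupancy[key[0]][0] - 0.8)
        assert np.all(np.abs(errs) <= 0.1)
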