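"""MM/GBSA component anchors, oracles and limiting behaviour."""

import numpy as np
import pytest

from conftest import make_ion
from oracles import mm_pair_oracle
from ppikit import synthetic_data as sd
from ppikit.gbsa_scoring import (COULOMB_K, DescreeningError, GBSAConfig,
                                 binding_free_energy, gb_energy,
                                 hct_born_radii, mm_energy, sasa)
from ppikit.structure_io import (Structure, TrajectoryEnsemble,
                                 assign_parameters)


def ion_structure(*specs):
    """specs: (name, chain, xyz, charge[, gb_radius])"""
    atoms = []
    for k, spec in enumerate(specs, 1):
        name, chain, xyz, q = spec[:4]
        gbr = spec[4] if len(spec) > 4 else 2.0
        atoms.append(make_ion(k, name, "CL", k, chain, xyz, q,
                              gb_radius=gbr))
    chains = {a.chain for a in atoms}
    return Structure(atoms, {c: ("A" if c == "A" else "B") for c in chains})


class TestMMEnergy:
    def test_coulomb_closed_form(self):
        s = ion_structure(("NA", "A", (0, 0, 0), 1.0),
                          ("CL", "B", (3.320636, 0, 0), -1.0))
        e_c, _ = mm_energy(s.coords, s)
        assert e_c == pytest.approx(-100.0, abs=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        s = ion_structure(("AR", "A", (0, 0, 0), 0.0),
                          ("AR", "B", (3.4, 0, 0), 0.0))
        _, e_v = mm_energy(s.coords, s)
        assert e_v == pytest.approx(-0.1, abs=1e-12)  # eps_ij = 0.1

    def test_random_fixture_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(20)
        specs = [(f"C{k}", "A" if k < 10 else "B",
                  tuple(rng.uniform(0, 12, 3)), float(rng.uniform(-1, 1)))
                 for k in range(20)]
        s = ion_structure(*specs)
        e_c, e_v = mm_energy(s.coords, s)
        q = [a.charge for a in s.atoms]
        eps = [a.lj_epsilon for a in s.atoms]
        rmh = [a.lj_rmin_half for a in s.atoms]
        excl = set(s.bonds)  # distance-based; isolated ions have none here
        oc, ov = mm_pair_oracle(s.coords, q, eps, rmh, excl)
        assert e_c == pytest.approx(oc, abs=1e-10)
        assert e_v == pytest.approx(ov, abs=1e-10)

    def test_bonded_12_and_13_pairs_excluded(self, default_complex):
        structure, _ = default_complex
        table, formal = sd.toy_parameter_table()
        topo = assign_parameters(structure, table, formal)
        lys = [i for i, a in enumerate(topo.atoms)
               if a.resid == 940 and a.chain == "B"]
        group = np.array(lys)
        e_c, e_v = mm_energy(topo.coords, topo, group)
        excl = set()
        bonds = topo.bonds
        neigh = {}
        for i, j in bonds:
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
            excl.add((i, j))
        for c, around in neigh.items():
            for i in around:
                for j in around:
                    if i < j:
                        excl.add((i, j))
        sub = {i: k for k, i in enumerate(group)}
        coords = topo.coords[group]
        q = [topo.atoms[i].charge for i in group]
        eps = [topo.atoms[i].lj_epsilon for i in group]
        rmh = [topo.atoms[i].lj_rmin_half for i in group]
        excl_sub = {(sub[i], sub[j]) for i, j in excl
                    if i in sub and j in sub}
        oc, ov = mm_pair_oracle(coords, q, eps, rmh, excl_sub)
        assert e_c == pytest.approx(oc, abs=1e-10)
        assert e_v == pytest.approx(ov, abs=1e-10)

    def test_overlapping_atoms_raise(self):
        s = ion_structure(("A1", "A", (0, 0, 0), 0.0),
                          ("A2", "B", (0.05, 0, 0), 0.0))
        with pytest.raises(ValueError, match="overlapping"):
            mm_energy(s.coords, s)


class TestGBEnergy:
    def test_born_ion_closed_form(self):
        s = ion_structure(("NA", "A", (0, 0, 0), 1.0, 2.0))
        g = gb_energy(s.coords, s, np.array([0]))
        expect = -(COULOMB_K / 2) * (1 - 1 / 78.5) / 2.0
        assert g == pytest.approx(expect, rel=1e-3)
        assert g == pytest.approx(-81.96, abs=0.01)

    def test_zero_charge_group_is_zero(self):
        s = ion_structure(("C1", "A", (0, 0, 0), 0.0),
                          ("C2", "B", (4, 0, 0), 0.0))
        assert gb_energy(s.coords, s) == 0.0

    def test_distant_ions_approach_sum_of_born_energies(self):
        s = ion_structure(("NA", "A", (0, 0, 0), 1.0, 2.0),
                          ("CL", "B", (5e4, 0, 0), -1.0, 2.0))
        g = gb_energy(s.coords, s)
        born_sum = 2 * (-(COULOMB_K / 2) * (1 - 1 / 78.5) / 2.0)
        assert g == pytest.approx(born_sum, rel=1e-4)

    def test_isolated_atom_keeps_intrinsic_radius(self):
        s = ion_structure(("NA", "A", (0, 0, 0), 1.0, 1.7))
        radii = hct_born_radii(s.coords, s, np.array([0]))
        assert radii[0] == pytest.approx(1.7, abs=1e-12)

    def test_descreening_shrinks_effective_radius_inverse(self):
        # a close neighbour descreens: effective radius grows
        s = ion_structure(("NA", "A", (0, 0, 0), 1.0, 1.7),
                          ("CL", "B", (3.0, 0, 0), -1.0, 1.7))
        radii = hct_born_radii(s.coords, s, np.arange(2))
        assert np.all(radii > 1.7)

    def test_descreening_failure_names_atom(self):
        # many overlapping heavy descreeners drive 1/R negative
        rng = np.random.default_rng(0)
        specs = [("C0", "A", (0, 0, 0), 0.0, 0.3)]
        for k in range(12):
            v = rng.normal(size=3)
            v = 1.5 * v / np.linalg.norm(v)
            specs.append((f"C{k+1}", "B", tuple(v), 0.0, 2.5))
        s = ion_structure(*specs)
        with pytest.raises(DescreeningError, match="C0"):
            hct_born_radii(s.coords, s, np.arange(len(s.atoms)))


class TestSasa:
    def test_isolated_atom_sphere_area(self):
        s = ion_structure(("NA", "A", (0, 0, 0), 0.0, 1.5))
        _, total = sasa(s.coords, s, np.array([0]))
        assert total == pytest.approx(4 * np.pi * 2.9 ** 2, rel=5e-3)

    def test_fully_buried_atom_has_zero_area(self):
        s = ion_structure(("C1", "A", (0, 0, 0), 0.0, 0.5),
                          ("C2", "B", (0.2, 0, 0), 0.0, 3.0))
        per_atom, _ = sasa(s.coords, s)
        assert per_atom[0] == 0.0

    def test_tangent_spheres_symmetric_and_reduced(self):
        s = ion_structure(("C1", "A", (0, 0, 0), 0.0, 1.5),
                          ("C2", "B", (3.0, 0, 0), 0.0, 1.5))
        per_atom, total = sasa(s.coords, s)
        isolated = 4 * np.pi * 2.9 ** 2
        # equality only up to the deterministic point discretisation
        assert per_atom[0] == pytest.approx(per_atom[1], rel=0.01)
        assert total < 2 * isolated

    def test_doubling_sphere_points_changes_area_below_half_percent(
            self, default_complex):
        structure, _ = default_complex
        table, formal = sd.toy_parameter_table()
        topo = assign_parameters(structure, table, formal)
        group = topo.select("resid 115-118 and chain A")
        _, a1 = sasa(topo.coords, topo, group, GBSAConfig(sphere_points=960))
        _, a2 = sasa(topo.coords, topo, group, GBSAConfig(sphere_points=1920))
        assert abs(a1 - a2) / a2 < 0.005

    def test_matches_mdtraj_shrake_rupley(self):
        md = pytest.importorskip("mdtraj")
        # use mdtraj's own element radii so only the algorithms differ
        radii = {"C": 1.7, "N": 1.55, "O": 1.52}
        rng = np.random.default_rng(21)
        n = 12
        elements = rng.choice(["C", "N", "O"], size=n)
        coords = rng.uniform(0, 8, size=(n, 3))
        specs = [(f"X{k}", "A" if k < 6 else "B", tuple(coords[k]), 0.0,
                  radii[elements[k]]) for k in range(n)]
        s = ion_structure(*specs)
        _, total = sasa(s.coords, s, cfg=GBSAConfig(sphere_points=960))

        top = md.Topology()
        chain = top.add_chain()
        res = top.add_residue("UNK", chain)
        for k in range(n):
            top.add_atom(f"X{k}", md.element.Element.getBySymbol(
                elements[k]), res)
        traj = md.Trajectory(coords[None] / 10.0, top)  # nm
        ref = float(md.shrake_rupley(traj, probe_radius=0.14,
                                     n_sphere_points=960).sum() * 100.0)
        assert total == pytest.approx(ref, rel=0.02)


class TestBindingFreeEnergy:
    def lj_pair_ensemble(self, separation):
        s = ion_structure(("AR", "A", (0, 0, 0), 0.0),
                          ("AR", "B", (separation, 0, 0), 0.0))
        return TrajectoryEnsemble(s, [s.coords[None].repeat(2, axis=0)])

    def test_neutral_pair_at_lj_minimum(self):
        ens = self.lj_pair_ensemble(3.4)
        res = binding_free_energy(ens, frame_stride=1)
        cfg = GBSAConfig()
        _, sasa_c = sasa(ens.replicas[0][0], ens.topology, None, cfg)
        _, sasa_a = sasa(ens.replicas[0][0], ens.topology, np.array([0]), cfg)
        _, sasa_b = sasa(ens.replicas[0][0], ens.topology, np.array([1]), cfg)
        expected = -0.1 + cfg.surface_tension * (sasa_c - sasa_a - sasa_b)
        assert res.mean == pytest.approx(expected, abs=1e-10)

    def test_infinite_separation_limit_is_zero(self):
        ens = self.lj_pair_ensemble(1e3)
        res = binding_free_energy(ens, frame_stride=1)
        assert abs(res.mean) < 1e-6

    def test_ion_pair_matches_component_sum_oracle(self, ion_pair_structure):
        s = ion_pair_structure
        ens = TrajectoryEnsemble(s, [s.coords[None]])
        res = binding_free_energy(ens, frame_stride=1)
        cfg = GBSAConfig()
        parts = []
        for grp in (None, np.array([0]), np.array([1])):
            e_c, e_v = mm_energy(s.coords, s, grp, cfg)
            g_gb = gb_energy(s.coords, s, grp, cfg)
            _, a = sasa(s.coords, s, grp, cfg)
            parts.append(e_c + e_v + g_gb + cfg.surface_tension * a)
        assert res.mean == pytest.approx(parts[0] - parts[1] - parts[2],
                                         abs=1e-8)
        assert res.mean < 0  # opposite charges in contact bind favourably

    def test_rigid_motion_invariance(self, ion_pair_structure):
        from test_trajectory_metrics import random_rotation
        s = ion_pair_structure
        rng = np.random.default_rng(22)
        rot = random_rotation(rng)
        moved = s.coords @ rot.T + np.array([30.0, -7.0, 2.0])
        e1 = binding_free_energy(
            TrajectoryEnsemble(s, [s.coords[None]]), frame_stride=1)
        e2 = binding_free_energy(
            TrajectoryEnsemble(s, [moved[None]]), frame_stride=1)
        # exact up to the SASA point-set discretisation
        assert e1.mean == pytest.approx(e2.mean, abs=0.05)
        # the rotation-invariant components match tightly
        mm1 = mm_energy(s.coords, s)
        mm2 = mm_energy(moved, s)
        assert mm1 == pytest.approx(mm2, abs=1e-9)
        assert gb_energy(s.coords, s) == pytest.approx(
            gb_energy(moved, s), abs=1e-9)

    def test_decomposition_identity(self, ion_pair_structure):
        s = ion_pair_structure
        ens = TrajectoryEnsemble(s, [s.coords[None]])
        res = binding_free_energy(ens, frame_stride=1)
        for d in res.decompositions:
            assert d.g_total == pytest.approx(
                d.e_coulomb + d.e_vdw + d.g_gb + d.g_sa, abs=1e-12)

    def test_separation_drives_binding_energy_to_zero_monotonically(self):
        values = []
        for sep in (3.4, 8.0, 30.0, 200.0):
            res = binding_free_energy(self.lj_pair_ensemble(sep),
                                      frame_stride=1)
            values.append(abs(res.mean))
        assert values == sorted(values, reverse=True)
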