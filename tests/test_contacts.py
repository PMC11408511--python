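import numpy as np
import pytest

from tauramd.contacts import (
    ContactParams,
    assign_interaction_groups,
    compute_ppre_series,
    extract_bsres,
)
from tauramd.errors import (
    EmptyInterfaceError,
    InconsistentInputError,
    UnassignedResidueError,
)
from tauramd.fixtures import make_contact_fixture
from tauramd.trajectory_io import Topology, Trajectory

from conftest import make_topology


def res_key(top, chain, number):
    for k in top.residues():
        if k.chain_id == chain and k.residue_number == number:
            return k
    raise KeyError((chain, number))


class TestGroupAssignment:
    def test_lys_cation_and_donor_sets(self, protein_topology):
        ga = assign_interaction_groups(protein_topology)
        lys = ga.residue_groups(res_key(protein_topology, "A", 1))
        names = protein_topology.atom_names
        assert set(names[lys["cation"]]) == {"NZ"}
        assert {"NZ", "N"} <= set(names[lys["hbond_donor"]])

    def test_asp_anion_and_acceptors(self, protein_topology):
        ga = assign_interaction_groups(protein_topology)
        asp = ga.residue_groups(res_key(protein_topology, "A", 2))
        names = protein_topology.atom_names
        assert set(names[asp["anion"]]) == {"OD1", "OD2"}
        assert {"OD1", "OD2", "O"} <= set(names[asp["hbond_acceptor"]])

    def test_gly_sidechain_group_is_backbone(self, protein_topology):
        ga = assign_interaction_groups(protein_topology)
        gly = ga.residue_groups(res_key(protein_topology, "A", 3))
        names = set(protein_topology.atom_names[gly["sidechain"]])
        assert names == {"N", "CA", "C", "O"}

    def test_tyr_aromatic_ring(self, protein_topology):
        ga = assign_interaction_groups(protein_topology)
        tyr = ga.residue_groups(res_key(protein_topology, "B", 1))
        names = set(protein_topology.atom_names[tyr["aromatic"]])
        assert names == {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}

    def test_groups_contain_only_own_residue_atoms(self, protein_topology):
        ga = assign_interaction_groups(protein_topology)
        res_atoms = protein_topology.residue_atom_indices()
        for key, groups in ga.groups.items():
            own = set(res_atoms[key])
            for idx in groups.values():
                assert set(idx) <= own
                assert len(idx) > 0

    def test_unknown_residue_raises_listing_names(self):
        top = make_topology([("C1", "C", "LIG", 1, "A"),
                             ("CA", "C", "GLY", 1, "B")])
        with pytest.raises(UnassignedResidueError, match="LIG"):
            assign_interaction_groups(top)

    def test_override_covers_nonstandard_residue(self):
        top = make_topology([("C1", "C", "LIG", 1, "A"),
                             ("CA", "C", "GLY", 1, "B")])
        ga = assign_interaction_groups(
            top, overrides={"LIG": {"hydrophobic": ["C1"]}})
        grp = ga.residue_groups(res_key(top, "A", 1))
        assert "hydrophobic" in grp and "sidechain" in grp


def brute_force_ppre(traj, top, ga, params):
    """Independent nested-loop scan over every candidate group distance."""
    compatible = [
        {"hbond_donor", "hbond_acceptor"}, {"cation", "anion"},
        {"aromatic"}, {"aromatic", "cation"}, {"hydrophobic"},
        {"sidechain"},
    ]
    res = top.residues()
    res_a = [k for k in res if k.chain_id in top.partner_a_chains]
    res_b = [k for k in res if k.chain_id in top.partner_b_chains]
    out = {}
    for a in res_a:
        for b in res_b:
            series = []
            for f in range(traj.n_frames):
                coords = traj.coords[f]
                best = np.inf
                for na, ia in ga.residue_groups(a).items():
                    for nb, ib in ga.residue_groups(b).items():
                        if {na, nb} not in compatible:
                            continue
                        ma = top.masses[ia]
                        mb = top.masses[ib]
                        ca = (coords[ia] * ma[:, None]).sum(0) / ma.sum()
                        cb = (coords[ib] * mb[:, None]).sum(0) / mb.sum()
                        best = min(best, float(np.linalg.norm(ca - cb)))
                series.append(best)
            if series[0] <= params.ppre_cutoff:
                out[(a, b)] = series
    return out


class TestPPRESeries:
    def test_matches_brute_force_oracle(self, protein_topology,
                                        protein_trajectory):
        params = ContactParams()
        ga = assign_interaction_groups(protein_topology)
        mat = compute_ppre_series(protein_trajectory, protein_topology,
                                  ga, params)
        expected = brute_force_ppre(protein_trajectory, protein_topology,
                                    ga, params)
        assert set(mat.pairs) == set(expected)
        for i, pair in enumerate(mat.pairs):
            assert np.allclose(mat.distances[:, i], expected[pair],
                               atol=1e-10)

    def test_representative_is_minimum_of_candidates(self, protein_topology,
                                                     protein_trajectory):
        # spot check: the representative can never exceed the sidechain
        # carbon COM distance, one of its candidates
        ga = assign_interaction_groups(protein_topology)
        mat = compute_ppre_series(protein_trajectory, protein_topology, ga)
        for i, (a, b) in enumerate(mat.pairs):
            ia = ga.residue_groups(a)["sidechain"]
            ib = ga.residue_groups(b)["sidechain"]
            ma = protein_topology.masses[ia]
            mb = protein_topology.masses[ib]
            for f in range(mat.n_frames):
                coords = protein_trajectory.coords[f]
                ca = (coords[ia] * ma[:, None]).sum(0) / ma.sum()
                cb = (coords[ib] * mb[:, None]).sum(0) / mb.sum()
                assert mat.distances[f, i] <= np.linalg.norm(ca - cb) + 1e-9

    def test_partner_swap_preserves_distances(self, protein_topology,
                                              protein_trajectory):
        swapped = Topology(
            atom_names=protein_topology.atom_names,
            elements=protein_topology.elements,
            residue_names=protein_topology.residue_names,
            residue_numbers=protein_topology.residue_numbers,
            chain_ids=protein_topology.chain_ids,
            masses=protein_topology.masses,
            is_water=protein_topology.is_water,
            partner_a_chains=protein_topology.partner_b_chains,
            partner_b_chains=protein_topology.partner_a_chains,
        )
        ga1 = assign_interaction_groups(protein_topology)
        ga2 = assign_interaction_groups(swapped)
        m1 = compute_ppre_series(protein_trajectory, protein_topology, ga1)
        m2 = compute_ppre_series(protein_trajectory, swapped, ga2)
        d1 = {frozenset([a, b]): m1.distances[:, i]
              for i, (a, b) in enumerate(m1.pairs)}
        d2 = {frozenset([a, b]): m2.distances[:, i]
              for i, (a, b) in enumerate(m2.pairs)}
        assert d1.keys() == d2.keys()
        for k in d1:
            assert np.allclose(d1[k], d2[k])

    def test_identical_frames_zero_dcom_and_rmsd(self, protein_topology,
                                                 protein_trajectory):
        coords = np.repeat(protein_trajectory.coords[:1], 2, axis=0)
        traj = Trajectory(coords, snapshot_interval=10.0,
                          kind="equilibration")
        ga = assign_interaction_groups(protein_topology)
        mat = compute_ppre_series(traj, protein_topology, ga)
        assert mat.delta_com[1] == pytest.approx(0.0, abs=1e-9)
        assert mat.rmsd[1] == pytest.approx(0.0, abs=1e-6)

    def test_far_partners_empty_interface(self, protein_topology):
        coords = np.zeros((1, protein_topology.n_atoms, 3))
        coords[0, protein_topology.chain_ids == "B", 0] += 200.0
        traj = Trajectory(coords, snapshot_interval=10.0,
                          kind="equilibration")
        ga = assign_interaction_groups(protein_topology)
        with pytest.raises(EmptyInterfaceError):
            compute_ppre_series(traj, protein_topology, ga)


class TestBSREExtraction:
    def test_occupancy_counting_and_strict_threshold(self):
        # pair 0: 60/100 frames below 5.5 -> kept; pair 1: exactly 50/100
        # -> excluded; pair 2: never below -> excluded
        planted = np.full((100, 3), 10.0)
        planted[:60, 0] = 4.0
        planted[:50, 1] = 4.0
        fx = make_contact_fixture(planted)
        from tauramd.contacts import (
            assign_interaction_groups as assign,
            compute_ppre_series as series,
        )
        ga = assign(fx.topology, fx.group_overrides)
        mat = series(fx.trajectory, fx.topology, ga)
        bs = extract_bsres([mat])
        kept = {p[0].residue_number for p in
                [(a, b) for a, b in bs.pairs]}
        assert kept == {1}
        assert bs.occupancies[0] == pytest.approx(0.60)

    def test_pooling_across_replicas(self):
        planted_lo = np.full((50, 1), 4.0)   # always in contact
        planted_hi = np.full((50, 1), 10.0)  # never in contact
        fx1 = make_contact_fixture(planted_lo)
        fx2 = make_contact_fixture(planted_hi)
        ga = assign_interaction_groups(fx1.topology, fx1.group_overrides)
        m1 = compute_ppre_series(fx1.trajectory, fx1.topology, ga)
        m2 = compute_ppre_series(fx2.trajectory, fx2.topology, ga)
        bs = extract_bsres([m1, m2])
        # pooled occupancy exactly 0.5: strict > excludes the pair
        assert len(bs.pairs) == 0

    def test_mismatched_pair_lists_rejected(self):
        fx1 = make_contact_fixture(np.full((10, 2), 4.0))
        fx2 = make_contact_fixture(np.full((10, 3), 4.0))
        ga1 = assign_interaction_groups(fx1.topology, fx1.group_overrides)
        ga2 = assign_interaction_groups(fx2.topology, fx2.group_overrides)
        m1 = compute_ppre_series(fx1.trajectory, fx1.topology, ga1)
        m2 = compute_ppre_series(fx2.trajectory, fx2.topology, ga2)
        with pytest.raises(InconsistentInputError):
            extract_bsres([m1, m2])

    def test_bsres_subset_of_ppres(self):
        rng = np.random.default_rng(7)
        planted = rng.uniform(3.0, 20.0, size=(40, 6))
        fx = make_contact_fixture(planted)
        ga = assign_interaction_groups(fx.topology, fx.group_overrides)
        mat = compute_ppre_series(fx.trajectory, fx.topology, ga)
        bs = extract_bsres([mat])
        assert set(map(tuple, bs.pairs)) <= set(map(tuple, mat.pairs))
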