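import itertools

import networkx as nx
import numpy as np
import pytest

from cholbind.contacts import ContactRecord, events_from_bound
from cholbind.md_io import LipidMolecule, ProteinResidue, Topology, Trajectory
from cholbind.sites import (
    build_cocontact_graph,
    classify_orientation,
    detect_sites,
    estimate_midplane,
    rank_sites,
    representative_pose,
    score_site,
    site_bound_by_lipid,
    sites_to_frame,
)


def record(lipid_id, residue, bound):
    bound = np.asarray(bound, dtype=bool)
    return ContactRecord(lipid_id=lipid_id, residue=residue, bound=bound,
                         events=events_from_bound(bound, 1.0))


class TestCoContactGraph:
    def test_half_trajectory_cobinding_weight(self):
        bound = np.zeros(100, dtype=bool)
        bound[:50] = True
        g = build_cocontact_graph([record(0, "R1", bound),
                                   record(0, "R2", bound)])
        assert g["R1"]["R2"]["weight"] == pytest.approx(0.5)

    def test_disjoint_lipids_give_disjoint_components(self):
        b = np.ones(10, dtype=bool)
        g = build_cocontact_graph([
            record(0, "R1", b), record(0, "R2", b),
            record(1, "R3", b), record(1, "R4", b),
        ])
        assert nx.number_connected_components(g) == 2

    def test_no_simultaneous_contacts_gives_edgeless_graph(self):
        b1 = np.array([True, False, False])
        b2 = np.array([False, True, False])
        g = build_cocontact_graph([record(0, "R1", b1), record(0, "R2", b2)])
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"R1", "R2"}

    def test_weights_bounded_and_symmetric(self):
        rng = np.random.default_rng(2)
        recs = [record(l, f"R{r}", rng.random(50) < 0.5)
                for l in range(3) for r in range(4)]
        g = build_cocontact_graph(recs)
        for _, _, w in g.edges(data="weight"):
            assert 0.0 <= w <= 1.0
        assert not any(u == v for u, v in g.edges)


class TestDetectSites:
    def _clique_graph(self, *cliques, weight=0.5):
        g = nx.Graph()
        for clique in cliques:
            g.add_nodes_from(clique)
            for a, b in itertools.combinations(clique, 2):
                g.add_edge(a, b, weight=weight)
        return g

    def test_two_planted_cliques_recovered_exactly(self):
        c1 = [f"A{i}" for i in range(6)]
        c2 = [f"B{i}" for i in range(6)]
        sites = detect_sites(self._clique_graph(c1, c2), seed=0)
        assert sorted(map(tuple, sites)) == sorted([tuple(sorted(c1)),
                                                    tuple(sorted(c2))])

    def test_edgeless_graph_yields_no_sites(self):
        g = nx.Graph()
        g.add_nodes_from(["R1", "R2", "R3"])
        assert detect_sites(g, seed=0) == []

    def test_single_clique_is_one_site(self):
        c = [f"A{i}" for i in range(5)]
        sites = detect_sites(self._clique_graph(c), seed=0)
        assert sites == [sorted(c)]

    def test_small_communities_discarded(self):
        g = self._clique_graph(["A0", "A1", "A2"])
        assert detect_sites(g, min_residues=4, seed=0) == []

    def test_weight_floor_prunes_weak_edges(self):
        g = self._clique_graph([f"A{i}" for i in range(6)], weight=0.01)
        assert detect_sites(g, weight_floor=0.05, seed=0) == []


class TestScoreSite:
    def test_full_occupancy(self):
        site = score_site(["R1"], [record(0, "R1", np.ones(50, dtype=bool))],
                          timestep_ns=1.0, n_bootstrap=0)
        assert site.occupancy_pct == pytest.approx(100.0)

    def test_occupancy_counts_or_over_lipids(self):
        b = np.zeros(100, dtype=bool)
        b[:60] = True
        site = score_site(["R1"], [record(0, "R1", b)], timestep_ns=1.0,
                          n_bootstrap=0)
        assert site.occupancy_pct == pytest.approx(60.0)

    def test_single_residue_site_tau_equals_residue_tau(self):
        rng = np.random.default_rng(3)
        bound = rng.random(2000) < 0.3
        site = score_site(["R1"], [record(0, "R1", bound)], timestep_ns=1.0,
                          n_bootstrap=0)
        assert site.kinetic_fit.tau_ns == pytest.approx(
            site.per_residue_tau_ns["R1"])

    def test_site_occupancy_at_least_max_residue_occupancy(
            self, small_system, small_contacts):
        truth = small_system.ground_truth
        for site in truth.sites:
            per_lipid = site_bound_by_lipid(site.residues, small_contacts)
            any_bound = np.zeros(small_system.trajectory.frame_count,
                                 dtype=bool)
            for b in per_lipid.values():
                any_bound |= b
            site_occ = any_bound.mean() * 100
            for res in site.residues:
                res_bound = np.zeros_like(any_bound)
                for rec in small_contacts:
                    if rec.residue == res:
                        res_bound |= rec.bound
                assert site_occ >= res_bound.mean() * 100 - 1e-12


class TestRanking:
    def test_sites_ordered_by_descending_tau(self, small_system,
                                             small_contacts):
        from cholbind.sites import build_cocontact_graph as bcg
        comms = detect_sites(bcg(small_contacts), seed=0)
        ranked = rank_sites([
            score_site(c, small_contacts, 1.0, n_bootstrap=0, seed=0)
            for c in comms
        ])
        taus = [s.tau_ns for s in ranked]
        assert taus == sorted(taus, reverse=True)
        assert [s.site_id for s in ranked] == list(range(1, len(ranked) + 1))
        df = sites_to_frame(ranked)
        assert list(df["site_id"]) == [s.site_id for s in ranked]

    def test_detection_and_ranking_deterministic(self, small_contacts):
        def run():
            comms = detect_sites(build_cocontact_graph(small_contacts), seed=4)
            ranked = rank_sites([
                score_site(c, small_contacts, 1.0, n_bootstrap=20, seed=4)
                for c in comms
            ])
            return [(s.site_id, tuple(s.residues), s.occupancy_pct,
                     s.kinetic_fit.tau_ns, s.kinetic_fit.ci_ns)
                    for s in ranked]

        assert run() == run()


def _pose_fixture(n_a=80, n_b=20):
    """One site residue and one 3-bead lipid, two planted pose clusters."""
    n = n_a + n_b
    coords = np.zeros((n, 4, 3))
    coords[:, 0] = [5.0, 5.0, 1.0]  # residue bead, static
    pose_a = np.array([[5.3, 5.0, 1.0], [5.3, 5.0, 1.4], [5.3, 5.0, 1.8]])
    pose_b = pose_a + [0.0, 0.8, 0.0]
    coords[:n_a, 1:] = pose_a
    coords[n_a:, 1:] = pose_b
    topo = Topology(
        names=np.array(["BB", "ROH", "RC", "CT"], dtype=object),
        resnames=np.array(["GLY", "CHOL", "CHOL", "CHOL"], dtype=object),
        resids=np.array([1, 2, 2, 2]),
        chains=np.array(["A"] * 4, dtype=object),
        protein_residues=[ProteinResidue("G1", "GLY", 1, "A", np.array([0]))],
        lipids=[LipidMolecule(0, "cholesterol", np.array([1, 2, 3]), 1)],
        box=np.array([10.0, 10.0, 4.0]),
    )
    traj = Trajectory(coords=coords, timestep_ns=1.0, box=topo.box)
    recs = [record(0, "G1", np.ones(n, dtype=bool))]
    site = score_site(["G1"], recs, 1.0, n_bootstrap=0)
    return site, recs, traj, topo


class TestRepresentativePose:
    def test_identical_poses_form_one_cluster(self):
        site, recs, traj, topo = _pose_fixture(n_a=30, n_b=0)
        poses = representative_pose(site, recs, traj, topo, rmsd_cutoff=0.2)
        assert len(poses) == 1
        assert poses[0].cluster_size == 30

    def test_top_pose_is_medoid_of_dominant_cluster(self):
        site, recs, traj, topo = _pose_fixture(n_a=80, n_b=20)
        poses = representative_pose(site, recs, traj, topo, rmsd_cutoff=0.2,
                                    max_poses=100)
        assert len(poses) == 2
        assert poses[0].cluster_size == 80
        assert poses[0].frame < 80  # medoid drawn from the dominant cluster
        assert poses[1].cluster_size == 20

    def test_no_occupied_frames_is_an_error(self):
        site, recs, traj, topo = _pose_fixture(n_a=10, n_b=0)
        empty = [record(0, "G1", np.zeros(10, dtype=bool))]
        site_empty = score_site(["G1"], empty, 1.0, n_bootstrap=0)
        with pytest.raises(ValueError):
            representative_pose(site_empty, empty, traj, topo)


class TestOrientation:
    def test_hydroxyl_at_midplane_is_flipped(self):
        label, leaflet = classify_orientation(hydroxyl_z=0.1, ring_z=1.0,
                                              midplane_z=0.0)
        assert label == "flipped" and leaflet == 1

    def test_hydroxyl_at_interface_is_canonical(self):
        label, leaflet = classify_orientation(hydroxyl_z=1.9, ring_z=1.2,
                                              midplane_z=0.0)
        assert label == "canonical" and leaflet == 1

    def test_lower_leaflet_sign(self):
        label, leaflet = classify_orientation(hydroxyl_z=-1.9, ring_z=-1.2,
                                              midplane_z=0.0)
        assert label == "canonical" and leaflet == -1

    def test_midplane_estimate_centres_symmetric_bilayer(self, small_system):
        mid = estimate_midplane(small_system.trajectory, small_system.topology)
        box_mid = small_system.trajectory.box[2] / 2
        assert np.all(np.abs(mid - box_mid) < 0.3)
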