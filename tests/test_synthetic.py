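import numpy as np
import pytest
from scipy import stats

from cholbind.contacts import ContactParameters, detect_contacts
from cholbind.synthetic import (
    PlantedSite,
    SyntheticSpec,
    default_spec,
    generate_dose_response,
    generate_membrane_trajectory,
    generate_titration_dataset,
    simulate_occupancy_titration,
    titration_template,
)


class TestDeterminism:
    def test_same_seed_reproduces_coordinates_and_ledger(self):
        spec = default_spec(seed=11, n_frames=300)
        a = generate_membrane_trajectory(spec)
        b = generate_membrane_trajectory(default_spec(seed=11, n_frames=300))
        np.testing.assert_array_equal(a.ground_truth.occupant,
                                      b.ground_truth.occupant)
        np.testing.assert_array_equal(a.trajectory.coords, b.trajectory.coords)

    def test_different_seed_differs(self):
        a = generate_membrane_trajectory(default_spec(seed=1, n_frames=300))
        b = generate_membrane_trajectory(default_spec(seed=2, n_frames=300))
        assert (a.ground_truth.occupant != b.ground_truth.occupant).any()

    def test_dose_response_reproducible(self):
        t1, p1, _ = generate_dose_response(seed=5)
        t2, p2, _ = generate_dose_response(seed=5)
        np.testing.assert_array_equal(t1.responses, t2.responses)
        np.testing.assert_array_equal(p1.responses, p2.responses)


class TestSpecValidation:
    def test_overfilled_leaflet_rejected(self):
        spec = SyntheticSpec(box=(3.0, 3.0, 4.0), n_lipids=200)
        with pytest.raises(ValueError, match="overfilled"):
            spec.validate()

    def test_too_coarse_timestep_rejected(self):
        spec = default_spec()
        spec.sites[0].k_off_per_us = 2000.0
        with pytest.raises(ValueError, match="timestep"):
            spec.validate()

    def test_kd_is_koff_over_kon_scale(self):
        site = PlantedSite(site_id=1, anchor_xy=(1.0, 1.0),
                           k_off_per_us=1.25, k_on_scale_per_us_pct=0.25)
        assert site.kd_pct == pytest.approx(5.0)
        assert site.tau_ns == pytest.approx(800.0)


class TestBindingLedger:
    def test_zero_on_rate_means_zero_events_and_zero_sites(self):
        from cholbind.sites import build_cocontact_graph, detect_sites

        spec = default_spec(seed=4, n_frames=1500)
        for s in spec.sites:
            s.k_on_scale_per_us_pct = 0.0
        system = generate_membrane_trajectory(spec)
        for s in system.ground_truth.sites:
            assert system.ground_truth.events(s.site_id) == []
        recs = detect_contacts(system.trajectory, system.topology,
                               "cholesterol", ContactParameters())
        assert recs == [] or detect_sites(build_cocontact_graph(recs),
                                          seed=0) == []

    def test_bound_durations_are_exponential(self):
        """Kolmogorov-Smirnov check of the memoryless unbinding kinetics."""
        durations = []
        template = titration_template(kd_pct=6.6)  # tau = 80 ns
        ss = np.random.SeedSequence(123)
        for child in ss.spawn(30):
            spec = titration_template(
                kd_pct=6.6, seed=int(child.generate_state(1)[0] % 2**31))
            spec.cholesterol_pct = 25.0
            system_truth = generate_truth_only(spec)
            durations.append(system_truth.bound_durations_ns(1))
        d = np.concatenate(durations)
        assert d.size >= 1000
        tau = template.sites[0].tau_ns
        assert d.mean() == pytest.approx(tau, rel=0.1)
        _, p = stats.kstest(d, "expon", args=(0, tau))
        assert p > 0.01

    def test_occupancy_tracks_saturation_isotherm(self):
        """Empirical occupancy vs x/(x + Kd) at three compositions."""
        kd = 10.0
        tmpl = titration_template(kd_pct=kd)
        recs = simulate_occupancy_titration(tmpl, [5.0, 10.0, 30.0], 3,
                                            seed=77)
        by_comp = {}
        for r in recs:
            by_comp.setdefault(r["composition_pct"], []).append(
                (r["x_free_pct"], r["occupancy_pct"][1]))
        for comp, reps in by_comp.items():
            x = np.mean([r[0] for r in reps])
            occ = np.mean([r[1] for r in reps])
            assert occ == pytest.approx(100.0 * x / (x + kd), abs=5.0)


def generate_truth_only(spec):
    from cholbind.synthetic import GroundTruth, SiteTruth, _simulate_ctmc

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    occupant = _simulate_ctmc(spec, rng)
    sites = [SiteTruth(s.site_id, [], s.tau_ns, s.kd_pct, s.flipped, s.leaflet)
             for s in spec.sites]
    return GroundTruth(sites=sites, occupant=occupant,
                       timestep_ns=spec.timestep_ns)


class TestRenderingConsistency:
    def test_rendered_trajectory_reproduces_ctmc_occupancy(self):
        """Contact detection on coordinates must agree with the Markov
        ledger frame by frame (the fast titration path relies on this)."""
        spec = titration_template(kd_pct=6.6, n_frames=1200, n_lipids=200)
        spec.cholesterol_pct = 20.0
        system = generate_membrane_trajectory(spec)
        recs = detect_contacts(system.trajectory, system.topology,
                               "cholesterol", ContactParameters())
        truth_bound = system.ground_truth.occupant[:, 0] >= 0
        detected = np.zeros(spec.n_frames, dtype=bool)
        site_res = set(system.ground_truth.sites[0].residues)
        for rec in recs:
            if rec.residue in site_res:
                detected |= rec.bound
        np.testing.assert_array_equal(detected, truth_bound)

    def test_flipped_site_written_with_buried_hydroxyl(self):
        from cholbind.sites import classify_lipid_orientation, estimate_midplane

        system = generate_membrane_trajectory(default_spec(seed=6,
                                                           n_frames=2000))
        truth = system.ground_truth
        mid = estimate_midplane(system.trajectory, system.topology)
        lipids = {l.mol_id: l for l in system.topology.lipids}
        for si, site in enumerate(truth.sites):
            frames = np.flatnonzero(truth.occupant[:, si] >= 0)[:50]
            want = "flipped" if site.flipped else "canonical"
            for f in frames:
                lid = int(truth.occupant[f, si])
                label, _ = classify_lipid_orientation(
                    system.trajectory, system.topology, lipids[lid], [f], mid
                )[0]
                assert label == want


class TestTitrationDataset:
    def test_single_composition_rejected(self):
        with pytest.raises(ValueError):
            generate_titration_dataset(titration_template(), [10.0], 2, seed=0)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            generate_titration_dataset(titration_template(),
                                       [5.0, 10.0, 150.0], 2, seed=0)

    def test_fast_path_matches_rendered_route(self, tmp_path):
        tmpl = titration_template(kd_pct=6.6, n_frames=400, n_lipids=200)
        comps = [10.0, 20.0, 30.0]
        records, manifest = generate_titration_dataset(tmpl, comps, 2, seed=9)
        fast = simulate_occupancy_titration(tmpl, comps, 2, seed=9)
        assert len(records) == len(fast) == 6
        for rec, f in zip(records, fast):
            truth = rec["system"].ground_truth
            assert truth.occupancy_pct(1) == pytest.approx(
                f["occupancy_pct"][1])
        assert set(manifest.columns) >= {"composition_label", "structure",
                                         "trajectory", "replicate"}


class TestDoseResponse:
    def test_zero_noise_is_exact(self):
        total, ptx, truth = generate_dose_response(noise_sd=0.0,
                                                   n_replicates=1, seed=0)
        np.testing.assert_allclose(total.responses,
                                   truth.total(total.concentrations_m))
        np.testing.assert_allclose(ptx.responses,
                                   truth.stimulatory(ptx.concentrations_m))

    def test_default_truth_has_tenfold_ec50_separation(self):
        _, _, truth = generate_dose_response(seed=0)
        assert truth.ec50_i_m / truth.ec50_s_m == pytest.approx(10.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_response(noise_sd=-1.0)
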