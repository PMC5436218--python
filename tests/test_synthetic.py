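"""CTMC generator: exact sampling, calibration, rendering, adaptive respawn."""

import numpy as np
import pytest

from plqex import events as ev
from plqex import synthetic_data as sd


def _two_state_model(k12=1.0, k21=3.0):
    states = sd.build_states(0)  # just the two bulk leaflets
    Q = np.array([[-k12, k12], [k21, -k21]])
    return sd.CompartmentModel(states=states, Q=Q, n_ligands=1000)


class TestSimulateCTMC:
    def test_zero_rates_freeze_every_ligand(self):
        states = sd.build_states(1)
        model = sd.CompartmentModel(states=states, Q=np.zeros((len(states),) * 2),
                                    n_ligands=5)
        sim = sd.simulate_ctmc(model, 10.0, seed=0)
        assert all(len(p.states) == 1 for p in sim.paths)

    def test_invalid_rate_matrices_are_rejected(self):
        states = sd.build_states(1)
        Q = np.zeros((len(states),) * 2)
        Q[0, 0] = 1.0  # rows no longer sum to zero
        with pytest.raises(sd.SyntheticError):
            sd.CompartmentModel(states=states, Q=Q, n_ligands=1)
        Q = np.zeros((len(states),) * 2)
        # bulk -> Q_B is not physically adjacent
        qb = next(i for i, s in enumerate(states) if s.kind == "QB")
        Q[0, qb] = 1.0
        Q[0, 0] = -1.0
        with pytest.raises(sd.SyntheticError, match="adjacent"):
            sd.CompartmentModel(states=states, Q=Q, n_ligands=1)

    def test_two_state_occupancy_matches_stationary_law(self):
        # k12=1, k21=3: stationary occupancy of state 1 is k21/(k12+k21)=0.75
        model = _two_state_model()
        sim = sd.simulate_ctmc(model, 100.0, seed=5)
        fractions = []
        for p in sim.paths:
            bounds = np.append(p.times, 100.0)
            dwell = np.diff(bounds)
            fractions.append(dwell[p.states == 0].sum() / 100.0)
        fractions = np.asarray(fractions)
        sem = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - 0.75) <= 3 * sem

    def test_dwell_times_are_exponential(self):
        from scipy.stats import kstest

        model = _two_state_model(k12=1.0, k21=3.0)
        sim = sd.simulate_ctmc(model, 50.0, seed=7)
        dwells = []
        for p in sim.paths:
            ends = p.times[1:]
            starts = p.times[:-1]
            for s, t0, t1 in zip(p.states[:-1], starts, ends):
                if s == 0:
                    dwells.append(t1 - t0)
            if len(dwells) >= 1000:
                break
        stat = kstest(dwells[:1000], "expon", args=(0, 1.0))  # total exit rate 1
        assert stat.pvalue > 0.01

    def test_seed_determinism_is_bitwise(self):
        model = sd.psii_exchange_model(n_ligands=4, duration_us=5.0, rate_scale=4.0,
                                    calibrate=False)
        a = sd.simulate_ctmc(model, 5.0, seed=3)
        b = sd.simulate_ctmc(model, 5.0, seed=3)
        for pa, pb in zip(a.paths, b.paths):
            assert np.array_equal(pa.states, pb.states)
            assert np.array_equal(pa.times, pb.times)
        ta, _, _ = sd.render_simulation(a)
        tb, _, _ = sd.render_simulation(b)
        assert np.array_equal(ta.positions, tb.positions)

    def test_adding_ligands_preserves_existing_substreams(self):
        base = sd.psii_exchange_model(n_ligands=8, duration_us=5.0, calibrate=False)
        model4 = sd.CompartmentModel(states=base.states, Q=base.Q, n_ligands=4)
        model8 = sd.CompartmentModel(states=base.states, Q=base.Q, n_ligands=8)
        a = sd.simulate_ctmc(model4, 5.0, seed=11)
        b = sd.simulate_ctmc(model8, 5.0, seed=11)
        for pa, pb in zip(a.paths, b.paths[:4]):
            assert np.array_equal(pa.states, pb.states)
            assert np.array_equal(pa.times, pb.times)


class TestCalibration:
    def test_expected_fluxes_hit_the_configured_targets(self):
        model = sd.psii_exchange_model(n_ligands=24, duration_us=95.0)
        flux = model.expected["flux_ms_per_monomer"]
        targets = {"in_I": 10.0, "in_II": 1.0, "in_III": 8.0,
                   "out_I": 4.0, "out_II": 1.0, "out_III": 6.0}
        for key, target in targets.items():
            assert flux[key] == pytest.approx(target, rel=1e-4)

    def test_flip_rates_follow_the_preset_timescales(self):
        model = sd.psii_exchange_model(n_ligands=4, duration_us=5.0, calibrate=False)
        # total leaflet-exchange rate: cavity 1/100 us^-1, bulk 1 us^-1
        assert 2 * model.rates["cavity_flip"] == pytest.approx(0.01)
        assert 2 * model.rates["bulk_flip"] == pytest.approx(1.0)


class TestRendering:
    def _model(self, **kw):
        return sd.psii_exchange_model(n_ligands=1, duration_us=10.0, calibrate=False, **kw)

    def test_permanent_cavity_resident_labels_cavity(self):
        model = self._model()
        cav = model.index(kind="CAVITY", leaflet="stromal", monomer=0)
        paths = [sd.LigandPath(states=np.array([cav]), times=np.array([0.0]),
                               duration_us=10.0)]
        scene = sd.default_scene(2)
        traj, rm, _ = sd.render_trajectory(paths, model, scene, seed=1)
        traces = ev.label_trace(traj, rm, scene.model)
        labels = {str(scene.model.labels[c]) for c in traces["lig000"].codes}
        assert labels == {"CAVITY@0"}

    def test_scripted_transit_recovers_one_full_entry(self):
        model = self._model()
        b = model.index(kind="BULK", leaflet="stromal")
        ch = model.index(kind="CHANNEL", channel="I", monomer=0)
        cav = model.index(kind="CAVITY", leaflet="stromal", monomer=0)
        paths = [sd.LigandPath(states=np.array([b, ch, cav]),
                               times=np.array([0.0, 3.0, 6.0]), duration_us=10.0)]
        scene = sd.default_scene(2)
        traj, rm, _ = sd.render_trajectory(paths, model, scene, seed=2)
        traces = ev.label_trace(traj, rm, scene.model)
        events = ev.detect_passages(traces["lig000"])
        full = [e for e in events if e.completeness == "full"]
        assert [(e.direction, e.channel, e.monomer) for e in full] == [("in", "I", 0)]

    def test_rendered_coordinates_stay_inside_the_box(self):
        model = sd.psii_exchange_model(n_ligands=10, duration_us=10.0, rate_scale=4.0,
                                    calibrate=False)
        sim = sd.simulate_ctmc(model, 10.0, seed=4)
        traj, rm, scene = sd.render_simulation(sim)
        assert np.all(traj.positions >= 0)
        assert np.all(traj.positions <= scene.box + 1e-6)

    def test_scripted_orientation_is_recovered(self):
        model = self._model()
        b = model.index(kind="BULK", leaflet="stromal")
        ch = model.index(kind="CHANNEL", channel="I", monomer=0)
        cav = model.index(kind="CAVITY", leaflet="stromal", monomer=0)
        path = sd.LigandPath(states=np.array([b, ch, cav]),
                             times=np.array([0.0, 4.0, 8.0]), duration_us=12.0)
        scene = sd.default_scene(2)
        for lead_prob, expected in ((1.0, "head_first"), (0.0, "tail_first")):
            traj, rm, leads = sd.render_trajectory([path], model, scene, seed=6,
                                                   head_lead_prob=lead_prob,
                                                   tail_lag_ns=8.0)
            traces = ev.label_trace(traj, rm, scene.model)
            events = ev.detect_passages(traces["lig000"])
            full = [e for e in events if e.completeness == "full"]
            assert len(full) == 1
            got = ev.classify_orientation(traj, full[0], rm, scene.model)
            assert got == expected
            assert leads["lig000"] == ("head" if lead_prob else "tail")


class TestGroundTruthFidelity:
    def test_full_transits_recovered_with_high_sensitivity_and_precision(self):
        model = sd.psii_exchange_model(n_ligands=24, duration_us=25.0, rate_scale=6.0)
        pooled = {"n_true": 0, "n_recovered": 0, "n_matched": 0}
        for seed in range(3):
            sim = sd.simulate_ctmc(model, 25.0, seed=300 + seed)
            traj, rm, scene = sd.render_simulation(sim)
            traces = ev.label_trace(traj, rm, scene.model)
            passages = ev.detect_passages_all(traces)
            res = sd.match_passages(sim.ground_truth, passages)
            for k in pooled:
                pooled[k] += res[k]
        assert pooled["n_true"] > 10
        assert pooled["n_matched"] / pooled["n_true"] >= 0.95
        assert pooled["n_matched"] / pooled["n_recovered"] >= 0.95

    def test_cavity_flipflop_rate_recovered_within_three_se(self):
        # flips are Poisson in total cavity residence: at ~600 expected
        # events the configured rate must come back within 3 sqrt(N)
        model = sd.psii_exchange_model(n_ligands=20, duration_us=300.0,
                                    cavity_flip_per_us=0.05, calibrate=False)
        cav_s = model.index(kind="CAVITY", leaflet="stromal", monomer=0)
        cav_l = model.index(kind="CAVITY", leaflet="lumenal", monomer=0)
        # confine every ligand to the cavity: only flip rates are active
        S = model.n_states
        Q = np.zeros((S, S))
        Q[cav_s, cav_l] = Q[cav_l, cav_s] = 0.05
        Q[cav_s, cav_s] = Q[cav_l, cav_l] = -0.05
        confined = sd.CompartmentModel(states=model.states, Q=Q, n_ligands=20)
        rng_states = [cav_s, cav_l]
        paths = []
        for li, rng in enumerate(sd._ligand_rngs(77, 20)):
            st, tt = sd._gillespie(Q, rng_states[li % 2], 300.0, rng)
            paths.append(sd.LigandPath(states=st, times=tt, duration_us=300.0))
        scene = sd.default_scene(2)
        traj, rm, _ = sd.render_trajectory(paths, confined, scene, seed=78,
                                           render_tails=False)
        traces = ev.label_trace(traj, rm, scene.model)
        n_events = sum(len(ev.detect_flipflops(tr, scene.model)) for tr in traces.values())
        residence_us = 20 * 300.0
        from plqex.stats import estimate_timescale

        est = estimate_timescale(n_events, residence_us)
        expected_rate = 0.05  # per us, per direction ( = total switch rate here)
        lam = expected_rate * residence_us
        assert abs(n_events - lam) <= 3 * np.sqrt(lam)
        assert est.value_us == pytest.approx(1 / expected_rate,
                                             rel=3 * np.sqrt(lam) / lam)


class TestAdaptiveRespawn:
    def test_single_round_spawns_only_from_the_initial_state(self):
        model = sd.rare_binding_model()
        eng = sd.CTMCEngine(model, model.index(kind="QB"))
        sel = sd.distance_selector(model, model.index(kind="QB"))
        init = model.index(kind="BULK", leaflet="stromal")
        rep = sd.adaptive_respawn(eng, sel, n_rounds=1, k_select=8,
                                  spawn_len_us=2.0, seed=1, run_baseline=False)
        assert rep.start_states == [[init] * 8]

    def test_zero_k_select_is_an_error(self):
        model = sd.rare_binding_model()
        eng = sd.CTMCEngine(model, model.index(kind="QB"))
        with pytest.raises(sd.SyntheticError):
            sd.adaptive_respawn(eng, lambda s: 0, n_rounds=1, k_select=0,
                                spawn_len_us=1.0, seed=0)

    def test_distance_selector_orders_states_by_hops_to_target(self):
        model = sd.rare_binding_model()
        target = model.index(kind="QB")
        sel = sd.distance_selector(model, target)
        assert sel(target) == 0
        assert sel(model.index(kind="CAVITY", leaflet="stromal", monomer=0)) == 1
        assert sel(model.index(kind="CHANNEL", channel="I", monomer=0)) == 2
        assert sel(model.index(kind="BULK", leaflet="stromal")) == 3


def test_dataset_round_trip_through_the_trajectory_layer(tmp_path):
    from plqex.trajio import RoleMap, read_trajectory

    model = sd.psii_exchange_model(n_ligands=3, duration_us=2.0, rate_scale=4.0,
                                calibrate=False)
    sim = sd.simulate_ctmc(model, 2.0, seed=21)
    traj, rm, scene = sd.render_simulation(sim, stride_ns=2.0)
    paths = sd.write_dataset(tmp_path, traj, rm, scene.model, sim.ground_truth)
    rm2 = RoleMap.from_yaml(paths["role_map"])
    traj2 = read_trajectory(None, paths["trajectory"], rm2)
    assert traj2.n_frames == traj.n_frames
    assert sorted(rm2.ligands) == sorted(rm.ligands)
    head = traj.head_path(rm, "lig000")
    head2 = traj2.head_path(rm2, "lig000")
    assert np.allclose(head, head2, atol=1e-4)  # TSV written at 1e-5 precision
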