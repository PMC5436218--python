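"""Hysteresis labeling and passage / flip-flop / unbinding detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plqex.events import (DEFAULT_HYSTERESIS_NM, classify_orientation,
                          detect_flipflops, detect_passages, detect_unbinding,
                          label_positions, label_trace)
from plqex.trajio import LigandRoles, RoleMap

from conftest import make_trace, simple_role_map, traj_from_paths

# single-monomer alphabet for random label sequences
ALPHABET = ["BULK", "OFF", "CHANNEL_I@0", "CHANNEL_II@0", "CHANNEL_III@0", "CAVITY@0"]


# ---------------------------------------------------------------------------
# labeling with hysteresis

class TestLabelHysteresis:
    def test_static_cavity_point_labels_constant(self, toy_model):
        pts = np.tile([6.0, 6.0, 5.0], (100, 1))
        codes = label_positions(pts, np.arange(100) * 0.5, toy_model, 0.3)
        assert all(str(toy_model.labels[c]) == "CAVITY@0" for c in codes)

    def test_subthreshold_gate_flicker_is_suppressed(self, toy_model):
        # oscillate +-delta/4 across channel I's inner gate (x = 4)
        delta = 0.3
        x = 4.0 + (delta / 4) * np.sin(np.arange(200))
        pts = np.column_stack([x, np.full(200, 6.0), np.full(200, 5.0)])
        codes = label_positions(pts, np.arange(200) * 0.5, toy_model, delta)
        assert len(set(codes.tolist())) == 1

    def test_zero_delta_equals_raw_locate(self, toy_model, rng):
        # random walk through the monomer-0 neighbourhood
        pts = np.cumsum(rng.normal(0, 0.4, (500, 3)), axis=0) + [5.0, 5.0, 5.0]
        codes = label_positions(pts, np.arange(500) * 0.5, toy_model, 0.0)
        assert np.array_equal(codes, toy_model.locate_batch(pts))

    def test_deep_crossing_is_accepted(self, toy_model):
        # straight path from bulk through channel I into the cavity
        x = np.linspace(1.5, 7.0, 120)
        pts = np.column_stack([x, np.full(120, 6.0), np.full(120, 5.0)])
        codes = label_positions(pts, np.arange(120) * 0.5, toy_model, 0.3)
        labels = [str(toy_model.labels[c]) for c in codes]
        seen = [lab for i, lab in enumerate(labels) if i == 0 or lab != labels[i - 1]]
        assert seen == ["BULK", "CHANNEL_I@0", "CAVITY@0"]


# ---------------------------------------------------------------------------
# passages

def oracle_events(labels, times, min_dwell=0.0):
    """Independent excursion-scanning oracle (explicit state machine).

    Walks the label sequence once, tracking the last side occupancy, and
    classifies every bulk->...->cavity / cavity->...->bulk excursion.
    Returns a sorted list of (direction, completeness) tuples.
    """
    def side(lab):
        if lab.startswith("CHANNEL"):
            return "chan"
        if lab.startswith("CAVITY") or lab.startswith("SITE"):
            return "cavity"
        return "bulk"

    out = []
    last_side_idx = None
    for i, lab in enumerate(labels):
        s = side(lab)
        if s == "chan":
            continue
        if last_side_idx is None:
            if i > 0:  # trace began inside a channel
                out.append(("in" if s == "cavity" else "out", "trapped"))
        else:
            prev = side(labels[last_side_idx])
            if i > last_side_idx + 1:  # channel frames in between
                if prev == s:
                    if times[i] - times[last_side_idx] >= min_dwell:
                        out.append(("in" if prev == "bulk" else "out", "partial"))
                else:
                    out.append(("in" if s == "cavity" else "out", "full"))
            elif prev != s:
                out.append(("in" if s == "cavity" else "out", "full"))
        last_side_idx = i
    if last_side_idx is None and len(labels) > 0:
        out.append(("in", "trapped"))
    elif last_side_idx is not None and last_side_idx < len(labels) - 1:
        prev = side(labels[last_side_idx])
        out.append(("out" if prev == "cavity" else "in", "trapped"))
    return sorted(out)


class TestDetectPassages:
    def test_canonical_full_entry(self, toy_model):
        trace = make_trace(toy_model, ["BULK", "BULK", "CHANNEL_I@0", "CHANNEL_I@0",
                                       "CAVITY@0"])
        events = detect_passages(trace, min_dwell_ns=0.0)
        assert len(events) == 1
        ev = events[0]
        assert (ev.direction, ev.completeness, ev.channel, ev.monomer) == \
            ("in", "full", "I", 0)
        assert ev.t_start_ns == 0.5 and ev.t_end_ns == 2.0

    def test_retreat_is_partial(self, toy_model):
        trace = make_trace(toy_model, ["BULK", "CHANNEL_I@0", "BULK"])
        events = detect_passages(trace, min_dwell_ns=0.0)
        assert [(e.direction, e.completeness) for e in events] == [("in", "partial")]

    def test_channel_at_trace_end_is_trapped(self, toy_model):
        trace = make_trace(toy_model, ["CAVITY@0", "CHANNEL_II@0", "CHANNEL_II@0"])
        events = detect_passages(trace, min_dwell_ns=0.0)
        assert [(e.direction, e.completeness) for e in events] == [("out", "trapped")]
        assert events[0].origin_side == "cavity" and events[0].dest_side is None

    def test_recrossings_do_not_fragment_one_transit(self, toy_model):
        # wiggle at the outer gate mid-transit is still a single full entry
        labels = ["BULK", "CHANNEL_I@0", "CHANNEL_I@0", "CHANNEL_I@0", "CAVITY@0"]
        events = detect_passages(make_trace(toy_model, labels), min_dwell_ns=0.0)
        assert [(e.direction, e.completeness) for e in events] == [("in", "full")]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=60))
    def test_matches_excursion_scanning_oracle(self, labels):
        model = toy_geometry_cached()
        trace = make_trace(model, labels)
        events = detect_passages(trace, min_dwell_ns=0.0)
        got = sorted((e.direction, e.completeness) for e in events)
        assert got == oracle_events(labels, trace.times)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=60))
    def test_time_reversal_swaps_entries_and_exits(self, labels):
        model = toy_geometry_cached()
        fwd = detect_passages(make_trace(model, labels), min_dwell_ns=0.0)
        rev = detect_passages(make_trace(model, labels[::-1]), min_dwell_ns=0.0)
        def count(evs, d, c="full"):
            return sum(1 for e in evs if e.direction == d and e.completeness == c)
        assert count(fwd, "in") == count(rev, "out")
        assert count(fwd, "out") == count(rev, "in")
        assert len(fwd) == len(rev)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(ALPHABET + ["CAVITY@1", "CHANNEL_I@1"]),
                    min_size=1, max_size=60))
    def test_cavity_balance_identity_on_arbitrary_sequences(self, labels):
        from plqex.stats import conservation_audit

        model = toy_geometry_cached()
        trace = make_trace(model, labels)
        events = detect_passages(trace, min_dwell_ns=0.0)
        report = conservation_audit({"lig": trace}, events)
        assert report.ok, report.violations

    def test_min_dwell_never_drops_full_events(self, toy_model):
        labels = ["BULK", "CHANNEL_I@0", "CAVITY@0", "CHANNEL_II@0", "CAVITY@0",
                  "CHANNEL_III@0", "BULK"]
        for dwell in (0.0, 1.0, 10.0, 1000.0):
            events = detect_passages(make_trace(toy_model, labels), dwell)
            assert sum(1 for e in events if e.completeness == "full") == 2

    def test_min_dwell_filters_short_partials(self, toy_model):
        labels = ["BULK", "CHANNEL_I@0", "BULK"]  # 1-frame excursion (1.0 ns)
        assert len(detect_passages(make_trace(toy_model, labels), 0.5)) == 1
        assert len(detect_passages(make_trace(toy_model, labels), 5.0)) == 0


def toy_geometry_cached():
    global _TOY
    try:
        return _TOY
    except NameError:
        from plqex.synthetic_data import toy_geometry
        _TOY = toy_geometry(2)
        return _TOY


# ---------------------------------------------------------------------------
# orientation

def _orientation_setup(toy_model, head_cross_frame, tail_cross_frame, n=30):
    """Entry through channel I of monomer 0; outer gate at x = 3."""
    from plqex.events import PassageEvent

    times = np.arange(n) * 0.5
    def path(cross):
        x = np.where(np.arange(n) >= cross, 3.5, 2.0)
        return np.column_stack([x, np.full(n, 6.0), np.full(n, 5.0)])
    beads = {"H": path(head_cross_frame), "T1": path(tail_cross_frame),
             "T2": path(tail_cross_frame)}
    traj = traj_from_paths(times, beads)
    rm = RoleMap(ligands={"lig": LigandRoles(head_beads=("H",),
                                             tail_beads=("T1", "T2"))})
    event = PassageEvent(ligand="lig", monomer=0, channel="I", direction="in",
                         completeness="full", t_start_ns=0.0, t_end_ns=times[-1])
    return traj, event, rm


class TestOrientation:
    def test_head_crossing_first_is_head_first(self, toy_model):
        traj, event, rm = _orientation_setup(toy_model, 10, 12)
        assert classify_orientation(traj, event, rm, toy_model) == "head_first"

    def test_tail_crossing_first_is_tail_first(self, toy_model):
        traj, event, rm = _orientation_setup(toy_model, 12, 10)
        assert classify_orientation(traj, event, rm, toy_model) == "tail_first"

    def test_same_frame_crossing_is_undetermined(self, toy_model):
        traj, event, rm = _orientation_setup(toy_model, 10, 10)
        assert classify_orientation(traj, event, rm, toy_model) == "undetermined"

    def test_missing_tail_beads_warns_and_is_undetermined(self, toy_model):
        traj, event, rm = _orientation_setup(toy_model, 10, 12)
        rm2 = RoleMap(ligands={"lig": LigandRoles(head_beads=("H",))})
        with pytest.warns(UserWarning, match="tail"):
            assert classify_orientation(traj, event, rm2, toy_model) == "undetermined"

    def test_swapping_head_and_tail_roles_flips_the_call(self, toy_model):
        traj, event, rm = _orientation_setup(toy_model, 10, 12)
        swapped = RoleMap(ligands={"lig": LigandRoles(head_beads=("T1", "T2"),
                                                      tail_beads=("H",))})
        assert classify_orientation(traj, event, rm, toy_model) == "head_first"
        assert classify_orientation(traj, event, swapped, toy_model) == "tail_first"


# ---------------------------------------------------------------------------
# flip-flops

class TestFlipFlops:
    def test_clean_crossing_fires_once(self, toy_model):
        z = np.concatenate([np.full(50, 6.0), np.full(50, 4.0)])
        trace = make_trace(toy_model, ["CAVITY@0"] * 100, z=z)
        events = detect_flipflops(trace, toy_model, delta_z_nm=0.3)
        assert len(events) == 1
        ev = events[0]
        assert (ev.compartment, ev.from_leaflet, ev.to_leaflet) == \
            ("cavity", "stromal", "lumenal")

    def test_subthreshold_oscillation_is_silent(self, toy_model):
        z = 5.0 + 0.2 * np.sin(np.arange(200))
        trace = make_trace(toy_model, ["CAVITY@0"] * 200, z=z)
        assert detect_flipflops(trace, toy_model, delta_z_nm=0.3) == []

    def test_compartment_exit_resets_the_detector(self, toy_model):
        # above midplane in the cavity, through a channel, below in bulk:
        # no flip is counted because the compartment changed in between
        labels = ["CAVITY@0"] * 10 + ["CHANNEL_I@0"] * 5 + ["BULK"] * 10
        z = np.concatenate([np.full(10, 6.0), np.full(5, 5.0), np.full(10, 4.0)])
        trace = make_trace(toy_model, labels, z=z)
        assert detect_flipflops(trace, toy_model, delta_z_nm=0.3) == []

    def test_telegraph_counts_follow_poisson_statistics(self, toy_model):
        # two-state telegraph z process at rate k per leg: the switch count
        # over T is Poisson(kT); pooled counts over seeds must sit in the
        # central 95% band
        from scipy.stats import poisson

        k, T, n_seeds = 0.05, 400.0, 20  # per ns, ns
        total = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t, s, switch_times = 0.0, 1, []
            while True:
                t += rng.exponential(1.0 / k)
                if t >= T:
                    break
                switch_times.append(t)
                s = -s
            times = np.arange(0, T, 0.5)
            sign = 1 - 2 * (np.searchsorted(switch_times, times) % 2)
            z = 5.0 + sign * 1.0 + rng.normal(0, 0.05, len(times))
            trace = make_trace(toy_model, ["CAVITY@0"] * len(times), z=z)
            total += len(detect_flipflops(trace, toy_model, delta_z_nm=0.3))
        lam = k * T * n_seeds
        assert poisson.ppf(0.025, lam) <= total <= poisson.ppf(0.975, lam)


# ---------------------------------------------------------------------------
# unbinding

def _unbinding_traj(d_path, tail_xy=None, toy=None):
    """Head at distance d from the monomer-0 site centre (6, 6, 5.5)."""
    n = len(d_path)
    head = np.column_stack([6.0 + np.asarray(d_path), np.full(n, 6.0),
                            np.full(n, 5.5)])
    if tail_xy is None:
        tail = head.copy()
    else:
        tail = np.asarray(tail_xy, float)
    traj = traj_from_paths(np.arange(n) * 0.5, {"H": head, "T1": tail})
    rm = RoleMap(ligands={"lig": LigandRoles(head_beads=("H",), tail_beads=("T1",))})
    return traj, rm


class TestUnbinding:
    def test_clean_escape_is_full(self, toy_model):
        d = np.concatenate([np.full(20, 0.3), np.full(200, 2.5)])
        traj, rm = _unbinding_traj(d)
        events = detect_unbinding(traj, toy_model, rm, 0.6, 1.2, t_rebind_ns=50.0,
                                  monomer=0)
        assert [e.type for e in events] == ["full"]

    def test_rapid_rebinding_is_transient(self, toy_model):
        # leaves to 1.5 nm for 5 ns, then returns to 0.4 nm
        d = np.concatenate([np.full(20, 0.3), np.full(10, 1.5), np.full(50, 0.4)])
        traj, rm = _unbinding_traj(d)
        events = detect_unbinding(traj, toy_model, rm, 0.6, 1.2, t_rebind_ns=50.0,
                                  monomer=0)
        assert [e.type for e in events] == ["transient"]
        assert events[0].rebind_t_ns is not None

    def test_tail_release_with_bound_head_is_partial(self, toy_model):
        n = 60
        d = np.full(n, 0.4)
        # tail starts inside channel II's interior and slides out into the cavity
        tail = np.column_stack([np.full(n, 5.25),
                                np.where(np.arange(n) < 30, 3.5, 6.0),
                                np.full(n, 5.0)])
        traj, rm = _unbinding_traj(d, tail_xy=tail)
        events = detect_unbinding(traj, toy_model, rm, 0.6, 1.2, t_rebind_ns=50.0,
                                  monomer=0)
        assert [e.type for e in events] == ["partial"]

    def test_bad_thresholds_and_missing_site_error(self, toy_model):
        traj, rm = _unbinding_traj(np.full(10, 0.3))
        with pytest.raises(ValueError):
            detect_unbinding(traj, toy_model, rm, 1.2, 0.6)
        cfg_model = toy_model
        with pytest.raises(ValueError):
            detect_unbinding(traj, cfg_model, rm, 0.6, 1.2, monomer=5)


# ---------------------------------------------------------------------------
# jitter robustness (hysteresis property)

def test_jitter_below_half_delta_preserves_full_event_counts(toy_model, rng):
    # clean piecewise path bulk -> channel I -> cavity -> channel III -> bulk
    segs = [([1.5, 6.0, 5.0], [3.5, 6.0, 5.0], 60), ([3.5, 6.0, 5.0], [6.0, 6.0, 5.0], 60),
            ([6.0, 6.0, 5.0], [6.75, 3.5, 5.0], 60), ([6.75, 3.5, 5.0], [6.75, 1.5, 5.0], 60)]
    pts = np.concatenate([np.linspace(a, b, n) for a, b, n in segs])
    times = np.arange(len(pts)) * 0.5
    clean = label_positions(pts, times, toy_model, DEFAULT_HYSTERESIS_NM)

    def full_count(codes):
        trace = make_trace(toy_model, [str(toy_model.labels[c]) for c in codes])
        return sum(1 for e in detect_passages(trace, 0.0) if e.completeness == "full")

    base = full_count(clean)
    assert base == 2  # one entry, one exit
    for _ in range(10):
        jitter = rng.uniform(-DEFAULT_HYSTERESIS_NM / 2 * 0.95,
                             DEFAULT_HYSTERESIS_NM / 2 * 0.95, pts.shape)
        noisy = label_positions(pts + jitter, times, toy_model, DEFAULT_HYSTERESIS_NM)
        assert full_count(noisy) == base
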