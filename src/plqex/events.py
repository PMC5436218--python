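"""Event detection: hysteresis state traces, channel passages, flip-flops,
and binding-site unbinding.

State labeling uses two-threshold hysteresis to suppress boundary flicker: a
raw label change is accepted only once the head bead has moved at least
``delta`` nm past the decision boundary between the old and the new region.
Because region overlap is resolved by priority, that boundary is the boundary
of whichever of the two regions ranks higher — entering a higher-priority
region requires penetrating ``delta`` into it, while leaving one requires
moving ``delta`` beyond its boundary.

Passage bookkeeping partitions each ligand trace into *side* occupancies
(bulk-side: bulk membrane, off-membrane, protein surface; cavity-side:
exchange cavity, binding site) separated by channel excursions.  Every
excursion whose two endpoints lie on opposite sides is a full passage;
same-side excursions are partial; excursions cut off by the start or end of
the trace are trapped.  Full passages are never filtered by dwell time, which
makes the cavity balance Delta(cavity) = entries - exits (+ trapped
corrections) an exact identity on any trace; the ``min_dwell_ns`` threshold
only drops sub-threshold partial excursions (single-frame gate flicker).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryModel, STROMAL, LUMENAL
from .trajio import RoleMap, Trajectory

__all__ = [
    "StateTrace",
    "PassageEvent",
    "FlipFlopEvent",
    "UnbindingEvent",
    "label_trace",
    "label_positions",
    "detect_passages",
    "classify_orientation",
    "annotate_orientations",
    "detect_flipflops",
    "detect_unbinding",
    "events_to_frame",
    "write_events_tsv",
    "DEFAULT_HYSTERESIS_NM",
    "DEFAULT_MIN_DWELL_NS",
]

# ~ one CG bead radius: suppress single-frame flicker at a 500 ps stride
DEFAULT_HYSTERESIS_NM = 0.3
DEFAULT_MIN_DWELL_NS = 1.0
DEFAULT_FLIPFLOP_DELTA_Z_NM = 0.3

_LEAFLET_CODE = {None: 0, STROMAL: 1, LUMENAL: 2}
_LEAFLET_NAME = {0: None, 1: STROMAL, 2: LUMENAL}

# side categories for passage bookkeeping
_SIDE_BULK, _SIDE_CAVITY, _SIDE_CHANNEL = 0, 1, 2
_KIND_SIDE = {"OFF": _SIDE_BULK, "BULK": _SIDE_BULK, "PROTEIN": _SIDE_BULK,
              "SITE": _SIDE_CAVITY, "CAVITY": _SIDE_CAVITY, "CHANNEL": _SIDE_CHANNEL}


@dataclass
class StateTrace:
    """Per-ligand compartment labels after hysteresis, on the frame grid."""

    ligand: str
    times: np.ndarray  # (F,) ns
    codes: np.ndarray  # (F,) int16 label codes into model.labels
    leaflets: np.ndarray  # (F,) int8: 0 none, 1 stromal, 2 lumenal
    z: np.ndarray  # (F,) head z, nm (kept for flip-flop detection)
    model: GeometryModel

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.codes < 0) or np.any(self.codes >= len(self.model.labels)):
            raise ValueError("trace contains labels outside the model's label set")

    @property
    def labels(self) -> list[str]:
        """Human-readable label per frame, with leaflet annotation."""
        out = []
        for c, lf in zip(self.codes, self.leaflets):
            s = str(self.model.labels[c])
            if lf and self.model.labels[c].kind in ("BULK", "CAVITY"):
                s += f":{_LEAFLET_NAME[lf]}"
            out.append(s)
        return out


@dataclass(frozen=True)
class PassageEvent:
    """One channel excursion: full transit, partial retreat, or trapped."""

    ligand: str
    monomer: int | None
    channel: str | None  # None when the trace jumps sides with no channel frame
    direction: str  # in | out
    completeness: str  # full | partial | trapped
    t_start_ns: float
    t_end_ns: float
    orientation: str = "undetermined"  # head_first | tail_first | undetermined
    origin_side: str | None = None  # bulk | cavity | None (trace start)
    dest_side: str | None = None  # bulk | cavity | None (trace end)

    def __post_init__(self):
        if self.t_start_ns > self.t_end_ns:
            raise ValueError("event requires t_start <= t_end")


@dataclass(frozen=True)
class FlipFlopEvent:
    ligand: str
    compartment: str  # cavity | bulk
    monomer: int | None
    from_leaflet: str
    to_leaflet: str
    time_ns: float

    def __post_init__(self):
        if self.from_leaflet == self.to_leaflet:
            raise ValueError("flip-flop requires distinct leaflets")


@dataclass(frozen=True)
class UnbindingEvent:
    ligand: str
    site: str
    type: str  # full | transient | partial
    t_ns: float
    rebind_t_ns: float | None = None

    def __post_init__(self):
        if self.type == "transient" and self.rebind_t_ns is None:
            raise ValueError("transient unbinding requires a rebinding time")


# ---------------------------------------------------------------------------
# state labeling with hysteresis

def label_positions(points: np.ndarray, times: np.ndarray, model: GeometryModel,
                    hysteresis_delta_nm: float = DEFAULT_HYSTERESIS_NM) -> np.ndarray:
    """Hysteresis-filtered label codes for one head-bead path."""
    if hysteresis_delta_nm < 0:
        raise ValueError("hysteresis delta must be >= 0")
    pts = np.asarray(points, dtype=float)
    raw = model.locate_batch(pts)
    if hysteresis_delta_nm == 0 or len(raw) == 0:
        return raw
    ranks = model.ranks
    out = np.empty_like(raw)
    cur = raw[0]
    # scan runs of constant raw label; hysteresis only matters at run changes
    change = np.flatnonzero(np.diff(raw)) + 1
    bounds = np.concatenate([[0], change, [len(raw)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        cand = raw[s]
        if cand == cur:
            out[s:e] = cur
            continue
        if ranks[cand] >= ranks[cur]:
            depth = model.depth_into(int(cand), pts[s:e])
        else:
            depth = model.depth_out_of(int(cur), pts[s:e])
        ok = depth >= hysteresis_delta_nm
        if np.any(ok):
            i = s + int(np.argmax(ok))
            out[s:i] = cur
            out[i:e] = cand
            cur = cand
        else:
            out[s:e] = cur
    return out


def label_trace(traj: Trajectory, role_map: RoleMap, model: GeometryModel,
                hysteresis_delta_nm: float = DEFAULT_HYSTERESIS_NM) -> dict[str, StateTrace]:
    """Hysteresis state trace per ligand, from head-bead centroids.

    Leaflet annotation (for BULK/CAVITY frames) is taken from the raw head z
    against the compartment midplane; flip-flop detection applies its own
    z hysteresis, so the annotation itself is unfiltered.
    """
    traces: dict[str, StateTrace] = {}
    kinds = np.array([lab.kind for lab in model.labels])
    monomers = np.array([-1 if lab.monomer is None else lab.monomer for lab in model.labels])
    for ligand in role_map.ligands:
        head = traj.head_path(role_map, ligand)
        codes = label_positions(head, traj.times, model, hysteresis_delta_nm)
        z = head[:, 2]
        leaflets = np.zeros(len(codes), dtype=np.int8)
        k = kinds[codes]
        in_bulk = k == "BULK"
        in_cav = k == "CAVITY"
        mid = np.full(len(codes), model.midplane)
        if np.any(in_cav):
            for m in np.unique(monomers[codes[in_cav]]):
                mid[in_cav & (monomers[codes] == m)] = model.compartment_mid_z("CAVITY", int(m))
        sel = in_bulk | in_cav
        leaflets[sel] = np.where(z[sel] > mid[sel], 1, 2)
        traces[ligand] = StateTrace(ligand=ligand, times=traj.times, codes=codes,
                                    leaflets=leaflets, z=z, model=model)
    return traces


# ---------------------------------------------------------------------------
# channel passages

def _side_tables(model: GeometryModel):
    side = np.array([_KIND_SIDE[lab.kind] for lab in model.labels], dtype=np.int8)
    mono = np.array([-1 if lab.monomer is None else lab.monomer for lab in model.labels],
                    dtype=np.int16)
    return side, mono


def _majority_channel(codes_gap: np.ndarray, model: GeometryModel):
    """(channel_label, monomer) carried by the plurality of gap frames."""
    if len(codes_gap) == 0:
        return None, None
    vals, counts = np.unique(codes_gap, return_counts=True)
    lab = model.labels[int(vals[np.argmax(counts)])]
    return lab.channel, lab.monomer


def _side_token(code: int, side: np.ndarray, mono: np.ndarray):
    s = side[code]
    return ("cavity", int(mono[code])) if s == _SIDE_CAVITY else ("bulk", None)


def detect_passages(trace: StateTrace, min_dwell_ns: float = DEFAULT_MIN_DWELL_NS
                    ) -> list[PassageEvent]:
    """Channel passage events from one hysteresis-filtered state trace."""
    model = trace.model
    side, mono = _side_tables(model)
    codes = trace.codes
    times = trace.times
    cat = side[codes]
    events: list[PassageEvent] = []
    side_idx = np.flatnonzero(cat != _SIDE_CHANNEL)

    def emit(origin, dest, gap, t0, t1):
        channel, ch_mono = _majority_channel(codes[gap], model)
        if origin is None or dest is None:
            # excursion cut off by the trace boundary -> trapped, not flux
            known = dest if origin is None else origin
            if known is None:  # whole trace inside a channel
                direction = "in"
            else:
                direction = ("in" if known[0] == ("cavity" if origin is None else "bulk")
                             else "out")
            # cavity bookkeeping is per monomer: a trapped leg touching a
            # cavity is attributed to that cavity's monomer
            if known is not None and known[1] is not None:
                monomer = known[1]
            else:
                monomer = ch_mono
            events.append(PassageEvent(
                ligand=trace.ligand, monomer=monomer, channel=channel,
                direction=direction, completeness="trapped",
                t_start_ns=float(t0), t_end_ns=float(t1),
                origin_side=None if origin is None else origin[0],
                dest_side=None if dest is None else dest[0]))
            return
        if origin == dest:
            if len(gap) == 0 or (t1 - t0) < min_dwell_ns:
                return  # sub-threshold flicker
            direction = "in" if origin[0] == "bulk" else "out"
            monomer = ch_mono if ch_mono is not None else origin[1]
            events.append(PassageEvent(
                ligand=trace.ligand, monomer=monomer, channel=channel,
                direction=direction, completeness="partial",
                t_start_ns=float(t0), t_end_ns=float(t1),
                origin_side=origin[0], dest_side=dest[0]))
            return
        # side change: always a full event (exact cavity bookkeeping)
        pieces = []
        if origin[0] == "cavity":
            pieces.append(("out", origin[1]))
        if dest[0] == "cavity":
            pieces.append(("in", dest[1]))
        if not pieces:  # bulk -> bulk with different tokens cannot happen
            return
        for direction, monomer in pieces:
            events.append(PassageEvent(
                ligand=trace.ligand, monomer=monomer,
                channel=channel, direction=direction, completeness="full",
                t_start_ns=float(t0), t_end_ns=float(t1),
                origin_side=origin[0], dest_side=dest[0]))

    if side_idx.size == 0:
        if len(codes) > 0:
            emit(None, None, np.arange(len(codes)), times[0], times[-1])
        return events
    first, last = side_idx[0], side_idx[-1]
    if first > 0:
        emit(None, _side_token(codes[first], side, mono), np.arange(0, first),
             times[0], times[first])
    prev = first
    for i in side_idx[1:]:
        tok_prev = _side_token(codes[prev], side, mono)
        tok_i = _side_token(codes[i], side, mono)
        if i == prev + 1 and tok_i == tok_prev:
            prev = i
            continue
        emit(tok_prev, tok_i, np.arange(prev + 1, i), times[prev], times[i])
        prev = i
    if last < len(codes) - 1:
        emit(_side_token(codes[last], side, mono), None, np.arange(last + 1, len(codes)),
             times[last], times[-1])
    return events


def detect_passages_all(traces: Mapping[str, StateTrace],
                        min_dwell_ns: float = DEFAULT_MIN_DWELL_NS) -> list[PassageEvent]:
    events: list[PassageEvent] = []
    for trace in traces.values():
        events.extend(detect_passages(trace, min_dwell_ns))
    return events


# ---------------------------------------------------------------------------
# orientation

def classify_orientation(traj: Trajectory, event: PassageEvent, role_map: RoleMap,
                         model: GeometryModel, lookback_ns: float = 100.0) -> str:
    """head_first / tail_first by which centroid enters the channel first.

    Entries are judged at the outer gate, exits at the inner gate: the
    crossing frame is the first frame at which the centroid lies inside the
    channel interior on the gate's side.  The search window opens
    ``lookback_ns`` before the event, because the event clock starts from
    the head's state labels — a tail that led the way crossed earlier.
    """
    if event.channel is None or event.monomer is None:
        return "undetermined"
    tails = role_map.ligands[event.ligand].tail_beads
    if not tails:
        warnings.warn(f"ligand {event.ligand} has no tail beads; orientation undetermined")
        return "undetermined"
    spec = model.channel_spec(event.channel, event.monomer)
    gate = spec.outer_gate if event.direction == "in" else spec.inner_gate
    window = ((traj.times >= event.t_start_ns - lookback_ns)
              & (traj.times <= event.t_end_ns))
    if not np.any(window):
        return "undetermined"
    head = traj.head_path(role_map, event.ligand)[window]
    tail = traj.tail_path(role_map, event.ligand)[window]

    def crossing_frame(path):
        # crossing = first arrival inside the channel interior on the
        # interior side of the gate (the bare plane-side test would fire for
        # any point of the membrane beyond the gate plane)
        inside = ((gate.signed_distance(path) <= 0)
                  & spec.interior.contains(path))
        hits = np.flatnonzero(inside)
        return int(hits[0]) if hits.size else None

    fh, ft = crossing_frame(head), crossing_frame(tail)
    if fh is None or ft is None or fh == ft:
        return "undetermined"
    return "head_first" if fh < ft else "tail_first"


def annotate_orientations(events: Iterable[PassageEvent], traj: Trajectory,
                          role_map: RoleMap, model: GeometryModel) -> list[PassageEvent]:
    out = []
    for ev in events:
        if ev.completeness in ("full", "partial"):
            out.append(replace(ev, orientation=classify_orientation(traj, ev, role_map, model)))
        else:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# flip-flops

def detect_flipflops(trace: StateTrace, model: GeometryModel | None = None,
                     delta_z_nm: float = DEFAULT_FLIPFLOP_DELTA_Z_NM) -> list[FlipFlopEvent]:
    """Leaflet reorientation events from the head z coordinate.

    A Schmitt trigger per compartment residence: an event fires when the head
    moves from beyond +delta_z above the compartment midplane to beyond
    -delta_z below it (or vice versa) without leaving the compartment; any
    compartment exit resets the detector.
    """
    model = model or trace.model
    kinds = np.array([lab.kind for lab in model.labels])
    monos = np.array([-1 if lab.monomer is None else lab.monomer for lab in model.labels])
    k = kinds[trace.codes]
    # compartment id per frame: bulk=0 and cavities/site 1+m; -1 elsewhere
    comp = np.full(len(trace.codes), -1, dtype=np.int32)
    comp[k == "BULK"] = 0
    in_cav = (k == "CAVITY") | (k == "SITE")
    comp[in_cav] = 1 + monos[trace.codes[in_cav]]
    events: list[FlipFlopEvent] = []
    change = np.flatnonzero(np.diff(comp)) + 1
    bounds = np.concatenate([[0], change, [len(comp)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        c = comp[s]
        if c < 0:
            continue
        if c == 0:
            mid, name, monomer = model.midplane, "bulk", None
        else:
            monomer = int(c - 1)
            mid, name = model.compartment_mid_z("CAVITY", monomer), "cavity"
        zrel = trace.z[s:e] - mid
        sgn = np.where(zrel >= delta_z_nm, 1, np.where(zrel <= -delta_z_nm, -1, 0))
        idx = np.flatnonzero(sgn != 0)
        if idx.size < 2:
            continue
        flips = np.flatnonzero(np.diff(sgn[idx]) != 0) + 1
        for j in flips:
            frame = s + idx[j]
            to_strom = sgn[idx[j]] > 0
            events.append(FlipFlopEvent(
                ligand=trace.ligand, compartment=name, monomer=monomer,
                from_leaflet=LUMENAL if to_strom else STROMAL,
                to_leaflet=STROMAL if to_strom else LUMENAL,
                time_ns=float(trace.times[frame])))
    return events


# ---------------------------------------------------------------------------
# unbinding

def detect_unbinding(traj: Trajectory, model: GeometryModel, role_map: RoleMap,
                     r_bound_nm: float = 0.6, r_unbound_nm: float = 1.2,
                     t_rebind_ns: float = 50.0, monomer: int | None = None
                     ) -> list[UnbindingEvent]:
    """Binding-site unbinding events via two-threshold distance hysteresis.

    full: the head-site distance exceeds ``r_unbound_nm`` and does not return
    below ``r_bound_nm`` within ``t_rebind_ns``; transient: it does; partial:
    the head stays bound while the tail centroid leaves the channel interior.
    """
    if not r_bound_nm < r_unbound_nm:
        raise ValueError("requires r_bound < r_unbound")
    monomers = ([monomer] if monomer is not None
                else [m for m, mon in enumerate(model.monomers) if mon.site is not None])
    for m in monomers:
        if m < 0 or m >= len(model.monomers) or model.monomers[m].site is None:
            raise ValueError(f"monomer {m} has no binding site in the model")
    events: list[UnbindingEvent] = []
    for m in monomers:
        site = model.monomers[m].site
        center = site.centers[0]
        site_label = f"SITE@{m}"
        chans = model.monomers[m].channels
        for ligand in role_map.ligands:
            head = traj.head_path(role_map, ligand)
            d = np.linalg.norm(head - center, axis=1)
            tail = traj.tail_path(role_map, ligand)
            tail_in = None
            if tail is not None and chans:
                tail_in = np.zeros(len(tail), dtype=bool)
                for ch in chans:
                    tail_in |= ch.interior.contains(tail)
            events.extend(_scan_unbinding(
                ligand, site_label, traj.times, d, tail_in,
                r_bound_nm, r_unbound_nm, t_rebind_ns))
    return events


def _scan_unbinding(ligand, site_label, times, d, tail_in,
                    r_bound, r_unbound, t_rebind) -> list[UnbindingEvent]:
    events: list[UnbindingEvent] = []
    n = len(times)
    i = 0
    bound = False
    excursion_start = None  # time d first exceeded r_unbound while bound
    for i in range(n):
        if not bound:
            if d[i] < r_bound:
                bound = True
                excursion_start = None
            continue
        if excursion_start is None:
            if d[i] > r_unbound:
                excursion_start = times[i]
            elif tail_in is not None and i > 0 and tail_in[i - 1] and not tail_in[i]:
                # head still bound, tail slipped out of the channel
                events.append(UnbindingEvent(ligand, site_label, "partial", float(times[i])))
        else:
            if d[i] < r_bound:
                dt = times[i] - excursion_start
                if dt <= t_rebind:
                    events.append(UnbindingEvent(ligand, site_label, "transient",
                                                 float(excursion_start),
                                                 rebind_t_ns=float(times[i])))
                    excursion_start = None  # still bound
                else:
                    events.append(UnbindingEvent(ligand, site_label, "full",
                                                 float(excursion_start)))
                    excursion_start = None  # rebound later: treat as fresh binding
    if bound and excursion_start is not None:
        # left and never came back within the trace
        events.append(UnbindingEvent(ligand, site_label, "full", float(excursion_start)))
    return events


# ---------------------------------------------------------------------------
# export

_PASSAGE_COLS = ["ligand", "monomer", "channel", "direction", "completeness",
                 "orientation", "t_start_ns", "t_end_ns", "origin_side", "dest_side"]


def events_to_frame(events: Sequence) -> pd.DataFrame:
    """Typed events as a DataFrame with a deterministic column order."""
    if not events:
        return pd.DataFrame()
    rows = [vars(ev).copy() for ev in events]
    df = pd.DataFrame(rows)
    if isinstance(events[0], PassageEvent):
        df = df[_PASSAGE_COLS]
    return df


def write_events_tsv(events: Sequence, path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False, float_format="%.6f")
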