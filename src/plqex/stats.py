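"""Aggregate statistics: per-channel flux tables, cavity occupancy,
reorientation timescales, and the cavity-balance conservation audit.

Fluxes are reported in molecules ms^-1 per monomer, with the standard error
of the mean taken over monomer-replicates (the convention for n = 10: five
replicate simulations x two monomers), never over events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import PassageEvent, StateTrace

__all__ = [
    "FluxTable",
    "OccupancySeries",
    "TimescaleEstimate",
    "AuditReport",
    "compute_flux_table",
    "cavity_occupancy",
    "estimate_timescale",
    "mean_interevent_time",
    "conservation_audit",
]


@dataclass
class FluxTable:
    """Per-(channel, direction) flux summary over monomer-replicates."""

    counts: pd.DataFrame  # long: monomer, channel, direction, count, time_ns, flux_ms
    summary: pd.DataFrame  # long: channel, direction, mean_flux_ms, sem_flux_ms, n_units

    @property
    def n_units(self) -> int:
        return int(self.summary["n_units"].iloc[0]) if len(self.summary) else 0

    def mean(self, channel: str, direction: str) -> float:
        row = self.summary[(self.summary.channel == channel) &
                           (self.summary.direction == direction)]
        return float(row["mean_flux_ms"].iloc[0]) if len(row) else 0.0

    def sem(self, channel: str, direction: str) -> float:
        row = self.summary[(self.summary.channel == channel) &
                           (self.summary.direction == direction)]
        return float(row["sem_flux_ms"].iloc[0]) if len(row) else 0.0

    def wide(self) -> pd.DataFrame:
        """Flux in / flux out rows by channel columns, 'mean+-sem' strings."""
        piv = self.summary.copy()
        piv["cell"] = piv.apply(lambda r: f"{r.mean_flux_ms:.1f}±{r.sem_flux_ms:.1f}", axis=1)
        out = piv.pivot(index="direction", columns="channel", values="cell")
        return out.reindex(index=["in", "out"]).rename(
            index={"in": "Flux in", "out": "Flux out"})

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format="%.6f")


def compute_flux_table(events: Sequence[PassageEvent],
                       per_monomer_monitored_time_ns: Mapping[int, float],
                       channels: Sequence[str] | None = None) -> FluxTable:
    """Mean +- s.e.m. full-passage flux per channel and direction.

    Per monomer, flux = (# full events of that channel/direction) /
    monitored time, converted to ms^-1.  Trapped and partial excursions are
    excluded.  ``channels`` fixes the table's channel set (defaults to the
    channels observed).
    """
    times = dict(per_monomer_monitored_time_ns)
    if not times:
        raise ValueError("need at least one monitored monomer")
    for m, t in times.items():
        if t <= 0:
            raise ValueError(f"monitored time for monomer {m} must be > 0")
    full = [ev for ev in events if ev.completeness == "full"]
    for ev in full:
        if ev.monomer not in times:
            raise ValueError(f"event on monomer {ev.monomer} has no monitored time")
    chan_set = list(channels) if channels is not None else sorted(
        {ev.channel for ev in full if ev.channel is not None})
    if any(ev.channel is None for ev in full):
        chan_set = chan_set + ["unassigned"]
    rows = []
    for m, t_ns in sorted(times.items()):
        t_ms = t_ns * 1e-6
        for ch in chan_set:
            for direction in ("in", "out"):
                count = sum(1 for ev in full
                            if ev.monomer == m and direction == ev.direction and
                            (ev.channel or "unassigned") == ch)
                rows.append({"monomer": m, "channel": ch, "direction": direction,
                             "count": count, "time_ns": t_ns, "flux_ms": count / t_ms})
    counts = pd.DataFrame(rows, columns=["monomer", "channel", "direction",
                                         "count", "time_ns", "flux_ms"])
    n = len(times)
    summary_rows = []
    for ch in chan_set:
        for direction in ("in", "out"):
            flux = counts[(counts.channel == ch) &
                          (counts.direction == direction)]["flux_ms"].to_numpy()
            mean = float(flux.mean()) if len(flux) else 0.0
            sem = float(flux.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            summary_rows.append({"channel": ch, "direction": direction,
                                 "mean_flux_ms": mean, "sem_flux_ms": sem, "n_units": n})
    summary = pd.DataFrame(summary_rows, columns=["channel", "direction",
                                                  "mean_flux_ms", "sem_flux_ms", "n_units"])
    return FluxTable(counts=counts, summary=summary)


@dataclass
class OccupancySeries:
    """Ligand count per cavity over time, plus the end-window statistic."""

    counts: pd.DataFrame  # index time_ns, one column per monomer
    end_window_ns: float
    per_monomer_end_mean: pd.Series
    end_mean: float
    end_sem: float

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", float_format="%.6f")


def cavity_occupancy(traces: Mapping[str, StateTrace], model=None,
                     end_window_ns: float | None = None) -> OccupancySeries:
    """Per-frame cavity ligand counts and the trailing-window mean +- s.e.m.

    The end statistic averages the per-frame count over the final window per
    monomer, then reports mean and s.e.m. over monomers.  The default window
    is the trailing 5% of the trajectory.
    """
    if not traces:
        raise ValueError("no traces given")
    first = next(iter(traces.values()))
    model = model or first.model
    times = first.times
    n_mono = len(model.monomers)
    counts = np.zeros((len(times), n_mono), dtype=np.int64)
    kinds = np.array([lab.kind for lab in model.labels])
    monos = np.array([-1 if lab.monomer is None else lab.monomer for lab in model.labels])
    cavityish = np.isin(kinds, ("CAVITY", "SITE"))
    for trace in traces.values():
        if len(trace.times) != len(times) or not np.allclose(trace.times, times):
            raise ValueError("all traces must share one frame grid")
        sel = cavityish[trace.codes]
        if np.any(sel):
            np.add.at(counts, (np.flatnonzero(sel), monos[trace.codes[sel]]), 1)
    span = times[-1] - times[0]
    window = end_window_ns if end_window_ns is not None else 0.05 * span
    if window <= 0 or window > span + 1e-9:
        raise ValueError(f"end window {window} ns outside trajectory span {span} ns")
    in_win = times >= times[-1] - window
    if not np.any(in_win):
        raise ValueError("end window contains no frames")
    per_mono = counts[in_win].mean(axis=0)
    df = pd.DataFrame(counts, index=pd.Index(times, name="time_ns"),
                      columns=[f"monomer_{m}" for m in range(n_mono)])
    sem = float(per_mono.std(ddof=1) / np.sqrt(n_mono)) if n_mono > 1 else 0.0
    return OccupancySeries(counts=df, end_window_ns=float(window),
                           per_monomer_end_mean=pd.Series(per_mono,
                                                          index=df.columns),
                           end_mean=float(per_mono.mean()), end_sem=sem)


@dataclass(frozen=True)
class TimescaleEstimate:
    """Per-event timescale: residence time / event count, or a lower bound.

    With zero observed events the total residence time is reported as a
    lower bound (the one-event-missed convention).
    """

    kind: str  # point | lower_bound
    value_us: float
    n_events: int
    residence_time_us: float


def estimate_timescale(n_events: int, residence_time_us: float) -> TimescaleEstimate:
    if n_events < 0 or residence_time_us < 0:
        raise ValueError("n_events and residence_time_us must be >= 0")
    if n_events == 0:
        return TimescaleEstimate("lower_bound", float(residence_time_us), 0,
                                 float(residence_time_us))
    return TimescaleEstimate("point", residence_time_us / n_events, int(n_events),
                             float(residence_time_us))


def mean_interevent_time(total_events: int, total_monitored_monomer_time_us: float) -> float:
    """Mean monomer-time between events (e.g. cavity entries+exits), in us."""
    if total_events < 1:
        raise ValueError("mean inter-event time undefined for zero events")
    return total_monitored_monomer_time_us / total_events


@dataclass
class AuditReport:
    """Cavity-balance audit: Delta(cavity) vs full entries - exits.

    The exact identity per monomer is
    ``delta = entries - exits + trapped_in - trapped_out`` where the trapped
    terms count excursions cut off by the trace boundaries (a ligand starting
    inside a channel that resolves into the cavity, or leaving the cavity
    into a channel and still there at the end).  With no trapped ligands this
    reduces to delta = entries - exits.
    """

    table: pd.DataFrame  # per-monomer terms
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def conservation_audit(traces: Mapping[str, StateTrace],
                       events: Sequence[PassageEvent]) -> AuditReport:
    if not traces:
        raise ValueError("no traces given")
    model = next(iter(traces.values())).model
    kinds = np.array([lab.kind for lab in model.labels])
    monos = np.array([-1 if lab.monomer is None else lab.monomer for lab in model.labels])
    cavityish = np.isin(kinds, ("CAVITY", "SITE"))
    n_mono = len(model.monomers)
    delta = np.zeros(n_mono, dtype=int)
    touching: dict[int, set[str]] = {m: set() for m in range(n_mono)}
    for name, trace in traces.items():
        for which, idx in (("start", 0), ("end", -1)):
            code = int(trace.codes[idx])
            if cavityish[code]:
                delta[monos[code]] += 1 if which == "end" else -1
        sel = cavityish[trace.codes]
        for m in np.unique(monos[trace.codes[sel]]) if np.any(sel) else []:
            touching[int(m)].add(name)
    terms = np.zeros((n_mono, 4), dtype=int)  # entries, exits, trapped_in, trapped_out
    for ev in events:
        if ev.monomer is None:
            continue
        m = ev.monomer
        if ev.completeness == "full":
            terms[m, 0 if ev.direction == "in" else 1] += 1
        elif ev.completeness == "trapped":
            if ev.origin_side is None and ev.dest_side == "cavity":
                terms[m, 2] += 1
            elif ev.dest_side is None and ev.origin_side == "cavity":
                terms[m, 3] += 1
    rows, violations = [], []
    for m in range(n_mono):
        entries, exits, t_in, t_out = terms[m]
        balance = entries - exits + t_in - t_out
        rows.append({"monomer": m, "delta_cavity": int(delta[m]), "entries": int(entries),
                     "exits": int(exits), "trapped_in": int(t_in),
                     "trapped_out": int(t_out), "balance": int(balance)})
        if balance != delta[m]:
            violations.append({"monomer": m, "delta_cavity": int(delta[m]),
                               "balance": int(balance),
                               "ligands": sorted(touching[m])})
    return AuditReport(table=pd.DataFrame(rows), violations=violations)
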