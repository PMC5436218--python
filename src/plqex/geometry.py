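"""Region model of the membrane/protein system and point-in-region queries.

The analysis frame is a right-handed protein-fixed frame with the membrane
normal along +z (stromal side positive).  A :class:`GeometryModel` names the
volumes the event detection reasons about: the thylakoid membrane slab (bulk),
per-monomer exchange cavities, the Q_B binding-site sphere, exchange channels
with planar inner/outer gates, and optional protein footprints excluded from
bulk.  All lengths are nm.

Overlaps between regions are resolved by a fixed priority,
``channel > cavity > binding site > protein footprint > bulk > off-membrane``,
so that channel residence dominates at the gate boundaries where passage
counting happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Plane",
    "Region",
    "ZSlab",
    "Prism",
    "SphereUnion",
    "ChannelSpec",
    "MonomerGeometry",
    "GeometryModel",
    "Label",
    "build_geometry",
    "load_geometry",
    "locate",
    "channel_cross_section",
    "leaflet_of",
    "STROMAL",
    "LUMENAL",
]

STROMAL = "stromal"
LUMENAL = "lumenal"

# priority ranks, larger wins
_RANK = {"OFF": 0, "BULK": 1, "PROTEIN": 2, "SITE": 3, "CAVITY": 4, "CHANNEL": 5}


class GeometryError(ValueError):
    """Raised when a geometry configuration violates a model invariant."""


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError("plane normal must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive on the side the normal points to."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def translated(self, vec) -> "Plane":
        return Plane(self.point + np.asarray(vec, float), self.normal)

    def rotated_z(self, theta: float, origin_xy=(0.0, 0.0)) -> "Plane":
        return Plane(
            _rot_z_points(self.point[None], theta, origin_xy)[0],
            _rot_z_vec(self.normal, theta),
        )

    def mirrored_z(self, z0: float) -> "Plane":
        p = self.point.copy()
        p[2] = 2 * z0 - p[2]
        n = self.normal.copy()
        n[2] = -n[2]
        return Plane(p, n)


def _rot_z_points(points, theta, origin_xy):
    pts = np.array(points, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    ox, oy = origin_xy
    x = pts[..., 0] - ox
    y = pts[..., 1] - oy
    out = pts.copy()
    out[..., 0] = c * x - s * y + ox
    out[..., 1] = s * x + c * y + oy
    return out


def _rot_z_vec(v, theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


class Region:
    """A named volume with containment tests and a boundary-distance measure.

    ``signed_distance`` is negative inside and measures the distance to the
    region boundary.  For convex prisms the outside value is the supporting
    half-plane distance (a lower bound of the true Euclidean distance near
    corners), which is the measure the hysteresis labeling uses.
    """

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) <= 0.0

    def signed_distance(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def translated(self, vec) -> "Region":  # pragma: no cover
        raise NotImplementedError

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)) -> "Region":  # pragma: no cover
        raise NotImplementedError

    def mirrored_z(self, z0) -> "Region":  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class ZSlab(Region):
    """Infinite slab z_lo <= z <= z_hi (the membrane)."""

    z_lo: float
    z_hi: float

    def __post_init__(self):
        if not self.z_lo < self.z_hi:
            raise GeometryError(f"slab requires z_lo < z_hi, got ({self.z_lo}, {self.z_hi})")

    @property
    def midplane(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)

    def signed_distance(self, points):
        z = np.atleast_2d(np.asarray(points, float))[:, 2]
        return np.maximum(self.z_lo - z, z - self.z_hi)

    def translated(self, vec):
        dz = float(np.asarray(vec, float)[2])
        return ZSlab(self.z_lo + dz, self.z_hi + dz)

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)):
        return self

    def mirrored_z(self, z0):
        return ZSlab(2 * z0 - self.z_hi, 2 * z0 - self.z_lo)


@dataclass(frozen=True)
class Prism(Region):
    """Convex polygon in xy extruded between z_lo and z_hi."""

    vertices: np.ndarray  # (m, 2), convex, any orientation
    z_lo: float
    z_hi: float
    # inward edge data precomputed in __post_init__
    _edge_normals: np.ndarray = field(default=None, repr=False, compare=False)
    _edge_offsets: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise GeometryError("prism needs >= 3 xy vertices")
        if not self.z_lo < self.z_hi:
            raise GeometryError("prism requires z_lo < z_hi")
        # enforce CCW order
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        if area2 < 0:
            v = v[::-1].copy()
        edges = np.roll(v, -1, axis=0) - v
        cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(edges, -1, axis=0)[:, 0]
        if np.any(cross < -1e-12) or np.all(np.abs(cross) < 1e-12):
            raise GeometryError("prism polygon must be convex and non-degenerate")
        # outward normals of CCW polygon
        normals = np.stack([edges[:, 1], -edges[:, 0]], axis=1)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        offsets = np.einsum("ij,ij->i", normals, v)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_edge_normals", normals)
        object.__setattr__(self, "_edge_offsets", offsets)

    def signed_distance(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        sd_xy = (pts[:, :2] @ self._edge_normals.T - self._edge_offsets).max(axis=1)
        z = pts[:, 2]
        return np.maximum(sd_xy, np.maximum(self.z_lo - z, z - self.z_hi))

    def centroid(self) -> np.ndarray:
        cx, cy = self.vertices.mean(axis=0)
        return np.array([cx, cy, 0.5 * (self.z_lo + self.z_hi)])

    def translated(self, vec):
        vec = np.asarray(vec, float)
        return Prism(self.vertices + vec[:2], self.z_lo + vec[2], self.z_hi + vec[2])

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)):
        v3 = np.column_stack([self.vertices, np.zeros(len(self.vertices))])
        return Prism(_rot_z_points(v3, theta, origin_xy)[:, :2], self.z_lo, self.z_hi)

    def mirrored_z(self, z0):
        return Prism(self.vertices, 2 * z0 - self.z_hi, 2 * z0 - self.z_lo)


def box_prism(x_lo, x_hi, y_lo, y_hi, z_lo, z_hi) -> Prism:
    """Axis-aligned rectangular prism convenience constructor."""
    verts = [(x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)]
    return Prism(np.array(verts), z_lo, z_hi)


@dataclass(frozen=True)
class SphereUnion(Region):
    """Union of spheres (the binding-site locus)."""

    centers: np.ndarray  # (k, 3)
    radii: np.ndarray  # (k,)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, float))
        r = np.atleast_1d(np.asarray(self.radii, float))
        if len(c) != len(r) or len(c) == 0:
            raise GeometryError("sphere union needs matching centers/radii")
        if np.any(r <= 0):
            raise GeometryError("sphere radii must be > 0")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)

    def signed_distance(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        d = np.linalg.norm(pts[:, None, :] - self.centers[None], axis=2) - self.radii[None]
        return d.min(axis=1)

    def translated(self, vec):
        return SphereUnion(self.centers + np.asarray(vec, float), self.radii)

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)):
        return SphereUnion(_rot_z_points(self.centers, theta, origin_xy), self.radii)

    def mirrored_z(self, z0):
        c = self.centers.copy()
        c[:, 2] = 2 * z0 - c[:, 2]
        return SphereUnion(c, self.radii)


@dataclass(frozen=True)
class Label:
    """A location label: region kind plus channel/monomer identity."""

    kind: str  # OFF | BULK | PROTEIN | SITE | CAVITY | CHANNEL
    monomer: int | None = None
    channel: str | None = None

    def __str__(self):
        if self.kind == "CHANNEL":
            return f"CHANNEL_{self.channel}@{self.monomer}"
        if self.monomer is not None:
            return f"{self.kind}@{self.monomer}"
        return self.kind

    @property
    def rank(self) -> int:
        return _RANK[self.kind]


@dataclass(frozen=True)
class ChannelSpec:
    """A channel: prism interior plus two oriented gate planes.

    Gate normals point out of the interior; the inner gate faces the exchange
    cavity, the outer gate faces the bulk membrane.
    """

    label: str  # "I", "II", "III", ...
    monomer: int
    interior: Prism
    inner_gate: Plane
    outer_gate: Plane

    def validate(self, cavity: Region, tol: float = 1e-6) -> None:
        verts = self.interior.vertices
        z = np.array([self.interior.z_lo, self.interior.z_hi])
        corners = np.array([[x, y, zz] for (x, y) in verts for zz in z])
        for name, gate in (("inner", self.inner_gate), ("outer", self.outer_gate)):
            sd = gate.signed_distance(corners)
            # the plane must touch the closed interior: strictly inside on one
            # side and reaching the boundary (gates on a prism face are valid)
            if not (sd.min() < -tol and sd.max() > -tol):
                raise GeometryError(
                    f"channel {self.label}@{self.monomer}: {name} gate does not intersect interior"
                )
            if gate.signed_distance(self.interior.centroid()[None])[0] > 0:
                raise GeometryError(
                    f"channel {self.label}@{self.monomer}: {name} gate normal must point out of interior"
                )
        if abs(cavity.signed_distance(self.inner_gate.point[None])[0]) > 0.25:
            raise GeometryError(
                f"channel {self.label}@{self.monomer}: inner gate must lie on the cavity boundary"
            )

    def translated(self, vec):
        return ChannelSpec(self.label, self.monomer, self.interior.translated(vec),
                           self.inner_gate.translated(vec), self.outer_gate.translated(vec))

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)):
        return ChannelSpec(self.label, self.monomer, self.interior.rotated_z(theta, origin_xy),
                           self.inner_gate.rotated_z(theta, origin_xy),
                           self.outer_gate.rotated_z(theta, origin_xy))

    def mirrored_z(self, z0):
        return ChannelSpec(self.label, self.monomer, self.interior.mirrored_z(z0),
                           self.inner_gate.mirrored_z(z0), self.outer_gate.mirrored_z(z0))


@dataclass(frozen=True)
class MonomerGeometry:
    cavity: Region
    channels: tuple
    site: SphereUnion | None = None
    footprint: Region | None = None
    cavity_mid_z: float | None = None

    def _map(self, fn):
        return MonomerGeometry(
            cavity=fn(self.cavity),
            channels=tuple(fn(c) for c in self.channels),
            site=None if self.site is None else fn(self.site),
            footprint=None if self.footprint is None else fn(self.footprint),
            cavity_mid_z=self.cavity_mid_z,
        )


class GeometryModel:
    """Validated region model with vectorized point-location queries."""

    def __init__(self, slab: ZSlab, monomers: Sequence[MonomerGeometry]):
        self.slab = slab
        self.monomers = list(monomers)
        self._validate()
        self._build_tables()

    # -- construction -------------------------------------------------
    def _validate(self):
        if not self.monomers:
            raise GeometryError("model needs at least one monomer")
        for m, mon in enumerate(self.monomers):
            for ch in mon.channels:
                ch.validate(mon.cavity)
                if ch.monomer != m:
                    raise GeometryError(f"channel {ch.label} monomer id mismatch ({ch.monomer} != {m})")
        # cavities of different monomers must be disjoint (sampled check)
        rng = np.random.default_rng(0)
        for a in range(len(self.monomers)):
            for b in range(a + 1, len(self.monomers)):
                ca, cb = self.monomers[a].cavity, self.monomers[b].cavity
                pts = _sample_region(ca, rng, 256)
                if pts is not None and np.any(cb.contains(pts)):
                    raise GeometryError(f"cavities of monomers {a} and {b} overlap")

    def _build_tables(self):
        labels: list[Label] = [Label("OFF"), Label("BULK")]
        regions: list[Region | None] = [None, self.slab]
        for m, mon in enumerate(self.monomers):
            if mon.footprint is not None:
                labels.append(Label("PROTEIN", monomer=m))
                regions.append(mon.footprint)
            if mon.site is not None:
                labels.append(Label("SITE", monomer=m))
                regions.append(mon.site)
            labels.append(Label("CAVITY", monomer=m))
            regions.append(mon.cavity)
            for ch in mon.channels:
                labels.append(Label("CHANNEL", monomer=m, channel=ch.label))
                regions.append(ch.interior)
        self.labels: tuple[Label, ...] = tuple(labels)
        self._regions = regions
        self.ranks = np.array([lab.rank for lab in labels], dtype=np.int8)
        self._code_of = {str(lab): i for i, lab in enumerate(labels)}
        # evaluation order: ascending rank so later (higher-rank) assignments win
        self._eval_order = sorted(range(1, len(labels)), key=lambda i: self.ranks[i])

    # -- queries ------------------------------------------------------
    @property
    def midplane(self) -> float:
        return self.slab.midplane

    def code(self, label: str | Label) -> int:
        return self._code_of[str(label)]

    def region_of(self, code: int) -> Region | None:
        return self._regions[code]

    def locate_batch(self, points: np.ndarray) -> np.ndarray:
        """Highest-priority label code for each point (vectorized)."""
        pts = np.atleast_2d(np.asarray(points, float))
        codes = np.zeros(len(pts), dtype=np.int16)  # OFF
        for i in self._eval_order:
            codes[self._regions[i].contains(pts)] = i
        return codes

    def locate(self, point) -> Label:
        return self.labels[self.locate_batch(np.asarray(point, float)[None])[0]]

    def depth_into(self, code: int, points: np.ndarray) -> np.ndarray:
        """Penetration depth of points inside region ``code`` (>=0 inside)."""
        if code == 0:  # off-membrane: depth beyond the slab boundary
            return np.maximum(self.slab.signed_distance(points), 0.0)
        return np.maximum(-self._regions[code].signed_distance(points), 0.0)

    def depth_out_of(self, code: int, points: np.ndarray) -> np.ndarray:
        """Distance of points beyond the boundary of region ``code``."""
        if code == 0:
            return np.maximum(-self.slab.signed_distance(points), 0.0)
        return np.maximum(self._regions[code].signed_distance(points), 0.0)

    def channel_spec(self, channel: str, monomer: int) -> ChannelSpec:
        for ch in self.monomers[monomer].channels:
            if ch.label == channel:
                return ch
        raise KeyError(f"no channel {channel} in monomer {monomer}")

    def compartment_mid_z(self, kind: str, monomer: int | None) -> float:
        if kind == "CAVITY" and monomer is not None:
            override = self.monomers[monomer].cavity_mid_z
            if override is not None:
                return override
        return self.midplane

    # -- transforms (used by the covariance/mirror properties) --------
    def _map(self, region_fn, slab_fn):
        return GeometryModel(slab_fn(self.slab), [m._map(region_fn) for m in self.monomers])

    def translated(self, vec):
        return self._map(lambda r: r.translated(vec), lambda s: s.translated(vec))

    def rotated_z(self, theta, origin_xy=(0.0, 0.0)):
        return self._map(lambda r: r.rotated_z(theta, origin_xy), lambda s: s)

    def mirrored_z(self):
        z0 = self.midplane
        monomers = []
        for mon in self.monomers:
            mirrored = mon._map(lambda r: r.mirrored_z(z0))
            if mon.cavity_mid_z is not None:
                mirrored = replace(mirrored, cavity_mid_z=2 * z0 - mon.cavity_mid_z)
            monomers.append(mirrored)
        return GeometryModel(self.slab.mirrored_z(z0), monomers)

    # -- serialization ------------------------------------------------
    def to_config(self) -> dict:
        def prism_cfg(p: Prism):
            return {"shape": "prism", "vertices": p.vertices.tolist(),
                    "z_lo": float(p.z_lo), "z_hi": float(p.z_hi)}

        def region_cfg(r: Region):
            if isinstance(r, Prism):
                return prism_cfg(r)
            if isinstance(r, SphereUnion):
                return {"shape": "spheres", "centers": r.centers.tolist(), "radii": r.radii.tolist()}
            if isinstance(r, ZSlab):
                return {"shape": "z_slab", "z_lo": float(r.z_lo), "z_hi": float(r.z_hi)}
            raise TypeError(type(r))

        cfg = {"slab": {"z_lo": float(self.slab.z_lo), "z_hi": float(self.slab.z_hi)},
               "monomers": []}
        for mon in self.monomers:
            mcfg = {"cavity": region_cfg(mon.cavity), "channels": []}
            if mon.cavity_mid_z is not None:
                mcfg["cavity_mid_z"] = float(mon.cavity_mid_z)
            if mon.site is not None:
                mcfg["site"] = region_cfg(mon.site)
            if mon.footprint is not None:
                mcfg["footprint"] = region_cfg(mon.footprint)
            for ch in mon.channels:
                mcfg["channels"].append({
                    "label": ch.label,
                    "interior": prism_cfg(ch.interior),
                    "inner_gate": {"point": ch.inner_gate.point.tolist(),
                                   "normal": ch.inner_gate.normal.tolist()},
                    "outer_gate": {"point": ch.outer_gate.point.tolist(),
                                   "normal": ch.outer_gate.normal.tolist()},
                })
            cfg["monomers"].append(mcfg)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


def _sample_region(region: Region, rng, n: int):
    if isinstance(region, Prism):
        lo = region.vertices.min(axis=0)
        hi = region.vertices.max(axis=0)
        pts = np.column_stack([
            rng.uniform(lo[0], hi[0], n),
            rng.uniform(lo[1], hi[1], n),
            rng.uniform(region.z_lo, region.z_hi, n),
        ])
        return pts[region.contains(pts)]
    if isinstance(region, SphereUnion):
        out = []
        for c, r in zip(region.centers, region.radii):
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            out.append(c + u * (r * rng.uniform(0, 1, (n, 1)) ** (1 / 3)))
        return np.concatenate(out)
    return None


def _region_from_config(cfg: Mapping) -> Region:
    shape = cfg.get("shape", "prism")
    if shape == "prism":
        return Prism(np.asarray(cfg["vertices"], float), float(cfg["z_lo"]), float(cfg["z_hi"]))
    if shape == "spheres":
        return SphereUnion(np.asarray(cfg["centers"], float), np.asarray(cfg["radii"], float))
    if shape == "z_slab":
        return ZSlab(float(cfg["z_lo"]), float(cfg["z_hi"]))
    raise GeometryError(f"unknown region shape {shape!r}")


def build_geometry(config: Mapping) -> GeometryModel:
    """Build and validate a :class:`GeometryModel` from a config mapping.

    See :meth:`GeometryModel.to_config` for the schema; a round-trip through
    YAML is lossless.
    """
    try:
        slab = ZSlab(float(config["slab"]["z_lo"]), float(config["slab"]["z_hi"]))
    except KeyError as exc:
        raise GeometryError(f"geometry config missing key: {exc}") from exc
    monomers = []
    for m, mcfg in enumerate(config.get("monomers", [])):
        cavity = _region_from_config(mcfg["cavity"])
        site = _region_from_config(mcfg["site"]) if "site" in mcfg else None
        footprint = _region_from_config(mcfg["footprint"]) if "footprint" in mcfg else None
        channels = []
        for ccfg in mcfg.get("channels", []):
            interior = _region_from_config(ccfg["interior"])
            if not isinstance(interior, Prism):
                raise GeometryError("channel interiors must be prisms")
            channels.append(ChannelSpec(
                label=str(ccfg["label"]), monomer=m, interior=interior,
                inner_gate=Plane(np.asarray(ccfg["inner_gate"]["point"], float),
                                 np.asarray(ccfg["inner_gate"]["normal"], float)),
                outer_gate=Plane(np.asarray(ccfg["outer_gate"]["point"], float),
                                 np.asarray(ccfg["outer_gate"]["normal"], float)),
            ))
        monomers.append(MonomerGeometry(
            cavity=cavity, channels=tuple(channels), site=site, footprint=footprint,
            cavity_mid_z=mcfg.get("cavity_mid_z"),
        ))
    return GeometryModel(slab, monomers)


def load_geometry(path) -> GeometryModel:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise GeometryError(f"geometry file {path} does not contain a mapping")
    return build_geometry(cfg)


def locate(point, model: GeometryModel) -> Label:
    """Highest-priority region label containing ``point``."""
    return model.locate(point)


def channel_cross_section(group_a: np.ndarray, group_b: np.ndarray,
                          slab: ZSlab) -> tuple[float, float]:
    """Width x height (nm) of a channel opening from two lining bead groups.

    Width is the minimum inter-group bead distance; height is the extent of
    the combined groups along the membrane normal, clipped to the slab.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("channel lining groups must be non-empty")
    width = float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)))
    z = np.concatenate([a[:, 2], b[:, 2]])
    height = max(0.0, min(float(z.max()), slab.z_hi) - max(float(z.min()), slab.z_lo))
    return width, height


def leaflet_of(position, model: GeometryModel, region_label: str | Label) -> str:
    """Leaflet assignment (stromal above the midplane, lumenal at or below).

    The tie at exactly the midplane goes to the lumenal leaflet.  The named
    region supplies the midplane: a cavity may override the slab midplane
    with its own mid-z.
    """
    lab = region_label if isinstance(region_label, Label) else _parse_label(region_label)
    pos = np.asarray(position, float)
    if lab.kind not in ("BULK", "CAVITY"):
        raise ValueError(f"leaflet is defined for BULK/CAVITY, not {lab.kind}")
    if lab.kind == "BULK":
        if model.slab.signed_distance(pos[None])[0] > 0:
            raise ValueError("position outside the membrane slab")
        mid = model.midplane
    else:
        if model.monomers[lab.monomer].cavity.signed_distance(pos[None])[0] > 0:
            raise ValueError("position outside the named cavity")
        mid = model.compartment_mid_z("CAVITY", lab.monomer)
    return STROMAL if pos[2] > mid else LUMENAL


def _parse_label(s: str) -> Label:
    s = str(s)
    if "@" in s:
        head, mon = s.split("@")
        monomer = int(mon)
    else:
        head, monomer = s, None
    if head.startswith("CHANNEL_"):
        return Label("CHANNEL", monomer=monomer, channel=head[len("CHANNEL_"):])
    return Label(head, monomer=monomer)
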