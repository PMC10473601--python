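"""Synthetic annotated synaptic profiles with exact per-vesicle ground truth.

The generator emulates a freeze-timepoint x genotype cohort design: per
profile, docked, replacement-zone and bulk vesicle counts are independent
Poisson draws whose means are scaled per group. Vesicles are placed so that
their *measured* edge distance to the active-zone sub-polyline equals the
drawn ground-truth distance to machine precision (root-finding along the
local membrane normal), and vesicle discs never overlap.

Freeze-timepoint presets are expressed purely as per-group scale factors;
no kinetic model of docking is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ..em import Pit, SynapticProfile, Vesicle
from ..geometry import (
    point_at_arc,
    point_to_polyline_distance,
    polyline_arc_lengths,
    tangent_at_arc,
)

__all__ = ["CohortSpec", "ProfileSet", "generate_profile_set"]

_MAX_PLACEMENT_ATTEMPTS = 10_000
#: Outer edge of the "bulk" band, nm; beyond the replacement zone.
_BULK_MAX_NM = 200.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic EM cohort.

    ``groups`` is a list of (genotype, timepoint) labels. Per-group
    multiplicative factors scale the replacement-zone mean
    (``zone_scale_by_group``) and the docked mean (``docked_scale_by_group``);
    keys are ``"genotype|timepoint"`` or genotype alone.
    """

    n_profiles_per_group: int = 100
    groups: tuple = (("WT", "no stim"), ("KO", "no stim"))
    mean_docked: float = 2.0
    mean_zone: float = 2.0
    mean_bulk: float = 5.0
    zone_scale_by_group: dict = field(default_factory=dict)
    docked_scale_by_group: dict = field(default_factory=dict)
    vesicle_diameter: float = 40.0  # nm
    active_zone_length: float = 500.0  # nm
    membrane_length: float = 1200.0  # nm
    mean_pits: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mean_docked", "mean_zone", "mean_bulk", "mean_pits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("zone_scale_by_group", "docked_scale_by_group"):
            for k, s in getattr(self, name).items():
                if not s > 0:
                    raise ValueError(f"{name}[{k!r}] must be > 0, got {s}")
        if not self.vesicle_diameter > 0:
            raise ValueError(f"vesicle_diameter must be > 0, got {self.vesicle_diameter}")
        if self.active_zone_length > self.membrane_length:
            raise ValueError("active_zone_length must be <= membrane_length")
        if self.n_profiles_per_group < 0:
            raise ValueError("n_profiles_per_group must be >= 0")

    def scale(self, table: dict, genotype: str, timepoint: str) -> float:
        return table.get(f"{genotype}|{timepoint}", table.get(genotype, 1.0))


@dataclass
class ProfileSet:
    """Generated profiles plus their ground-truth sidecar records."""

    profiles: list
    truth: list  # one dict per profile: per-vesicle class/distance, counts
    metadata: dict


def _make_membrane(rng: np.random.Generator, length: float, n_segments: int = 12) -> np.ndarray:
    """Gently curved polyline: random-walk heading bounded to +-10 deg/segment."""
    seg = length / n_segments
    headings = np.cumsum(rng.uniform(-np.deg2rad(10), np.deg2rad(10), size=n_segments))
    steps = seg * np.column_stack([np.cos(headings), np.sin(headings)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def _place_at_edge_distance(
    az_line: np.ndarray,
    base: np.ndarray,
    normal: np.ndarray,
    radius: float,
    target: float,
) -> np.ndarray | None:
    """Centre position whose edge distance to ``az_line`` equals ``target``.

    Starts from offset radius+target along the outward normal and solves
    the 1-D root problem exactly; returns None if no bracket is found
    (pathological curvature), so the caller can redraw.
    """

    def f(t: float) -> float:
        c = base + t * normal
        return (point_to_polyline_distance(c, az_line) - radius) - target

    t0 = radius + target
    hi = t0
    # distance along a normal is <= offset, so f(t0) <= 0; grow the bracket
    for _ in range(8):
        if f(hi) >= 0:
            break
        hi *= 1.25
    else:
        return None
    if hi == t0 and abs(f(t0)) < 1e-9:
        return base + t0 * normal
    lo = t0 if f(t0) < 0 else max(radius * 0.5, t0 * 0.5)
    if f(lo) > 0:
        lo = 1e-6
        if f(lo) > 0:
            return None
    t = brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)
    return base + t * normal


def generate_profile_set(spec: CohortSpec) -> ProfileSet:
    """Generate a labelled cohort of synthetic synaptic profiles.

    Per profile: docked vesicles at edge distance exactly 0 to the active
    zone, replacement-zone vesicles at distances uniform on (0, 20], bulk
    vesicles uniform on (20, 200]; counts are Poisson with group-scaled
    means. Reproducible under a fixed seed (PCG64).
    """
    rng = np.random.default_rng(spec.seed)
    radius = spec.vesicle_diameter / 2.0
    profiles: list[SynapticProfile] = []
    truth: list[dict] = []

    for genotype, timepoint in spec.groups:
        zone_scale = spec.scale(spec.zone_scale_by_group, genotype, timepoint)
        dock_scale = spec.scale(spec.docked_scale_by_group, genotype, timepoint)
        for i in range(spec.n_profiles_per_group):
            pid = f"{genotype}_{timepoint}_{i:04d}".replace(" ", "-")
            profile, rec = _generate_profile(
                rng, spec, pid, genotype, timepoint,
                mean_docked=spec.mean_docked * dock_scale,
                mean_zone=spec.mean_zone * zone_scale,
                mean_bulk=spec.mean_bulk,
                radius=radius,
            )
            profiles.append(profile)
            truth.append(rec)

    meta = {
        "generator": "synaptoquant.simulate.em.generate_profile_set",
        "rng": "numpy PCG64",
        "seed": spec.seed,
        "n_profiles": len(profiles),
        "vesicle_radius_nm": radius,
    }
    return ProfileSet(profiles=profiles, truth=truth, metadata=meta)


def _generate_profile(rng, spec, pid, genotype, timepoint, *, mean_docked, mean_zone, mean_bulk, radius):
    """Build one profile; counts whose vesicles cannot be packed without
    overlap (a physical impossibility for the drawn geometry, far in the
    Poisson tail) are redrawn with a fresh membrane, up to 10 attempts."""
    last_err = None
    for _ in range(10):
        try:
            return _generate_profile_once(
                rng, spec, pid, genotype, timepoint,
                mean_docked=mean_docked, mean_zone=mean_zone, mean_bulk=mean_bulk,
                radius=radius,
            )
        except _PackingError as exc:
            last_err = exc
    raise RuntimeError(str(last_err))


class _PackingError(RuntimeError):
    pass


def _generate_profile_once(rng, spec, pid, genotype, timepoint, *, mean_docked, mean_zone, mean_bulk, radius):
    membrane = _make_membrane(rng, spec.membrane_length)
    total_arc = polyline_arc_lengths(membrane)[-1]
    az_start = (total_arc - spec.active_zone_length) / 2.0
    az = (az_start, az_start + spec.active_zone_length)
    from ..geometry import subpolyline

    az_line = subpolyline(membrane, *az)

    n_docked = rng.poisson(mean_docked)
    n_zone = rng.poisson(mean_zone)
    n_bulk = rng.poisson(mean_bulk)

    vesicles: list[Vesicle] = []
    records: list[dict] = []
    for cls, n in (("docked", n_docked), ("replacement", n_zone), ("other", n_bulk)):
        for _ in range(n):
            placed = False
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                if cls == "docked":
                    d = 0.0
                elif cls == "replacement":
                    d = rng.uniform(0.0, 20.0)
                    if d == 0.0:  # open at 0
                        continue
                else:
                    d = rng.uniform(20.0, _BULK_MAX_NM)
                    if d == 20.0:
                        continue
                # undocked vesicles may also sit laterally past the zone ends,
                # where the distance is measured to the endpoint; sample a
                # wing of 60 nm of arc on each side mapped to ray angles
                wing = 0.0 if cls == "docked" else 60.0
                s = rng.uniform(-wing, spec.active_zone_length + wing)
                s_clip = float(np.clip(s, 0.0, spec.active_zone_length))
                base = point_at_arc(az_line, s_clip)
                tx, ty = tangent_at_arc(az_line, s_clip)
                normal = np.array([-ty, tx])  # consistent side of the membrane
                if s < 0.0 or s > spec.active_zone_length:
                    # rotate the ray toward the outward tangent, up to 90 deg
                    over = (s - s_clip) / wing  # in [-1, 1], sign = which end
                    phi = over * (np.pi / 2) * 0.99
                    cphi, sphi = np.cos(phi), np.sin(phi)
                    tangent = np.array([tx, ty])
                    normal = cphi * normal + sphi * tangent
                center = _place_at_edge_distance(az_line, base, normal, radius, d)
                if center is None:
                    continue
                if cls == "docked":
                    # push 1e-6 nm into the membrane so the floored edge
                    # distance is exactly 0, robust to root-finding residue
                    center = center - 1e-6 * normal
                if any(
                    np.hypot(center[0] - v.center[0], center[1] - v.center[1]) < 2 * radius
                    for v in vesicles
                ):
                    continue
                vesicles.append(Vesicle(center=(float(center[0]), float(center[1])), radius=radius))
                records.append({"class": cls, "edge_distance_nm": float(d),
                                "center": [float(center[0]), float(center[1])]})
                placed = True
                break
            if not placed:
                raise _PackingError(
                    f"profile {pid}: could not place a {cls} vesicle without overlap "
                    f"after {_MAX_PLACEMENT_ATTEMPTS} attempts"
                )

    pits = []
    n_pits = rng.poisson(spec.mean_pits) if spec.mean_pits > 0 else 0
    kinds = ("exocytic", "endocytic", "clathrin-coated")
    for _ in range(n_pits):
        s = rng.uniform(0.0, total_arc)
        loc = point_at_arc(membrane, s)
        pits.append(Pit(location=(float(loc[0]), float(loc[1])), kind=kinds[rng.integers(0, 3)]))

    profile = SynapticProfile(
        profile_id=pid,
        pixel_size=0.56,  # nm/px, typical EM magnification
        membrane=membrane,
        active_zone=az,
        vesicles=vesicles,
        pits=pits,
        labels={"genotype": genotype, "timepoint": timepoint, "replicate": "sim"},
    )
    rec = {
        "profile_id": pid,
        "genotype": genotype,
        "timepoint": timepoint,
        "vesicles": records,
        "counts": {
            "docked": int(n_docked),
            "replacement": int(n_zone),
            "other": int(n_bulk),
            "total": int(n_docked + n_zone + n_bulk),
        },
        "pits": int(n_pits),
    }
    return profile, rec
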