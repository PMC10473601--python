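"""Vesicle morphometry on annotated 2D synaptic profiles.

A profile is one electron-micrograph cross-section of a synapse: the plasma
membrane as a polyline, the active zone as a contiguous arc-length span of
that polyline, vesicles as circles and membrane pits as marked points.
Distances are in nanometres throughout.

Vesicle classes follow the flash-freeze morphometry convention: a vesicle
touching the membrane over the active zone is *docked*; an undocked vesicle
whose edge lies within 20 nm of the active-zone membrane sits in the
*replacement zone*; everything else is *other*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    point_to_polyline_distance,
    polyline_arc_lengths,
    polyline_is_simple,
    subpolyline,
)

__all__ = [
    "Vesicle",
    "Pit",
    "SynapticProfile",
    "DistanceHistogram",
    "edge_distance",
    "classify_vesicles",
    "profile_counts",
    "bin_undocked",
    "cohort_summary",
    "PIT_KINDS",
    "DOCK_TOLERANCE_NM",
    "ZONE_RADIUS_NM",
]

PIT_KINDS = ("exocytic", "endocytic", "clathrin-coated")

#: Default docking tolerance, ~one EM pixel, absorbing annotation jitter.
DOCK_TOLERANCE_NM = 0.5
#: Replacement-zone outer radius.
ZONE_RADIUS_NM = 20.0


@dataclass(frozen=True)
class Vesicle:
    """Circular vesicle annotation (nm)."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class Pit:
    """Membrane pit annotation: a point on the membrane plus its kind."""

    location: tuple[float, float]
    kind: str

    def __post_init__(self):
        if self.kind not in PIT_KINDS:
            raise ValueError(f"kind must be one of {PIT_KINDS}, got {self.kind!r}")


@dataclass
class SynapticProfile:
    """One annotated synaptic cross-section, coordinates in nm."""

    profile_id: str
    pixel_size: float  # nm / px of the source image
    membrane: np.ndarray  # (n, 2) polyline, nm
    active_zone: tuple[float, float] | None  # (start_arc, end_arc) along membrane, nm
    vesicles: list[Vesicle] = field(default_factory=list)
    pits: list[Pit] = field(default_factory=list)
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.membrane = np.asarray(self.membrane, dtype=float)
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.membrane.ndim != 2 or self.membrane.shape[1] != 2 or len(self.membrane) < 2:
            raise ValueError("membrane must be a polyline of >= 2 points")
        if self.active_zone is not None:
            lo, hi = self.active_zone
            total = polyline_arc_lengths(self.membrane)[-1]
            if not (0.0 <= lo < hi <= total + 1e-6):
                raise ValueError(
                    f"active_zone span ({lo}, {hi}) must lie within membrane arc length {total:.6g}"
                )

    def validate(self) -> None:
        """Raise if the membrane polyline self-intersects."""
        if not polyline_is_simple(self.membrane):
            raise ValueError(f"profile {self.profile_id}: membrane polyline self-intersects")

    def active_zone_polyline(self) -> np.ndarray:
        if self.active_zone is None:
            raise ValueError(f"profile {self.profile_id} has no active zone annotation")
        return subpolyline(self.membrane, *self.active_zone)


def edge_distance(vesicle: Vesicle, membrane, *, reference: str = "edge") -> float:
    """Distance from a vesicle to a membrane polyline, in nm.

    With ``reference='edge'`` (default) the vesicle radius is subtracted
    from the centre-to-polyline distance and the result is floored at 0,
    so a vesicle touching the membrane scores 0. ``reference='center'``
    returns the raw centre distance.
    """
    d = point_to_polyline_distance(vesicle.center, membrane)
    if reference == "center":
        return d
    if reference == "edge":
        return max(0.0, d - vesicle.radius)
    raise ValueError(f"reference must be 'edge' or 'center', got {reference!r}")


def classify_vesicles(
    profile: SynapticProfile,
    dock_tolerance: float = DOCK_TOLERANCE_NM,
    zone_radius: float = ZONE_RADIUS_NM,
    *,
    reference: str = "edge",
    membrane_scope: str = "active_zone",
) -> list[str]:
    """Classify each vesicle as ``docked``, ``replacement`` or ``other``.

    Distances are measured to the active-zone sub-polyline by default
    (``membrane_scope='whole'`` switches to the full membrane). Docked means
    distance <= ``dock_tolerance``; replacement means undocked with distance
    <= ``zone_radius``.
    """
    if dock_tolerance < 0:
        raise ValueError("dock_tolerance must be >= 0")
    if membrane_scope == "active_zone":
        ref_line = profile.active_zone_polyline()
    elif membrane_scope == "whole":
        ref_line = profile.membrane
    else:
        raise ValueError(f"membrane_scope must be 'active_zone' or 'whole', got {membrane_scope!r}")
    classes = []
    for v in profile.vesicles:
        d = edge_distance(v, ref_line, reference=reference)
        if d <= dock_tolerance:
            classes.append("docked")
        elif d <= zone_radius:
            classes.append("replacement")
        else:
            classes.append("other")
    return classes


def profile_counts(
    profile: SynapticProfile,
    dock_tolerance: float = DOCK_TOLERANCE_NM,
    **classify_kwargs,
) -> dict:
    """Per-profile counts: docked, replacement, undocked within 50 nm, total, pits.

    ``undocked_50nm`` counts undocked vesicles whose edge distance to the
    active zone lies in (dock_tolerance, 50].
    """
    classes = classify_vesicles(profile, dock_tolerance, **classify_kwargs) if profile.vesicles else []
    scope = classify_kwargs.get("membrane_scope", "active_zone")
    reference = classify_kwargs.get("reference", "edge")
    ref_line = (
        profile.active_zone_polyline() if scope == "active_zone" else profile.membrane
    ) if profile.vesicles else None
    undocked_50 = 0
    for v, c in zip(profile.vesicles, classes):
        if c != "docked" and edge_distance(v, ref_line, reference=reference) <= 50.0:
            undocked_50 += 1
    counts = {
        "docked": classes.count("docked"),
        "replacement": classes.count("replacement"),
        "undocked_50nm": undocked_50,
        "total": len(profile.vesicles),
    }
    for kind in PIT_KINDS:
        counts[f"pits_{kind.replace('-', '_')}"] = sum(p.kind == kind for p in profile.pits)
    return counts


@dataclass
class DistanceHistogram:
    """2-nm-binned distribution of undocked-vesicle edge distances over (0, 50].

    ``relative_freq`` is ``counts / n_total``; it is undefined (``None``)
    when no distance falls in range, never silently zero.
    """

    bin_edges: np.ndarray  # 26 edges: 0, 2, ..., 50
    counts: np.ndarray  # 25 ints
    relative_freq: np.ndarray | None
    n_total: int

    def as_frame(self) -> pd.DataFrame:
        rel = self.relative_freq if self.relative_freq is not None else np.full(len(self.counts), np.nan)
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "rel_freq": rel,
            }
        )


def bin_undocked(distances, width: float = 2.0, max_distance: float = 50.0) -> DistanceHistogram:
    """Bin undocked edge distances into half-open bins (0,2], (2,4], ..., (48,50].

    Distances outside (0, max] are excluded from both the counts and the
    normalizing total, mirroring per-region normalization of distance
    distributions.
    """
    d = np.asarray(list(distances), dtype=float)
    edges = np.arange(0.0, max_distance + width / 2, width)
    in_range = d[(d > 0) & (d <= max_distance)]
    # right-closed bins: index via ceil(d/width) - 1
    idx = np.ceil(in_range / width).astype(int) - 1
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(int)
    n_total = int(len(in_range))
    rel = counts / n_total if n_total > 0 else None
    return DistanceHistogram(bin_edges=edges, counts=counts, relative_freq=rel, n_total=n_total)


MEASURES = (
    "docked",
    "replacement",
    "undocked_50nm",
    "total",
    "pits_exocytic",
    "pits_endocytic",
    "pits_clathrin_coated",
)


def cohort_summary(
    profiles,
    dock_tolerance: float = DOCK_TOLERANCE_NM,
    *,
    normalize_to_no_stim: bool = False,
    no_stim_label: str = "no stim",
    **classify_kwargs,
) -> pd.DataFrame:
    """Per-(genotype, timepoint) mean, SEM and n for every count measure.

    When ``normalize_to_no_stim`` is set, each measure is additionally
    divided by the same genotype's ``no_stim_label`` group mean (norm_mean,
    norm_sem columns), matching the common normalization of stimulated
    timepoints to the unstimulated control.
    """
    rows = []
    for p in profiles:
        if "genotype" not in p.labels or "timepoint" not in p.labels:
            raise ValueError(f"profile {p.profile_id} missing genotype/timepoint labels")
        rec = profile_counts(p, dock_tolerance, **classify_kwargs)
        rec["genotype"] = p.labels["genotype"]
        rec["timepoint"] = p.labels["timepoint"]
        rows.append(rec)
    per_profile = pd.DataFrame(rows)
    if per_profile.empty:
        return pd.DataFrame(columns=["genotype", "timepoint", "measure", "mean", "sem", "n"])

    out = []
    for (gt, tp), grp in per_profile.groupby(["genotype", "timepoint"], sort=True):
        for m in MEASURES:
            vals = grp[m].to_numpy(dtype=float)
            n = len(vals)
            sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            out.append(
                {"genotype": gt, "timepoint": tp, "measure": m,
                 "mean": float(np.mean(vals)), "sem": sem, "n": n}
            )
    table = pd.DataFrame(out)

    if normalize_to_no_stim:
        baselines = {}
        for gt in table["genotype"].unique():
            base = table[(table["genotype"] == gt) & (table["timepoint"] == no_stim_label)]
            if base.empty:
                raise ValueError(f"genotype {gt!r} has no {no_stim_label!r} group to normalize to")
            baselines[gt] = base.set_index("measure")["mean"]
        norm_mean, norm_sem = [], []
        for _, row in table.iterrows():
            b = baselines[row["genotype"]].get(row["measure"], np.nan)
            if not b or np.isnan(b):
                raise ValueError(
                    f"zero or missing {no_stim_label!r} mean for measure {row['measure']!r}, "
                    f"genotype {row['genotype']!r}; cannot normalize"
                )
            norm_mean.append(row["mean"] / b)
            norm_sem.append(row["sem"] / b)
        table["norm_mean"] = norm_mean
        table["norm_sem"] = norm_sem
    return table
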