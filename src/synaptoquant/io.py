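"""File formats, validation, manifests and pipeline orchestration.

Annotation documents are JSON: a list of profiles, each with one membrane
polyline, at most one active-zone span (arc positions along the membrane),
vesicle circles and pit marks, all in 0-based pixel coordinates
(pixel-centre convention, y increasing downward). Loading scales px -> nm
with the document's pixel size. Tables are UTF-8 comma-separated CSV with
a mandatory header row.

Every pipeline artifact is hashed into a manifest together with the seed
and a hash of the configuration, so a fixed-seed run is reproducible
byte-for-byte and verifiable after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .em import Pit, SynapticProfile, Vesicle, PIT_KINDS

logger = logging.getLogger("synaptoquant")

SCHEMA_VERSION = "1.0"

__all__ = [
    "AnnotationError",
    "load_annotations",
    "write_annotations",
    "write_truth_sidecar",
    "write_manifest",
    "verify_manifest",
    "run_pipeline",
    "SCHEMA_VERSION",
]


class AnnotationError(ValueError):
    """Schema violation with a JSON-pointer-style location."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise AnnotationError(pointer, f"missing required field {key!r}")
    return obj[key]


def _parse_profile(doc: dict, pointer: str) -> SynapticProfile:
    pixel_size = float(_require(doc, "pixel_size_nm", pointer))
    if not pixel_size > 0:
        raise AnnotationError(f"{pointer}/pixel_size_nm", "must be > 0")
    image_id = str(_require(doc, "image_id", pointer))
    objects = _require(doc, "objects", pointer)
    labels = doc.get("labels", {})

    membrane = None
    active_zone = None
    vesicles: list[Vesicle] = []
    pits: list[Pit] = []
    for i, obj in enumerate(objects):
        optr = f"{pointer}/objects/{i}"
        kind = _require(obj, "kind", optr)
        geom = _require(obj, "geometry", optr)
        if kind == "membrane":
            if membrane is not None:
                raise AnnotationError(optr, "more than one membrane in profile")
            membrane = np.asarray(_require(geom, "polyline", optr), dtype=float) * pixel_size
        elif kind == "active_zone":
            if active_zone is not None:
                raise AnnotationError(optr, "more than one active_zone in profile")
            active_zone = (
                float(_require(geom, "start_arc", optr)) * pixel_size,
                float(_require(geom, "end_arc", optr)) * pixel_size,
            )
        elif kind == "vesicle":
            cx, cy = _require(geom, "center", optr)
            r = float(_require(geom, "radius", optr))
            vesicles.append(Vesicle(center=(cx * pixel_size, cy * pixel_size), radius=r * pixel_size))
        elif kind == "pit":
            px, py = _require(geom, "point", optr)
            pk = obj.get("attributes", {}).get("pit_kind", "exocytic")
            if pk not in PIT_KINDS:
                raise AnnotationError(f"{optr}/attributes/pit_kind", f"must be one of {PIT_KINDS}")
            pits.append(Pit(location=(px * pixel_size, py * pixel_size), kind=pk))
        else:
            raise AnnotationError(f"{optr}/kind", f"unknown object kind {kind!r}")
    if membrane is None:
        raise AnnotationError(pointer, "profile has no membrane object")
    return SynapticProfile(
        profile_id=image_id, pixel_size=pixel_size, membrane=membrane,
        active_zone=active_zone, vesicles=vesicles, pits=pits, labels=dict(labels),
    )


def load_annotations(path, *, strict: bool = False) -> list[SynapticProfile]:
    """Load an annotation document; skip (and log) invalid profiles.

    With ``strict=True`` the first invalid profile raises instead.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "profiles" not in doc:
        raise AnnotationError("", "document has no 'profiles' list")
    out = []
    for i, pdoc in enumerate(doc["profiles"]):
        try:
            prof = _parse_profile(pdoc, f"/profiles/{i}")
            prof.validate()
            out.append(prof)
        except (AnnotationError, ValueError) as exc:
            if strict:
                raise
            logger.warning("skipping invalid profile /profiles/%d: %s", i, exc)
    return out


def write_annotations(profiles, path, *, provenance: dict | None = None) -> None:
    """Serialize profiles to the annotation-JSON schema (nm -> px)."""
    docs = []
    for p in profiles:
        px = p.pixel_size
        objects = [{"kind": "membrane", "geometry": {"polyline": (p.membrane / px).tolist()}}]
        if p.active_zone is not None:
            objects.append({"kind": "active_zone",
                            "geometry": {"start_arc": p.active_zone[0] / px,
                                         "end_arc": p.active_zone[1] / px}})
        for v in p.vesicles:
            objects.append({"kind": "vesicle",
                            "geometry": {"center": [v.center[0] / px, v.center[1] / px],
                                         "radius": v.radius / px}})
        for pit in p.pits:
            objects.append({"kind": "pit",
                            "geometry": {"point": [pit.location[0] / px, pit.location[1] / px]},
                            "attributes": {"pit_kind": pit.kind}})
        docs.append({"image_id": p.profile_id, "pixel_size_nm": px,
                     "labels": p.labels, "objects": objects})
    payload = {"schema_version": SCHEMA_VERSION,
               "provenance": provenance or {"tool": "synaptoquant"},
               "profiles": docs}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_truth_sidecar(truth, path, metadata: dict | None = None) -> None:
    """Machine-readable ground-truth sidecar for generated fixtures."""
    payload = {"metadata": metadata or {}, "truth": truth}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def config_hash(config: dict) -> str:
    """Hash of the analysis-relevant configuration (output location excluded,
    so runs into different directories compare equal)."""
    cfg = {k: v for k, v in config.items() if k != "out"}
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(outdir, config: dict, artifacts: list[str]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.get("seed"),
        "artifacts": {name: _sha256(outdir / name) for name in sorted(artifacts)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def verify_manifest(outdir) -> bool:
    """Re-hash every artifact listed in the manifest; True if all match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(_sha256(outdir / name) == digest
               for name, digest in manifest["artifacts"].items())


# ---------------------------------------------------------------------------
# pipeline stages

def _stage_simulate_em(config: dict, outdir: Path, seed: int) -> list[str]:
    from .simulate import CohortSpec, generate_profile_set

    params = dict(config.get("simulate_em", {}))
    params.setdefault("seed", seed)
    if "groups" in params:
        params["groups"] = tuple(tuple(g) for g in params["groups"])
    for key in ("zone_scale_by_group", "docked_scale_by_group"):
        if key in params:
            params[key] = dict(params[key])
    pset = generate_profile_set(CohortSpec(**params))
    write_annotations(pset.profiles, outdir / "annotations.json",
                      provenance={"tool": "synaptoquant", "seed": seed,
                                  "config_hash": config_hash(config)})
    write_truth_sidecar(pset.truth, outdir / "em_truth.json", pset.metadata)
    return ["annotations.json", "em_truth.json"]


def _stage_analyze_em(config: dict, outdir: Path, seed: int) -> list[str]:
    from .em import bin_undocked, cohort_summary, edge_distance, classify_vesicles, profile_counts

    params = config.get("analyze_em", {})
    path = params.get("input", outdir / "annotations.json")
    profiles = load_annotations(path)
    artifacts = []
    if not profiles:
        (outdir / "em_status.json").write_text(json.dumps({"status": "no data"}))
        pd.DataFrame().to_csv(outdir / "em_per_profile.csv", index=False)
        pd.DataFrame().to_csv(outdir / "em_cohort.csv", index=False)
        return ["em_status.json", "em_per_profile.csv", "em_cohort.csv"]
    dock_tol = params.get("dock_tolerance", 0.5)
    rows = []
    zone_distances = []
    for p in profiles:
        rec = profile_counts(p, dock_tol)
        rec["profile_id"] = p.profile_id
        rec.update({k: p.labels.get(k) for k in ("genotype", "timepoint", "replicate")})
        rows.append(rec)
        az = p.active_zone_polyline()
        classes = classify_vesicles(p, dock_tol)
        for v, c in zip(p.vesicles, classes):
            if c != "docked":
                zone_distances.append(edge_distance(v, az))
    pd.DataFrame(rows).to_csv(outdir / "em_per_profile.csv", index=False)
    cohort_summary(profiles, dock_tol,
                   normalize_to_no_stim=params.get("normalize_to_no_stim", False)
                   ).to_csv(outdir / "em_cohort.csv", index=False)
    bin_undocked(zone_distances).as_frame().to_csv(outdir / "em_histogram.csv", index=False)
    artifacts += ["em_per_profile.csv", "em_cohort.csv", "em_histogram.csv"]
    (outdir / "em_status.json").write_text(json.dumps({"status": "ok", "n_profiles": len(profiles)}))
    artifacts.append("em_status.json")
    return artifacts


def _stage_simulate_sted(config: dict, outdir: Path, seed: int) -> list[str]:
    import tifffile

    from .simulate import StedLayoutSpec, generate_sted_fixture

    params = dict(config.get("simulate_sted", {}))
    params.setdefault("seed", seed)
    if "boundary_shape" in params:
        params["boundary_shape"] = tuple(params["boundary_shape"])
    if "puncta_signed_distances" in params:
        params["puncta_signed_distances"] = tuple(params["puncta_signed_distances"])
    fx = generate_sted_fixture(StedLayoutSpec(**params))
    stack = np.stack([fx.reference, fx.target]).astype(np.float32)
    tifffile.imwrite(outdir / "sted_roi.tif", stack)
    write_truth_sidecar(fx.truth_sidecar(), outdir / "sted_truth.json")
    return ["sted_roi.tif", "sted_truth.json"]


def _stage_analyze_sted(config: dict, outdir: Path, seed: int) -> list[str]:
    import tifffile

    from .sted import RoiImagePair, analyze_roi_pair, boundary_distribution

    params = config.get("analyze_sted", {})
    path = params.get("input", outdir / "sted_roi.tif")
    stack = tifffile.imread(path)
    pair = RoiImagePair(reference_channel=stack[0], target_channel=stack[1],
                        pixel_size=params.get("pixel_size", 20.0))
    puncta, _ = analyze_roi_pair(pair, preprocess=params.get("preprocess", True))
    pd.DataFrame(
        [{"x_px": p.center[0], "y_px": p.center[1], "intensity": p.intensity,
          "signed_distance_nm": p.signed_distance, "excluded": p.excluded,
          "reason": p.reason} for p in puncta]
    ).to_csv(outdir / "sted_puncta.csv", index=False)
    summ = boundary_distribution(puncta)
    (outdir / "sted_summary.json").write_text(json.dumps(
        {"n": summ.n, "inside_fraction": summ.inside_fraction,
         "outside_fraction": summ.outside_fraction,
         "mean_abs_distance_nm": summ.mean_abs_distance,
         "mean_signed_distance_nm": summ.mean_signed_distance,
         "defined": summ.defined}, indent=1, sort_keys=True))
    return ["sted_puncta.csv", "sted_summary.json"]


def _stage_frap(config: dict, outdir: Path, seed: int) -> list[str]:
    from .condensate import FrapTrace, fit_one_phase, fractional_recovery

    params = config.get("frap", {})
    path = params.get("input")
    if path is None:
        from .simulate import generate_frap_trace

        sim = dict(params.get("simulate", {"tau": 2.0, "plateau": 0.8, "noise_sd": 0.05}))
        sim.setdefault("seed", seed)
        traces = {"sim_0": generate_frap_trace(**sim)}
    else:
        df = pd.read_csv(path)
        traces = {}
        for tid, grp in df.groupby("id"):
            grp = grp.sort_values("time_or_position")
            traces[tid] = FrapTrace(times=grp["time_or_position"].to_numpy(),
                                    intensities=grp["value"].to_numpy(),
                                    bleach_frame=int(grp["bleach_frame"].iloc[0]))
    rows = []
    for tid, tr in traces.items():
        fit = fit_one_phase(fractional_recovery(tr))
        rows.append({"id": tid, "tau_s": fit.tau, "plateau": fit.plateau,
                     "residual_norm": fit.residual_norm, "converged": fit.converged})
    pd.DataFrame(rows).to_csv(outdir / "frap_fits.csv", index=False)
    return ["frap_fits.csv"]


def _stage_cv(config: dict, outdir: Path, seed: int) -> list[str]:
    from .condensate import LineProfile, DispersionResult, dispersion_table, line_dispersion, normalize_dispersion

    params = config.get("cv", {})
    path = params.get("input")
    if path is None:
        from .simulate import generate_axon_profiles

        profiles = generate_axon_profiles("punctate", 5, seed=seed) + generate_axon_profiles(
            "diffuse", 5, seed=seed + 1)
    else:
        df = pd.read_csv(path)
        profiles = []
        for (aid, cond), grp in df.groupby(["id", "condition"]):
            grp = grp.sort_values("time_or_position")
            profiles.append(LineProfile(intensities=grp["value"].to_numpy(),
                                        condition=cond, axon_id=str(aid)))
    results = [DispersionResult(p.axon_id, p.condition, line_dispersion(p)) for p in profiles]
    dispersion_table(normalize_dispersion(results)).to_csv(outdir / "cv_results.csv", index=False)
    return ["cv_results.csv"]


def _stage_trains(config: dict, outdir: Path, seed: int) -> list[str]:
    from .trains import normalize_train, phase_means, rrp_back_extrapolation

    params = config.get("trains", {})
    path = params.get("input")
    if path is None:
        from .simulate import ReleaseModelSpec, simulate_depression_train

        sim = dict(params.get("simulate", {}))
        sim.setdefault("seed", seed)
        recs = {"sim_0": simulate_depression_train(ReleaseModelSpec(**sim))}
        amps = {k: v.amplitudes for k, v in recs.items()}
    else:
        df = pd.read_csv(path)
        amps = {sid: grp.sort_values("stimulus_index")["amplitude"].to_numpy()
                for sid, grp in df.groupby("sweep_id")}
    rows = []
    for sid, a in amps.items():
        norm = normalize_train(a)
        f10, l10 = phase_means(norm) if len(norm) >= 20 else (np.nan, np.nan)
        est = rrp_back_extrapolation(norm)
        rows.append({"sweep_id": sid, "a1": a[0], "first10_mean": f10, "last10_mean": l10,
                     "rrp_intercept_norm": est.intercept,
                     "rrp_nq_estimate": est.intercept * a[0],
                     "steady_slope": est.steady_slope, "r_squared": est.r_squared,
                     "window_lo": est.window[0], "window_hi": est.window[1],
                     "steady": est.steady})
    pd.DataFrame(rows).to_csv(outdir / "train_metrics.csv", index=False)
    return ["train_metrics.csv"]


def _stage_stats(config: dict, outdir: Path, seed: int) -> list[str]:
    from .stats import run_comparison, select_method

    params = config.get("stats", {})
    path = params.get("input", outdir / "em_per_profile.csv")
    df = pd.read_csv(path)
    group_col = params.get("group_column", "genotype")
    value_col = params.get("value_column", "replacement")
    groups = {str(k): v[value_col].to_numpy(dtype=float) for k, v in df.groupby(group_col)}
    plan = select_method(groups, zero_rule=params.get("zero_rule", "any_zero"))
    res = run_comparison(groups, plan)
    res.posthoc.to_csv(outdir / "stats_posthoc.csv", index=False)
    (outdir / "stats_result.json").write_text(json.dumps(
        {"test_name": res.test_name, "statistic": res.statistic, "p_value": res.p_value,
         "alpha": res.alpha, "selection_rationale": res.selection_rationale,
         "group_summaries": res.group_summaries.to_dict(orient="records")},
        indent=1, sort_keys=True))
    return ["stats_posthoc.csv", "stats_result.json"]


_STAGES = {
    "simulate-em": _stage_simulate_em,
    "analyze-em": _stage_analyze_em,
    "simulate-sted": _stage_simulate_sted,
    "analyze-sted": _stage_analyze_sted,
    "frap": _stage_frap,
    "cv": _stage_cv,
    "trains": _stage_trains,
    "stats": _stage_stats,
}


def run_pipeline(config: dict) -> Path:
    """Run the requested stages in order and write a manifest.

    ``config`` needs ``out`` (output directory) and may set ``seed``
    (default 0) and ``stages`` (default: simulate-em, analyze-em). Unknown
    stage names raise before any stage runs. Returns the manifest path.
    """
    outdir = Path(config["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ["simulate-em", "analyze-em"])
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages: {unknown}")
    artifacts: list[str] = []
    for name in stages:
        logger.info("running stage %s", name)
        try:
            artifacts += _STAGES[name](config, outdir, seed)
        except Exception as exc:
            write_manifest(outdir, config, artifacts)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return write_manifest(outdir, config, artifacts)
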