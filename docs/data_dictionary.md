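# Data dictionary

All tables are tidy (one observation per row), UTF-8, comma-separated,
'.' decimal, header row mandatory. All JSON artifacts are
`sort_keys=True`, indent 1.

## annotations.json (annotation document)

- `schema_version` — "1.0".
- `provenance` — tool name, seed, config hash (no timestamps).
- `profiles[]` — one object per synaptic profile:
  - `image_id` — profile identifier (string).
  - `pixel_size_nm` — nm per pixel; all geometry below is in pixels.
  - `labels` — `genotype`, `timepoint`, `replicate`.
  - `objects[]` — each with `kind` and `geometry`:
    - `membrane` — `{"polyline": [[x, y], ...]}`; exactly one per profile.
    - `active_zone` — `{"start_arc": s0, "end_arc": s1}` arc-length
      positions along the membrane polyline; at most one.
    - `vesicle` — `{"center": [x, y], "radius": r}`.
    - `pit` — `{"point": [x, y]}` plus
      `attributes.pit_kind` ∈ {exocytic, endocytic, clathrin-coated}.

## em_truth.json / sted_truth.json (ground-truth sidecars)

`metadata` (generator name, RNG algorithm, seed, gain where applicable)
plus `truth`: for EM, per profile the per-vesicle `class`,
`edge_distance_nm`, `center` and the drawn counts; for STED, the
half-max contour polygon (px), puncta positions (px) and realized signed
distances (nm).

## em_per_profile.csv

One row per profile: `profile_id`, `genotype`, `timepoint`, `replicate`,
`docked`, `replacement`, `undocked_50nm`, `total`, `pits_exocytic`,
`pits_endocytic`, `pits_clathrin_coated`.

## em_cohort.csv

One row per (genotype, timepoint, measure): `mean`, `sem`, `n`, plus
`norm_mean`, `norm_sem` when normalization to the "no stim" control is
requested.

## em_histogram.csv

One row per 2-nm bin: `bin_left`, `bin_right`, `count`, `rel_freq`
(NaN when the histogram is empty — undefined, not zero).

## sted_puncta.csv

One row per detected punctum: `x_px`, `y_px` (sub-pixel centre),
`intensity`, `signed_distance_nm` (negative = inside the boundary),
`excluded` (bool), `reason` ("edge" for border-touching foci).

## sted_summary.json

`n`, `inside_fraction` (signed distance ≤ 0), `outside_fraction`,
`mean_abs_distance_nm`, `mean_signed_distance_nm`, `defined`.

## frap_fits.csv

One row per trace: `id`, `tau_s`, `plateau`, `residual_norm`,
`converged`.

## cv_results.csv

One row per axon: `axon_id`, `condition`, `cv_raw` (variance/mean),
`cv_normalized` (per-condition mean = 1).

## train_metrics.csv

One row per sweep: `sweep_id`, `a1` (first response, raw units),
`first10_mean`, `last10_mean` (normalized), `rrp_intercept_norm`
(multiples of the first response), `rrp_nq_estimate` (intercept × A₁),
`steady_slope`, `r_squared`, `window_lo`, `window_hi` (1-based,
inclusive), `steady` (curvature flag).

## stats_result.json / stats_posthoc.csv

Result: `test_name`, `statistic`, `p_value`, `alpha`,
`selection_rationale`, `group_summaries` (group, n, mean, sem).
Post hoc: one row per pair: `group1`, `group2`, `statistic`,
`p_unadjusted`, `p_adjusted`.

## manifest.json

`config_hash` (SHA-256 prefix of the configuration minus the output
path), `seed`, and `artifacts`: file name → SHA-256 of its bytes.

## Long-format input CSVs (frap, cv stages)

`id`, `time_or_position`, `value`, plus `condition` (cv) or
`bleach_frame` (frap). Train input CSVs: `sweep_id`, `stimulus_index`,
`amplitude` (peak or slope — the caller's explicit choice).
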