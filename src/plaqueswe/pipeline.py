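"""End-to-end orchestration of the SWE analysis chain.

One run executes, per simulated acquisition: wave-field synthesis
(optionally encoded to speckle IQ and decoded again by the
autocorrelation estimator), directional filtering, depth averaging, the
time-to-peak group-velocity fit and the f-k phase-velocity band
analysis; acquisitions are then aggregated per plaque and view and fed
to the cohort statistics. Every excluded acquisition is logged with a
machine-readable reason code, and the manifest reconciles exclusion
counts against output row counts per metric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    AHA_TYPES,
    CohortTable,
    METRICS,
    TABLE_DEFAULT_VELOCITIES,
    default_component_specs,
    default_lipid_specs,
    _draw_component,
)
from .config import PipelineConfig
from .datatypes import AcquisitionGrid, ParticleVelocityField, ROIMask
from .dispersion import DispersionLaw
from .groupvel import RansacConfig, combine_directional_estimates, estimate_group_velocity
from .motion import estimate_particle_velocity
from .phasevel import BAND_EDGES, band_average, compute_dispersion, extract_curve
from .simulate import WaveSimConfig, modulate_to_iq, simulate_wavefield
from .stats import aggregate_plaque, run_full_evaluation
from .waves import depth_average, directional_filter

__all__ = ["RunManifest", "run_pipeline", "process_acquisition"]

BAND_NAMES = ("pv_200_300", "pv_300_400", "pv_400_500")

# Constant-law demo speeds must clear the record end: the slowest packet
# has to cross the ROI (plus burst tails) inside the 18 ms window.
_SPEED_FLOOR = 2.8
_SPEED_CEIL = 9.5


@dataclass
class RunManifest:
    config: dict
    version: str
    n_acquisitions: int
    exclusions: list[dict] = field(default_factory=list)
    excluded_counts: dict = field(default_factory=dict)
    included_counts: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        """Exclusions + included rows must account for every acquisition,
        per metric."""
        metrics = set(self.excluded_counts) | set(self.included_counts)
        return all(
            self.excluded_counts.get(m, 0) + self.included_counts.get(m, 0)
            == self.n_acquisitions
            for m in metrics
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_acquisition(
    field: ParticleVelocityField,
    roi: ROIMask,
    cfg: PipelineConfig,
    ransac_seed: int = 0,
) -> tuple[float | None, dict[str, float], dict]:
    """Run one velocity movie through filtering, group- and
    phase-velocity analysis.

    Returns ``(group_velocity, band_velocities, details)``;
    ``group_velocity`` is ``None`` when no direction passes the quality
    gate, and ``band_velocities`` holds only the bands valid in at least
    one direction (directions are averaged).
    """
    left, right = directional_filter(field, tukey_alpha=cfg.maps.tukey_alpha)
    maps = {
        "leftward": depth_average(left, roi, "leftward"),
        "rightward": depth_average(right, roi, "rightward"),
    }
    ransac = RansacConfig(
        n_iter=cfg.group_velocity.n_iter,
        residual_threshold=cfg.group_velocity.residual_threshold,
        min_samples=cfg.group_velocity.min_samples,
        seed=ransac_seed,
        quality_gate=cfg.group_velocity.quality_gate,
    )
    gv_ests = {d: estimate_group_velocity(m, ransac=ransac) for d, m in maps.items()}
    gv = combine_directional_estimates(list(gv_ests.values()))

    pv = cfg.phase_velocity
    band_values: dict[str, list[float]] = {b: [] for b in BAND_NAMES}
    for d, m in maps.items():
        disp = compute_dispersion(m, pad_factor=pv.pad_factor, tukey_alpha=cfg.maps.tukey_alpha)
        curve = extract_curve(
            disp,
            v_min=pv.v_min,
            v_max=pv.v_max,
            crop=pv.crop,
            prominence_threshold=pv.prominence_threshold,
        )
        bands = band_average(curve, min_valid_fraction=pv.min_valid_fraction, direction=d)
        for name, mean, ok in zip(BAND_NAMES, bands.band_means, bands.band_valid):
            if ok:
                band_values[name].append(mean)
    bands_out = {b: float(np.mean(v)) for b, v in band_values.items() if v}
    details = {
        "gv_estimates": gv_ests,
        "inlier_ratios": {d: e.inlier_ratio for d, e in gv_ests.items()},
    }
    return gv, bands_out, details


def run_pipeline(cfg: PipelineConfig, out_dir) -> RunManifest:
    """Simulate a small cohort and run the full analysis chain.

    Writes ``gv.csv`` (one row per included acquisition), ``pv.csv``
    (one row per included acquisition x band), ``cohort.csv`` (per
    plaque x view summaries with synthetic component covariates),
    ``report/`` (statistics tables) and ``manifest.json`` under
    ``out_dir``. Identical config and seed give identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid = AcquisitionGrid(**asdict(cfg.grid))
    roi = ROIMask.box(grid)
    sim = cfg.simulate
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x919E]))

    aha = [AHA_TYPES[i % len(AHA_TYPES)] for i in range(sim.n_plaques)]
    true_speed = {}
    for p in range(sim.n_plaques):
        for view in sim.views:
            mu, sd = TABLE_DEFAULT_VELOCITIES[("group_velocity", view, aha[p])]
            true_speed[(p, view)] = float(np.clip(rng.normal(mu, sd), _SPEED_FLOOR, _SPEED_CEIL))

    n_total = sim.n_plaques * len(sim.views) * sim.acquisitions_per_plaque
    seeds = np.random.SeedSequence([cfg.seed, 0xACC]).generate_state(2 * n_total) % (2**31)

    gv_rows: list[dict] = []
    pv_rows: list[dict] = []
    exclusions: list[dict] = []
    idx = 0
    for p in range(sim.n_plaques):
        pid = f"P{p + 1:03d}"
        for view in sim.views:
            for acq in range(sim.acquisitions_per_plaque):
                corrupted = idx < sim.corrupt_acquisitions
                if corrupted:
                    noise_rng = np.random.default_rng(int(seeds[2 * idx]))
                    values = noise_rng.normal(
                        0.0, sim.amplitude, size=(grid.n_depth, grid.n_lateral, grid.n_frames)
                    )
                    fld = ParticleVelocityField(values=values, grid=grid)
                else:
                    wave_cfg = WaveSimConfig(
                        grid=grid,
                        dispersion=DispersionLaw.constant(true_speed[(p, view)]),
                        push_time=sim.push_time,
                        push_duration=sim.push_duration,
                        amplitude=sim.amplitude,
                        snr_db=sim.snr_db,
                        seed=int(seeds[2 * idx]),
                        roi=roi,
                    )
                    fld = simulate_wavefield(wave_cfg)
                if cfg.motion.use_iq:
                    vmax = float(np.max(np.abs(fld.values)))
                    if vmax >= grid.aliasing_limit:
                        exclusions.append(
                            {"plaque_id": pid, "view": view, "acq": acq,
                             "metric": "all", "reason": "aliasing_limit"}
                        )
                        for m in ("group_velocity",) + BAND_NAMES:
                            exclusions.append(
                                {"plaque_id": pid, "view": view, "acq": acq,
                                 "metric": m, "reason": "aliasing_limit"}
                            )
                        idx += 1
                        continue
                    iq = modulate_to_iq(fld, scatter_seed=int(seeds[2 * idx + 1]))
                    fld = estimate_particle_velocity(iq, *cfg.motion.kernel)

                gv, bands, details = process_acquisition(
                    fld, roi, cfg, ransac_seed=int(seeds[2 * idx])
                )
                if gv is None:
                    exclusions.append(
                        {"plaque_id": pid, "view": view, "acq": acq,
                         "metric": "group_velocity", "reason": "gv_quality_gate"}
                    )
                else:
                    ratios = details["inlier_ratios"]
                    gv_rows.append(
                        {"plaque_id": pid, "view": view, "acq": acq, "velocity": gv,
                         "inlier_ratio_leftward": ratios["leftward"],
                         "inlier_ratio_rightward": ratios["rightward"]}
                    )
                for band in BAND_NAMES:
                    if band in bands:
                        pv_rows.append(
                            {"plaque_id": pid, "view": view, "acq": acq,
                             "band": band, "velocity": bands[band]}
                        )
                    else:
                        exclusions.append(
                            {"plaque_id": pid, "view": view, "acq": acq,
                             "metric": band, "reason": "band_invalid"}
                        )
                idx += 1

    gv_df = pd.DataFrame(gv_rows, columns=[
        "plaque_id", "view", "acq", "velocity",
        "inlier_ratio_leftward", "inlier_ratio_rightward",
    ])
    pv_df = pd.DataFrame(pv_rows, columns=["plaque_id", "view", "acq", "band", "velocity"])
    gv_df.to_csv(out / "gv.csv", index=False)
    pv_df.to_csv(out / "pv.csv", index=False)

    cohort = _aggregate_cohort(cfg, aha, sim, gv_df, pv_df)
    cohort.to_csv(out / "cohort.csv")

    if cfg.evaluate.enabled:
        report = run_full_evaluation(cohort)
        report.write(out / "report")

    excluded_counts = {m: 0 for m in ("group_velocity",) + BAND_NAMES}
    for e in exclusions:
        if e["metric"] in excluded_counts:
            excluded_counts[e["metric"]] += 1
    included_counts = {"group_velocity": len(gv_df)}
    for band in BAND_NAMES:
        included_counts[band] = int((pv_df["band"] == band).sum()) if len(pv_df) else 0

    manifest = RunManifest(
        config=cfg.to_dict(),
        version=__version__,
        n_acquisitions=n_total,
        exclusions=exclusions,
        excluded_counts=excluded_counts,
        included_counts=included_counts,
    )
    for name in ("gv.csv", "pv.csv", "cohort.csv"):
        manifest.digests[name] = _sha256(out / name)
    if cfg.evaluate.enabled:
        for f in sorted((out / "report").iterdir()):
            manifest.digests[f"report/{f.name}"] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest


def _aggregate_cohort(
    cfg: PipelineConfig,
    aha: list[str],
    sim,
    gv_df: pd.DataFrame,
    pv_df: pd.DataFrame,
) -> CohortTable:
    """Per-plaque summaries plus synthetic component covariates tied to
    the realized velocities."""
    n_plaques = len(aha)
    rows = []
    mean_by_metric: dict[tuple[str, str], np.ndarray] = {}
    for metric in METRICS:
        for view in sim.views:
            arr = np.full(n_plaques, np.nan)
            for p in range(n_plaques):
                pid = f"P{p + 1:03d}"
                if metric == "group_velocity":
                    vals = gv_df.loc[
                        (gv_df["plaque_id"] == pid) & (gv_df["view"] == view), "velocity"
                    ].to_numpy()
                else:
                    vals = pv_df.loc[
                        (pv_df["plaque_id"] == pid)
                        & (pv_df["view"] == view)
                        & (pv_df["band"] == metric),
                        "velocity",
                    ].to_numpy()
                if vals.size:
                    arr[p] = vals.mean()
            mean_by_metric[(metric, view)] = arr

    z_by_metric = {}
    for key, arr in mean_by_metric.items():
        filled = np.where(np.isfinite(arr), arr, np.nanmean(arr) if np.isfinite(arr).any() else 0.0)
        sd = filled.std()
        z_by_metric[key] = (filled - filled.mean()) / sd if sd > 0 else np.zeros(n_plaques)

    comp_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC09]))
    covariates = {}
    for spec in default_component_specs() + default_lipid_specs():
        if spec.target is not None and (spec.target[0], spec.target[1]) not in z_by_metric:
            continue
        vals = _draw_component(comp_rng, spec, z_by_metric, n_plaques)
        if cfg.evaluate.missing_fraction > 0:
            miss = comp_rng.random(n_plaques) < cfg.evaluate.missing_fraction
            vals[miss] = np.nan
        covariates[spec.name] = vals

    for p in range(n_plaques):
        for view in sim.views:
            row = {
                "plaque_id": f"P{p + 1:03d}",
                "subject_id": f"S{p + 1:03d}",
                "view": view,
                "aha_type": aha[p],
            }
            for metric in METRICS:
                pid = f"P{p + 1:03d}"
                if metric == "group_velocity":
                    vals = gv_df.loc[
                        (gv_df["plaque_id"] == pid) & (gv_df["view"] == view), "velocity"
                    ].to_numpy()
                else:
                    vals = pv_df.loc[
                        (pv_df["plaque_id"] == pid)
                        & (pv_df["view"] == view)
                        & (pv_df["band"] == metric),
                        "velocity",
                    ].to_numpy()
                if vals.size:
                    mean, sd, n = aggregate_plaque(vals)
                else:
                    mean, sd, n = np.nan, np.nan, 0
                row[f"{metric}_mean"] = mean
                row[f"{metric}_sd"] = sd
                row[f"{metric}_n"] = n
            for name, vals in covariates.items():
                row[name] = vals[p]
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))
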