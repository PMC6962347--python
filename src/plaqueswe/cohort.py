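"""Synthetic carotid-plaque cohort generation.

Generates per-plaque SWE summaries and MRI-style component metrics with
a known statistical structure so the cohort-level statistics stage has a
recovery target. Defaults reproduce the study conditions of a 27-plaque
carotid cohort: 7 / 8 / 8 / 4 plaques of modified AHA types
III / V / VI / VII, per-group velocity means and standard deviations for
group velocity and the three phase-velocity bands in both imaging views,
5-15 acquisitions per plaque and view, and a per-acquisition scatter of
1.5 m/s (the middle of the 1-2 m/s single-plaque spread typical of this
kind of data).

Component metrics (lipid-rich necrotic core content, cap volume,
intraplaque hemorrhage, calcification, loose matrix, ...) are built by
the standard bivariate-normal device: the component's z-score is
R * z_v + sqrt(1 - R^2) * eps against the standardized realized value of
a named velocity metric, hitting the target Pearson R in expectation.
Missing values (components that could not be delineated for a plaque)
are inserted independently at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AHA_TYPES",
    "VIEWS",
    "METRICS",
    "COMPONENT_COLUMNS",
    "LIPID_COLUMNS",
    "TABLE_DEFAULT_VELOCITIES",
    "ComponentSpec",
    "CohortSimConfig",
    "CohortTable",
    "simulate_cohort",
]

AHA_TYPES = ("III", "V", "VI", "VII")
VIEWS = ("L", "T")
METRICS = ("group_velocity", "pv_200_300", "pv_300_400", "pv_400_500")

#: Default per-group velocity (mean, sd) in m/s, keyed (metric, view, aha).
TABLE_DEFAULT_VELOCITIES: dict[tuple[str, str, str], tuple[float, float]] = {}
_T2 = {
    "group_velocity": {
        "L": {"III": (4.2, 1.1), "V": (4.0, 1.1), "VI": (5.8, 0.6), "VII": (4.1, 1.0)},
        "T": {"III": (3.6, 1.3), "V": (3.3, 0.7), "VI": (7.3, 2.5), "VII": (3.1, 0.6)},
    },
    "pv_200_300": {
        "L": {"III": (3.0, 0.7), "V": (4.0, 1.1), "VI": (4.6, 1.1), "VII": (3.8, 2.2)},
        "T": {"III": (3.0, 1.3), "V": (3.0, 1.5), "VI": (3.5, 1.2), "VII": (2.5, 0.4)},
    },
    "pv_300_400": {
        "L": {"III": (3.8, 1.0), "V": (4.1, 1.5), "VI": (6.1, 2.1), "VII": (4.8, 2.4)},
        "T": {"III": (3.3, 2.5), "V": (3.2, 1.5), "VI": (5.0, 2.5), "VII": (3.4, 0.6)},
    },
    "pv_400_500": {
        "L": {"III": (4.8, 1.7), "V": (4.1, 1.9), "VI": (7.0, 1.4), "VII": (4.6, 1.9)},
        "T": {"III": (4.1, 1.8), "V": (4.3, 1.4), "VI": (5.2, 2.1), "VII": (4.1, 0.8)},
    },
}
for _m, _views in _T2.items():
    for _v, _groups in _views.items():
        for _a, _ms in _groups.items():
            TABLE_DEFAULT_VELOCITIES[(_m, _v, _a)] = _ms


@dataclass(frozen=True)
class ComponentSpec:
    """Scale and (optional) correlation target of one cohort covariate."""

    name: str
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf
    #: (metric, view, target Pearson R) or None for an independent draw.
    target: Optional[tuple[str, str, float]] = None
    subject_level: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("component sd must be >= 0")
        if self.target is not None and abs(self.target[2]) > 1:
            raise ValueError("|target R| must be <= 1")


def default_component_specs() -> tuple[ComponentSpec, ...]:
    return (
        ComponentSpec("lrnc_pct", 25.0, 10.0, 0.0, 100.0, ("group_velocity", "T", 0.58)),
        ComponentSpec("lrnc_volume_mm3", 120.0, 55.0, 0.0, np.inf, ("group_velocity", "T", 0.62)),
        ComponentSpec("cap_volume_mm3", 60.0, 28.0, 0.0, np.inf, ("group_velocity", "L", 0.60)),
        ComponentSpec("cap_thickness_mm", 1.0, 0.4, 0.05, np.inf, None),
        ComponentSpec("iph_volume_mm3", 20.0, 15.0, 0.0, np.inf, ("pv_300_400", "L", -0.60)),
        ComponentSpec(
            "calcification_volume_mm3", 40.0, 28.0, 0.0, np.inf, ("pv_400_500", "T", 0.64)
        ),
        ComponentSpec(
            "loose_matrix_volume_mm3", 30.0, 18.0, 0.0, np.inf, ("pv_400_500", "T", -0.64)
        ),
        ComponentSpec("cap_core_ratio", 0.8, 0.35, 0.05, np.inf, ("pv_400_500", "T", -0.61)),
    )


def default_lipid_specs() -> tuple[ComponentSpec, ...]:
    # Lipid panel scales follow a typical statin-treated cohort.
    return (
        ComponentSpec("hdl_mgdl", 46.9, 14.3, 10.0, np.inf, ("group_velocity", "T", 0.56), True),
        ComponentSpec("ldl_mgdl", 89.1, 37.3, 20.0, np.inf, None, True),
        ComponentSpec("tg_mgdl", 175.3, 107.7, 20.0, np.inf, None, True),
        ComponentSpec("total_cholesterol_mgdl", 170.1, 41.3, 60.0, np.inf, None, True),
    )


COMPONENT_COLUMNS = tuple(s.name for s in default_component_specs())
LIPID_COLUMNS = tuple(s.name for s in default_lipid_specs())


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters of the cohort generator."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"III": 7, "V": 8, "VI": 8, "VII": 4}
    )
    velocity_means_sds: Mapping[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_DEFAULT_VELOCITIES)
    )
    acquisitions_per_plaque: tuple[int, int] = (5, 15)
    acquisition_noise_sd: float = 1.5
    components: Sequence[ComponentSpec] = field(default_factory=default_component_specs)
    lipids: Sequence[ComponentSpec] = field(default_factory=default_lipid_specs)
    missing_fraction: float = 0.1
    seed: int = 0
    min_velocity: float = 0.2  # truncation floor for drawn speeds, m/s

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for key, (m, s) in self.velocity_means_sds.items():
            if len(key) != 3:
                raise ValueError("velocity map keys must be (metric, view, aha)")
            if s < 0:
                raise ValueError(f"sd must be >= 0 for {key}")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        lo, hi = self.acquisitions_per_plaque
        if lo < 1 or hi < lo:
            raise ValueError("acquisitions_per_plaque must be a valid count range")
        if self.acquisition_noise_sd < 0:
            raise ValueError("acquisition_noise_sd must be >= 0")


REQUIRED_COLUMNS = ("plaque_id", "subject_id", "view", "aha_type")


@dataclass(frozen=True)
class CohortTable:
    """One row per plaque and imaging view; metric columns come as
    ``{metric}_mean`` / ``{metric}_sd`` / ``{metric}_n`` triples, with
    component and lipid covariates repeated across a plaque's rows.
    Missing values are empty cells (NaN)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"cohort table is missing required column {col!r}")
        bad_views = set(self.data["view"].unique()) - set(VIEWS)
        if bad_views:
            raise ValueError(f"unknown view labels in column 'view': {sorted(bad_views)}")

    @property
    def n_plaques(self) -> int:
        return self.data["plaque_id"].nunique()

    def metric_columns(self) -> list[str]:
        return [m for m in METRICS if f"{m}_mean" in self.data.columns]

    def covariate_columns(self) -> list[str]:
        known = set(REQUIRED_COLUMNS)
        known |= {f"{m}_{s}" for m in METRICS for s in ("mean", "sd", "n")}
        return [c for c in self.data.columns if c not in known]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, dtype={"view": str, "aha_type": str}))


def _draw_component(
    rng: np.random.Generator,
    spec: ComponentSpec,
    z_by_metric: dict[tuple[str, str], np.ndarray],
    n: int,
) -> np.ndarray:
    eps = rng.standard_normal(n)
    if spec.target is None or spec.sd == 0:
        z = eps
    else:
        metric, view, r = spec.target
        zv = z_by_metric[(metric, view)]
        z = r * zv + np.sqrt(1.0 - r * r) * eps
    return np.clip(spec.mean + spec.sd * z, spec.lo, spec.hi)


def simulate_cohort(config: CohortSimConfig = CohortSimConfig()) -> CohortTable:
    """Generate a seeded synthetic cohort table.

    Per plaque and metric the true velocity is drawn from its AHA
    group's normal; per-acquisition values add independent Gaussian
    noise and are summarised as mean / sample SD / count. Identical
    seeds give identical tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0F0]))

    aha = [a for a in AHA_TYPES if a in config.group_sizes for _ in range(config.group_sizes[a])]
    # keep any non-standard group labels too, in declaration order
    for a, n in config.group_sizes.items():
        if a not in AHA_TYPES:
            aha.extend([a] * n)
    n_plaques = len(aha)

    # ~20 subjects carried the 27 plaques; scale that ratio to any size.
    n_subjects = max(1, int(round(n_plaques * 20.0 / 27.0)))
    subj_idx = sorted(list(range(n_subjects)) + list(range(n_plaques - n_subjects)))

    metrics = sorted({k[0] for k in config.velocity_means_sds})
    metrics = [m for m in METRICS if m in metrics] + [m for m in metrics if m not in METRICS]
    views = sorted({k[1] for k in config.velocity_means_sds}, key=lambda v: (v != "L", v))

    lo, hi = config.acquisitions_per_plaque
    mean_arrays: dict[tuple[str, str], np.ndarray] = {}
    sd_arrays: dict[tuple[str, str], np.ndarray] = {}
    n_arrays: dict[tuple[str, str], np.ndarray] = {}
    for metric in metrics:
        for view in views:
            means = np.empty(n_plaques)
            sds = np.empty(n_plaques)
            counts = np.empty(n_plaques, dtype=int)
            for p in range(n_plaques):
                mu, sigma = config.velocity_means_sds[(metric, view, aha[p])]
                true = max(config.min_velocity, rng.normal(mu, sigma))
                n_acq = int(rng.integers(lo, hi + 1))
                acq = true + config.acquisition_noise_sd * rng.standard_normal(n_acq)
                means[p] = acq.mean()
                sds[p] = acq.std(ddof=1) if n_acq > 1 else 0.0
                counts[p] = n_acq
            mean_arrays[(metric, view)] = means
            sd_arrays[(metric, view)] = sds
            n_arrays[(metric, view)] = counts

    z_by_metric = {
        key: (arr - arr.mean()) / arr.std() if arr.std() > 0 else np.zeros_like(arr)
        for key, arr in mean_arrays.items()
    }

    covariates: dict[str, np.ndarray] = {}
    for spec in list(config.components) + list(config.lipids):
        if spec.target is not None and (spec.target[0], spec.target[1]) not in z_by_metric:
            raise ValueError(
                f"component {spec.name!r} targets unknown metric {spec.target[:2]}"
            )
        vals = _draw_component(rng, spec, z_by_metric, n_plaques)
        if spec.subject_level:
            # subjects contributing several plaques share one lipid panel
            first_of_subject: dict[int, float] = {}
            for p in range(n_plaques):
                vals[p] = first_of_subject.setdefault(subj_idx[p], vals[p])
        if config.missing_fraction > 0:
            miss = rng.random(n_plaques) < config.missing_fraction
            vals = vals.copy()
            vals[miss] = np.nan
        covariates[spec.name] = vals

    rows = []
    for p in range(n_plaques):
        for view in views:
            row = {
                "plaque_id": f"P{p + 1:03d}",
                "subject_id": f"S{subj_idx[p] + 1:03d}",
                "view": view,
                "aha_type": aha[p],
            }
            for metric in metrics:
                row[f"{metric}_mean"] = mean_arrays[(metric, view)][p]
                row[f"{metric}_sd"] = sd_arrays[(metric, view)][p]
                row[f"{metric}_n"] = n_arrays[(metric, view)][p]
            for name, vals in covariates.items():
                row[name] = vals[p]
            rows.append(row)
    return CohortTable(pd.DataFrame(rows))
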