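"""Seeded synthetic cohorts with the structure the analysis assumes.

Generates a two-group cohort over a configurable age span with
region-specific nonlinear age trajectories (exponential decay toward an
adult asymptote), site offsets, per-subject offsets, optionally
age-dependent residual noise, a planted subgroup of region-wise outliers,
a few globally-thin subjects, and phenotype scores partially coupled to
the planted deviations. Ground truth is returned alongside the tables so
recovery can be tested.

One global seed expands into named substreams (ages, sites, params, noise,
planting, phenotypes); adding a stream never perturbs earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import CohortTable, MorphMatrix

_STREAMS = ("params", "demographics", "sites", "subject", "noise", "planting", "phenotypes")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs (not estimates of any real dataset).

    Trajectories: thickness(age) = asymptote + offset * exp(-(age-age_min)/tau),
    with per-region (asymptote, offset, tau) drawn uniformly from the given
    ranges. Residual noise is Gaussian with SD ``residual_sd`` optionally
    scaled linearly with age by ``residual_sd_age_slope`` (per year, applied
    around the age-range midpoint).
    """

    n_control: int = 500
    n_case: int = 500
    n_regions: int = 308
    age_range: tuple[float, float] = (5.0, 40.0)
    n_sites: int = 4
    site_sd: float = 0.03
    asymptote_range: tuple[float, float] = (2.2, 2.8)
    offset_range: tuple[float, float] = (0.3, 0.7)
    tau_range: tuple[float, float] = (5.0, 12.0)
    residual_sd: float = 0.10
    residual_sd_age_slope: float = 0.0
    subject_sd: float = 0.0
    outlier_prevalence: float = 0.0
    outlier_magnitude: float = 3.0
    outlier_negative_fraction: float = 0.5
    n_global_thin: int = 0
    global_thin_region_fraction: float = 0.75
    female_fraction: float = 0.0
    age_skew: float = 2.5
    seed: int = 0
    #: seeds the population structure (region trajectories, site offsets);
    #: two cohorts sharing a population_seed are draws from the same world
    population_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 0 or self.n_regions < 1:
            raise ValueError("cohort sizes and region count must be positive")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("age_range min must be < max")
        for name in ("site_sd", "residual_sd", "subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.outlier_prevalence <= 1.0):
            raise ValueError("outlier_prevalence must be in [0, 1]")
        if not (0.0 <= self.outlier_negative_fraction <= 1.0):
            raise ValueError("outlier_negative_fraction must be in [0, 1]")
        if not (0.5 < self.global_thin_region_fraction <= 1.0):
            raise ValueError("global_thin_region_fraction must exceed 0.5")
        if self.n_global_thin > self.n_case:
            raise ValueError("n_global_thin cannot exceed n_case")
        if self.outlier_magnitude <= 0:
            raise ValueError("outlier_magnitude must be > 0")

    @property
    def region_ids(self) -> list[str]:
        width = len(str(self.n_regions))
        return [f"region_{i:0{width}d}" for i in range(1, self.n_regions + 1)]


@dataclass
class GroundTruth:
    """What was planted, for recovery tests.

    ``deviation_sd`` holds the pre-noise planted shift per subject x region
    in units of the local residual SD (0 where nothing was planted).
    """

    trajectory: pd.DataFrame          # subjects x regions, noise-free trajectory values
    outlier_flags: pd.DataFrame       # bool, subjects x regions
    global_thin: pd.Series            # bool per subject
    deviation_sd: pd.DataFrame        # planted shift in local-SD units
    region_params: pd.DataFrame = field(default=None)  # asymptote/offset/tau per region


def _trajectory(age: np.ndarray, asym: np.ndarray, off: np.ndarray,
                tau: np.ndarray, age_min: float) -> np.ndarray:
    """Noise-free regional thickness, shape (n_subjects, n_regions)."""
    return asym[None, :] + off[None, :] * np.exp(-(age[:, None] - age_min) / tau[None, :])


def _local_sd(cfg: SimConfig, age: np.ndarray) -> np.ndarray:
    mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    sd = cfg.residual_sd + cfg.residual_sd_age_slope * (age - mid)
    return np.clip(sd, 0.0, None)


def generate_cohort(cfg: SimConfig) -> tuple[CohortTable, MorphMatrix, GroundTruth]:
    """Draw a full synthetic cohort; bit-identical for identical config + seed."""
    rng = _substreams(cfg.seed)
    rng_pop = _substreams(cfg.population_seed)
    n = cfg.n_control + cfg.n_case
    lo, hi = cfg.age_range

    # right-skewed ages: more children than adults
    ages = lo + (hi - lo) * rng["demographics"].beta(1.2, cfg.age_skew, size=n)
    sexes = np.where(rng["demographics"].random(n) < cfg.female_fraction, "female", "male")
    groups = np.array(["control"] * cfg.n_control + ["case"] * cfg.n_case)

    # population structure is tied to population_seed, not the cohort seed
    site_labels = [f"site_{i + 1:02d}" for i in range(cfg.n_sites)]
    site_offsets = rng_pop["sites"].normal(0.0, cfg.site_sd, size=cfg.n_sites)
    site_idx = rng["sites"].integers(0, cfg.n_sites, size=n)

    asym = rng_pop["params"].uniform(*cfg.asymptote_range, size=cfg.n_regions)
    off = rng_pop["params"].uniform(*cfg.offset_range, size=cfg.n_regions)
    tau = rng_pop["params"].uniform(*cfg.tau_range, size=cfg.n_regions)

    ids = [f"sub_{i + 1:05d}" for i in range(n)]
    traj = _trajectory(ages, asym, off, tau, lo)
    sd = _local_sd(cfg, ages)[:, None]

    subj_offset = rng["subject"].normal(0.0, cfg.subject_sd, size=n) if cfg.subject_sd else np.zeros(n)
    noise = rng["noise"].normal(0.0, 1.0, size=(n, cfg.n_regions)) * sd

    # region-wise independent outlier planting, cases only
    is_case = groups == "case"
    plant = np.zeros((n, cfg.n_regions), dtype=bool)
    if cfg.outlier_prevalence > 0 and cfg.n_case:
        plant[is_case] = rng["planting"].random((cfg.n_case, cfg.n_regions)) < cfg.outlier_prevalence
    signs = np.where(rng["planting"].random((n, cfg.n_regions)) < cfg.outlier_negative_fraction,
                     -1.0, 1.0)
    deviation = np.where(plant, signs * cfg.outlier_magnitude, 0.0)

    global_thin = np.zeros(n, dtype=bool)
    if cfg.n_global_thin:
        case_pos = np.flatnonzero(is_case)
        chosen = rng["planting"].choice(case_pos, size=cfg.n_global_thin, replace=False)
        global_thin[chosen] = True
        for i in chosen:
            k = int(round(cfg.global_thin_region_fraction * cfg.n_regions))
            regs = rng["planting"].choice(cfg.n_regions, size=k, replace=False)
            deviation[i, regs] = -cfg.outlier_magnitude

    values = traj + site_offsets[site_idx][:, None] + subj_offset[:, None] \
        + deviation * sd + noise
    values = np.clip(values, 1e-3, None)  # thickness must stay positive

    cohort = CohortTable(pd.DataFrame(dict(
        subject_id=ids, group=groups, sex=sexes, age=ages,
        site=[site_labels[i] for i in site_idx],
        motion_fd=np.round(rng["demographics"].gamma(2.0, 0.05, size=n), 6),
        euler=np.round(rng["demographics"].gamma(3.0, 30.0, size=n)).astype(float),
    )), age_range=(lo - 1e-9, hi + 1e-9))

    region_ids = cfg.region_ids
    index = pd.Index(ids, name="subject_id")
    morph = MorphMatrix(pd.DataFrame(values, index=index, columns=region_ids))
    truth = GroundTruth(
        trajectory=pd.DataFrame(traj, index=index, columns=region_ids),
        outlier_flags=pd.DataFrame(deviation != 0, index=index, columns=region_ids),
        global_thin=pd.Series(global_thin, index=index),
        deviation_sd=pd.DataFrame(deviation, index=index, columns=region_ids),
        region_params=pd.DataFrame(dict(asymptote=asym, offset=off, tau=tau),
                                   index=pd.Index(region_ids, name="region")),
    )
    return cohort, morph, truth


@dataclass(frozen=True)
class PhenotypeCoupling:
    """One phenotype coupled to the mean planted deviation in target regions."""

    name: str
    regions: tuple[str, ...]
    slope: float = 0.0
    baseline: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0


def generate_phenotypes(
    cohort: CohortTable,
    truth: GroundTruth,
    couplings: list[PhenotypeCoupling],
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype = baseline + slope * mean planted deviation (SD units) + noise.

    A missing-at-random mask with the configured rate is applied per
    phenotype. Returns a table indexed by subject_id.
    """
    rng = _substreams(seed)["phenotypes"]
    ids = truth.deviation_sd.index
    out = pd.DataFrame(index=ids)
    known = set(truth.deviation_sd.columns)
    for cp in couplings:
        unknown = [r for r in cp.regions if r not in known]
        if unknown:
            raise ValueError(f"coupling {cp.name!r} names unknown regions: {unknown}")
        signal = truth.deviation_sd[list(cp.regions)].mean(axis=1).to_numpy()
        vals = cp.baseline + cp.slope * signal
        if cp.noise_sd > 0:
            vals = vals + rng.normal(0.0, cp.noise_sd, size=len(ids))
        if cp.missing_rate > 0:
            vals = np.where(rng.random(len(ids)) < cp.missing_rate, np.nan, vals)
        out[cp.name] = vals
    return out.loc[out.index.intersection(cohort.subject_ids)]
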