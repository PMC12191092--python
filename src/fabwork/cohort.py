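"""Synthetic SED-style cohort generator.

Generates seeded longitudinal person-year panels with the marginal moments,
change-from-baseline structure, missingness patterns, and steady-work
prevalence of the Supported Employment Demonstration Public Use File, so the
downstream modelling stages are testable without access to the restricted
file.

The generating mechanism is, deliberately, the analysis model run forward:

* WD-FAB scale trajectories: baseline ~ N(mu_s, sd_s) per scale, year-t value
  = baseline + an independent change draw with that year's change moments
  (within-participant correlation induced by the shared baseline);
* medical/utilization variables: per-year negative-binomial counts or
  >=0-truncated normal scores, independent across years;
* Community Mobility Drive/Ride/Wheelchair presence flags: per-year Bernoulli;
* steady work: y_it ~ Bernoulli(logit^-1(alpha_t + z' beta_true)) on a
  population-standardized "truth" design built from the pre-missingness panel;
* missingness: a participant-level pattern from {0, 7, 14, 21} blanking all
  seven scale scores in 0-3 follow-up waves, completely at random.

The pre-missingness values are retained in a hidden truth channel so oracle
tests can unmask exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from . import tables

logger = logging.getLogger(__name__)

DEMOGRAPHIC_COLUMNS = (
    "age",
    "baseline_working",
    "worked_past_2yr",
    "education",
    "race",
    "stable_housing",
    "vehicle_access",
    "arm",
)

_REFERENCE_SEED = 20_202_020  # internal stream for intercept calibration


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class ScaleParams(BaseModel):
    """Baseline and per-year change moments for one WD-FAB scale."""

    model_config = ConfigDict(frozen=True)

    baseline: tuple[float, float]
    change: tuple[tuple[float, float], ...]
    mdc90: Optional[float] = None

    @field_validator("baseline")
    @classmethod
    def _baseline_sd_positive(cls, v):
        if v[1] <= 0:
            raise ValueError("baseline SD must be strictly positive")
        return v

    @field_validator("change")
    @classmethod
    def _change_sd_nonneg(cls, v):
        for mean, sd in v:
            if sd < 0:
                raise ValueError("change SD must be non-negative")
        return v


class MedicalParams(BaseModel):
    """Per-year moments of one medical/utilization variable."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["score", "count"]
    by_year: tuple[tuple[float, float], ...]

    @field_validator("by_year")
    @classmethod
    def _moments_valid(cls, v):
        for mean, sd in v:
            if mean < 0:
                raise ValueError("medical variable means must be non-negative")
            if sd < 0:
                raise ValueError("medical variable SDs must be non-negative")
        return v


class MissingnessParams(BaseModel):
    """Participant-level pattern weights and presence-flag rates."""

    model_config = ConfigDict(frozen=True)

    pattern_weights: tuple[float, float, float, float] = tables.DEFAULT_PATTERN_WEIGHTS
    presence_rates: dict[str, tuple[float, ...]] = Field(
        default_factory=lambda: dict(tables.PRESENCE_RATES_BY_YEAR)
    )

    @field_validator("pattern_weights")
    @classmethod
    def _weights_sum_to_one(cls, v):
        if any(w < 0 or w > 1 for w in v):
            raise ValueError("pattern_weights must lie in [0, 1]")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("pattern_weights must sum to 1")
        return v

    @field_validator("presence_rates")
    @classmethod
    def _rates_are_probs(cls, v):
        for name, rates in v.items():
            if any(r < 0 or r > 1 for r in rates):
                raise ValueError(f"presence_rates[{name!r}] must lie in [0, 1]")
        return v

    @property
    def driving_missing_rate(self) -> float:
        """Pooled marginal missingness of the Drive score (~0.60 by default)."""
        return 1.0 - float(np.mean(self.presence_rates["has_drive"]))

    @property
    def transit_missing_rate(self) -> float:
        """Pooled marginal missingness of the Ride/transit score (~0.80)."""
        return 1.0 - float(np.mean(self.presence_rates["has_ride"]))


class OutcomeParams(BaseModel):
    """Logistic outcome mechanism on the standardized truth-design scale.

    If ``intercept`` is None, per-year intercepts are calibrated numerically
    so the population steady-work rate matches ``target_rates`` given the
    coefficient vector; otherwise ``intercept`` (+ optional per-year offsets)
    is used as given.
    """

    model_config = ConfigDict(frozen=True)

    intercept: Optional[float] = None
    year_offsets: Optional[tuple[float, ...]] = None
    coefficients: dict[str, float] = Field(
        default_factory=lambda: dict(tables.DEFAULT_TRUE_COEFFICIENTS)
    )
    target_rates: tuple[float, ...] = tables.STEADY_WORK_RATE_BY_YEAR


class DemographicParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_range: tuple[float, float] = tables.DEMOGRAPHIC_DEFAULTS["age_range"]
    baseline_working_rate: float = tables.DEMOGRAPHIC_DEFAULTS["baseline_working_rate"]
    worked_past_2yr_rate: float = tables.DEMOGRAPHIC_DEFAULTS["worked_past_2yr_rate"]
    education_probs: dict[str, float] = Field(
        default_factory=lambda: dict(tables.DEMOGRAPHIC_DEFAULTS["education_probs"])
    )
    race_probs: dict[str, float] = Field(
        default_factory=lambda: dict(tables.DEMOGRAPHIC_DEFAULTS["race_probs"])
    )
    stable_housing_rate: float = tables.DEMOGRAPHIC_DEFAULTS["stable_housing_rate"]
    vehicle_access_rate: float = tables.DEMOGRAPHIC_DEFAULTS["vehicle_access_rate"]

    @field_validator("education_probs", "race_probs")
    @classmethod
    def _probs_sum_to_one(cls, v):
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        return v


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(default=tables.N_PARTICIPANTS, gt=0)
    n_years: int = Field(default=tables.N_YEARS, ge=2)
    arm_probabilities: tuple[float, float, float] = tables.ARM_PROBABILITIES
    scale_params: dict[str, ScaleParams] = Field(
        default_factory=lambda: {
            name: ScaleParams(
                baseline=spec["baseline"],
                change=tuple(spec["change"]),
                mdc90=spec["mdc90"],
            )
            for name, spec in tables.FAB_SCALES.items()
        }
    )
    medical_params: dict[str, MedicalParams] = Field(
        default_factory=lambda: {
            name: MedicalParams(kind=spec["kind"], by_year=tuple(spec["by_year"]))
            for name, spec in tables.MEDICAL_VARIABLES.items()
        }
    )
    missingness_params: MissingnessParams = Field(default_factory=MissingnessParams)
    demographic_params: DemographicParams = Field(default_factory=DemographicParams)
    outcome_params: OutcomeParams = Field(default_factory=OutcomeParams)
    seed: int = 0

    @field_validator("arm_probabilities")
    @classmethod
    def _arms_sum_to_one(cls, v):
        if any(p < 0 or p > 1 for p in v):
            raise ValueError("arm_probabilities must lie in [0, 1]")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("arm_probabilities must sum to 1")
        return v

    @model_validator(mode="after")
    def _lengths_consistent(self):
        for name, sp in self.scale_params.items():
            if len(sp.change) != self.n_years - 1:
                raise ValueError(
                    f"scale_params[{name!r}].change must have n_years-1 entries"
                )
        for name, mp in self.medical_params.items():
            if len(mp.by_year) != self.n_years:
                raise ValueError(
                    f"medical_params[{name!r}].by_year must have n_years entries"
                )
        for name, rates in self.missingness_params.presence_rates.items():
            if len(rates) != self.n_years:
                raise ValueError(
                    f"missingness_params.presence_rates[{name!r}] must have "
                    "n_years entries"
                )
        if self.outcome_params.year_offsets is not None and len(
            self.outcome_params.year_offsets
        ) != self.n_years - 1:
            raise ValueError("outcome_params.year_offsets must have n_years-1 entries")
        if len(self.outcome_params.target_rates) != self.n_years - 1:
            raise ValueError("outcome_params.target_rates must have n_years-1 entries")
        return self

    @property
    def fab_scales(self) -> tuple[str, ...]:
        return tuple(self.scale_params)

    @property
    def medical_variables(self) -> tuple[str, ...]:
        return tuple(self.medical_params)

    @property
    def presence_flags(self) -> tuple[str, ...]:
        return tuple(self.missingness_params.presence_rates)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.model_validate_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------


@dataclass
class PanelDataset:
    """Long-format person-year panel with a hidden pre-missingness channel.

    ``data`` holds one row per (participant, year); missing scale scores are
    NaN.  ``truth`` carries the pre-missingness scale-score values (same row
    order) for oracle tests and is never consumed by the models.
    """

    data: pd.DataFrame
    fab_columns: tuple[str, ...]
    medical_columns: tuple[str, ...]
    presence_columns: tuple[str, ...]
    truth: Optional[pd.DataFrame] = None
    config: Optional[CohortConfig] = None

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def n_years(self) -> int:
        return self.data["year"].nunique()

    @property
    def demographic_columns(self) -> tuple[str, ...]:
        return DEMOGRAPHIC_COLUMNS

    def missing_counts(self) -> pd.Series:
        """Missing non-Community-Mobility scale-score cells per participant."""
        fab = self.data[list(self.fab_columns)]
        return (
            fab.isna()
            .sum(axis=1)
            .groupby(self.data["participant_id"])
            .sum()
            .astype(int)
        )

    def unmask(self) -> "PanelDataset":
        """Restore the pre-missingness panel from the truth channel."""
        if self.truth is None:
            raise ValueError("panel has no truth channel")
        data = self.data.copy()
        data[list(self.fab_columns)] = self.truth[list(self.fab_columns)].to_numpy()
        return replace(self, data=data)

    def mask_frame(self) -> pd.DataFrame:
        """Boolean observed-mask over the scale-score columns."""
        out = self.data[["participant_id", "year"]].copy()
        for c in self.fab_columns:
            out[c] = self.data[c].notna()
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, format: str = "parquet") -> dict[str, Path]:
        """Write the panel (+ mask, truth, config) as sibling files."""
        path = Path(path)
        stem, suffix = path.with_suffix(""), ".parquet" if format == "parquet" else ".csv"
        writer = (
            (lambda df, p: df.to_parquet(p, index=False))
            if format == "parquet"
            else (lambda df, p: df.to_csv(p, index=False))
        )
        files = {"panel": stem.with_suffix(suffix)}
        writer(self.data, files["panel"])
        files["mask"] = Path(f"{stem}_mask{suffix}")
        writer(self.mask_frame(), files["mask"])
        if self.truth is not None:
            files["truth"] = Path(f"{stem}_truth{suffix}")
            writer(self.truth, files["truth"])
        if self.config is not None:
            files["config"] = Path(f"{stem}_config.json")
            self.config.to_json(files["config"])
        return files

    @classmethod
    def load(cls, path: str | Path) -> "PanelDataset":
        path = Path(path)
        reader = pd.read_parquet if path.suffix == ".parquet" else pd.read_csv
        data = reader(path)
        stem = str(path.with_suffix(""))
        truth_path = Path(f"{stem}_truth{path.suffix}")
        truth = reader(truth_path) if truth_path.exists() else None
        config_path = Path(f"{stem}_config.json")
        config = CohortConfig.from_json(config_path) if config_path.exists() else None
        fab = tuple(c for c in data.columns if c.startswith("fab_"))
        med = tuple(c for c in data.columns if c.startswith("med_"))
        pres = tuple(c for c in data.columns if c.startswith("has_"))
        return cls(
            data=data,
            fab_columns=fab,
            medical_columns=med,
            presence_columns=pres,
            truth=truth,
            config=config,
        )


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------


def _sample_demographics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    d = config.demographic_params
    edu_levels = list(d.education_probs)
    race_levels = list(d.race_probs)
    arms = ["full", "basic", "usual"]
    return pd.DataFrame(
        {
            "age": rng.uniform(*d.age_range, size=n),
            "baseline_working": rng.binomial(1, d.baseline_working_rate, size=n),
            "worked_past_2yr": rng.binomial(1, d.worked_past_2yr_rate, size=n),
            "education": rng.choice(
                edu_levels, size=n, p=list(d.education_probs.values())
            ),
            "race": rng.choice(race_levels, size=n, p=list(d.race_probs.values())),
            "stable_housing": rng.binomial(1, d.stable_housing_rate, size=n),
            "vehicle_access": rng.binomial(1, d.vehicle_access_rate, size=n),
            "arm": rng.choice(arms, size=n, p=list(config.arm_probabilities)),
        }
    )


def sample_fab_trajectory(
    config: CohortConfig, participant_rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw WD-FAB score trajectories, shape (n, n_years, n_scales).

    Baseline ~ N(mean, SD) per scale; the year-t value is baseline plus an
    independent change draw with that year's change mean/SD, so year-to-year
    correlation within a participant comes from the shared baseline.
    """
    scales = config.fab_scales
    T, S = config.n_years, len(scales)
    out = np.empty((n, T, S))
    for j, name in enumerate(scales):
        sp = config.scale_params[name]
        base = participant_rng.normal(sp.baseline[0], sp.baseline[1], size=n)
        out[:, 0, j] = base
        for t in range(1, T):
            mean, sd = sp.change[t - 1]
            out[:, t, j] = base + participant_rng.normal(mean, sd, size=n)
    return out


@lru_cache(maxsize=512)
def _truncnorm_loc(target_mean: float, sd: float) -> float:
    """Location of a >=0-truncated normal with scale ``sd`` whose truncated
    mean equals ``target_mean``."""
    if sd == 0 or target_mean / sd > 8:
        return target_mean

    def trunc_mean(loc: float) -> float:
        a = -loc / sd
        return loc + sd * norm.pdf(a) / norm.sf(a)

    lo, hi = target_mean - 6 * sd, target_mean + sd
    return brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-10)


def sample_medical_counts(
    config: CohortConfig, participant_rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw the medical/utilization block, shape (n, n_years, n_variables).

    Count variables use a negative binomial matched to the per-year mean/SD
    (Poisson when the target is under-dispersed, with a logged warning);
    score variables (CSI, BMI, DAST, AUDIT) use a >=0-truncated normal whose
    location is solved so the truncated mean hits the target.
    """
    names = config.medical_variables
    T, M = config.n_years, len(names)
    out = np.zeros((n, T, M))
    for j, name in enumerate(names):
        mp = config.medical_params[name]
        for t in range(T):
            mean, sd = mp.by_year[t]
            if mp.kind == "score":
                loc = _truncnorm_loc(mean, sd)
                draws = participant_rng.normal(loc, sd, size=n)
                # resample the negative tail (exact truncated-normal draws)
                neg = draws < 0
                while neg.any():
                    draws[neg] = participant_rng.normal(loc, sd, size=int(neg.sum()))
                    neg = draws < 0
                out[:, t, j] = draws
            else:
                if mean == 0:
                    continue
                var = sd**2
                if var > mean:
                    r = mean**2 / (var - mean)
                    p = r / (r + mean)
                    out[:, t, j] = participant_rng.negative_binomial(r, p, size=n)
                else:
                    logger.warning(
                        "medical variable %r year %d: SD^2 <= mean, "
                        "falling back to Poisson",
                        name,
                        t,
                    )
                    out[:, t, j] = participant_rng.poisson(mean, size=n)
    return out


def _sample_presence(
    config: CohortConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Community Mobility presence flags, shape (n, n_years, n_flags)."""
    flags = config.presence_flags
    T = config.n_years
    out = np.empty((n, T, len(flags)), dtype=np.int64)
    for j, name in enumerate(flags):
        rates = config.missingness_params.presence_rates[name]
        for t in range(T):
            out[:, t, j] = rng.binomial(1, rates[t], size=n)
    return out


# ---------------------------------------------------------------------------
# truth design and outcome mechanism
# ---------------------------------------------------------------------------


@dataclass
class TruthDesign:
    """Fully observed, population-standardized design over post-baseline
    person-years, used only by the outcome mechanism and oracle studies."""

    X: np.ndarray
    columns: list[str]
    year: np.ndarray
    participant: np.ndarray

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def _pooled_change_moments(per_year: list[tuple[float, float]]) -> tuple[float, float]:
    """Mean and SD of a change variable pooled over follow-up years."""
    means = np.array([m for m, _ in per_year])
    sds = np.array([s for _, s in per_year])
    mean = means.mean()
    var = (sds**2 + means**2).mean() - mean**2
    return float(mean), float(np.sqrt(max(var, 1e-12)))


def population_design_moments(config: CohortConfig) -> dict[str, tuple[float, float]]:
    """Population (mean, SD) used to standardize each truth-design column.

    Binary columns are not standardized (returned as (0, 1)); score/count
    columns use their nominal generating moments.
    """
    out: dict[str, tuple[float, float]] = {}
    lo, hi = config.demographic_params.age_range
    out["age"] = ((lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0))
    for name in (
        "baseline_working",
        "worked_past_2yr",
        "stable_housing",
        "vehicle_access",
        "edu_hs",
        "edu_some_college",
        "edu_bachelor",
        "race_black",
        "race_other",
        "arm_full",
        "arm_basic",
    ):
        out[name] = (0.0, 1.0)
    for scale in config.fab_scales:
        sp = config.scale_params[scale]
        out[f"{scale}_base"] = sp.baseline
        out[f"{scale}_change"] = _pooled_change_moments(list(sp.change))
    for flag in config.presence_flags:
        out[flag] = (0.0, 1.0)
    for name in config.medical_variables:
        mp = config.medical_params[name]
        m0, s0 = mp.by_year[0]
        out[f"{name}_base"] = (m0, max(s0, 1e-12))
        per_year = [
            (mt - m0, np.sqrt(st**2 + s0**2)) for mt, st in mp.by_year[1:]
        ]
        out[f"{name}_change"] = _pooled_change_moments(per_year)
    return out


def build_truth_design(
    demo: pd.DataFrame,
    fab: np.ndarray,
    med: np.ndarray,
    presence: np.ndarray,
    config: CohortConfig,
) -> TruthDesign:
    """Assemble the standardized truth design from raw covariate arrays.

    One row per post-baseline person-year, ordered year-major within
    participant (participant 0 years 1..T-1, participant 1 years 1..T-1, ...).
    """
    n, T = fab.shape[0], config.n_years
    moments = population_design_moments(config)
    cols: list[str] = []
    blocks: list[np.ndarray] = []

    def add(name: str, per_participant: np.ndarray | None = None, per_row=None):
        mean, sd = moments[name]
        if per_row is None:
            per_row = np.repeat(per_participant, T - 1)
        cols.append(name)
        blocks.append((np.asarray(per_row, dtype=float) - mean) / sd)

    add("age", demo["age"].to_numpy())
    add("baseline_working", demo["baseline_working"].to_numpy())
    add("worked_past_2yr", demo["worked_past_2yr"].to_numpy())
    for level in ("hs", "some_college", "bachelor"):
        add(f"edu_{level}", (demo["education"] == level).astype(float).to_numpy())
    for level in ("black", "other"):
        add(f"race_{level}", (demo["race"] == level).astype(float).to_numpy())
    add("stable_housing", demo["stable_housing"].to_numpy())
    add("vehicle_access", demo["vehicle_access"].to_numpy())
    for level in ("full", "basic"):
        add(f"arm_{level}", (demo["arm"] == level).astype(float).to_numpy())

    for j, scale in enumerate(config.fab_scales):
        add(f"{scale}_base", fab[:, 0, j])
        change = (fab[:, 1:, j] - fab[:, [0], j]).reshape(-1)
        add(f"{scale}_change", per_row=change)
    for j, flag in enumerate(config.presence_flags):
        add(flag, per_row=presence[:, 1:, j].reshape(-1).astype(float))
    for j, name in enumerate(config.medical_variables):
        add(f"{name}_base", med[:, 0, j])
        change = (med[:, 1:, j] - med[:, [0], j]).reshape(-1)
        add(f"{name}_change", per_row=change)

    X = np.column_stack(blocks)
    year = np.tile(np.arange(1, T), n)
    participant = np.repeat(np.arange(n), T - 1)
    return TruthDesign(X=X, columns=cols, year=year, participant=participant)


def _coefficient_vector(design: TruthDesign, coefficients: dict[str, float]) -> np.ndarray:
    beta = np.zeros(len(design.columns))
    for name, value in coefficients.items():
        if name not in design.columns:
            raise ValueError(
                f"outcome coefficient {name!r} does not match any design column"
            )
        beta[design.column_index(name)] = value
    return beta


def sample_outcome(
    design: TruthDesign,
    outcome_params: OutcomeParams,
    rng: np.random.Generator,
    intercepts_by_year: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw y_it ~ Bernoulli(logit^-1(alpha_t + z' beta_true)) per row."""
    beta = _coefficient_vector(design, outcome_params.coefficients)
    eta = design.X @ beta
    if intercepts_by_year is None:
        if outcome_params.intercept is None:
            raise ValueError(
                "outcome_params.intercept is None and no calibrated intercepts given"
            )
        offsets = outcome_params.year_offsets
        years = np.unique(design.year)
        intercepts_by_year = np.array(
            [
                outcome_params.intercept
                + (offsets[i] if offsets is not None else 0.0)
                for i, _ in enumerate(years)
            ]
        )
    eta = eta + intercepts_by_year[design.year - 1]
    return rng.binomial(1, expit(eta)).astype(np.int64)


@lru_cache(maxsize=32)
def _calibrated_intercepts_cached(config_json: str) -> tuple[float, ...]:
    config = CohortConfig.model_validate_json(config_json)
    ref = config.model_copy(update={"n_participants": 50_000})
    rng = np.random.default_rng(_REFERENCE_SEED)
    demo = _sample_demographics(ref, rng)
    fab = sample_fab_trajectory(ref, rng, n=ref.n_participants)
    med = sample_medical_counts(ref, rng, n=ref.n_participants)
    presence = _sample_presence(ref, rng, ref.n_participants)
    design = build_truth_design(demo, fab, med, presence, ref)
    beta = _coefficient_vector(design, config.outcome_params.coefficients)
    eta = design.X @ beta
    alphas = []
    for i, t in enumerate(range(1, config.n_years)):
        eta_t = eta[design.year == t]
        target = config.outcome_params.target_rates[i]

        def gap(alpha: float) -> float:
            return float(expit(alpha + eta_t).mean() - target)

        alphas.append(brentq(gap, -15.0, 15.0, xtol=1e-10))
    return tuple(alphas)


def calibrated_intercepts(config: CohortConfig) -> np.ndarray:
    """Per-year intercepts solving the population prevalence equation.

    Uses a fixed internal reference cohort (n=50,000, fixed seed independent
    of the user's seed), so the result is a deterministic function of the
    configuration (the user's seed is excluded from the cache key).
    """
    key = config.model_copy(update={"seed": 0}).model_dump_json()
    return np.array(_calibrated_intercepts_cached(key))


# ---------------------------------------------------------------------------
# cohort assembly and missingness
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig) -> PanelDataset:
    """Generate a complete synthetic cohort: covariates, outcome, missingness.

    Deterministic given ``config.seed``: identical configurations yield
    byte-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_participants, config.n_years
    demo = _sample_demographics(config, rng)
    fab = sample_fab_trajectory(config, rng, n=n)
    med = sample_medical_counts(config, rng, n=n)
    presence = _sample_presence(config, rng, n)

    design = build_truth_design(demo, fab, med, presence, config)
    if config.outcome_params.intercept is None:
        intercepts = calibrated_intercepts(config)
    else:
        intercepts = None
    y = sample_outcome(design, config.outcome_params, rng, intercepts)

    fab_cols = [f"fab_{s}" for s in config.fab_scales]
    med_cols = [f"med_{m}" for m in config.medical_variables]
    pres_cols = list(config.presence_flags)

    rows = n * T
    data = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), T),
            "year": np.tile(np.arange(T), n),
        }
    )
    steady = np.full(rows, np.nan)
    post = data["year"].to_numpy() > 0
    # outcome rows are ordered (participant, year 1..T-1) in both layouts
    steady[post] = y
    data["steady_work"] = steady
    for j, c in enumerate(fab_cols):
        data[c] = fab[:, :, j].reshape(-1)
    for j, c in enumerate(pres_cols):
        data[c] = presence[:, :, j].reshape(-1)
    for j, c in enumerate(med_cols):
        data[c] = med[:, :, j].reshape(-1)
    for c in DEMOGRAPHIC_COLUMNS:
        data[c] = np.repeat(demo[c].to_numpy(), T)

    panel = PanelDataset(
        data=data,
        fab_columns=tuple(fab_cols),
        medical_columns=tuple(med_cols),
        presence_columns=tuple(pres_cols),
        truth=None,
        config=config,
    )
    return apply_missingness(panel, config)


def apply_missingness(
    panel: PanelDataset,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> PanelDataset:
    """Blank scale scores by participant-level {0, 7, 14, 21} patterns.

    A pattern of 7k blanks all seven non-Community-Mobility scale scores in k
    follow-up waves chosen uniformly at random (missing completely at
    random).  The pre-missingness values are kept in the truth channel.
    """
    weights = np.asarray(config.missingness_params.pattern_weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("missingness pattern weights must sum to 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    data = panel.data.copy()
    truth = panel.data[["participant_id", "year", *panel.fab_columns]].copy()

    ids = data["participant_id"].to_numpy()
    years = data["year"].to_numpy()
    unique_ids = np.unique(ids)
    n = len(unique_ids)
    n_waves = int(years.max())  # follow-up waves
    k_max = len(weights) - 1
    patterns = rng.choice(np.arange(k_max + 1), size=n, p=weights)
    patterns = np.minimum(patterns, n_waves)

    fab_cols = list(panel.fab_columns)
    fab_values = data[fab_cols].to_numpy()
    # row index lookup: rows are (participant, year) sorted already
    row_of = {(pid, t): i for i, (pid, t) in enumerate(zip(ids, years))}
    for pid, k in zip(unique_ids, patterns):
        if k == 0:
            continue
        waves = rng.choice(np.arange(1, n_waves + 1), size=k, replace=False)
        for t in waves:
            fab_values[row_of[(pid, t)], :] = np.nan
    data[fab_cols] = fab_values
    return replace(panel, data=data, truth=truth)


def default_config(**overrides) -> CohortConfig:
    """The default study configuration (n=2944, published moments)."""
    return CohortConfig(**overrides)


def reduced_config(
    n_participants: int,
    seed: int = 0,
    medical_subset: tuple[str, ...] = (
        "csi",
        "bmi",
        "dast",
        "audit",
        "total_er_visits",
        "er_mental_visits",
        "total_inpatient_nights",
        "outpatient_mental_visits",
    ),
    coefficients: Optional[dict[str, float]] = None,
    **overrides,
) -> CohortConfig:
    """A small-cohort configuration with a trimmed medical block.

    At small n the rare-event utilization variables (baseline means near
    0.01) are often all-zero, which the standardizer rejects as constant
    columns; this helper keeps the common medical variables and drops
    outcome coefficients that reference removed columns.
    """
    medical = {
        name: MedicalParams(
            kind=tables.MEDICAL_VARIABLES[name]["kind"],
            by_year=tuple(tables.MEDICAL_VARIABLES[name]["by_year"]),
        )
        for name in medical_subset
    }
    if coefficients is None:
        dropped = set(tables.MEDICAL_VARIABLE_NAMES) - set(medical_subset)
        dropped_cols = {f"{m}_base" for m in dropped} | {f"{m}_change" for m in dropped}
        coefficients = {
            k: v
            for k, v in tables.DEFAULT_TRUE_COEFFICIENTS.items()
            if k not in dropped_cols
        }
    overrides.setdefault("outcome_params", OutcomeParams(coefficients=coefficients))
    return CohortConfig(
        n_participants=n_participants,
        seed=seed,
        medical_params=medical,
        **overrides,
    )
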