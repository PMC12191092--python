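"""Panel preparation: changes from baseline, standardization, design assembly.

Transforms a :class:`~fabwork.cohort.PanelDataset` into the model-ready
design: every continuous predictor enters twice (its baseline value and its
change from baseline for the study year), both standardized; Community
Mobility scores enter only as presence indicators; participants are filtered
by their count of missing functioning measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DEMOGRAPHIC_COLUMNS, PanelDataset

COVARIATE_SETS = ("demo", "demo+fab", "demo+med", "full")
MISSINGNESS_TOLERANCES = (0, 7, 14)

VarClass = Literal["demographic", "medical", "function"]
VarKind = Literal["baseline", "change", "indicator"]

#: demographic dummy coding: (column, source column, level); reference levels
#: are less-than-high-school education, white race, usual-services arm.
_DEMO_DUMMIES = (
    ("edu_hs", "education", "hs"),
    ("edu_some_college", "education", "some_college"),
    ("edu_bachelor", "education", "bachelor"),
    ("race_black", "race", "black"),
    ("race_other", "race", "other"),
    ("arm_full", "arm", "full"),
    ("arm_basic", "arm", "basic"),
)
_DEMO_BINARY = ("baseline_working", "worked_past_2yr", "stable_housing", "vehicle_access")


@dataclass(frozen=True)
class ColumnMeta:
    name: str
    var_class: VarClass
    kind: VarKind


@dataclass
class StandardizationParams:
    """Observed-cell means/SDs for baseline columns and for change columns.

    Learned on an analysis dataset and persisted so submodels share identical
    scaling; reapplying to the training data reproduces mean 0 / SD 1 on the
    observed cells exactly.
    """

    baseline: dict[str, tuple[float, float]]
    change: dict[str, tuple[float, float]]

    def standardize(self, name: str, kind: str, values: np.ndarray) -> np.ndarray:
        table = self.baseline if kind == "baseline" else self.change
        mean, sd = table[name]
        return (values - mean) / sd

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"baseline": self.baseline, "change": self.change}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StandardizationParams":
        raw = json.loads(Path(path).read_text())
        return cls(
            baseline={k: tuple(v) for k, v in raw["baseline"].items()},
            change={k: tuple(v) for k, v in raw["change"].items()},
        )


@dataclass
class DesignMatrix:
    """Model-ready design over post-baseline person-years.

    ``Z`` holds standardized values with masked (missing) cells set to 0 and
    flagged False in ``mask``; indicator and dummy columns are raw 0/1 and
    never masked.
    """

    y: np.ndarray
    Z: np.ndarray
    mask: np.ndarray
    columns: list[ColumnMeta]
    year: np.ndarray
    participant: np.ndarray
    covariate_set: str = "full"

    def __post_init__(self):
        assert self.Z.shape == self.mask.shape
        assert self.Z.shape[0] == len(self.y) == len(self.year)

    @property
    def n_rows(self) -> int:
        return self.Z.shape[0]

    @property
    def n_cols(self) -> int:
        return self.Z.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)

    def select_columns(self, names: Sequence[str]) -> "DesignMatrix":
        idx = [self.column_index(n) for n in names]
        return DesignMatrix(
            y=self.y,
            Z=self.Z[:, idx],
            mask=self.mask[:, idx],
            columns=[self.columns[i] for i in idx],
            year=self.year,
            participant=self.participant,
            covariate_set=self.covariate_set,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.Z, columns=self.column_names)
        for c in self.column_names:
            df[f"__mask_{c}"] = self.mask[:, self.column_index(c)]
        df["__y"] = self.y
        df["__year"] = self.year
        df["__participant"] = self.participant
        df.to_parquet(path, index=False)
        meta = {
            "covariate_set": self.covariate_set,
            "columns": [
                {"name": c.name, "var_class": c.var_class, "kind": c.kind}
                for c in self.columns
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DesignMatrix":
        path = Path(path)
        df = pd.read_parquet(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        columns = [ColumnMeta(**c) for c in meta["columns"]]
        names = [c.name for c in columns]
        return cls(
            y=df["__y"].to_numpy(dtype=np.int64),
            Z=df[names].to_numpy(dtype=float),
            mask=df[[f"__mask_{n}" for n in names]].to_numpy(dtype=bool),
            columns=columns,
            year=df["__year"].to_numpy(dtype=np.int64),
            participant=df["__participant"].to_numpy(dtype=np.int64),
            covariate_set=meta["covariate_set"],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _value_columns(panel: PanelDataset) -> list[str]:
    return [*panel.fab_columns, *panel.medical_columns]


def compute_changes(panel: PanelDataset) -> pd.DataFrame:
    """Per post-baseline person-year: baseline value and change from baseline.

    ``{var}__base`` repeats the participant's year-0 value; ``{var}__change``
    is x_t - x_0, NaN whenever either side is missing.
    """
    data = panel.data
    base_rows = data[data["year"] == 0].set_index("participant_id")
    post = data[data["year"] > 0].copy()
    missing_base = sorted(
        set(post["participant_id"].unique()) - set(base_rows.index)
    )
    if missing_base:
        raise ValueError(f"participants lacking a baseline row: {missing_base}")

    out = post[["participant_id", "year", "steady_work"]].copy()
    for col in _value_columns(panel):
        base = base_rows[col].reindex(post["participant_id"]).to_numpy()
        out[f"{col}__base"] = base
        out[f"{col}__change"] = post[col].to_numpy() - base
    for col in panel.presence_columns:
        out[col] = post[col].to_numpy()
    for col in DEMOGRAPHIC_COLUMNS:
        out[col] = post[col].to_numpy()
    return out.reset_index(drop=True)


def fit_standardizer(panel: PanelDataset) -> StandardizationParams:
    """Observed-cell mean/SD per baseline column; mean/SD of observed
    differences per change column.  Continuous demographic columns (age) are
    included; binary indicators and dummies are not standardized."""
    changes = compute_changes(panel)
    baseline: dict[str, tuple[float, float]] = {}
    change: dict[str, tuple[float, float]] = {}

    def moments(series: pd.Series, label: str) -> tuple[float, float]:
        obs = series.dropna()
        if len(obs) < 2:
            raise ValueError(f"column {label!r} has fewer than 2 observed values")
        sd = float(obs.std(ddof=1))
        if sd == 0:
            raise ValueError(f"column {label!r} is constant; cannot standardize")
        return float(obs.mean()), sd

    baseline["age"] = moments(changes["age"], "age")
    for col in _value_columns(panel):
        baseline[col] = moments(changes[f"{col}__base"], f"{col}__base")
        change[col] = moments(changes[f"{col}__change"], f"{col}__change")
    return StandardizationParams(baseline=baseline, change=change)


def filter_by_missingness(panel: PanelDataset, tolerance: int) -> PanelDataset:
    """Keep participants with at most ``tolerance`` missing functioning
    measurements (Community Mobility excluded from the count)."""
    if tolerance not in MISSINGNESS_TOLERANCES:
        raise ValueError(
            f"tolerance must be one of {MISSINGNESS_TOLERANCES}, got {tolerance}"
        )
    counts = panel.missing_counts()
    keep = set(counts[counts <= tolerance].index)
    mask = panel.data["participant_id"].isin(keep).to_numpy()
    data = panel.data[mask].reset_index(drop=True)
    truth = panel.truth[mask].reset_index(drop=True) if panel.truth is not None else None
    from dataclasses import replace

    return replace(panel, data=data, truth=truth)


def build_design(
    panel: PanelDataset,
    params: StandardizationParams,
    covariate_set: str = "full",
) -> DesignMatrix:
    """Assemble the design matrix for one covariate submodel.

    Column classes follow the submodel definition: ``demo`` uses demographic
    columns only; ``demo+fab`` adds the function block (scale baselines,
    changes, and Community Mobility presence indicators); ``demo+med`` adds
    the medical block; ``full`` uses everything.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"unknown covariate_set {covariate_set!r}; expected one of {COVARIATE_SETS}"
        )
    changes = compute_changes(panel)
    cols: list[ColumnMeta] = []
    values: list[np.ndarray] = []

    def add(meta: ColumnMeta, vals: np.ndarray):
        cols.append(meta)
        values.append(np.asarray(vals, dtype=float))

    # demographic block
    add(
        ColumnMeta("age", "demographic", "baseline"),
        params.standardize("age", "baseline", changes["age"].to_numpy()),
    )
    for name in _DEMO_BINARY:
        add(ColumnMeta(name, "demographic", "indicator"), changes[name].to_numpy())
    for name, source, level in _DEMO_DUMMIES:
        add(
            ColumnMeta(name, "demographic", "indicator"),
            (changes[source] == level).astype(float).to_numpy(),
        )

    include_fab = covariate_set in ("demo+fab", "full")
    include_med = covariate_set in ("demo+med", "full")

    if include_fab:
        for col in panel.fab_columns:
            for kind in ("baseline", "change"):
                raw = changes[f"{col}__{'base' if kind == 'baseline' else 'change'}"]
                add(
                    ColumnMeta(f"{col}_{kind}", "function", kind),
                    params.standardize(col, kind, raw.to_numpy()),
                )
        for col in panel.presence_columns:
            add(ColumnMeta(col, "function", "indicator"), changes[col].to_numpy())
    if include_med:
        for col in panel.medical_columns:
            for kind in ("baseline", "change"):
                raw = changes[f"{col}__{'base' if kind == 'baseline' else 'change'}"]
                add(
                    ColumnMeta(f"{col}_{kind}", "medical", kind),
                    params.standardize(col, kind, raw.to_numpy()),
                )

    Z = np.column_stack(values)
    mask = np.isfinite(Z)
    bad = ~mask & np.array(
        [c.var_class == "demographic" or c.kind == "indicator" for c in cols]
    )[None, :]
    if bad.any():
        raise ValueError("missing values in demographic or indicator columns")
    Z = np.where(mask, Z, 0.0)
    y = changes["steady_work"].to_numpy()
    if np.isnan(y).any():
        raise ValueError("steady_work outcome missing on post-baseline rows")
    return DesignMatrix(
        y=y.astype(np.int64),
        Z=Z,
        mask=mask,
        columns=cols,
        year=changes["year"].to_numpy(dtype=np.int64),
        participant=changes["participant_id"].to_numpy(dtype=np.int64),
        covariate_set=covariate_set,
    )


def prepare_design(
    panel: PanelDataset,
    tolerance: int = 14,
    covariate_set: str = "full",
    params: Optional[StandardizationParams] = None,
) -> tuple[DesignMatrix, StandardizationParams]:
    """Filter, standardize, and build in one call (the default workflow)."""
    filtered = filter_by_missingness(panel, tolerance)
    if params is None:
        params = fit_standardizer(filtered)
    return build_design(filtered, params, covariate_set), params
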