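"""End-to-end orchestration: simulate -> prep -> fit -> evaluate -> compare.

A run is driven by a :class:`RunConfig`; every stage writes its artifacts
under the output directory and the manifest records paths, seeds and content
hashes.  Reports (top-k odds-ratio tables, ROC/PRC operating points, the
model-comparison table) are emitted as data files; plot rendering is
optional and never part of the test surface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import CohortConfig, generate_cohort
from .evaluation import ModelEvaluation, compare_models, evaluate_model
from .models.bnn import BayesianNeuralNet, BnnResults, BnnSpec
from .models.logistic import (
    LogisticModelSpec,
    LogisticResults,
    Posterior,
    SteadyWorkLogistic,
)
from .models.piecewise import (
    PartitionSpec,
    PiecewiseLogistic,
    PiecewiseModelSpec,
    PiecewiseResults,
)
from .prep import (
    COVARIATE_SETS,
    DesignMatrix,
    build_design,
    filter_by_missingness,
    fit_standardizer,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("glm", "piecewise", "bnn")


class RunConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    tolerance: int = 14
    covariate_sets: tuple[str, ...] = COVARIATE_SETS
    models: tuple[str, ...] = ("glm",)
    glm_spec: LogisticModelSpec = Field(default_factory=LogisticModelSpec)
    piecewise_spec: PiecewiseModelSpec = Field(default_factory=PiecewiseModelSpec)
    partition: PartitionSpec = Field(
        default_factory=lambda: PartitionSpec(
            covariates=("baseline_working", "fab_comm_cog_baseline")
        )
    )
    bnn_spec: BnnSpec = Field(default_factory=BnnSpec)
    out_dir: str = "fabwork_run"
    seed: int = 0
    top_k: int = 32
    thin_to: int = 1000

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def save_results(results, directory: str | Path) -> None:
    """Persist a fitted results object (draw table + model metadata)."""
    directory = Path(directory)
    results.posterior.save(directory)
    meta: dict = {"spec": results.spec.model_dump()}
    if isinstance(results, PiecewiseResults):
        meta["model_kind"] = "piecewise"
        meta["partition"] = results.model.partition.model_dump()
    elif isinstance(results, BnnResults):
        meta["model_kind"] = "bnn"
    else:
        meta["model_kind"] = "glm"
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_results(directory: str | Path, design: DesignMatrix):
    """Reconstruct a results object from ``save_results`` output."""
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    pmeta = json.loads((directory / "posterior.json").read_text())
    table = pd.read_parquet(directory / "draws.parquet")
    draws: dict[str, np.ndarray] = {}
    for key, shape in pmeta["shapes"].items():
        if len(shape) == 1:
            draws[key] = table[key].to_numpy()
        else:
            cols = [f"{key}_{j}" for j in range(int(np.prod(shape[1:])))]
            draws[key] = table[cols].to_numpy().reshape(shape)
    posterior = Posterior(
        draws=draws,
        chains=pmeta["chains"],
        seed=pmeta["seed"],
        diagnostics=pmeta["diagnostics"],
        column_names=pmeta["column_names"],
        imp_col_names=pmeta["imp_col_names"],
    )
    kind = meta["model_kind"]
    if kind == "glm":
        model = SteadyWorkLogistic(design, LogisticModelSpec(**meta["spec"]))
        return LogisticResults(model, posterior)
    if kind == "piecewise":
        model = PiecewiseLogistic(
            design,
            PartitionSpec(**meta["partition"]),
            PiecewiseModelSpec(**meta["spec"]),
        )
        return PiecewiseResults(model, posterior)
    if kind == "bnn":
        model = BayesianNeuralNet(design, BnnSpec(**meta["spec"]))
        return BnnResults(model, posterior)
    raise ValueError(f"unknown model kind {kind!r}")


def _fit_one(kind: str, design: DesignMatrix, config: RunConfig, seed: int):
    if kind == "glm":
        return SteadyWorkLogistic(design, config.glm_spec).fit(seed=seed)
    if kind == "piecewise":
        return PiecewiseLogistic(design, config.partition, config.piecewise_spec).fit(
            seed=seed
        )
    if kind == "bnn":
        return BayesianNeuralNet(design, config.bnn_spec).fit(seed=seed)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; return (and write) the run manifest."""
    for cs in config.covariate_sets:
        if cs not in COVARIATE_SETS:
            raise ValueError(f"unknown covariate set {cs!r}")
    for mk in config.models:
        if mk not in MODEL_KINDS:
            raise ValueError(f"unknown model {mk!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256_12": _hash_file(path),
        }

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = "started"

    try:
        stage("simulate")
        cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
        panel = generate_cohort(cohort_cfg)
        files = panel.save(out / "panel.parquet")
        for k, p in files.items():
            record(f"panel_{k}", p)
        manifest["stages"]["simulate"] = "done"

        stage("prep")
        filtered = filter_by_missingness(panel, config.tolerance)
        params = fit_standardizer(filtered)
        params.to_json(out / "standardization.json")
        record("standardization", out / "standardization.json")
        designs: dict[str, DesignMatrix] = {}
        for cs in config.covariate_sets:
            design = build_design(filtered, params, cs)
            path = out / f"design_{cs.replace('+', '_')}.parquet"
            design.save(path)
            record(f"design_{cs}", path)
            designs[cs] = design
        manifest["stages"]["prep"] = "done"

        evaluations: list[ModelEvaluation] = []
        for mi, kind in enumerate(config.models):
            for ci, cs in enumerate(config.covariate_sets):
                label = f"{kind}_{cs.replace('+', '_')}"
                stage(f"fit_{label}")
                fit_seed = config.seed + 1000 * (mi + 1) + ci
                results = _fit_one(kind, designs[cs], config, fit_seed)
                fit_dir = out / f"post_{label}"
                save_results(results, fit_dir)
                record(f"posterior_{label}", fit_dir / "draws.parquet")
                if hasattr(results, "odds_ratios"):
                    or_path = out / f"odds_ratios_{label}.csv"
                    results.odds_ratios().to_csv(or_path)
                    record(f"odds_ratios_{label}", or_path)
                manifest["stages"][f"fit_{label}"] = "done"

                stage(f"evaluate_{label}")
                ev = evaluate_model(results, name=label, thin_to=config.thin_to)
                ev_dir = out / f"eval_{label}"
                ev.save(ev_dir)
                for f in ("roc.csv", "prc.csv", "loo_pointwise.csv", "summary.json"):
                    record(f"eval_{label}_{f}", ev_dir / f)
                evaluations.append(ev)
                manifest["stages"][f"evaluate_{label}"] = "done"

        stage("compare")
        comparison = compare_models(evaluations)
        comparison.to_csv(out / "comparison.csv", index=False)
        record("comparison", out / "comparison.csv")
        manifest["stages"]["compare"] = "done"
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if v == "started"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(
            f"pipeline stage {failed[-1] if failed else '?'} failed: {exc}"
        ) from exc

    config.to_json(out / "run_config.json")
    record("run_config", out / "run_config.json")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def render_report(manifest: dict | str | Path, top_k: Optional[int] = None) -> dict:
    """Produce the report tables from a completed run's artifacts.

    Writes, under <out>/report/: the top-k odds-ratio table per fitted model
    (default k=32), a top-10 table per covariate set, and the rendered
    comparison table.  Numbers are taken from the underlying CSV summaries
    without recomputation.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    artifacts = manifest["artifacts"]
    missing = [k for k, v in artifacts.items() if not Path(v["path"]).exists()]
    if missing:
        raise FileNotFoundError(f"missing run artifacts: {missing}")
    out = Path(artifacts["comparison"]["path"]).parent
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    k = top_k or 32
    written: dict[str, str] = {}
    for name, art in artifacts.items():
        if not name.startswith("odds_ratios_"):
            continue
        table = pd.read_csv(art["path"])
        label = name.removeprefix("odds_ratios_")
        top = table.head(k)
        path = report_dir / f"top{k}_{label}.csv"
        top.to_csv(path, index=False)
        written[f"top{k}_{label}"] = str(path)
        top10 = table.head(10)
        path10 = report_dir / f"top10_{label}.csv"
        top10.to_csv(path10, index=False)
        written[f"top10_{label}"] = str(path10)
    comparison = pd.read_csv(artifacts["comparison"]["path"])
    txt = report_dir / "comparison.txt"
    txt.write_text(comparison.to_string(index=False) + "\n")
    written["comparison"] = str(txt)
    (report_dir / "report_manifest.json").write_text(json.dumps(written, indent=2))
    return written


def render_plots(manifest: dict | str | Path) -> list[str]:  # pragma: no cover
    """Optional matplotlib rendering of the ROC/PRC operating points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    artifacts = manifest["artifacts"]
    out = Path(artifacts["comparison"]["path"]).parent
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    paths = []
    for kind, (xl, yl) in {"roc": ("FPR", "TPR"), "prc": ("recall", "precision")}.items():
        fig, ax = plt.subplots(figsize=(6, 5))
        for name, art in artifacts.items():
            if name.endswith(f"_{kind}.csv"):
                df = pd.read_csv(art["path"])
                label = name.removeprefix("eval_").removesuffix(f"_{kind}.csv")
                ax.plot(df.iloc[:, 0], df.iloc[:, 1], label=label)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.legend(fontsize=7)
        p = report_dir / f"{kind}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(str(p))
    return paths
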