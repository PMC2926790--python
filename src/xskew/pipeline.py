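"""End-to-end orchestration: simulate/load -> validate -> fit -> escapers -> cellcount.

Each stage writes its outputs in the data_model formats so every stage is
re-runnable standalone on the previous stage's files, and a single global
seed is split into independent per-stage substreams so toggling one stage
never perturbs another's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .anova import AnovaModelSpec, fit_nested_anova, ls_means, variance_components
from .data_model import ExpressionTable, read_table, validate_table, write_table
from .errors import FormatError, XskewError
from .escapers import call_escapers, reciprocal_difference, sign_test_direction
from .progenitor import (
    estimate_cell_number,
    observed_sampling_variance,
    simulate_variance_curve,
)
from .simulate import GeneParams, SimulationParams, default_params, simulate_dataset

log = logging.getLogger("xskew")

ALL_STAGES = ("simulate", "validate", "fit", "escapers", "cellcount")

# substream indices, fixed so stage toggling is non-perturbing
_STAGE_STREAM = {"simulate": 0, "cellcount": 1}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str | Path = "xskew_run"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    # input: either file paths...
    data_path: str | Path | None = None
    annotations_path: str | Path | None = None
    # ...or a simulation spec ("default" uses the packaged PWD-AKR design)
    simulation: SimulationParams | str | None = "default"
    response: str = "ref_fraction"
    ss_type: str = "sequential"
    gene_classes: Sequence[str] = ("inactivated",)
    male_tolerance: float = 0.05
    inactivated_floor: float = 0.5
    calibration_margin: float = 0.05
    grid: tuple[int, int] = (30, 150)
    reps: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.get("simulation")
        if isinstance(sim, dict):
            genes = [GeneParams(**g) for g in sim.pop("genes", [])]
            base = sim.pop("base", None)
            if base:
                params = default_params(base)
                sim.setdefault("strain_pair", params.strain_pair)
                raw["simulation"] = dataclasses.replace(
                    params, **({"genes": genes} if genes else {}), **sim
                )
            else:
                raw["simulation"] = SimulationParams(genes=genes, **sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(**raw)

    def anova_spec(self) -> AnovaModelSpec:
        return AnovaModelSpec(
            response=self.response,
            ss_type=self.ss_type,
            gene_classes=tuple(self.gene_classes),
        )

    def digest(self) -> str:
        def default(o: Any) -> Any:
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Aggregated numeric outcomes of a pipeline run."""

    config_digest: str
    seed: int
    version: str
    stages_run: list[str] = field(default_factory=list)
    design: dict | None = None
    validation: dict | None = None
    anova_table: dict | None = None
    ls_means: dict | None = None
    ls_mean_difference: float | None = None
    variance_components: dict | None = None
    sign_test: dict | None = None
    escaper_calls: dict | None = None
    escaper_warnings: list[str] = field(default_factory=list)
    cell_number: dict | None = None

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str, **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    streams = np.random.SeedSequence(seed).spawn(len(_STAGE_STREAM))
    return np.random.default_rng(streams[_STAGE_STREAM[stage]])


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Validation errors abort the run before any analysis; stage failures
    surface as :class:`XskewError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in set(config.stages)]
    report = RunReport(
        config_digest=config.digest(), seed=config.seed, version=__version__
    )

    # ------------------------------------------------------------ input
    if "simulate" in stages:
        sim = config.simulation
        if sim == "default" or sim is None:
            sim = default_params()
        log.info("simulate: %d genes, %d+%d females, seed %d",
                 len(sim.genes), sim.n_females_per_cross, sim.n_females_per_cross,
                 config.seed)
        table = simulate_dataset(sim, _stage_rng(config.seed, "simulate"))
        write_table(table, out / "data.csv", out / "annotations.csv")
        report.stages_run.append("simulate")
    elif config.data_path and config.annotations_path:
        table = read_table(config.data_path, config.annotations_path)
    else:
        raise XskewError(
            "configuration error: need either the simulate stage or data/annotation paths"
        )
    report.design = table.design_summary()

    # --------------------------------------------------------- validate
    if "validate" in stages:
        vr = validate_table(table, male_tolerance=config.male_tolerance)
        report.validation = {
            "ok": vr.ok,
            "errors": vr.errors,
            "warnings": vr.warnings,
        }
        (out / "validation.json").write_text(json.dumps(report.validation, indent=2) + "\n")
        report.stages_run.append("validate")
        if not vr.ok:
            raise XskewError(f"stage 'validate' rejected the table: {vr.errors}")

    result = None
    # -------------------------------------------------------------- fit
    if "fit" in stages:
        log.info("fit: nested ANOVA (%s SS) on classes %s",
                 config.ss_type, tuple(config.gene_classes))
        result = fit_nested_anova(table, config.anova_spec())
        result.table.to_csv(out / "anova_table.csv")
        lsm = ls_means(result)
        lsm.to_csv(out / "ls_means.csv")
        vc = variance_components(result)
        vc.to_csv(out / "variance_components.csv")
        report.anova_table = {
            src: {k: (None if (isinstance(v, float) and np.isnan(v)) else v)
                  for k, v in row.items() if k != "error_stratum"}
            for src, row in result.table.to_dict(orient="index").items()
        }
        report.ls_means = lsm["ls_mean"].to_dict()
        means = lsm["ls_mean"].to_numpy()
        report.ls_mean_difference = float(means.max() - means.min())
        report.variance_components = vc["prop_ems"].to_dict()

        bias = reciprocal_difference(
            table, genes=table.genes_of_class(config.gene_classes)
        )
        bias.frame.to_csv(out / "reciprocal_bias.csv", index=False)
        report.sign_test = sign_test_direction(bias.frame["difference"])
        report.stages_run.append("fit")

    # --------------------------------------------------------- escapers
    if "escapers" in stages:
        log.info("escapers: correlation profiling + clustering")
        esc = call_escapers(
            table,
            inactivated_floor=config.inactivated_floor,
            calibration_margin=config.calibration_margin,
        )
        esc.calls.to_csv(out / "escaper_calls.csv", index=False)
        if esc.tree is not None:
            (out / "gene_tree.nwk").write_text(esc.tree.to_newick() + "\n")
        report.escaper_calls = esc.calls.set_index("gene_id")["call"].to_dict()
        report.escaper_warnings = esc.warnings
        report.stages_run.append("escapers")

    # -------------------------------------------------------- cellcount
    if "cellcount" in stages:
        if result is None:
            result = fit_nested_anova(table, config.anova_spec())
        obs_var = observed_sampling_variance(result)
        lsm = ls_means(result)
        p = float(np.clip(lsm["ls_mean"].mean(), 0.0, 1.0))
        n_per_cross = int(round(np.mean(list(
            result.meta["individuals_per_cross"].values()))))
        log.info("cellcount: observed variance %.5f, p %.3f, grid %s, %d reps",
                 obs_var, p, config.grid, config.reps)
        curve = simulate_variance_curve(
            range(config.grid[0], config.grid[1] + 1),
            n_individuals=n_per_cross,
            p=p,
            reps=config.reps,
            rng=_stage_rng(config.seed, "cellcount"),
        )
        np.savetxt(
            out / "variance_curve.csv",
            np.column_stack([curve.grid, curve.mean_variance,
                             curve.quantile(0.025), curve.quantile(0.975)]),
            delimiter=",",
            header="n_cells,mean_variance,q025,q975",
            comments="",
            fmt="%.10g",
        )
        est = estimate_cell_number(obs_var, curve)
        report.cell_number = {
            "n_hat": est.n_hat,
            "ci95": list(est.ci95),
            "observed_variance": est.observed_variance,
            "extrapolated": est.extrapolated,
            **est.meta,
        }
        (out / "cell_number.json").write_text(
            json.dumps(report.cell_number, indent=2) + "\n"
        )
        report.stages_run.append("cellcount")

    report.save(out / "report.json")
    return report


def make_fixture(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the packaged simulated datasets for both strain-pair designs.

    Produces ``pwd_akr_data.csv`` / ``pwd_akr_annotations.csv`` (41 genes,
    18+18 females, male controls) and the ``b6_cast_*`` companion files
    (20 genes, 11+11 females).  Deterministic under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(2)
    paths = {}
    for stream, pair, stem in zip(
        streams, ("PWD-AKR", "B6-CAST"), ("pwd_akr", "b6_cast")
    ):
        table = simulate_dataset(default_params(pair), np.random.default_rng(stream))
        data_path = out / f"{stem}_data.csv"
        ann_path = out / f"{stem}_annotations.csv"
        write_table(table, data_path, ann_path)
        paths[f"{stem}_data"] = data_path
        paths[f"{stem}_annotations"] = ann_path
    return paths
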