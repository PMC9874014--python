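"""End-to-end pipeline: impute -> bounds -> sweep -> calibrate -> budget.

One run processes one condition (all sample columns of the proteome are
treated as replicates and averaged after imputation).  Outputs are TSV
tables plus a calibration JSON, a resolved-config YAML and a
deterministic run log; given the same config and seed, the numeric
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_annotation
from .completerot import compare_prepost, impute, reports_to_frame
from .demand import budget, build_consumers, consumers_to_frame, protein_synthesis
from .fba import CalibrationPoint, calibrate, exchange_report, solve_fba, sweep
from .gpr import CompressionParams, ExchangeSpec, effective_abundances, exchange_bounds, internal_bounds
from .io import load_gene_map, read_measured_fluxes, read_medium, read_model
from .proteome import ProteomeTable

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_K_GRID = [0.001, 0.004, 0.016, 0.063, 0.25, 1.0]
DEFAULT_R_GRID = [0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6]


@dataclass
class PipelineConfig:
    model_path: str
    proteome_path: str
    annotation_path: str
    medium_path: str
    output_dir: str
    model_dialect: str | None = None  # json | sbml (inferred from suffix)
    kcat_path: str | None = None
    measured_flux_path: str | None = None
    gene_map_path: str | None = None
    condition: str | None = None
    objective_reaction_id: str | None = None  # default: model's declared objective
    glucose_id: str = "glc_e"
    mode: str = "dmem"  # dmem | measured
    k_grid: list[float] = field(default_factory=lambda: list(DEFAULT_K_GRID))
    r_grid: list[float] = field(default_factory=lambda: list(DEFAULT_R_GRID))
    b_max: float = 1000.0
    turnover_rate: float = 0.5
    measured_atp: float | None = None  # pmol ATP / ng protein / day
    measured_glucose: float | None = None  # pmol glucose / ng protein / day
    secretion_constraint: str = "floor"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_grid or not self.r_grid:
            raise ValueError("k_grid and r_grid must be non-empty")
        if self.mode not in ("dmem", "measured"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def check_paths(self) -> None:
        required = [self.model_path, self.proteome_path, self.annotation_path, self.medium_path]
        optional = [self.kcat_path, self.measured_flux_path, self.gene_map_path]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full supply-and-demand pipeline and write all outputs.

    Returns a dict with the in-memory results (completed proteome, sweep
    grid, calibration, budget, protein-synthesis estimate) and the paths
    written.
    """
    config.check_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.random.seed(config.seed % 2**31)  # no stage is stochastic; belt and braces

    gene_map = load_gene_map(config.gene_map_path) if config.gene_map_path else None
    model = _stage("read_model")(read_model)(config.model_path, config.model_dialect, gene_map)
    proteome = _stage("read_proteome")(ProteomeTable.from_tsv)(config.proteome_path)
    ann = _stage("read_annotation")(load_annotation)(config.annotation_path)
    if config.kcat_path:
        kcat = pd.read_csv(config.kcat_path, sep="\t").set_index("gene_id")["kcat_per_s"]
        ann.table["kcat"] = kcat.reindex(ann.table.index).combine_first(ann.table["kcat"])
    medium = _stage("read_medium")(read_medium)(config.medium_path)
    measured_fluxes: dict[str, float] = {}
    if config.measured_flux_path:
        measured_fluxes = _stage("read_measured_fluxes")(read_measured_fluxes)(
            config.measured_flux_path, config.condition
        )
    mode = config.mode
    if mode == "measured" and not measured_fluxes:
        logger.warning("measured mode requested without measured fluxes; using DMEM mode")
        mode = "dmem"

    # 1. imputation ------------------------------------------------------
    completed, reports = _stage("impute")(impute)(proteome, ann)
    report_frame = reports_to_frame(reports)
    _, prepost_corr = compare_prepost(proteome, completed, ann, "level2")
    abundance = completed.data.mean(axis=1)  # replicate average per protein

    # 2/3. bounds + sweep ------------------------------------------------
    exchange = ExchangeSpec(
        mode=mode,
        medium_mM=medium,
        r=config.r_grid[0],
        measured_fluxes=measured_fluxes,
        glucose_id=config.glucose_id,
        secretion_constraint=config.secretion_constraint,
    )
    grid = _stage("sweep")(sweep)(
        model,
        abundance.to_dict(),
        exchange,
        config.k_grid,
        config.r_grid,
        b_max=config.b_max,
        objective_id=config.objective_reaction_id,
    )

    # 4. calibration -----------------------------------------------------
    calibration: CalibrationPoint | None = None
    if config.measured_atp is not None and config.measured_glucose is not None:
        calibration = _stage("calibrate")(calibrate)(
            grid, config.measured_atp, config.measured_glucose
        )
        k_star, r_star = calibration.k_star, calibration.r_star
        total_capacity = calibration.predicted_atp
        capacity_unit = "pmol ATP/ng protein/day"
    else:
        # no calibration data: report at the conventional grid point
        k_star = min(config.k_grid, key=lambda k: abs(k - 0.016))
        r_star = min(config.r_grid, key=lambda r: abs(r - 0.05))
        i = config.k_grid.index(k_star)
        j = config.r_grid.index(r_star)
        total_capacity = float(grid.objective[i, j])
        capacity_unit = "arbitrary units"

    # 5. demand budget ---------------------------------------------------
    params = CompressionParams(k=k_star, b_max=config.b_max)
    consumers = _stage("build_consumers")(build_consumers)(abundance.to_dict(), ann, params)
    budget_frame = _stage("budget")(budget)(consumers, total_capacity)
    try:
        synthesis = protein_synthesis(budget_frame, config.turnover_rate)
    except ValueError:
        synthesis = None

    # calibrated exchange fluxes ----------------------------------------
    exchange_fluxes = None
    if calibration is not None:
        star_exchange = ExchangeSpec(
            mode=mode,
            medium_mM=medium,
            r=r_star,
            measured_fluxes=measured_fluxes,
            glucose_id=config.glucose_id,
            secretion_constraint=config.secretion_constraint,
        )
        star_model = exchange_bounds(
            internal_bounds(model, effective_abundances(model, abundance.to_dict()), params),
            star_exchange,
            params,
        )
        sol = solve_fba(star_model, config.objective_reaction_id)
        if sol.optimal:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                exchange_fluxes = exchange_report(sol, calibration.scale_factor, model)

    # 6. outputs ---------------------------------------------------------
    paths = {}

    def _write(name: str, frame: pd.DataFrame, **kwargs) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
        paths[name] = str(path)

    _write("sweep_grid.tsv", grid.to_frame(), index=False)
    obj = pd.DataFrame(grid.objective, index=pd.Index(grid.k_values, name="k"), columns=grid.r_values)
    _write("sweep_objective_matrix.tsv", obj)
    _write("imputation_report.tsv", report_frame, index=False)
    budget_out = budget_frame.copy()
    budget_out["flux_unit"] = capacity_unit
    _write("budget.tsv", budget_out)
    _write("consumers.tsv", consumers_to_frame(consumers))
    if exchange_fluxes is not None:
        _write(
            "exchange_report.tsv",
            exchange_fluxes.rename("flux").to_frame().rename_axis("reaction"),
        )

    cal_doc = {
        "k_star": k_star,
        "r_star": r_star,
        "total_capacity": total_capacity,
        "capacity_unit": capacity_unit,
        "mode": mode,
        "imputation_prepost_correlation": prepost_corr,
        "n_missing_imputed": int(len(report_frame)),
    }
    if calibration is not None:
        cal_doc.update(
            measured_atp=calibration.measured_atp,
            predicted_atp=calibration.predicted_atp,
            scale_factor=calibration.scale_factor,
        )
    if synthesis is not None:
        cal_doc["protein_synthesis"] = {
            "atp_to_ligases": synthesis.atp_to_ligases,
            "aa_flux": synthesis.aa_flux,
            "total_rate_per_day": synthesis.total_rate,
            "net_rate_per_day": synthesis.net_rate,
            "turnover_rate_per_day": synthesis.turnover_rate,
        }
    cal_path = outdir / "calibration.json"
    cal_path.write_text(json.dumps(cal_doc, indent=2, sort_keys=True) + "\n")
    paths["calibration.json"] = str(cal_path)

    config.to_yaml(outdir / "resolved_config.yaml")
    paths["resolved_config.yaml"] = str(outdir / "resolved_config.yaml")
    log_lines = [
        f"enerflow {__version__}",
        f"model={model.id} reactions={len(model.reactions)}",
        f"proteome proteins={len(proteome.protein_ids)} samples={len(proteome.samples)}",
        f"missing imputed={len(report_frame)} prepost_corr={prepost_corr:.6f}",
        f"mode={mode} k_grid={config.k_grid} r_grid={config.r_grid} b_max={config.b_max}",
        f"k_star={k_star} r_star={r_star} capacity={total_capacity} [{capacity_unit}]",
        f"seed={config.seed}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log.txt"] = str(outdir / "run_log.txt")

    return {
        "completed": completed,
        "imputation_report": report_frame,
        "prepost_correlation": prepost_corr,
        "grid": grid,
        "calibration": calibration,
        "k_star": k_star,
        "r_star": r_star,
        "total_capacity": total_capacity,
        "consumers": consumers,
        "budget": budget_frame,
        "protein_synthesis": synthesis,
        "exchange_fluxes": exchange_fluxes,
        "paths": paths,
    }
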