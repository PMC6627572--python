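"""End-to-end pipeline orchestration and diagnostic artefacts.

One configuration file drives simulate -> quantify -> fold changes ->
normalize -> fit -> call targets, writing every intermediate as a
tab-delimited table plus a run log.  The configuration is a flat YAML
key-value mapping; unknown keys are rejected so typos fail loudly.
All artefacts are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ExperimentDesign, TemperatureGradient
from .normalize import (
    DEFAULT_WINDOWS,
    apply_normalization,
    compute_correction_factors,
    select_normalization_set,
    write_factors_table,
)
from .quantio import (
    aggregate_top3,
    compute_fold_changes,
    read_abundance_table,
    read_peptide_table,
    write_abundance_table,
    write_results_table,
)
from .simdata import SimulationConfig, simulate_study, write_ground_truth
from .targets import AnalysisThresholds, TargetRecord, call_targets, records_to_frame

logger = logging.getLogger(__name__)

#: Volcano-plot steepness cutoff on the absolute slope (per °C); a protein
#: whose best slope magnitude is exactly at the cutoff counts as shallow.
SLOPE_FLAG_THRESHOLD = 0.06


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artefacts are retained."""


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    output_dir: str = "btpp_out"
    input: str | None = None
    input_kind: str = "abundance"  # or "peptides"
    temperatures: tuple[float, ...] = TemperatureGradient().temps
    normalize: bool = True
    windows: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    nparc_method: str = "permutation"
    n_permutations: int = 1000
    seed: int = 0
    simulation: SimulationConfig | None = None

    _SCALARS = {
        "output_dir": str,
        "input": str,
        "input_kind": str,
        "normalize": bool,
        "nparc_method": str,
        "n_permutations": int,
        "seed": int,
    }
    _THRESHOLDS = {"r2_min", "vehicle_plateau_max", "slope_max", "alpha"}
    _SIM_KEYS = {
        f"sim_{f.name}": f.name
        for f in dc_fields(SimulationConfig)
        if f.name not in ("dtm_range", "vesicle_fraction_range", "steepness_range", "seed")
    }
    _SIM_PAIRS = {
        "sim_dtm_low": ("dtm_range", 0),
        "sim_dtm_high": ("dtm_range", 1),
        "sim_vesicle_low": ("vesicle_fraction_range", 0),
        "sim_vesicle_high": ("vesicle_fraction_range", 1),
        "sim_steepness_low": ("steepness_range", 0),
        "sim_steepness_high": ("steepness_range", 1),
    }

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        thresholds = {}
        sim_kwargs: dict = {}
        windows: dict[float, tuple[float, float]] = {}
        simulate = False
        for key, value in raw.items():
            if key in cls._SCALARS:
                setattr(cfg, key, cls._SCALARS[key](value))
            elif key in cls._THRESHOLDS:
                thresholds[key] = float(value)
            elif key == "temperatures":
                parts = (
                    value if isinstance(value, (list, tuple)) else str(value).split(",")
                )
                cfg.temperatures = tuple(float(v) for v in parts)
            elif key.startswith("norm_window_"):
                t = float(key.removeprefix("norm_window_"))
                lo, hi = str(value).split(",")
                windows[t] = (float(lo), float(hi))
            elif key == "simulate":
                simulate = bool(value)
            elif key in cls._SIM_KEYS:
                simulate = True
                name = cls._SIM_KEYS[key]
                typ = {"mode": str}.get(name, None)
                if name in ("n_proteins", "n_replicates"):
                    sim_kwargs[name] = int(value)
                elif typ is str:
                    sim_kwargs[name] = str(value)
                else:
                    sim_kwargs[name] = float(value)
            elif key in cls._SIM_PAIRS:
                simulate = True
                name, pos = cls._SIM_PAIRS[key]
                pair = list(sim_kwargs.get(name, getattr(SimulationConfig(1), name)))
                pair[pos] = float(value)
                sim_kwargs[name] = tuple(pair)
            else:
                raise PipelineError(f"unknown configuration key {key!r}")
        if thresholds:
            cfg.thresholds = AnalysisThresholds(**thresholds)
        if windows:
            cfg.windows = windows
        if simulate:
            cfg.simulation = SimulationConfig(
                **{"n_proteins": 1000, **sim_kwargs, "seed": cfg.seed}
            )
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"{path}: configuration must be a flat key-value mapping")
        return cls.from_mapping(raw)

    @property
    def gradient(self) -> TemperatureGradient:
        return TemperatureGradient(self.temperatures)


def fits_table(records: list[TargetRecord], design: ExperimentDesign) -> pd.DataFrame:
    """Per-protein, per-experiment fitted parameters (curve export layout)."""
    rows = []
    for rec in records:
        for (cond, rep), fit in zip(design.experiments(), _fits_in_design_order(rec)):
            rows.append(
                {
                    "accession": rec.accession,
                    "experiment": f"{cond}_{rep}",
                    "a": fit.a,
                    "b": fit.b,
                    "plateau": fit.plateau,
                    "tm": fit.tm if fit.tm is not None else np.nan,
                    "steepest_slope": fit.steepest_slope,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def _fits_in_design_order(rec: TargetRecord):
    # records store fits as (vehicle_1, treatment_1, vehicle_2, treatment_2);
    # design order is vehicle_1, vehicle_2, treatment_1, treatment_2
    veh1, trt1, veh2, trt2 = rec.fits
    return (veh1, veh2, trt1, trt2)


def volcano_table(
    records: list[TargetRecord],
    slope_threshold: float = SLOPE_FLAG_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Vehicle-vehicle Tm difference vs best absolute slope, per protein.

    Rows with an undefined vehicle melting point are omitted; the second
    return value counts them.  ``steep`` is strict: a slope magnitude exactly
    at the threshold is shallow.
    """
    rows = []
    omitted = 0
    for rec in records:
        if not (np.isfinite(rec.tm_vehicle_1) and np.isfinite(rec.tm_vehicle_2)):
            omitted += 1
            continue
        slopes = [abs(f.steepest_slope) for f in rec.fits if f.converged]
        min_abs_slope = min(slopes) if slopes else np.nan
        rows.append(
            {
                "accession": rec.accession,
                "vehicle_dtm": abs(rec.tm_vehicle_1 - rec.tm_vehicle_2),
                "min_abs_slope": min_abs_slope,
                "steep": bool(min_abs_slope > slope_threshold),
            }
        )
    return pd.DataFrame(rows), omitted


def heatmap_matrix(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    records: list[TargetRecord],
    condition: str | None = None,
    replicate: int | None = None,
) -> pd.DataFrame:
    """Proteins x temperatures fold changes of one experiment, Tm-ordered.

    Rows are sorted by the selected experiment's fitted melting point, ties
    and undefined melting points by accession (undefined last).  The first
    column is identically 1 (the reference temperature).
    """
    condition = condition or design.vehicle
    replicate = replicate if replicate is not None else design.replicates[0]
    exp_index = design.experiments().index((condition, replicate))
    tm_by_acc = {}
    for rec in records:
        fit = _fits_in_design_order(rec)[exp_index]
        tm_by_acc[rec.accession] = (
            fit.tm if (fit.converged and fit.tm is not None) else np.inf
        )
    cols = design.experiment_labels(condition, replicate)
    sub = fc[cols].copy()
    sub.columns = [f"{t:g}" for t in design.gradient]
    order = sorted(sub.index, key=lambda acc: (tm_by_acc.get(acc, np.inf), acc))
    return sub.loc[order]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artefacts into ``config.output_dir``.

    Returns a dict with the target records, tables and artefact paths.
    Raises :class:`PipelineError` on a stage failure; artefacts written
    before the failure are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"btpp {__version__}",
        f"seed: {config.seed}",
        f"thresholds: {config.thresholds}",
        f"nparc: {config.nparc_method} ({config.n_permutations} permutations)",
        f"gradient: {config.temperatures}",
    ]
    gradient = config.gradient
    truth = None

    if config.simulation is not None:
        truth, abundance, design = simulate_study(config.simulation, gradient)
        write_ground_truth(truth, out / "ground_truth.tsv")
        write_abundance_table(abundance, out / "abundance.tsv")
        log_lines.append(f"simulated: {config.simulation}")
    elif config.input is not None:
        path = Path(config.input)
        if not path.exists():
            raise PipelineError(f"input file not found: {path}")
        if config.input_kind == "peptides":
            peptides = read_peptide_table(path)
            abundance = aggregate_top3(peptides)
            from .design import design_from_columns

            design = design_from_columns(list(abundance.columns))
            abundance = abundance[design.sample_labels()]
            write_abundance_table(abundance, out / "abundance.tsv")
        elif config.input_kind == "abundance":
            abundance, design = read_abundance_table(path)
        else:
            raise PipelineError(f"unknown input_kind {config.input_kind!r}")
    else:
        raise PipelineError("no input path and no simulation block configured")

    fc, exclusions = compute_fold_changes(abundance, design)
    write_abundance_table(fc, out / "fold_changes.tsv")
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    log_lines.append(f"proteins: {len(fc)}; unusable experiments: {len(exclusions)}")

    if config.normalize:
        norm_set = select_normalization_set(fc, design, config.windows)
        factors = compute_correction_factors(fc, design, norm_set)
        fc_used = apply_normalization(fc, factors, design)
        write_factors_table(factors, out / "normalization_factors.tsv")
        write_abundance_table(fc_used, out / "normalized_fold_changes.tsv")
        log_lines.append(
            f"normalization: {len(norm_set)} proteins, reference {factors.reference}"
        )
    else:
        fc_used = fc
        log_lines.append("normalization: disabled")

    records = call_targets(
        fc_used,
        design,
        thresholds=config.thresholds,
        nparc_method=config.nparc_method,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    results = records_to_frame(records)
    write_results_table(results, out / "targets.tsv")
    failures = results.loc[
        ~results["is_target"], ["accession", "first_failed"]
    ]
    failures.to_csv(out / "failures.tsv", sep="\t", index=False)

    fits = fits_table(records, design)
    fits.to_csv(out / "fits.tsv", sep="\t", index=False, float_format="%.10g")

    volcano, n_omitted = volcano_table(records)
    volcano.to_csv(out / "volcano.tsv", sep="\t", index=False, float_format="%.10g")
    heat = heatmap_matrix(fc_used, design, records)
    heat.to_csv(out / "heatmap.tsv", sep="\t", float_format="%.10g")
    log_lines.append(
        f"targets: {int(results['is_target'].sum())} by criteria, "
        f"{int(results['passes_significance'].sum())} significant; "
        f"volcano rows omitted: {n_omitted}"
    )

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    for line in log_lines:
        logger.info(line)
    return {
        "records": records,
        "results": results,
        "fits": fits,
        "volcano": volcano,
        "heatmap": heat,
        "truth": truth,
        "output_dir": out,
    }
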