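"""File contracts, manifests and the end-to-end pipeline driver.

Trace tables are long-format CSV with the fixed header
``cell_id,genotype,promoter,stimulus,time_min,channel,value``; per-cell
features are TSV; binned relationships are TSV; gate calls, regulator fits
and summaries are JSON. All formats are plain text so fixtures diff cleanly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .analysis import (
    BinnedRelationship,
    derive_responder_threshold,
    distribution_summary,
    bin_by_tf,
)
from .features import extract_features
from .gates import fit_regulator_mode, gate_vs_duration
from .params import (
    ExperimentConfig,
    Genotype,
    PromoterParams,
    StimulusProgram,
    TFParams,
)
from .simulate import SCHEMA_VERSION, CellTrace, ExperimentSet, generate_experiment

logger = logging.getLogger("msngate")

TRACE_COLUMNS = ["cell_id", "genotype", "promoter", "stimulus", "time_min", "channel", "value"]
CHANNELS = ("msn2", "msn4", "reporter")


class PipelineStageError(RuntimeError):
    """An error raised by one named stage of the pipeline."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def write_traces(experiment: ExperimentSet, path) -> None:
    """Write an experiment as a long-format CSV trace table.

    Floats are written with 17 significant digits so that reading the file
    back restores values exactly.
    """
    experiment.to_long_frame().to_csv(path, index=False, float_format="%.17g")


def read_traces(path) -> ExperimentSet:
    """Read and validate a long-format CSV trace table.

    Enforces the exact header, known channels, and a shared uniform time
    grid; a cell missing a timepoint in any channel is reported by name.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(
            f"unexpected header in {path}: {list(df.columns)}; expected {TRACE_COLUMNS}"
        )
    if len(df) == 0:
        logger.warning("trace file %s is empty", path)
        return ExperimentSet(traces=[], metadata={"schema_version": SCHEMA_VERSION})
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channels in {path}: {sorted(bad)}")

    grid = np.sort(df["time_min"].unique())
    if len(grid) > 1:
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"non-uniform time grid in {path}")

    traces: List[CellTrace] = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        channels = {}
        for ch, chsub in sub.groupby("channel"):
            chsub = chsub.sort_values("time_min")
            if len(chsub) != len(grid) or not np.array_equal(
                chsub["time_min"].to_numpy(), grid
            ):
                raise ValueError(
                    f"cell {cell_id!r} channel {ch!r} does not cover the shared "
                    f"time grid ({len(chsub)} of {len(grid)} samples)"
                )
            channels[ch] = chsub["value"].to_numpy(dtype=float)
        missing = set(CHANNELS) - set(channels)
        if missing:
            raise ValueError(f"cell {cell_id!r} lacks channels {sorted(missing)}")
        genotype = Genotype(sub["genotype"].iloc[0])
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                genotype=genotype,
                time_min=grid.astype(float),
                msn2_nuc=channels["msn2"],
                msn4_nuc=channels["msn4"],
                reporter=channels["reporter"],
            )
        )
    metadata = {
        "schema_version": SCHEMA_VERSION,
        "promoter": str(df["promoter"].iloc[0]),
        "stimulus": str(df["stimulus"].iloc[0]),
        "genotype": str(df["genotype"].iloc[0]),
    }
    return ExperimentSet(traces=traces, metadata=metadata)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_binned(binned: BinnedRelationship, path) -> None:
    binned.to_frame().to_csv(path, sep="\t", index=False)


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, enum.Enum):
            return o.value
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_JSONEncoder) + "\n")


class ManifestEntry(BaseModel):
    label: str
    genotype: Genotype
    promoter: str
    stimulus: str
    traces_path: str
    features_path: Optional[str] = None


class ExperimentManifest(BaseModel):
    """Index of the experiments making up one analysis run."""

    schema_version: str = SCHEMA_VERSION
    entries: List[ManifestEntry] = Field(default_factory=list)
    seeds: Dict[str, int] = Field(default_factory=dict)

    @field_validator("entries")
    @classmethod
    def _unique_labels(cls, v):
        labels = [e.label for e in v]
        if len(set(labels)) != len(labels):
            raise ValueError("manifest labels must be unique")
        return v

    @classmethod
    def load(cls, path) -> "ExperimentManifest":
        return cls.model_validate_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


class PipelineConfig(BaseModel):
    """Configuration of the end-to-end demo pipeline.

    Simulates both promoter classes for every genotype at the listed pulse
    durations, extracts features, bins the slow-promoter WT data by each TF,
    fits regulator modes, and classifies gate logic per duration.
    """

    n_cells: int = Field(default=200, ge=1)
    seed: int = Field(default=0, ge=0)
    durations_min: List[float] = Field(default_factory=lambda: [30.0, 60.0])
    #: doses pooled for the single-cell regulator-mode fits, mirroring the
    #: pooled-dose design that exposes the full dynamic range of TF levels
    fit_doses: List[float] = Field(default_factory=lambda: [0.1, 0.25, 0.5, 0.75, 1.0])
    genotypes: List[Genotype] = Field(
        default_factory=lambda: [Genotype.WT, Genotype.MSN2D, Genotype.MSN4D,
                                 Genotype.MSN2D_MSN4D]
    )
    tf: TFParams = TFParams()
    n_bins: int = 5
    responder_quantile: float = 0.95
    low_cut: float = 0.25
    high_cut: float = 0.5


def _control_threshold(cfg: PipelineConfig, promoter: PromoterParams):
    """Responder rule from an unstimulated (dose 0) control simulation."""
    control = generate_experiment(
        ExperimentConfig(
            genotype=Genotype.WT,
            n_cells=max(50, cfg.n_cells),
            seed=cfg.seed + 900,
            tf=cfg.tf,
            promoter=promoter,
            stimulus=StimulusProgram(dose=0.0, duration_min=30.0),
        )
    )
    endpoints = [tr.reporter[-1] for tr in control.traces]
    return derive_responder_threshold(endpoints, cfg.responder_quantile)


def run_pipeline(config: PipelineConfig | dict, outdir) -> dict:
    """Execute simulate -> features -> analyze -> gates -> report.

    Writes traces (CSV), features (TSV), binned relationships (TSV),
    gates.json and report.md under ``outdir`` and returns the result bundle.
    Identical config and seed give byte-identical outputs.
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    promoters = {"fast": PromoterParams.fast(), "slow": PromoterParams.slow()}
    manifest = ExperimentManifest(seeds={"base": config.seed})
    experiments: Dict[str, Dict[float, Dict[str, ExperimentSet]]] = {}
    features: Dict[str, pd.DataFrame] = {}

    try:
        for pname, prom in promoters.items():
            experiments[pname] = {}
            for duration in config.durations_min:
                stim = StimulusProgram(duration_min=duration)
                sets = {}
                for genotype in config.genotypes:
                    cfg = ExperimentConfig(
                        genotype=genotype,
                        n_cells=config.n_cells,
                        seed=config.seed,
                        tf=config.tf,
                        promoter=prom,
                        stimulus=stim,
                    )
                    expset = generate_experiment(cfg)
                    label = cfg.resolved_label()
                    tpath = outdir / f"traces_{label}.csv"
                    write_traces(expset, tpath)
                    fdf = extract_features(expset)
                    fpath = outdir / f"features_{label}.tsv"
                    write_features(fdf, fpath)
                    manifest.entries.append(
                        ManifestEntry(
                            label=label,
                            genotype=genotype,
                            promoter=pname,
                            stimulus=stim.label(),
                            traces_path=tpath.name,
                            features_path=fpath.name,
                        )
                    )
                    sets[genotype.value] = expset
                    features[label] = fdf
                experiments[pname][duration] = sets
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate", str(exc)) from exc

    try:
        gate_tables = {
            pname: gate_vs_duration(by_dur, config.low_cut, config.high_cut)
            for pname, by_dur in experiments.items()
        }
    except KeyError as exc:
        raise PipelineStageError("gates", f"missing genotype entry: {exc}") from exc

    try:
        rule = _control_threshold(config, promoters["slow"])
        first_duration = config.durations_min[0]
        # regulator-mode fits need the full dynamic range of TF levels,
        # so WT slow-promoter responses are pooled across doses
        n_per_dose = max(20, config.n_cells // len(config.fit_doses))
        pooled = pd.concat(
            [
                extract_features(
                    generate_experiment(
                        ExperimentConfig(
                            genotype=Genotype.WT,
                            n_cells=n_per_dose,
                            seed=config.seed + 100 + i,
                            tf=config.tf,
                            promoter=promoters["slow"],
                            stimulus=StimulusProgram(
                                duration_min=first_duration, dose=dose
                            ),
                        )
                    )
                )
                for i, dose in enumerate(config.fit_doses)
            ],
            ignore_index=True,
        )
        binned = {}
        fits = {}
        for tf_name in ("msn2", "msn4"):
            b = bin_by_tf(pooled, tf=tf_name, n_bins=config.n_bins,
                          responder_rule=rule)
            binned[tf_name] = b
            write_binned(b, outdir / f"binned_slow_WT_{tf_name}.tsv")
            fits[tf_name] = fit_regulator_mode(b)
        summary = distribution_summary(
            pd.concat(
                [features[e.label].assign(label=e.label) for e in manifest.entries],
                ignore_index=True,
            ),
            by=("label",),
        )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("analyze", str(exc)) from exc

    gates_payload = {
        "schema_version": SCHEMA_VERSION,
        "responder_threshold": rule.threshold,
        "gates": {p: t.to_dict(orient="records") for p, t in gate_tables.items()},
        "regulator_fits": {
            tf_name: {
                "mode": fit.mode.value,
                "theta_hat": fit.theta_hat,
                "theta_pct_of_max": fit.theta_pct_of_max,
                "slope": fit.slope,
                "criterion": fit.criterion,
            }
            for tf_name, fit in fits.items()
        },
    }
    write_json(gates_payload, outdir / "gates.json")
    manifest.save(outdir / "manifest.json")
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    report = render_report(gate_tables, fits, rule.threshold)
    (outdir / "report.md").write_text(report)
    return {
        "manifest": manifest,
        "gates": gate_tables,
        "fits": fits,
        "binned": binned,
        "responder_rule": rule,
        "report": report,
    }


def render_report(gate_tables, fits, responder_threshold: float) -> str:
    """Markdown summary of gate calls and regulator-mode fits."""
    lines = ["# Gate logic and regulator modes", ""]
    lines.append(f"Responder threshold (control 95th percentile): "
                 f"{responder_threshold:.3g} expression a.u.")
    for pname, table in gate_tables.items():
        lines.append("")
        lines.append(f"## {pname} kinetics promoter")
        lines.append("")
        lines.append("| duration (min) | gate | WT mean | msn2d/WT | msn4d/WT |")
        lines.append("|---|---|---|---|---|")
        for _, row in table.iterrows():
            lines.append(
                f"| {row['duration_min']:g} | {row['label']} | "
                f"{row['wt_mean']:.3g} | {row['frac_msn4_only']:.2f} | "
                f"{row['frac_msn2_only']:.2f} |"
            )
    lines.append("")
    lines.append("## Slow-promoter single-cell regulator modes (WT)")
    lines.append("")
    for tf_name, fit in fits.items():
        extra = ""
        if fit.mode.value == "switch" and fit.theta_pct_of_max is not None:
            extra = (f" (threshold {fit.theta_hat:.3g} normalized a.u. = "
                     f"{fit.theta_pct_of_max:.1f}% of max)")
        if fit.mode.value == "rheostat":
            extra = f" (slope {fit.slope:.3g} a.u. per normalized a.u.)"
        lines.append(f"- {tf_name}: {fit.mode.value}{extra}")
    lines.append("")
    return "\n".join(lines)
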