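"""End-to-end orchestration: one declarative, hashable run definition.

A :class:`WorkflowConfig` binds sequences, the target peptide workbook,
run inputs (real mzML files or a simulation scenario) and processing
parameters into a single validated document, mirroring how a locked
acquisition/processing method travels between laboratories. The config hash
is recorded in every output so identical configs provably produced identical
reports; reruns with the same seed are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .components import (
    read_component_csv,
    validate_component_table,
    write_component_csv,
)
from .digest import read_fasta
from .msio import Run, RunMetadata, read_mzml, write_mzml
from .quant import estimate_rt_shift, quantify_components
from .rollup import (
    attribute_definitions,
    coverage_map,
    missed_cleavage_rate,
    nonspecific_rate,
    rollup_attributes,
    venn_membership,
    write_coverage_csv,
)
from .simulate import (
    ScenarioConfig,
    build_component_table,
    bundled_chains,
    make_ground_truth,
    simulate_study,
)
from .stats import precision_report, trend_summary


class RunInput(BaseModel):
    path: str
    lab: str = "lab0"
    replicate: int = 0
    sample: str = "sample"
    timepoint: float = 0.0


class SimulationSection(BaseModel):
    preset: str = "nist_table1"
    lab_column: str = "Ireland"
    scenario: ScenarioConfig


class ProcessingParams(BaseModel):
    ppm: float = Field(default=5.0, gt=0)
    rt_window_min: float = Field(default=1.5, gt=0)
    max_missed: int = Field(default=1, ge=0)
    isotope_sum: int = Field(default=1, ge=1)
    envelope_correct: bool = True
    smooth_points: int = Field(default=3, ge=1)
    snr_k: float = Field(default=3.0, ge=0)
    estimate_rt_shift: bool = True
    gradient_min: float = Field(default=105.0, gt=0)


class WorkflowConfig(BaseModel):
    fasta: str | None = None  # bundled synthetic chains when omitted
    component_csv: str | None = None  # derived from the simulation truth when omitted
    runs: list[RunInput] = Field(default_factory=list)
    simulate: SimulationSection | None = None
    params: ProcessingParams = Field(default_factory=ProcessingParams)
    outdir: str = "mampep_out"

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"outdir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: WorkflowConfig) -> None:
    """Check every referenced file before any compute."""
    missing = []
    for attr in ("fasta", "component_csv"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            missing.append(path)
    for entry in config.runs:
        if not Path(entry.path).exists():
            missing.append(entry.path)
    if missing:
        raise FileNotFoundError(f"config references missing files: {missing}")
    if not config.runs and config.simulate is None:
        raise ValueError("config needs either mzML runs or a simulation section")


def run_workflow(config: WorkflowConfig, log=None) -> dict[str, Path]:
    """Execute digest -> (simulate) -> quantify -> rollup -> stats.

    Returns a map of report name -> written path. Any stage error aborts with
    the stage name attached.
    """
    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines: list[str] = [f"mampep {__version__} config_hash={chash}"]

    def _log(msg: str) -> None:
        log_lines.append(msg)
        if log is not None:
            print(msg, file=log)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                _log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _log(f"stage {name}: FAILED: {exc}")
                    raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
                _log(f"stage {name}: done")
        return _Ctx()

    with _stage("sequences"):
        chains = read_fasta(config.fasta) if config.fasta else bundled_chains()
        _log(f"chains: {', '.join(f'{c.id}({len(c)} aa)' for c in chains)}")

    truth = None
    with _stage("components"):
        if config.component_csv:
            components = read_component_csv(config.component_csv)
        elif config.simulate is not None:
            truth = make_ground_truth(config.simulate.preset, lab=config.simulate.lab_column)
            components = build_component_table(
                truth, chains, rt_window_min=config.params.rt_window_min,
                mz_range=config.simulate.scenario.mz_range)
        else:
            raise ValueError("no component table and no simulation to derive one from")
        components, rejects = validate_component_table(
            components, max_missed=config.params.max_missed,
            gradient_min=config.params.gradient_min)
        for cid, rule, msg in rejects:
            _log(f"component rejected [{rule}]: {cid}: {msg}")
        if not components:
            raise ValueError("no valid components after workbook validation")
        _log(f"components accepted: {len(components)}")

    runs: list[Run] = []
    with _stage("runs"):
        if config.simulate is not None:
            if truth is None:
                truth = make_ground_truth(config.simulate.preset,
                                          lab=config.simulate.lab_column)
            sim_dir = outdir / "runs"
            sim_dir.mkdir(exist_ok=True)
            for run in simulate_study(truth, components, config.simulate.scenario):
                meta = run.metadata
                path = sim_dir / f"{meta.lab}_r{meta.replicate}.mzML"
                write_mzml(run, path)
                runs.append(read_mzml(path))
        for entry in config.runs:
            meta = RunMetadata(lab=entry.lab, replicate=entry.replicate,
                               sample=entry.sample, timepoint=entry.timepoint)
            runs.append(read_mzml(entry.path, metadata=meta))
        _log(f"runs loaded: {len(runs)}")

    with _stage("quantify"):
        landmarks = [c for c in components if not c.is_modified][:10]
        frames = []
        found_tally: dict[str, int] = {}
        for run in runs:
            shift = 0.0
            if config.params.estimate_rt_shift:
                try:
                    shift = estimate_rt_shift(run, landmarks, ppm=config.params.ppm)
                except ValueError as exc:
                    _log(f"{run.metadata.lab}/r{run.metadata.replicate}: "
                         f"RT shift not estimated ({exc}); using 0")
            result = quantify_components(
                run, components, ppm=config.params.ppm, rt_shift=shift,
                isotope_sum=config.params.isotope_sum,
                envelope_correct=config.params.envelope_correct,
                smooth_points=config.params.smooth_points, snr_k=config.params.snr_k)
            n_found = int(result.components["found"].sum())
            found_tally[f"{run.metadata.lab}/r{run.metadata.replicate}"] = n_found
            _log(f"{run.metadata.lab}/r{run.metadata.replicate}: shift={shift:+.3f} min, "
                 f"found {n_found}/{len(components)} components")
            frames.append(result.components)
        comp_df = pd.concat(frames, ignore_index=True)

    outputs: dict[str, Path] = {}
    with _stage("rollup"):
        attrs = attribute_definitions(components)
        attr_df = rollup_attributes(comp_df, attrs)
        maps = [coverage_map(comp_df, chain) for chain in chains]
        rates = {
            "missed_cleavage_rate_pct": missed_cleavage_rate(comp_df),
            "nonspecific_rate_pct": nonspecific_rate(comp_df),
        }
        labs = sorted(comp_df["lab"].unique())
        venn = None
        if 2 <= len(labs) <= 4:
            lab_peptides = {}
            id_to_mass = {c.component_id: c.form().mass for c in components}
            for lab in labs:
                sub = comp_df[(comp_df.lab == lab) & comp_df.found]
                lab_peptides[lab] = [
                    (r["sequence"], r["modification"], id_to_mass[r["component_id"]])
                    for _, r in sub.drop_duplicates("component_id").iterrows()]
            venn = {"+".join(sorted(k)): v
                    for k, v in venn_membership(lab_peptides, ppm=config.params.ppm).items()}

    with _stage("stats"):
        prec = precision_report(attr_df) if len(labs) >= 2 else pd.DataFrame()
        timepoints = comp_df["timepoint"].unique()
        trend = trend_summary(attr_df) if len(timepoints) >= 2 else pd.DataFrame()

    with _stage("report"):
        def _write(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            with open(path, "w", newline="") as fh:
                fh.write(f"# config_hash={chash}\n")
                df.to_csv(fh, index=False)
            outputs[name] = path

        _write(comp_df, "quant_components.csv")
        _write(attr_df, "attributes.csv")
        if not prec.empty:
            _write(prec, "precision.csv")
        if not trend.empty:
            _write(trend, "trend.csv")
        cov_path = outdir / "coverage.csv"
        write_coverage_csv(maps, cov_path)
        outputs["coverage.csv"] = cov_path
        workbook_path = outdir / "components_used.csv"
        write_component_csv(components, workbook_path)
        outputs["components_used.csv"] = workbook_path
        summary = {
            "config_hash": chash,
            "version": __version__,
            "python": sys.version.split()[0],
            "n_runs": len(runs),
            "n_components": len(components),
            "coverage_percent": {m.chain_id: m.coverage_percent for m in maps},
            "rates": rates,
            "venn_regions": venn,
            "component_found_tally": found_tally,
        }
        spath = outdir / "summary.json"
        spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        outputs["summary.json"] = spath
        lpath = outdir / "log.txt"
        lpath.write_text("\n".join(log_lines) + "\n")
        outputs["log.txt"] = lpath
    return outputs
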