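"""End-to-end orchestration: reconstruct -> predict -> complement ->
concord -> scan, driven by a single YAML config.

Stages run in dependency order; any stage failure halts the run with a
manifest recording partial progress.  Identical config + inputs + seed
produce byte-identical outputs (the only stochastic stages are the
simulators, which are seeded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import strainflux
from strainflux.complementation import complementation_report, write_report
from strainflux.fba import call_growth, solve_fba
from strainflux.models import (
    AnalysisConfig,
    load_conditions,
    load_model,
)
from strainflux.pm import load_calls, load_pm_kinetics, quantitate_plate, save_calls, concordance
from strainflux.strain_delta import load_delta
from strainflux.models import GrowthCall
from strainflux import islands as isl

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class RunManifest:
    config_snapshot: dict
    seed: int
    version: str = strainflux.__version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config_snapshot,
                "inputs": self.input_digests,
                "stages": self.stages,
            },
            indent=1,
            sort_keys=True,
        )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _analysis_config(cfg: dict) -> AnalysisConfig:
    return AnalysisConfig(**cfg.get("analysis", {}))


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the configured stages; see the project README for the
    config schema.  Returns the run manifest (also written to the output
    directory as ``manifest.json``)."""
    config_path = Path(config_path)
    try:
        cfg = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{config_path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{config_path}: config must be a mapping")
    out_dir = Path(cfg.get("out_dir", "results"))
    seed = int(cfg.get("seed", 0))
    inputs = cfg.get("inputs", {})
    for key, path in inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"inputs.{key}: file not found: {path}")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_snapshot=cfg, seed=seed)
    manifest.input_digests = {k: file_digest(v) for k, v in inputs.items()}
    config = _analysis_config(cfg)

    def record(stage: str, status: str, **extra) -> None:
        manifest.stages[stage] = {"status": status, **extra}

    try:
        target = load_model(inputs["target_model"]) if "target_model" in inputs else None
        reference = load_model(inputs["reference_model"]) if "reference_model" in inputs else None
        conditions = load_conditions(inputs["conditions"]) if "conditions" in inputs else []
        record("load", "ok")

        if target is not None and reference is not None and conditions:
            rows = []
            for cond in conditions:
                calls = {}
                for model in (target, reference):
                    try:
                        calls[model.id] = call_growth(solve_fba(model, cond), config).value
                    except Exception:
                        calls[model.id] = GrowthCall.NO_GROWTH.value
                rows.append({"condition": cond.name, **calls})
            import pandas as pd

            growth_path = out_dir / "growth_calls.tsv"
            pd.DataFrame(rows).to_csv(growth_path, sep="\t", index=False)
            record("fba", "ok", output=str(growth_path))

        if "delta" in inputs and target is not None and reference is not None and conditions:
            delta = load_delta(inputs["delta"], reference=reference)
            pm_calls = load_calls(inputs["pm_calls"]) if "pm_calls" in inputs else None
            table, n_distinct = complementation_report(
                target, reference, delta, conditions, pm_calls, config
            )
            report_path = out_dir / "complementation.tsv"
            write_report(table, n_distinct, report_path)
            record("complement", "ok", output=str(report_path),
                   distinct_responsible_reactions=n_distinct)

        if "pm_kinetics" in inputs:
            wells = load_pm_kinetics(inputs["pm_kinetics"])
            strain = cfg.get("pm", {}).get("strain", "strain")
            cutoffs = cfg.get("pm", {}).get("cutoffs")
            calls = quantitate_plate(
                wells, strain=strain, cutoffs=tuple(cutoffs) if cutoffs else None
            )
            calls_path = out_dir / "pm_calls.tsv"
            save_calls(calls, calls_path)
            record("pm", "ok", output=str(calls_path))

        if "genome_fasta" in inputs and "gene_table" in inputs:
            genome = isl.load_genome_fasta(inputs["genome_fasta"])
            table = isl.load_gene_table(inputs["gene_table"])
            genes = isl.compose_genes(genome, table)
            flags = isl.foreign_flags(genes, config=config)
            calls = isl.scan_islands(flags, genes, config)
            gff_path = out_dir / "islands.gff3"
            bed_path = out_dir / "islands.bed"
            per_gene_path = out_dir / "genes.tsv"
            isl.write_islands_gff3(calls, gff_path)
            isl.write_islands_bed(calls, bed_path)
            isl.per_gene_table(genes, config).to_csv(per_gene_path, sep="\t", index=False)
            record("islands", "ok", output=str(gff_path), n_islands=len(calls))
    except Exception as exc:
        stage = "run"
        record(stage, f"failed: {exc}")
        (out_dir / "manifest.json").write_text(manifest.to_json())
        raise
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
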