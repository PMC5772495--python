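"""End-to-end orchestration: simulate → filter → burden → signature → targets.

A run is described by one declarative YAML config (see :class:`RunConfig`).
Unknown keys are errors (fail-fast), the schema is versioned, and a fixed
seed makes the whole run deterministic.  Each stage writes its own output
file; the final run report repeats exactly the numbers written to those
files, plus an output manifest, library versions, and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .burden import collapse_supervariants, background_rate, run_burden
from .deleterious_filter import FilterConfig, apply_filter
from .io_formats import (
    read_bed,
    read_gene_models,
    read_mutation_table,
    write_bed,
    write_gene_models,
    write_mutation_table,
    write_results,
)
from .mark_targets import derive_target_report
from .synthetic_data import (
    RegionExperimentConfig,
    SyntheticConfig,
    simulate_cohort,
    simulate_region_experiment,
)
from .uv_signature import summarize_signature

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger("somaburden")

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run config violates the schema (unknown key, bad value, missing path)."""


_STAGES = ("simulate", "filter", "burden", "signature", "targets")


def _check_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _build(cls, section: Mapping, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, allowed, where)
    if "drivers" in section and section["drivers"] is not None:
        section = dict(section)
        section["drivers"] = tuple(tuple(d) for d in section["drivers"])
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


@dataclass
class RunConfig:
    """Validated pipeline run configuration."""

    seed: int = 0
    out_dir: Path = Path("somaburden_run")
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    cohort: SyntheticConfig = field(default_factory=SyntheticConfig)
    regions: RegionExperimentConfig = field(default_factory=RegionExperimentConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    burden_method: str = "binomial"
    normalize_strand: bool = False
    signature_basis: str = "record"
    targets_mode: str = "reference"
    min_overlap: int = 1
    inputs: dict[str, Path] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        allowed = {
            "schema_version", "seed", "out_dir", "stages", "cohort", "regions",
            "filter", "burden", "signature", "targets", "inputs", "log_level",
        }
        _check_keys(raw, allowed, "run config")
        version = raw.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")

        stages = {s: True for s in _STAGES}
        if "stages" in raw:
            _check_keys(raw["stages"], set(_STAGES), "stages")
            stages.update({k: bool(v) for k, v in raw["stages"].items()})

        seed = int(raw.get("seed", 0))
        cohort_raw = dict(raw.get("cohort", {}))
        cohort_raw.setdefault("seed", seed)
        regions_raw = dict(raw.get("regions", {}))
        regions_raw.setdefault("seed", seed)

        burden_raw = dict(raw.get("burden", {}))
        _check_keys(burden_raw, {"method"}, "burden")
        signature_raw = dict(raw.get("signature", {}))
        _check_keys(signature_raw, {"normalize_strand", "basis"}, "signature")
        targets_raw = dict(raw.get("targets", {}))
        _check_keys(targets_raw, {"mode", "min_overlap"}, "targets")
        inputs_raw = dict(raw.get("inputs", {}))
        _check_keys(
            inputs_raw, {"muts", "samples", "genes", "regions_a", "regions_b", "gene_bodies"},
            "inputs",
        )

        config = cls(
            seed=seed,
            out_dir=Path(raw.get("out_dir", "somaburden_run")),
            stages=stages,
            cohort=_build(SyntheticConfig, cohort_raw, "cohort"),
            regions=_build(RegionExperimentConfig, regions_raw, "regions"),
            filter=_build(FilterConfig, dict(raw.get("filter", {})), "filter"),
            burden_method=burden_raw.get("method", "binomial"),
            normalize_strand=bool(signature_raw.get("normalize_strand", False)),
            signature_basis=signature_raw.get("basis", "record"),
            targets_mode=targets_raw.get("mode", "reference"),
            min_overlap=int(targets_raw.get("min_overlap", 1)),
            inputs={k: Path(v) for k, v in inputs_raw.items()},
            log_level=str(raw.get("log_level", "INFO")),
        )
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: run config must be a mapping")
        return cls.from_mapping(raw)

    def validate(self) -> None:
        if self.burden_method not in ("binomial", "poisson"):
            raise ConfigError(f"burden.method must be binomial or poisson, got {self.burden_method}")
        if self.signature_basis not in ("record", "event"):
            raise ConfigError(f"signature.basis must be record or event, got {self.signature_basis}")
        if self.targets_mode not in ("reference", "intersection"):
            raise ConfigError(f"targets.mode must be reference or intersection, got {self.targets_mode}")
        if not self.stages.get("simulate", False):
            needed = []
            if any(self.stages.get(s) for s in ("filter", "burden", "signature")):
                needed.append("muts")
            if self.stages.get("targets"):
                needed += ["regions_a", "regions_b", "gene_bodies"]
            for key in needed:
                if key not in self.inputs:
                    raise ConfigError(f"stage needs inputs.{key} when simulate is off")
        for key, path in self.inputs.items():
            if not path.exists():
                raise ConfigError(f"inputs.{key}: no such file {path}")


def _configure_logging(level: str) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order and return the run report.

    Any stage failure propagates with the stage named; outputs land in
    ``config.out_dir`` and the report (also written to ``report.json``)
    repeats exactly the per-stage file contents.
    """
    _configure_logging(config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "somaburden_version": __version__,
        "seed": config.seed,
        "stages_run": [s for s in _STAGES if config.stages.get(s)],
        "manifest": {},
    }
    manifest = report["manifest"]

    records = None
    cohort_samples = None
    regions_a = regions_b = gene_bodies = None

    if config.stages.get("simulate"):
        logger.info("simulate: G=%d S=%d seed=%d", config.cohort.G, config.cohort.S, config.seed)
        records, truth = simulate_cohort(config.cohort)
        cohort_samples = list(truth.flag_matrix.samples)
        write_mutation_table(records, out / "muts.tsv")
        truth_doc = {
            "config": dataclasses.asdict(config.cohort),
            "drivers": [list(d) for d in truth.drivers],
            "flagged_pairs": [
                [truth.flag_matrix.genes[g], truth.flag_matrix.samples[s]]
                for g, s in zip(*map(list, truth.flag_matrix.d.nonzero()))
            ],
            "labels": [dataclasses.asdict(l) for l in truth.labels],
        }
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth_doc, fh)
        exp = simulate_region_experiment(config.regions)
        regions_a, regions_b, gene_bodies = exp.regions_a, exp.regions_b, exp.gene_models
        write_bed(regions_a, out / "regions_a.bed")
        write_bed(regions_b, out / "regions_b.bed")
        write_gene_models(gene_bodies, out / "genes.bed")
        manifest.update(
            {k: str(out / v) for k, v in {
                "muts": "muts.tsv", "truth": "truth.json", "regions_a": "regions_a.bed",
                "regions_b": "regions_b.bed", "genes": "genes.bed"}.items()}
        )
        report["simulate"] = {
            "n_records": len(records),
            "n_flagged_pairs": int(truth.flag_matrix.d.sum()),
            "n_regions_a": len(regions_a),
            "n_regions_b": len(regions_b),
            "n_genes": len(gene_bodies),
        }
    else:
        if "muts" in config.inputs:
            records = read_mutation_table(config.inputs["muts"])
        if "samples" in config.inputs:
            cohort_samples = [
                line.strip()
                for line in config.inputs["samples"].read_text().splitlines()
                if line.strip()
            ]
        if "regions_a" in config.inputs:
            regions_a = read_bed(config.inputs["regions_a"])
        if "regions_b" in config.inputs:
            regions_b = read_bed(config.inputs["regions_b"])
        if "gene_bodies" in config.inputs:
            gene_bodies = read_gene_models(config.inputs["gene_bodies"])

    kept = records
    if config.stages.get("filter"):
        logger.info("filter: %d input records", len(records))
        result = apply_filter(records, config.filter)
        kept = result.kept
        write_mutation_table(kept, out / "kept.tsv")
        with open(out / "reasons.json", "w", encoding="utf-8") as fh:
            json.dump(dict(result.reason_counts), fh, indent=2)
        manifest["kept"] = str(out / "kept.tsv")
        manifest["reasons"] = str(out / "reasons.json")
        report["filter"] = {
            "n_input": result.n_input,
            "n_kept": len(kept),
            "reason_counts": dict(result.reason_counts),
        }

    if config.stages.get("burden"):
        if cohort_samples is None:
            cohort_samples = list(dict.fromkeys(r.sample_id for r in kept))
        gene_universe = (
            config.cohort.gene_ids() if config.stages.get("simulate") else None
        )
        matrix = collapse_supervariants(
            kept, cohort_samples, gene_universe=gene_universe, strict=False
        )
        results = run_burden(matrix, method=config.burden_method)
        write_results(results, out / "burden.tsv", format="tsv")
        manifest["burden"] = str(out / "burden.tsv")
        top = results[0]
        report["burden"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "background_rate": background_rate(matrix),
            "top_gene": top.gene,
            "top_k": top.k,
            "top_p": top.p,
            "top_q": top.q,
        }
        logger.info("burden: top gene %s k=%d p=%.3g", top.gene, top.k, top.p)

    if config.stages.get("signature"):
        summary = summarize_signature(
            kept, normalize_strand=config.normalize_strand, basis=config.signature_basis
        )
        doc = dataclasses.asdict(summary)
        with open(out / "signature.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
        manifest["signature"] = str(out / "signature.json")
        report["signature"] = doc

    if config.stages.get("targets"):
        if regions_a is None or regions_b is None or gene_bodies is None:
            raise ConfigError("targets stage needs region and gene-body inputs")
        target_report = derive_target_report(
            regions_a,
            regions_b,
            gene_bodies,
            mode=config.targets_mode,
            min_overlap=config.min_overlap,
        )
        doc = target_report.to_dict()
        with open(out / "targets.json", "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
        manifest["targets"] = str(out / "targets.json")
        report["targets"] = doc

    manifest["report"] = str(out / "report.json")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report
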