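"""Pipeline orchestration: config, staged execution, manifest, report.

``run_pipeline`` executes load → (optional) standardize → per-subset
correlations → differential network per partition → stability map, writing
every artifact under one output directory together with a JSON manifest
(config hash, input hash, per-file SHA-256). Re-running with identical
inputs reproduces byte-identical outputs; only the manifest timestamp
differs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlation import DEFAULT_N_MIN, pairwise_correlations
from .data_model import (
    STABILITY_PARTITIONS,
    FactorRegistry,
    MetaboliteRegistry,
    TableSchema,
    get_partition,
    read_metabolite_table,
    standardize,
)
from .diffnet import build_differential_network, export_network
from .errors import ConfigError
from .stability import build_stability_map, heatmap_matrix, stability_subsets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml`` for the schema)."""

    table_path: Path
    delimiter: str | None = None
    sample_id: str = "sample_id"
    factor_columns: tuple[str, ...] = ("genotype", "mulch", "year", "stage", "replicate")
    exclude: tuple[str, ...] = ("B",)
    extra_factor_levels: dict = field(default_factory=dict)
    registry_overrides: dict = field(default_factory=dict)
    standardize: bool = False
    partitions: tuple[str, ...] = ("polyamine", "mejas", "mulch")
    alpha: float = 0.05
    multiplicity: str = "none"
    swap_colors: bool = False
    n_min: int = DEFAULT_N_MIN
    stability_partitions: tuple[str, ...] = STABILITY_PARTITIONS
    stability_threshold: float = 0.19
    export_format: str = "edge-csv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        io = raw.get("io", {})
        cols = raw.get("columns", {})
        mets = raw.get("metabolites", {})
        analysis = raw.get("analysis", {})
        known = {"io", "columns", "metabolites", "analysis", "registry", "factors"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        table = io.get("table")
        if not table:
            raise ConfigError("config must set io.table (path to the input table)")
        table_path = Path(table)
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        cfg = cls(
            table_path=table_path,
            delimiter=io.get("delimiter"),
            sample_id=cols.get("sample_id", "sample_id"),
            factor_columns=tuple(
                cols.get("factors", ["genotype", "mulch", "year", "stage", "replicate"])
            ),
            exclude=tuple(mets.get("exclude", ["B"])),
            extra_factor_levels=raw.get("factors", {}).get("extra_levels", {}),
            registry_overrides=raw.get("registry", {}),
            standardize=bool(analysis.get("standardize", False)),
            partitions=tuple(analysis.get("partitions", ["polyamine", "mejas", "mulch"])),
            alpha=float(analysis.get("alpha", 0.05)),
            multiplicity=str(analysis.get("multiplicity", "none")),
            swap_colors=bool(analysis.get("swap_colors", False)),
            n_min=int(analysis.get("n_min", DEFAULT_N_MIN)),
            stability_partitions=tuple(
                analysis.get("stability_partitions", list(STABILITY_PARTITIONS))
            ),
            stability_threshold=float(analysis.get("stability_threshold", 0.19)),
            export_format=str(analysis.get("format", "edge-csv")),
        )
        if cfg.multiplicity not in ("none", "bh"):
            raise ConfigError(f"analysis.multiplicity must be none|bh, got {cfg.multiplicity!r}")
        for name in (*cfg.partitions, *cfg.stability_partitions):
            get_partition(name)
        return cfg

    def schema(self) -> TableSchema:
        return TableSchema(
            sample_id=self.sample_id,
            factor_columns=self.factor_columns,
            metabolite_columns=None,
            delimiter=self.delimiter,
            exclude=self.exclude,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    table_hash: str
    version: str
    outputs: dict  # relative path -> sha256
    timestamp: str
    stages: dict  # stage name -> summary counts

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "table_hash": self.table_hash,
                "version": self.version,
                "outputs": dict(sorted(self.outputs.items())),
                "timestamp": self.timestamp,
                "stages": self.stages,
            },
            indent=2, sort_keys=False,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path
) -> RunManifest:
    """Execute all stages and write artifacts + manifest under ``out_dir``.

    Input files are never mutated. Any stage failure propagates with the
    stage context in the log.
    """
    if not isinstance(config, PipelineConfig):
        config_path = Path(config)
        config_hash = _sha256(config_path)
        config = PipelineConfig.from_yaml(config_path)
    else:
        config_hash = hashlib.sha256(
            repr(sorted(config.__dict__.items(), key=lambda kv: kv[0])).encode()
        ).hexdigest()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: dict[str, dict] = {}

    logger.info("stage load: reading %s", config.table_path)
    factor_registry = FactorRegistry.study_default().extended(config.extra_factor_levels)
    registry = None
    if config.registry_overrides:
        registry = MetaboliteRegistry.from_tuples(
            [(c, v.get("name", c), v.get("group", "other"))
             for c, v in config.registry_overrides.items()],
            excluded=config.exclude,
        )
    table = read_metabolite_table(
        config.table_path, config.schema(), registry=registry,
        factor_registry=factor_registry,
    )
    table_hash = _sha256(config.table_path)
    stages["load"] = {
        "samples": table.n_samples,
        "metabolites": len(table.metabolites),
        "missing_cells": table.n_missing(),
    }

    if config.standardize:
        logger.info("stage standardize")
        table = standardize(table)

    logger.info("stage correlate: %d partitions", len(config.partitions))
    corr_rows = []
    sets_by_partition = {}
    for name in config.partitions:
        scheme = get_partition(name)
        ids_a, ids_b = scheme.apply(table)
        set_a = pairwise_correlations(
            table, ids_a, label=scheme.subset_a_label, n_min=config.n_min
        )
        set_b = pairwise_correlations(
            table, ids_b, label=scheme.subset_b_label, n_min=config.n_min
        )
        sets_by_partition[name] = (set_a, set_b)
        for cs in (set_a, set_b):
            long = cs.to_long_frame()
            long.insert(0, "partition", name)
            corr_rows.append(long)
    corr_table = pd.concat(corr_rows, ignore_index=True)
    corr_path = out_dir / "correlations.csv"
    corr_table.to_csv(corr_path, index=False)
    outputs["correlations.csv"] = _sha256(corr_path)
    stages["correlate"] = {"rows": len(corr_table)}

    logger.info("stage diffnet")
    edge_files = []
    diffnet_summary = {}
    for name, (set_a, set_b) in sets_by_partition.items():
        net = build_differential_network(
            set_a, set_b, alpha=config.alpha,
            multiplicity=config.multiplicity, partition=name,
            provenance={"table_hash": table_hash, "config_hash": config_hash},
        )
        ext = "csv" if config.export_format == "edge-csv" else "graphml"
        edge_path = out_dir / f"diffnet_{name}.{ext}"
        export_network(net, edge_path, format=config.export_format,
                       swap_colors=config.swap_colors)
        outputs[edge_path.name] = _sha256(edge_path)
        edge_files.append(edge_path.name)
        frame = net.edge_frame()
        diffnet_summary[name] = {
            "tested": net.n_tested,
            "significant": len(net.edges),
            "min_delta_r": float(frame["delta_r"].min()) if len(frame) else None,
            "max_delta_r": float(frame["delta_r"].max()) if len(frame) else None,
        }
    stages["diffnet"] = diffnet_summary

    logger.info("stage stability")
    sets6 = stability_subsets(table, config.stability_partitions, n_min=config.n_min)
    smap = build_stability_map(sets6, threshold=config.stability_threshold)
    pair_path = out_dir / "stability_pairs.csv"
    smap.pairs.reset_index().to_csv(pair_path, index=False)
    outputs[pair_path.name] = _sha256(pair_path)
    counts_path = out_dir / "stability_counts.csv"
    smap.stable_association_counts().rename("stable_associations").to_csv(counts_path)
    outputs[counts_path.name] = _sha256(counts_path)
    roster = sorted({m for pair in smap.pairs.index for m in pair})
    values, bins = heatmap_matrix(smap, roster)
    heat_path = out_dir / "stability_heatmap.csv"
    values.to_csv(heat_path)
    outputs[heat_path.name] = _sha256(heat_path)
    bins_path = out_dir / "stability_bins.csv"
    bins.to_csv(bins_path)
    outputs[bins_path.name] = _sha256(bins_path)
    stages["stability"] = {
        "pairs_scored": len(smap.pairs),
        "pairs_dropped": len(smap.dropped),
        "subsets": list(smap.subset_labels),
    }

    manifest = RunManifest(
        config_hash=config_hash,
        table_hash=table_hash,
        version=__version__,
        outputs=outputs,
        timestamp=datetime.now(timezone.utc).isoformat(),
        stages=stages,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %d output files", len(outputs))
    return manifest


def verify_manifest(manifest: RunManifest, out_dir: str | Path) -> None:
    """Check that every listed output exists and its hash matches."""
    out_dir = Path(out_dir)
    for rel, digest in manifest.outputs.items():
        p = out_dir / rel
        if not p.exists():
            raise ConfigError(f"manifest output missing: {rel}")
        if _sha256(p) != digest:
            raise ConfigError(f"manifest hash mismatch for {rel}")


def report(manifest: RunManifest, out_dir: str | Path) -> str:
    """Human-readable run summary from the manifest and its artifacts."""
    verify_manifest(manifest, out_dir)
    out_dir = Path(out_dir)
    lines = [
        f"diffcornet {manifest.version} run at {manifest.timestamp}",
        f"input table {manifest.table_hash[:12]}…, config {manifest.config_hash[:12]}…",
        "",
    ]
    load = manifest.stages.get("load", {})
    lines.append(
        f"Loaded {load.get('samples')} samples × {load.get('metabolites')} "
        f"metabolites ({load.get('missing_cells')} missing cells)."
    )
    lines.append("")
    lines.append("Differential networks (significant changes in correlation):")
    for name, s in manifest.stages.get("diffnet", {}).items():
        extremes = ""
        if s.get("significant"):
            extremes = (
                f"; delta_r range [{s['min_delta_r']:+.3f}, {s['max_delta_r']:+.3f}]"
            )
        lines.append(
            f"  {name}: {s['significant']} significant of {s['tested']} tested pairs{extremes}"
        )
    stab = manifest.stages.get("stability")
    if stab:
        pairs = pd.read_csv(out_dir / "stability_pairs.csv")
        lines.append("")
        lines.append(
            f"Stability over subsets {stab['subsets']}: "
            f"{stab['pairs_scored']} pairs scored, {stab['pairs_dropped']} dropped."
        )
        if len(pairs):
            top = pairs.nsmallest(3, "sd_z")
            bot = pairs.nlargest(3, "sd_z")
            fmt = lambda row: (
                f"{row.metabolite_i}–{row.metabolite_j} "
                f"(sd_z={row.sd_z:.3f}, mean r={row.mean_r:+.3f})"
            )
            lines.append("  most stable:  " + "; ".join(fmt(r) for r in top.itertuples()))
            lines.append("  least stable: " + "; ".join(fmt(r) for r in bot.itertuples()))
    return "\n".join(lines) + "\n"
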