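"""End-to-end orchestration: simulate or ingest, then analyse and report.

A pipeline run takes a YAML/dict configuration (either a simulation block
or input paths, never both), executes the configured stages in dependency
order — aggregate → diversity → overlap → classify → junctions — and
produces a machine-readable report: a JSON summary plus per-stage TSV
tables. Reports are bit-reproducible for a fixed (config, seed): floats
are serialized at 12 significant digits and every source of randomness is
driven by the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .benchmark import cd5_summary, dependence_summary
from .classification import subrepertoire_diversity, top_expanded
from .diversity import auto_grid, rarefaction_curve
from .io import aggregate_bulk, read_rearrangements, write_abundance, SampleMeta
from .junctions import compare_edit_counts, compare_positional_bias
from .model import AbundanceTable
from .overlap import pairwise_overlap
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; carries the full error list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration with defaults filled in."""

    simulation: Optional[dict] = None
    inputs: Optional[dict] = None
    min_samples: int = 3
    min_umi: int = 1
    top_k: int = 10
    q: float = 1.0
    grid: str = "auto:8"
    reps: int = 100
    n_perm: int = 1000
    seed: int = 0
    group_a: str = "control"
    group_b: str = "mutant"


def validate_config(source) -> PipelineConfig:
    """Parse and validate a config mapping or YAML path; collect all errors."""
    if isinstance(source, (str, Path)):
        try:
            with open(source) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable config file: {exc}"])
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise ConfigError(["config must be a mapping or a YAML path"])

    errors: list[str] = []
    known = {f.name for f in dc_fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    if cfg.simulation is not None and cfg.inputs is not None:
        errors.append("simulation and inputs are mutually exclusive")
    if cfg.simulation is None and cfg.inputs is None:
        errors.append("one of simulation or inputs is required")
    if cfg.min_samples < 1:
        errors.append("min_samples must be >= 1")
    if cfg.min_umi < 1:
        errors.append("min_umi must be >= 1")
    if cfg.top_k < 1:
        errors.append("top_k must be >= 1")
    if cfg.reps < 1:
        errors.append("reps must be >= 1")
    if cfg.q < 0:
        errors.append("q must be >= 0")
    if cfg.simulation is not None:
        try:
            SimulationConfig(**cfg.simulation)
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid simulation block: {exc}")
    if cfg.inputs is not None:
        if "rearrangements" not in cfg.inputs:
            errors.append("inputs block requires a 'rearrangements' path")
        if "samples" not in cfg.inputs:
            errors.append("inputs block requires a 'samples' list")
    if errors:
        raise ConfigError(errors)
    return cfg


def _grid_for(n: int, spec: str) -> list[int]:
    if spec.startswith("auto:"):
        return auto_grid(n, k=int(spec.split(":", 1)[1]))
    pts = sorted(int(p) for p in spec.split(","))
    return pts


def _sigdig(x: float, digits: int = 12) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _roundtrip(obj: Any) -> Any:
    """Recursively round floats to 12 significant digits for the report."""
    if isinstance(obj, dict):
        return {k: _roundtrip(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return _sigdig(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


@dataclass
class ReportBundle:
    """Pipeline outputs: the JSON summary and any tables written to disk."""

    summary: dict
    outdir: Optional[Path] = None
    tables: dict[str, Path] = field(default_factory=dict)


def _load_inputs(cfg: PipelineConfig) -> AbundanceTable:
    spec = cfg.inputs or {}
    reads = read_rearrangements(spec["rearrangements"])
    samples = [
        SampleMeta(
            sample_id=s["sample_id"],
            group=s.get("group", ""),
            subset=s.get("subset", ""),
            replicate=int(s.get("replicate", 0)),
        )
        for s in spec["samples"]
    ]
    known = {s.sample_id for s in samples}
    seen = {r.sample_id for r in reads}
    missing = known - seen
    if missing:
        raise ValueError(f"configured sample(s) absent from input: {sorted(missing)}")
    return aggregate_bulk(reads, samples=samples)


def run_pipeline(config, outdir=None) -> ReportBundle:
    """Run all configured stages and return the report bundle.

    A failing stage aborts with :class:`StageError` naming the stage.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    raw_cfg = {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)}
    config_hash = hashlib.sha256(
        json.dumps(raw_cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash,
    }

    # -- input stage ----------------------------------------------------
    sim = None
    try:
        if cfg.simulation is not None:
            sim = simulate_study(SimulationConfig(**cfg.simulation), seed=cfg.seed)
            table = sim.genotype_table
            cd5_table = sim.cd5_table
        else:
            table = _load_inputs(cfg)
            cd5_table = None
        summary["input"] = {
            "n_clonotypes": len(table.counts),
            "n_samples": len(table.sample_ids),
            "molecules_per_sample": {
                s: int(table.counts[s].sum()) for s in table.sample_ids
            },
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    # -- diversity ------------------------------------------------------
    try:
        div = {}
        for sid in table.sample_ids:
            vec = table.vector(sid)
            grid = _grid_for(int(vec.sum()), cfg.grid)
            res = rarefaction_curve(vec, grid, reps=cfg.reps, seed=cfg.seed, q=cfg.q)
            div[sid] = {
                "d_obs": res.d_obs,
                "coverage": res.coverage,
                "curve": [[m, mean, se] for m, mean, se in res.curve],
            }
        summary["diversity"] = div
    except Exception as exc:
        raise StageError("diversity", exc) from exc

    # -- overlap --------------------------------------------------------
    try:
        om = pairwise_overlap(table, group_key="group")
        summary["overlap"] = {
            "category_means": {
                k: float(np.mean(v)) for k, v in om.values_by_category().items()
            },
            "pairs": om.pairs.to_dict(orient="records"),
        }
    except Exception as exc:
        raise StageError("overlap", exc) from exc

    # -- classification -------------------------------------------------
    try:
        labels, dep_summary = dependence_summary(
            table, cfg.group_a, cfg.group_b, min_samples=cfg.min_samples
        )
        summary["classification"] = dict(dep_summary)
        group_a_ids = table.group_ids(cfg.group_a)
        for name, clones in (
            ("dependent", labels.dependent),
            ("shared", labels.shared),
        ):
            if clones:
                sub = subrepertoire_diversity(table, clones, q=cfg.q)
                summary["classification"][f"subdiversity_{name}"] = {
                    s: sub[s] for s in group_a_ids
                }
        top = top_expanded(table, k=cfg.top_k)
        summary["classification"]["top_expanded"] = [
            {"v_gene": k[0], "j_gene": k[1], "cdr3_aa": k[2],
             "rank_freq": float(row["rank_freq"])}
            for k, row in top.iterrows()
        ]
        if cd5_table is not None:
            summary["classification"]["cd5"] = cd5_summary(cd5_table, labels)
        if sim is not None:
            truth_dep = sim.clones_with_label("dependent")
            truth_new = sim.clones_with_label("newcomer")
            summary["classification"]["truth_recovery"] = {
                "planted_dependent": len(truth_dep),
                "planted_newcomer": len(truth_new),
                "recovered_dependent_true": len(labels.dependent & truth_dep),
                "recovered_newcomer_true": len(labels.newcomer & truth_new),
                "false_dependent": len(labels.dependent - truth_dep),
            }
    except Exception as exc:
        raise StageError("classification", exc) from exc

    # -- junctions (simulation only: annotations come from the truth) ----
    try:
        if sim is not None and labels.newcomer and labels.shared:
            ref = sorted(labels.shared)
            new = sorted(labels.newcomer)
            pos_v = compare_positional_bias(
                ref, new, segment="V", n_perm=cfg.n_perm, seed=cfg.seed
            )
            pos_j = compare_positional_bias(
                ref, new, segment="J", n_perm=cfg.n_perm, seed=cfg.seed + 1
            )
            edits = compare_edit_counts(
                [sim.junction_of(c) for c in ref],
                [sim.junction_of(c) for c in new],
                n_perm=cfg.n_perm,
                seed=cfg.seed + 2,
            )
            summary["junctions"] = {
                "positional_v": {"delta": pos_v.delta, "p": pos_v.p_value},
                "positional_j": {"delta": pos_j.delta, "p": pos_j.p_value},
                "edit_counts": {"delta": edits.delta, "p": edits.p_value},
            }
    except Exception as exc:
        raise StageError("junctions", exc) from exc

    summary = _roundtrip(summary)
    bundle = ReportBundle(summary=summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.outdir = outdir
        ab_path = outdir / "abundance.tsv"
        write_abundance(table, ab_path)
        bundle.tables["abundance"] = ab_path
        om_path = outdir / "overlap_pairs.tsv"
        om.pairs.to_csv(om_path, sep="\t", index=False)
        bundle.tables["overlap_pairs"] = om_path
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        bundle.tables["summary"] = outdir / "summary.json"
        logger.info("pipeline outputs written to %s", outdir)
    return bundle
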