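"""End-to-end pipeline: chain every analysis stage for one genome pair and
write a reproducible report bundle.

Outputs are deterministic: TSV floats are fixed at 4 significant digits,
JSON keys are sorted, and all gene lists are emitted in sorted order, so
re-running with identical inputs and configuration produces byte-identical
files.  Logs (stage progress) go to stderr; results never do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import breakpoints as bp_mod
from . import content as content_mod
from . import molevo, stats, synteny
from .genome_io import AnnotatedGenome, read_genbank

logger = logging.getLogger("plastocomp")

TSV_FLOAT_FORMAT = "%.4g"


@dataclass
class RunConfig:
    """Pipeline parameters; unknown keys in a YAML config are rejected."""

    window: int = 100
    upstream_bp: int = 50
    include_trna: bool = False
    junction_window: int = 100
    ir_min_len: int = 1000
    mu: float = molevo.DEFAULT_MU
    generation_times: dict[str, float] = field(
        default_factory=lambda: dict(molevo.DEFAULT_GENERATION_TIMES))
    averaging: str = "unweighted"
    per_lineage: bool = False
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    out_dir: Path
    reference: AnnotatedGenome
    reduced: AnnotatedGenome
    stats_table: object
    comparison: content_mod.ContentComparison
    synteny_result: synteny.SyntenyResult
    regions: list
    kska: object
    divergence: molevo.DivergenceEstimate | None
    summary_text: str


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    reference_path,
    reduced_path,
    out_dir,
    config: RunConfig | None = None,
) -> ReportBundle:
    """Run every stage on a (reference, reduced) genome pair and write the
    report bundle into ``out_dir``."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s", name)
        return time.monotonic()

    t0 = stage("parse")
    reference = read_genbank(reference_path)
    reduced = read_genbank(reduced_path)

    stage("stats")
    stats_df = stats.stats_table([reference, reduced])
    stats_df.to_csv(out / "stats.tsv", sep="\t", index=False,
                    float_format=TSV_FLOAT_FORMAT)

    stage("content")
    comp = content_mod.compare_content(reference, reduced)
    _write_json(out / "content.json", {
        "reference": comp.id_a,
        "reduced": comp.id_b,
        "n_reference": comp.n_a,
        "n_reduced": comp.n_b,
        "n_shared": comp.n_shared,
        "n_lost_from_reduced": len(comp.only_in_a),
        "lost_from_reduced": sorted(comp.only_in_a),
        "only_in_reduced": sorted(comp.only_in_b),
        "lost_by_category": comp.lost_from_b_by_category,
        "duplicated_in_reference": comp.duplicated_in_a,
        "duplicated_in_reduced": comp.duplicated_in_b,
    })

    stage("synteny")
    syn = synteny.compare_order(reference, reduced, config.include_trna)
    _write_json(out / "synteny.json", {
        "n_shared": syn.n_shared,
        "conserved_adjacencies": syn.conserved_adjacencies,
        "oriented_adjacencies": syn.oriented_adjacencies,
        "adjacency_fraction": syn.adjacency_fraction,
        "n_blocks": syn.n_blocks,
        "breakpoint_distance": syn.breakpoint_distance,
        "defined": syn.defined,
    })

    stage("breakpoints")
    regions = bp_mod.find_breakpoints(reference, reduced,
                                      config.junction_window)
    bp_df, bp_summary = bp_mod.junction_report(regions)
    bp_df.to_csv(out / "breakpoints.tsv", sep="\t", index=False,
                 float_format=TSV_FLOAT_FORMAT)
    _write_json(out / "breakpoints.json", bp_summary)

    stage("kska")
    kska_df, results = molevo.kska_table(reference, reduced)
    kska_df.to_csv(out / "kska.tsv", sep="\t", index=False,
                   float_format=TSV_FLOAT_FORMAT)

    stage("clock")
    divergence = None
    identical = all(r.ks == 0 for r in results) if results else False
    try:
        mks = 0.0 if identical else molevo.mean_ks(results, config.averaging)
        divergence = molevo.divergence_time(
            mks, config.mu, config.generation_times, config.per_lineage)
        _write_json(out / "divergence.json", {
            "mean_ks": divergence.mean_ks,
            "mu_per_generation": divergence.mu,
            "n_generations": divergence.n_generations,
            "per_lineage": divergence.per_lineage,
            "times_years": divergence.times_years,
            "t_low_years": divergence.t_low_years,
            "t_high_years": divergence.t_high_years,
        })
    except ValueError as exc:
        logger.warning("clock stage skipped: %s", exc)

    summary = _summary_text(reference, reduced, comp, syn, regions,
                            bp_summary, results, divergence)
    (out / "summary.txt").write_text(summary)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return ReportBundle(out, reference, reduced, stats_df, comp, syn,
                        regions, kska_df, divergence, summary)


def _summary_text(reference, reduced, comp, syn, regions, bp_summary,
                  results, divergence) -> str:
    lines = [
        f"Reference genome : {reference.id} ({len(reference):,} bp, "
        f"{len(reference.features)} genes)",
        f"Reduced genome   : {reduced.id} ({len(reduced):,} bp, "
        f"{len(reduced.features)} genes)",
        "",
        f"Gene accounting  : {comp.n_a} distinct genes in reference; "
        f"{comp.n_shared} shared; {len(comp.only_in_a)} lost from reduced",
        f"Lost by category : " + ", ".join(
            f"{k}={v}" for k, v in comp.lost_from_b_by_category.items()),
        "",
        f"Synteny          : {syn.n_shared} shared genes, "
        f"adjacency fraction {syn.adjacency_fraction:.3f}, "
        f"breakpoint distance {syn.breakpoint_distance}",
        "",
        f"Deletion regions : {len(regions)} "
        f"(tRNA-adjacent: {bp_summary['n_trna_adjacent']}, "
        f"mean junction AT {bp_summary['mean_junction_at_percent']:.1f}%)"
        if regions else "Deletion regions : none",
    ]
    defined = [r for r in results if r.ks is not None]
    if defined:
        mks = sum(r.ks for r in defined) / len(defined)
        lines += ["", f"Mean Ks          : {mks:.3f} over {len(defined)} genes "
                      f"({len(results) - len(defined)} excluded)"]
    if divergence is not None:
        lines += [
            f"Generations      : {divergence.n_generations:.3g}",
            f"Divergence time  : {divergence.t_low_years / 1e6:.1f} - "
            f"{divergence.t_high_years / 1e6:.1f} Myr",
        ]
    return "\n".join(lines) + "\n"
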