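"""End-to-end orchestration: config, staged run, summary, and report.

The pipeline executes the inference chain in order — library → similarity
network → target profiles → enrichment → evidence integration → triage —
writing one TSV per stage plus a structured log, a machine-readable
``summary.json`` (floats rounded to 6 dp for cross-platform stability), and
optionally a human-readable narrative report. Every threshold the chain
uses lives in :class:`PipelineConfig` with the published defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import enrichment as enr
from . import evidence as evid
from . import library as libmod
from . import network as netmod
from . import profiles as prof
from . import triage as tri
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

_RANGES = {
    "tau": (0.0, 1.0),
    "min_mean": (0.0, 1.0),
    "fdr_alpha": (0.0, 1.0),
    "de_alpha": (0.0, 1.0),
    "evidence_min_de_frac": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """All input paths and thresholds for a pipeline run."""

    # input files
    library: str | None = None
    predictions: list[str] = field(default_factory=list)
    gene_sets: str | None = None
    interactions: str | None = None
    expression: str | None = None
    sample_map: str | None = None
    disease_links: str | None = None
    # thresholds (published defaults)
    tau: float = 0.5
    min_mean: float = 0.1
    min_support: int = 3
    fdr_alpha: float = 0.05
    min_set_overlap: int = 3
    evidence_min_overlap: int = 11
    evidence_min_known: int = 2
    evidence_min_de_frac: float = 0.10
    affinity_max_nm: float = 10000.0
    de_alpha: float = 0.05
    fc_threshold: float = 2.0
    # behavior
    include_candidate_edges: bool = False
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    rng_seed: int = 17

    def __post_init__(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            value = getattr(self, key)
            if not (lo <= value <= hi):
                raise ConfigError(f"config key {key!r}: {value} outside [{lo}, {hi}]")
        for key in ("min_support", "min_set_overlap", "evidence_min_overlap",
                    "evidence_min_known", "fingerprint_radius", "fingerprint_bits"):
            if getattr(self, key) < 1:
                raise ConfigError(f"config key {key!r} must be >= 1")
        if self.evidence_min_known < 0:
            raise ConfigError("evidence_min_known must be >= 0")
        if self.affinity_max_nm <= 0:
            raise ConfigError("affinity_max_nm must be positive")
        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON, a YAML subset) config; absent keys get defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path.name}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _require_paths(cfg: PipelineConfig) -> None:
    missing = []
    single = ["library", "gene_sets", "interactions", "expression", "sample_map", "disease_links"]
    for key in single:
        value = getattr(cfg, key)
        if not value:
            missing.append(key)
        elif not Path(value).exists():
            raise InputError(f"config key {key!r}: no such file {value!r}")
    if not cfg.predictions:
        missing.append("predictions")
    else:
        for p in cfg.predictions:
            if not Path(p).exists():
                raise InputError(f"config key 'predictions': no such file {p!r}")
    if missing:
        raise ConfigError(f"missing input path(s) in config: {missing}")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing per-stage outputs under ``outdir``.

    Returns the summary dict (also written to ``summary.json``). A stage
    failure raises with the stage named; outputs of completed stages remain
    on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require_paths(cfg)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fibronet")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config": cfg.to_dict()}
    stage = "library"
    try:
        lib = libmod.read_compounds(cfg.library)
        lib = libmod.canonicalize_and_deduplicate(lib)
        summary["library"] = libmod.validate_library(lib, require_seeds=True)
        libmod.write_library(lib, outdir / "library.tsv")

        stage = "network"
        net = netmod.build_activity_network(
            lib, tau=cfg.tau, include_candidate_edges=cfg.include_candidate_edges,
            radius=cfg.fingerprint_radius, n_bits=cfg.fingerprint_bits,
        )
        net_summary = netmod.network_summary(net, lib)
        del net_summary["degree"]
        summary["network"] = net_summary
        netmod.export_network(net, outdir / "network_edges.tsv", "edge_tsv")
        netmod.export_network(net, outdir / "network.graphml", "graphml", lib)

        stage = "target_profiles"
        preds = prof.read_prediction_tables(cfg.predictions)
        profiles = prof.aggregate_target_profiles(preds, net.node_ids)
        filtered = prof.filter_target_profiles(
            profiles, min_mean=cfg.min_mean, min_support=cfg.min_support
        )
        prof.profiles_to_frame(profiles).to_csv(outdir / "target_profiles.tsv", sep="\t", index=False)
        prof.profiles_to_frame(filtered).to_csv(outdir / "potential_targets.tsv", sep="\t", index=False)
        summary["targets"] = {
            "n_predictions": int(len(preds)),
            "n_profiled": len(profiles),
            "n_potential": len(filtered),
            "class_counts": prof.classify_target_types(filtered),
        }

        stage = "evidence"
        interactions = evid.read_interaction_table(cfg.interactions)
        kept_interactions = evid.filter_known_interactions(interactions, max_nm=cfg.affinity_max_nm)
        mat = evid.read_expression_matrix(cfg.expression, cfg.sample_map)
        de_calls = evid.call_differential_genes(mat, alpha=cfg.de_alpha, fc_threshold=cfg.fc_threshold)
        evid.de_to_frame(de_calls).to_csv(outdir / "differential_genes.tsv", sep="\t", index=False)
        known_targets = {r.target_id for r in kept_interactions}
        known_de = {c.gene for c in de_calls}
        summary["evidence"] = {
            "n_interactions": len(interactions),
            "n_interactions_kept": len(kept_interactions),
            "n_known_targets": len(known_targets),
            "n_de_calls": len(de_calls),
            "n_de_genes": len(known_de),
        }

        stage = "enrichment"
        sets = enr.read_gmt(cfg.gene_sets)
        results = enr.enrich_sets(
            [p.target_id for p in filtered], sets,
            fdr_alpha=cfg.fdr_alpha, min_overlap=cfg.min_set_overlap,
        )
        kept_sets = enr.apply_evidence_filter(
            results, known_targets, known_de,
            min_overlap=cfg.evidence_min_overlap, min_known=cfg.evidence_min_known,
            min_de_frac=cfg.evidence_min_de_frac,
        )
        enr.results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "n_sets": len(sets),
            "n_tested": len(results),
            "n_significant": sum(r.significant for r in results),
            "n_kept": len(kept_sets),
            "kept_set_ids": sorted(r.set_id for r in kept_sets),
        }

        stage = "prioritization"
        pathway_targets = sorted(set().union(*(r.overlap_ids for r in kept_sets))) if kept_sets else []
        profile_map = {p.target_id: p for p in filtered}
        evidence_map = evid.map_evidence_to_targets(kept_interactions, de_calls, pathway_targets)
        links = tri.read_disease_links(cfg.disease_links)
        candidates = tri.assign_direction(evidence_map, links, profile_map)
        verdicts = tri.triage_targets(candidates)
        ranked = tri.prioritize_targets(verdicts, profile_map)
        tri.candidates_to_frame(verdicts).to_csv(outdir / "triage.tsv", sep="\t", index=False)
        verdict_counts = {v: 0 for v in tri.VERDICTS}
        for cand in verdicts:
            verdict_counts[cand.verdict] += 1
        summary["triage"] = {
            "n_candidates": len(verdicts),
            "verdict_counts": verdict_counts,
            "ranked_targets": [c.target_id for c in ranked],
            "selected_target": ranked[0].target_id if ranked else None,
        }
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    summary = _round_floats(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def write_report(run_dir: str | Path) -> Path:
    """Render a narrative markdown report from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise InputError(f"no summary.json in {run_dir}; run the pipeline first")
    summary = json.loads(summary_path.read_text())
    cfg = summary["config"]
    lines = [
        "# Pipeline run report",
        "",
        "## Thresholds",
        f"- similarity threshold tau: {cfg['tau']} (strict)",
        f"- target filters: mean score > {cfg['min_mean']}, support >= {cfg['min_support']} compounds",
        f"- enrichment: BH-FDR < {cfg['fdr_alpha']}, overlap >= {cfg['min_set_overlap']}",
        (f"- evidence filter: overlap >= {cfg['evidence_min_overlap']}, known targets >= "
         f"{cfg['evidence_min_known']}, DE fraction > {cfg['evidence_min_de_frac']}"),
        f"- affinity credibility: Kd/IC50 < {cfg['affinity_max_nm']} nM",
        f"- differential genes: p < {cfg['de_alpha']}, fold change >= {cfg['fc_threshold']} or <= {1.0 / cfg['fc_threshold']:.4g}",
        f"- candidate-candidate edges: {'included' if cfg['include_candidate_edges'] else 'excluded'}",
        "",
        "## Library",
        f"- {summary['library']['n_compounds']} compounds "
        f"({summary['library']['n_seeds']} seeds); class counts: {summary['library']['class_counts']}",
        "",
        "## Activity network",
        f"- {summary['network']['n_nodes']} nodes, {summary['network']['n_edges']} edges, "
        f"{summary['network']['n_candidates']} candidate compounds",
        f"- candidate classes: {summary['network']['candidate_class_counts']}",
        "",
        "## Potential targets",
        f"- {summary['targets']['n_profiled']} targets profiled, "
        f"{summary['targets']['n_potential']} pass the score/support filters",
        f"- class counts: {summary['targets']['class_counts']}",
        "",
        "## Evidence",
        f"- {summary['evidence']['n_interactions_kept']} credible affinity interactions "
        f"({summary['evidence']['n_known_targets']} known targets)",
        f"- {summary['evidence']['n_de_calls']} differential-gene calls over "
        f"{summary['evidence']['n_de_genes']} genes",
        "",
        "## Enrichment",
        f"- {summary['enrichment']['n_tested']} sets tested, "
        f"{summary['enrichment']['n_significant']} significant, "
        f"{summary['enrichment']['n_kept']} kept after the evidence filter: "
        f"{summary['enrichment']['kept_set_ids']}",
        "",
        "## Triage",
        f"- verdicts: {summary['triage']['verdict_counts']}",
        f"- ranking: {summary['triage']['ranked_targets']}",
        f"- **selected target: {summary['triage']['selected_target']}**",
        "",
    ]
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
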