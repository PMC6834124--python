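"""End-to-end orchestration: fold -> CpG -> triplex -> events, with a single
declarative config, deterministic reports and a cross-referencing summary.

Stages are independently runnable; they share no intermediate state except
the promoter sequences. Every report directory gets a run log carrying the
package version, the config hash, the seed, stage parameters and input
checksums -- and no timestamps, so identical configs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cpg_islands import (
    call_islands,
    summarize,
    window_stats,
    write_island_bed,
    write_summary_table,
    write_window_table,
)
from .event_networks import (
    edge_composition,
    export_network,
    load_edge_list,
    load_event_table,
    stage_of,
    write_composition_table,
)
from .rna_structure import (
    EnergyModel,
    dot_plot,
    fold_suboptimal,
    stability_rank,
    write_dot_bracket,
    write_fold_table,
)
from .sequence_io import extract_promoter, read_annotations, read_fasta
from .synthetic_data import TARGET_GENES, make_demo_bundle
from .triplex_search import (
    background_scores,
    find_triplex_sites,
    grade_hits,
    summarize_matrix,
    write_hit_bed,
    write_hit_table,
    write_summary_table as write_triplex_table,
)


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run.

    Promoters come either from ``promoter_fasta`` directly or from
    ``genome_fasta`` + ``annotation`` (600-bp 5'-flanking extraction).
    """

    output_dir: str = "mirfunc_out"
    mirna_fasta: str | None = None
    promoter_fasta: str | None = None
    genome_fasta: str | None = None
    annotation: str | None = None
    upstream_bp: int = 600
    event_table: str | None = None
    edge_list: str | None = None
    energy_window: float | None = None  # None -> 5% of |MFE|, floor 1.0
    cpg_window: int = 200
    cpg_step: int = 1
    score_threshold: float = 140.0
    energy_threshold: float = -140.0
    background_n: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self, need: tuple[str, ...]) -> None:
        for attr in need:
            p = getattr(self, attr)
            if p is None:
                raise FileNotFoundError(f"config is missing required input {attr!r}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: no such file: {p}")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_log(cfg: PipelineConfig, stage: str, inputs: dict, params: dict) -> None:
    out = Path(cfg.output_dir)
    with open(out / f"{stage}.log", "w") as fh:
        fh.write(f"mirfunc {__version__} | stage {stage}\n")
        fh.write(f"config_hash {cfg.config_hash()}\nseed {cfg.seed}\n")
        for k, v in sorted(params.items()):
            fh.write(f"param {k} = {v}\n")
        for name, path in sorted(inputs.items()):
            fh.write(f"input {name} = {path} sha256 {_sha256(path)}\n")


def _load_promoters(cfg: PipelineConfig) -> list:
    if cfg.promoter_fasta:
        cfg.validate(("promoter_fasta",))
        return read_fasta(cfg.promoter_fasta, "DNA")
    cfg.validate(("genome_fasta", "annotation"))
    genome = {s.id: s for s in read_fasta(cfg.genome_fasta, "DNA")}
    anns = read_annotations(cfg.annotation)
    proms = [extract_promoter(genome, a, cfg.upstream_bp) for a in anns]
    # promoter ids are "<gene>_promoter"; report under the bare gene id
    return [type(p)(id=p.id.removesuffix("_promoter"), seq=p.seq) for p in proms]


def run_fold(cfg: PipelineConfig) -> dict:
    """Fold each microRNA; write the Table-1-style report and dot plots."""
    cfg.validate(("mirna_fasta",))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirnas = read_fasta(cfg.mirna_fasta, "RNA")
    model = EnergyModel.default()
    folds = [fold_suboptimal(m, model, cfg.energy_window) for m in mirnas]
    write_fold_table(folds, out / "table1.tsv")
    write_dot_bracket(folds, out / "structures.txt")
    for f in folds:
        dot_plot(f, out / f"dotplot_{f.sequence.id}.png")
    _write_log(cfg, "fold", {"mirna_fasta": cfg.mirna_fasta},
               {"energy_window": cfg.energy_window})
    return {
        "folds": folds,
        "stability": stability_rank(folds),
        "counts": {f.sequence.id: f.structure_count for f in folds},
    }


def run_cpg(cfg: PipelineConfig) -> dict:
    """Window statistics, island calls and the Table-2-style summary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    promoters = _load_promoters(cfg)
    summaries = []
    islands_by_gene = {}
    with open(out / "islands.bed", "w") as bed:
        for prom in promoters:
            stats = window_stats(prom, cfg.cpg_window, cfg.cpg_step)
            islands = call_islands(stats)
            islands_by_gene[prom.id] = islands
            write_window_table(stats, out / f"cpg_windows_{prom.id}.tsv")
            summaries.append(summarize(prom.id, stats, islands))
            for k, isl in enumerate(islands):
                score = min(1000, int(round(isl.mean_obs_exp * 100)))
                bed.write(
                    f"{prom.id}\t{isl.start}\t{isl.end}\tCpG_island_{k + 1}\t{score}\t+\n"
                )
    write_summary_table(summaries, out / "table2.tsv")
    inputs = {"promoter_fasta": cfg.promoter_fasta} if cfg.promoter_fasta else {
        "genome_fasta": cfg.genome_fasta, "annotation": cfg.annotation}
    _write_log(cfg, "cpg", inputs,
               {"window": cfg.cpg_window, "step": cfg.cpg_step})
    return {"summaries": summaries, "islands": islands_by_gene}


def run_triplex(cfg: PipelineConfig) -> dict:
    """Scan all (microRNA, promoter) pairs; grade retained hits; write the
    hit table, BED and the signed Table-3-style matrix."""
    cfg.validate(("mirna_fasta",))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirnas = read_fasta(cfg.mirna_fasta, "RNA")
    promoters = _load_promoters(cfg)
    all_hits = []
    for m in mirnas:
        for p in promoters:
            hits = find_triplex_sites(
                m, p,
                score_threshold=cfg.score_threshold,
                energy_threshold=cfg.energy_threshold,
            )
            if hits:
                bg = background_scores(m, p, n=cfg.background_n, seed=cfg.seed)
                hits = grade_hits(hits, bg)
            all_hits.extend(hits)
    summary = summarize_matrix(
        all_hits, [m.id for m in mirnas], [p.id for p in promoters]
    )
    write_hit_table(all_hits, out / "triplex_hits.tsv")
    write_hit_bed(all_hits, out / "triplex_hits.bed")
    write_triplex_table(summary, [m.id for m in mirnas], [p.id for p in promoters],
                        out / "table3.tsv")
    inputs = {"mirna_fasta": cfg.mirna_fasta}
    if cfg.promoter_fasta:
        inputs["promoter_fasta"] = cfg.promoter_fasta
    _write_log(cfg, "triplex", inputs, {
        "score_threshold": cfg.score_threshold,
        "energy_threshold": cfg.energy_threshold,
        "background_n": cfg.background_n,
    })
    return {"hits": all_hits, "summary": summary}


def run_events(cfg: PipelineConfig) -> dict:
    """Assemble the temporal event network and the interaction composition."""
    cfg.validate(("event_table", "edge_list"))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes, edges = load_event_table(cfg.event_table, target_genes=TARGET_GENES)
    export_network(nodes, edges, out / "events.sif", fmt="SIF")
    export_network(nodes, edges, out / "events.graphml", fmt="GraphML")
    interactions = load_edge_list(cfg.edge_list)
    comp = edge_composition(interactions)
    write_composition_table(comp, out / "composition.tsv")
    _write_log(cfg, "events",
               {"event_table": cfg.event_table, "edge_list": cfg.edge_list}, {})
    return {"nodes": nodes, "edges": edges, "composition": comp}


def run_all(cfg: PipelineConfig) -> dict:
    """All stages in order plus a per-microRNA cross-reference summary.

    A microRNA with a retained triplex hit on a gene whose somatic events are
    early-stage is flagged as an early-detection candidate; one with no hits
    at all is flagged "no triplex evidence".
    """
    fold_res = run_fold(cfg)
    cpg_res = run_cpg(cfg)
    tri_res = run_triplex(cfg)
    ev_res = run_events(cfg)
    mirnas = read_fasta(cfg.mirna_fasta, "RNA")
    if not mirnas:
        raise ValueError("empty microRNA FASTA")
    nodes = ev_res["nodes"]
    rank = fold_res["stability"]
    out = Path(cfg.output_dir)
    rows = []
    for m in mirnas:
        partners = sorted({h.gene_id for h in tri_res["hits"] if h.mirna_id == m.id})
        stages: set[str] = set()
        for g in partners:
            try:
                stages |= stage_of(g, nodes)
            except KeyError:
                pass
        if not partners:
            flag = "no triplex evidence"
        elif "early" in stages:
            flag = "early-detection candidate"
        else:
            flag = ""
        rows.append({
            "mirna": m.id,
            "structure_count": fold_res["counts"][m.id],
            "stability_rank": rank.index(m.id) + 1,
            "triplex_partners": ",".join(partners),
            "partner_stages": ",".join(sorted(stages)),
            "flag": flag,
        })
    with open(out / "summary.tsv", "w") as fh:
        cols = ["mirna", "structure_count", "stability_rank", "triplex_partners",
                "partner_stages", "flag"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    return {"fold": fold_res, "cpg": cpg_res, "triplex": tri_res,
            "events": ev_res, "summary": rows}


def make_fixtures(outdir: str | Path, seed: int = 17) -> dict:
    """Write the demo bundle and a matching pipeline config YAML."""
    manifest = make_demo_bundle(outdir, seed=seed)
    cfg = PipelineConfig(
        output_dir=str(Path(outdir) / "results"),
        mirna_fasta=manifest["mirna_fasta"],
        promoter_fasta=manifest["promoter_fasta"],
        event_table=manifest["event_table"],
        edge_list=manifest["edge_list"],
        seed=seed,
    )
    with open(Path(outdir) / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    manifest["config"] = str(Path(outdir) / "config.yaml")
    return manifest
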