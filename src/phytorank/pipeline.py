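"""End-to-end prioritization pipeline with a reproducible run manifest.

``run_pipeline`` chains the stages: read associations -> build the bipartite
network -> score all eight measures -> per-measure top-k plant lists ->
replication counts -> cutoff selection -> literature-validation summary and
metabolite frequencies.  All artifacts are written to an output directory
together with a manifest recording the configuration, seed, package version
and SHA-256 of every input and output, so a rerun with identical inputs and
configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .centrality import MEASURES, ScoreTable, compute_all
from .errors import ConfigurationError, InputValidationError
from .network import (
    PLANT_PREFIX,
    BipartiteNetwork,
    NetworkStats,
    build_network,
    network_summary,
    normalize_plant_name,
    read_associations,
)
from .ranking import (
    CandidateRanking,
    MetaboliteFrequency,
    ReplicationTable,
    TopList,
    ValidationSummary,
    metabolite_frequency,
    replication_table,
    select_candidates,
    top_plants,
    validation_summary,
)


@dataclass
class PipelineConfig:
    """Everything a run depends on besides the input files."""

    seed: int | None = None
    k: int = 100
    cutoff: int = 5
    epc_realizations: int = 1000
    epc_p: float = 0.5
    tie_policy: str = "lexicographic"
    closeness_variant: str = "harmonic"
    eccentricity_smaller_is_central: bool = True
    plant_col: str = "plant"
    metabolite_col: str = "metabolite"
    id_validation: str = "lenient"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("pipeline requires an explicit seed")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if not (0 <= self.cutoff <= len(MEASURES)):
            raise ConfigurationError(f"cutoff must be in [0, {len(MEASURES)}]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """In-memory artifacts of one run, plus where they were written."""

    stats: NetworkStats
    scores: ScoreTable
    top_lists: list[TopList]
    replication: ReplicationTable
    candidates: CandidateRanking
    validation: ValidationSummary
    frequency: MetaboliteFrequency
    network: BipartiteNetwork
    out_dir: Path | None = None
    manifest: dict = field(default_factory=dict)


def read_annotations(path, plant_col: str = "plant",
                     status_col: str = "status") -> dict:
    """Read a plant -> known/novel table keyed by normalized plant name."""
    import csv

    path = Path(path)
    table: dict = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        delim = "\t" if "\t" in first else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in (plant_col, status_col):
            if col not in header:
                raise ConfigurationError(f"{path}: column {col!r} not found in header {header}")
        for i, row in enumerate(reader, start=1):
            key, _ = normalize_plant_name(row[plant_col] or "")
            status = (row[status_col] or "").strip().casefold()
            if status not in ("known", "novel"):
                raise InputValidationError(
                    f"{path}: row {i}: status must be 'known' or 'novel', got {status!r}"
                )
            table[key] = status
    return table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_stages(net: BipartiteNetwork, cfg: PipelineConfig,
               annotations: dict | None) -> PipelineResult:
    """Run scoring through validation on an already-built network."""
    cfg.validate()
    stats = network_summary(net)
    scores = compute_all(
        net,
        seed=cfg.seed,
        epc_realizations=cfg.epc_realizations,
        epc_p=cfg.epc_p,
        closeness_variant=cfg.closeness_variant,
        eccentricity_smaller_is_central=cfg.eccentricity_smaller_is_central,
    )
    lists = [top_plants(scores, m, k=cfg.k, tie_policy=cfg.tie_policy)
             for m in MEASURES]
    rep = replication_table(lists)
    # annotations are keyed by normalized plant name; candidate rows use
    # namespaced node ids, so re-key here
    node_ann = None
    if annotations is not None:
        node_ann = {PLANT_PREFIX + key: status for key, status in annotations.items()}
    cand = select_candidates(rep, cutoff=cfg.cutoff,
                             annotations=node_ann if node_ann is not None else {})
    val = validation_summary(cand) if len(cand) else None
    freq = metabolite_frequency(cand, net)
    return PipelineResult(
        stats=stats, scores=scores, top_lists=lists, replication=rep,
        candidates=cand, validation=val, frequency=freq, network=net,
    )


def run_pipeline(assoc_path, out_dir, config: PipelineConfig,
                 annotations_path=None) -> PipelineResult:
    """Full run from an association table to written artifacts + manifest."""
    config.validate()
    assoc_path = Path(assoc_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    assoc = read_associations(
        assoc_path, plant_col=config.plant_col,
        metabolite_col=config.metabolite_col, id_validation=config.id_validation,
    )
    net = build_network(assoc)
    annotations = (read_annotations(annotations_path)
                   if annotations_path is not None else {})
    result = run_stages(net, config, annotations)
    net_disp = result.network.display_name

    # ---- artifacts, all in canonical order --------------------------------
    result.stats.to_json(out / "network_stats.json")
    result.scores.to_tsv(out / "scores.tsv")
    result.scores.meta_to_json(out / "scores_meta.json")
    _write_tsv(out / "top_lists.tsv", ["measure", "rank", "plant"],
               [(tl.measure, i + 1, net_disp(p))
                for tl in result.top_lists for i, p in enumerate(tl.plants)])
    _write_tsv(out / "replication.tsv", ["plant", "replications"],
               sorted(((net_disp(p), c) for p, c in result.replication.counts.items()),
                      key=lambda r: (-r[1], r[0])))
    _write_tsv(out / "candidates.tsv",
               ["plant", "replications", "status", "n_metabolites"],
               [(net_disp(p), c, s if s is not None else "",
                 result.frequency.per_plant[p])
                for p, c, s in result.candidates.rows])
    _write_tsv(out / "metabolite_frequency.tsv", ["metabolite", "n_candidate_plants"],
               [(m.split(":", 1)[1], c) for m, c in result.frequency.per_metabolite])
    summary = {
        "n_candidates": len(result.candidates),
        "cutoff": result.candidates.cutoff,
        "validation": dataclasses.asdict(result.validation) if result.validation else None,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    # ---- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out.iterdir()
                     if p.name != "manifest.json" and p.is_file())
    manifest = {
        "phytorank_version": __version__,
        "config": config.as_dict(),
        "inputs": {
            assoc_path.name: _sha256(assoc_path),
            **({Path(annotations_path).name: _sha256(Path(annotations_path))}
               if annotations_path is not None else {}),
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    result.out_dir = out
    result.manifest = manifest
    return result
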