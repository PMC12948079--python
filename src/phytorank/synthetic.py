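"""Synthetic plant–metabolite association generator with planted ground truth.

Real input to this pipeline is a database export of species–metabolite
associations; its network is bipartite with a heavy-tailed metabolite degree
distribution (a handful of broadly distributed compounds found in >100
species, most nodes with degree below ten).  The generator reproduces that
shape at a configurable scale — defaults mirror the study system: 3250
plants, 650 metabolites, 5392 associations, maximum metabolite degree 244 —
and plants a small set of hub plants wired to many metabolites, providing
known ground truth for recovery tests.

Metabolite degrees are drawn from a truncated discrete power law and then
nudged (deterministically, under the run seed) so the degree total equals the
requested edge count exactly.  Plant endpoints are dealt from a shuffled slot
pool that covers every plant at least once, mimicking the fact that every
species in the real table carries at least one listed metabolite; duplicate
endpoints within a metabolite are resolved by rejection sampling with a
bounded retry budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputValidationError
from .network import AssociationList

_RETRY_BUDGET = 10_000


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    n_plants: int = 3250
    n_metabolites: int = 650
    target_edges: int = 5392
    degree_tail_exponent: float = 1.7
    max_metabolite_degree: int = 244
    n_planted_hubs: int = 5
    hub_metabolite_count: int = 50
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("SynthConfig requires an explicit seed")
        if self.degree_tail_exponent <= 1.0:
            raise ConfigurationError("degree_tail_exponent must be > 1")
        if self.n_planted_hubs > self.n_plants:
            raise ConfigurationError("more planted hubs than plants")
        if self.hub_metabolite_count > self.n_metabolites:
            raise ConfigurationError("hub_metabolite_count exceeds n_metabolites")
        if self.max_metabolite_degree > self.n_plants:
            raise ConfigurationError("max_metabolite_degree exceeds n_plants")
        background = self.target_edges - self.n_planted_hubs * self.hub_metabolite_count
        if background < max(self.n_plants, self.n_metabolites):
            raise ConfigurationError(
                "target_edges too small: background edge budget "
                f"{background} < max(n_plants, n_metabolites) — the network "
                "cannot cover both partitions without parallel edges"
            )
        if background > self.n_plants * self.n_metabolites:
            raise ConfigurationError("target_edges exceeds the bipartite capacity")


@dataclass
class SyntheticTruth:
    """Generated associations plus the planted ground truth."""

    planted_hub_plants: set
    association_list: AssociationList
    config: SynthConfig
    annotation_table: dict = field(default_factory=dict)


def _plant_name(i: int) -> str:
    return f"Plant {i + 1:04d}"


def _metabolite_id(i: int) -> str:
    return f"C{i + 1:08d}"


def _draw_degrees(rng: np.random.Generator, cfg: SynthConfig, total: int) -> np.ndarray:
    """Truncated power-law degrees adjusted to sum exactly to ``total``."""
    support = np.arange(1, cfg.max_metabolite_degree + 1)
    pmf = support.astype(float) ** (-cfg.degree_tail_exponent)
    pmf /= pmf.sum()
    deg = rng.choice(support, size=cfg.n_metabolites, p=pmf)
    # deterministic nudge toward the exact edge total, respecting [1, max]
    guard = 0
    while deg.sum() != total:
        diff = int(total - deg.sum())
        step = 1 if diff > 0 else -1
        idx = rng.integers(cfg.n_metabolites, size=min(abs(diff), cfg.n_metabolites))
        for i in idx:
            if deg.sum() == total:
                break
            nd = deg[i] + step
            if 1 <= nd <= cfg.max_metabolite_degree:
                deg[i] = nd
        guard += 1
        if guard > _RETRY_BUDGET:
            raise ConfigurationError(
                "could not adjust metabolite degrees to the requested edge count"
            )
    return deg


def generate_network(cfg: SynthConfig) -> SyntheticTruth:
    """Generate associations per the config; identical seed, identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    background_total = cfg.target_edges - cfg.n_planted_hubs * cfg.hub_metabolite_count
    degrees = _draw_degrees(rng, cfg, background_total)

    # slot pool covering every plant at least once
    extra = background_total - cfg.n_plants
    pool = np.concatenate([
        np.arange(cfg.n_plants),
        rng.integers(cfg.n_plants, size=extra),
    ])
    rng.shuffle(pool)

    edges: set[tuple[int, int]] = set()  # (metabolite index, plant index)
    cursor = 0
    for m in range(cfg.n_metabolites):
        d = int(degrees[m])
        chosen: set[int] = set()
        for _ in range(d):
            plant = int(pool[cursor])
            cursor += 1
            tries = 0
            while plant in chosen:
                plant = int(rng.integers(cfg.n_plants))
                tries += 1
                if tries > _RETRY_BUDGET:
                    raise ConfigurationError(
                        f"could not place {d} distinct plants on metabolite {m}"
                    )
            chosen.add(plant)
        edges.update((m, p) for p in chosen)

    # planted hubs: wired to the most common metabolites, mirroring the
    # observation that top-ranked plants share the highest-frequency
    # bioactive compounds rather than rare ones
    hub_plants = rng.choice(cfg.n_plants, size=cfg.n_planted_hubs, replace=False)
    order = np.argsort(-degrees, kind="stable")
    hub_mets = order[:cfg.hub_metabolite_count]
    for p in hub_plants:
        for m in hub_mets:
            edges.add((int(m), int(p)))

    pairs = [(_plant_name(p), _metabolite_id(m)) for m, p in edges]
    assoc = AssociationList.from_pairs(pairs)
    hub_keys = {_plant_name(int(p)).casefold() for p in hub_plants}
    return SyntheticTruth(planted_hub_plants=hub_keys, association_list=assoc,
                          config=cfg)


def generate_annotations(truth: SyntheticTruth, known_fraction: float = 0.85,
                         seed: int | None = None,
                         hub_status: str | None = None) -> dict:
    """Sample a plant -> known/novel annotation table.

    Statuses are independent Bernoulli(``known_fraction``) draws; planted
    hubs can be forced to a fixed status (e.g. ``"novel"``) for validation
    tests.  The table is attached to ``truth.annotation_table`` and returned.
    """
    if seed is None:
        raise ConfigurationError("generate_annotations requires an explicit seed")
    if not (0.0 <= known_fraction <= 1.0):
        raise ConfigurationError("known_fraction must be in [0, 1]")
    if hub_status is not None and hub_status not in ("known", "novel"):
        raise ConfigurationError("hub_status must be 'known' or 'novel'")
    rng = np.random.default_rng(seed)
    plants = sorted(truth.association_list.plants)
    draws = rng.random(len(plants)) < known_fraction
    table = {p: ("known" if keep else "novel") for p, keep in zip(plants, draws)}
    if hub_status is not None:
        for hub in truth.planted_hub_plants:
            table[hub] = hub_status
    truth.annotation_table = table
    return table


# -- file output (used by the CLI `simulate` command) -----------------------

def write_truth(truth: SyntheticTruth, out_dir) -> dict[str, Path]:
    """Write associations TSV, annotations TSV and truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assoc_path = out / "associations.tsv"
    disp = truth.association_list.display
    with assoc_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("plant\tmetabolite\n")
        for key, met in sorted(truth.association_list.pairs):
            fh.write(f"{disp[key]}\t{met}\n")
    ann_path = out / "annotations.tsv"
    with ann_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("plant\tstatus\n")
        for plant, status in sorted(truth.annotation_table.items()):
            fh.write(f"{disp.get(plant, plant)}\t{status}\n")
    truth_path = out / "truth.json"
    cfg = truth.config
    truth_path.write_text(json.dumps({
        "planted_hub_plants": sorted(truth.planted_hub_plants),
        "config": {k: getattr(cfg, k) for k in (
            "n_plants", "n_metabolites", "target_edges", "degree_tail_exponent",
            "max_metabolite_degree", "n_planted_hubs", "hub_metabolite_count",
            "seed")},
    }, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return {"associations": assoc_path, "annotations": ann_path, "truth": truth_path}
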