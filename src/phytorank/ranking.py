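"""Top-k hub lists, replication counts, candidate selection and validation.

Each centrality measure yields a ranked list of the top-k plant nodes; a
plant's *replication count* is the number of those lists it appears in
(0 to 8).  Plants at or above a replication cutoff form the candidate
ranking, which can be joined to a literature-annotation table
(plant -> known/novel) to summarize how many candidates already have
documented anticancer activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .centrality import MEASURES, ScoreTable
from .errors import ConfigurationError, InputValidationError
from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

TIE_POLICIES = ("lexicographic", "include_ties")


@dataclass
class TopList:
    """Ordered top-k plant list for one measure."""

    measure: str
    k: int
    plants: list
    tie_policy: str


@dataclass
class ReplicationTable:
    """Per-plant count of appearances across the per-measure top lists."""

    counts: dict
    n_measures: int = len(MEASURES)

    def count(self, plant) -> int:
        return self.counts.get(plant, 0)


@dataclass
class CandidateRanking:
    """Plants passing the replication cutoff, count-descending.

    Each row is ``(plant, replication_count, status)`` where status is
    ``"known"``/``"novel"`` when annotations were joined, else ``None``.
    """

    rows: list
    cutoff: int

    @property
    def plants(self) -> list:
        return [plant for plant, _, _ in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ValidationSummary:
    """Known/novel split of an annotated candidate ranking."""

    n_total: int
    n_known: int
    n_novel: int
    pct_known: float
    pct_novel: float


@dataclass
class MetaboliteFrequency:
    """Metabolite usage among candidate plants.

    ``per_metabolite``: (metabolite node, number of adjacent candidates),
    count-descending then lexicographic.  ``per_plant``: candidate ->
    its metabolite count, i.e. its degree in the network (the per-plant
    "anticancer metabolite" tally).
    """

    per_metabolite: list
    per_plant: dict

    def intersection(self, net: BipartiteNetwork, plant_a, plant_b) -> int:
        """Venn-style shared-metabolite count between two candidate plants."""
        g = net.graph
        return len(set(g.neighbors(plant_a)) & set(g.neighbors(plant_b)))


def top_plants(scores: ScoreTable, measure: str, k: int = 100,
               tie_policy: str = "lexicographic") -> TopList:
    """Rank plant-partition nodes by one measure and truncate to the top k.

    Ordering follows the measure's orientation (score-descending unless the
    table marks smaller as more central), with lexicographic node id as the
    tie-break.  The ``lexicographic`` policy returns exactly
    ``min(k, n_plants)`` entries; ``include_ties`` extends past k while the
    boundary score persists.  On score tables computed from plain graphs
    (no partitions) all nodes are eligible.
    """
    if measure not in MEASURES:
        raise ConfigurationError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if tie_policy not in TIE_POLICIES:
        raise ConfigurationError(
            f"unknown tie policy {tie_policy!r}; expected one of {TIE_POLICIES}"
        )
    df = scores.scores
    if "partition" in df.columns and (df["partition"] == "plant").any():
        df = df[df["partition"] == "plant"]
    col = df[measure]
    sign = -1.0 if scores.larger_is_central(measure) else 1.0
    ordered = sorted(col.items(), key=lambda kv: (sign * kv[1], str(kv[0])))
    if tie_policy == "lexicographic" or len(ordered) <= k:
        chosen = ordered[:k]
    else:
        cut = ordered[k - 1][1]
        chosen = ordered[:k] + [kv for kv in ordered[k:] if kv[1] == cut]
    return TopList(measure=measure, k=k, plants=[node for node, _ in chosen],
                   tie_policy=tie_policy)


def replication_table(lists) -> ReplicationTable:
    """Count, per plant, how many of the eight per-measure lists contain it."""
    lists = list(lists)
    seen = [tl.measure for tl in lists]
    if len(set(seen)) != len(seen):
        raise InputValidationError(f"duplicate measure among top lists: {sorted(seen)}")
    if set(seen) != set(MEASURES):
        missing = sorted(set(MEASURES) - set(seen))
        extra = sorted(set(seen) - set(MEASURES))
        raise InputValidationError(
            f"expected exactly one list per measure {MEASURES}; "
            f"missing {missing}, unexpected {extra}"
        )
    counts: dict = {}
    for tl in lists:
        for plant in set(tl.plants):
            counts[plant] = counts.get(plant, 0) + 1
    return ReplicationTable(counts=counts, n_measures=len(MEASURES))


def select_candidates(rep: ReplicationTable, cutoff: int = 5,
                      annotations: dict | None = None) -> CandidateRanking:
    """Plants with replication count >= cutoff, count-descending then by id.

    When an annotation mapping is supplied, plants missing from it default to
    ``"novel"`` (absence of literature evidence is what makes a candidate
    new) with a logged notice.
    """
    if not (0 <= cutoff <= rep.n_measures):
        raise ConfigurationError(
            f"cutoff must be in [0, {rep.n_measures}], got {cutoff}"
        )
    selected = [(p, c) for p, c in rep.counts.items() if c >= cutoff]
    selected.sort(key=lambda pc: (-pc[1], str(pc[0])))
    rows = []
    missing = []
    for plant, count in selected:
        if annotations is None:
            status = None
        else:
            status = annotations.get(plant)
            if status is None:
                missing.append(plant)
                status = "novel"
            elif status not in ("known", "novel"):
                raise InputValidationError(
                    f"annotation for {plant!r} must be 'known' or 'novel', got {status!r}"
                )
        rows.append((plant, count, status))
    if missing:
        logger.info("defaulted %d unannotated candidate(s) to 'novel': %s",
                    len(missing), missing)
    return CandidateRanking(rows=rows, cutoff=cutoff)


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to two decimals."""
    q = Decimal(numer) * 100 / Decimal(denom)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def validation_summary(cand: CandidateRanking) -> ValidationSummary:
    """Known/novel percentages over a fully annotated candidate ranking."""
    if len(cand) == 0:
        raise InputValidationError("cannot summarize an empty candidate ranking")
    statuses = [status for _, _, status in cand.rows]
    if any(s is None for s in statuses):
        raise InputValidationError(
            "candidate ranking is not annotated; pass annotations to select_candidates"
        )
    n_total = len(statuses)
    n_known = sum(s == "known" for s in statuses)
    n_novel = n_total - n_known
    return ValidationSummary(
        n_total=n_total,
        n_known=n_known,
        n_novel=n_novel,
        pct_known=_pct(n_known, n_total),
        pct_novel=_pct(n_novel, n_total),
    )


def metabolite_frequency(cand: CandidateRanking,
                         net: BipartiteNetwork) -> MetaboliteFrequency:
    """Metabolite counts among candidates and per-candidate metabolite tallies."""
    g = net.graph
    per_plant: dict = {}
    met_counts: dict = {}
    for plant in cand.plants:
        if plant not in g:
            raise InputValidationError(f"candidate plant {plant!r} absent from the network")
        nbrs = list(g.neighbors(plant))
        per_plant[plant] = len(nbrs)
        for met in nbrs:
            met_counts[met] = met_counts.get(met, 0) + 1
    per_met = sorted(met_counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return MetaboliteFrequency(per_metabolite=per_met, per_plant=per_plant)
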