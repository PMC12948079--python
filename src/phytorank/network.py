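"""Bipartite plant–metabolite network construction, summary statistics and I/O.

The analysis starts from a table of (plant, metabolite) associations — one row
per report that a plant species contains a given bioactive metabolite, with
KNApSAcK-style accession IDs of the form ``C`` + 8 digits.  The network built
from it is undirected, unweighted and bipartite: plant nodes on one side,
metabolite nodes on the other, one edge per distinct association.

Node identity is namespaced (``plant:<name>`` / ``met:<ID>``) so the two
partitions can never collide even if a token appears in both columns.  Plant
names are normalized for identity (whitespace-collapsed, case-folded) while the
first-seen display form is retained for output.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ConfigurationError, InputValidationError

logger = logging.getLogger(__name__)

METABOLITE_ID_PATTERN = re.compile(r"^C\d{8}$")

PLANT_PREFIX = "plant:"
METABOLITE_PREFIX = "met:"


def normalize_plant_name(raw: str) -> tuple[str, str]:
    """Return ``(identity_key, display_form)`` for a raw plant name.

    Identity: trim, collapse internal whitespace, case-fold.  Display: the
    whitespace-collapsed original casing.
    """
    collapsed = " ".join(str(raw).split())
    return collapsed.casefold(), collapsed


@dataclass
class AssociationList:
    """Deduplicated set of (plant, metabolite) association pairs.

    ``pairs`` holds ``(plant_key, metabolite_id)`` tuples where ``plant_key``
    is the normalized identity form; ``display`` maps each key back to its
    first-seen display form; ``source_rows`` is the raw input row count before
    deduplication.
    """

    pairs: set[tuple[str, str]]
    display: dict[str, str] = field(default_factory=dict)
    source_rows: int = 0

    def __post_init__(self) -> None:
        for plant_key, met_id in self.pairs:
            if not plant_key:
                raise InputValidationError("empty plant name in association pair")
            if not METABOLITE_ID_PATTERN.match(met_id):
                raise InputValidationError(
                    f"metabolite ID {met_id!r} does not match 'C' + 8 digits"
                )
            self.display.setdefault(plant_key, plant_key)

    @classmethod
    def from_pairs(cls, pairs) -> "AssociationList":
        """Build from an iterable of raw ``(plant_name, metabolite_id)`` pairs."""
        norm: set[tuple[str, str]] = set()
        display: dict[str, str] = {}
        n = 0
        for plant, met in pairs:
            n += 1
            key, disp = normalize_plant_name(plant)
            display.setdefault(key, disp)
            norm.add((key, str(met).strip()))
        return cls(pairs=norm, display=display, source_rows=n)

    @property
    def plants(self) -> set[str]:
        return {p for p, _ in self.pairs}

    @property
    def metabolites(self) -> set[str]:
        return {m for _, m in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def _sniff_delimiter(header_line: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def read_associations(
    path,
    plant_col: str = "plant",
    metabolite_col: str = "metabolite",
    sep: str | None = None,
    id_validation: str = "lenient",
) -> AssociationList:
    """Read a delimited association table into an :class:`AssociationList`.

    The file must be UTF-8 with a header row naming ``plant_col`` and
    ``metabolite_col``.  Tab is the default delimiter; comma is detected.
    Plant names are normalized and duplicate pairs dropped.

    ``id_validation`` controls what happens to rows whose metabolite ID does
    not match ``C`` + 8 digits: ``"strict"`` raises listing the offending row
    numbers, ``"lenient"`` (default) drops them with a logged warning —
    spreadsheet exports commonly carry footnote rows.
    """
    if id_validation not in ("strict", "lenient"):
        raise ConfigurationError(
            f"id_validation must be 'strict' or 'lenient', got {id_validation!r}"
        )
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first:
            raise InputValidationError(f"{path}: empty file, expected a header row")
        delim = _sniff_delimiter(first, sep)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in (plant_col, metabolite_col):
            if col not in header:
                raise ConfigurationError(
                    f"{path}: column {col!r} not found in header {header}"
                )
        pairs: set[tuple[str, str]] = set()
        display: dict[str, str] = {}
        bad_rows: list[int] = []
        n_rows = 0
        for i, row in enumerate(reader, start=1):
            n_rows += 1
            key, disp = normalize_plant_name(row[plant_col] or "")
            met = (row[metabolite_col] or "").strip()
            if not key or not METABOLITE_ID_PATTERN.match(met):
                bad_rows.append(i)
                continue
            display.setdefault(key, disp)
            pairs.add((key, met))
    if bad_rows:
        if id_validation == "strict":
            raise InputValidationError(
                f"{path}: malformed plant name or metabolite ID in data row(s) "
                f"{bad_rows} (expected non-empty name and 'C' + 8 digits)"
            )
        logger.warning(
            "%s: dropped %d row(s) with malformed IDs: rows %s",
            path, len(bad_rows), bad_rows,
        )
    return AssociationList(pairs=pairs, display=display, source_rows=n_rows)


class BipartiteNetwork:
    """Undirected unweighted bipartite graph of plants and metabolites.

    Backed by a :class:`networkx.Graph` whose node ids are namespaced
    (``plant:<key>`` / ``met:<ID>``) and carry ``partition`` and ``label``
    attributes.  Construction validates bipartiteness structurally.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.validate()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, pairs, display: dict[str, str] | None = None) -> "BipartiteNetwork":
        """Build from ``(plant_key, metabolite_id)`` pairs in canonical order.

        Nodes are inserted plants-first then metabolites, each lexicographic,
        and edges lexicographically, so serialization is reproducible.
        """
        display = display or {}
        pairs = sorted(set(pairs))
        g = nx.Graph()
        for key in sorted({p for p, _ in pairs}):
            g.add_node(PLANT_PREFIX + key, partition="plant",
                       label=display.get(key, key))
        for met in sorted({m for _, m in pairs}):
            g.add_node(METABOLITE_PREFIX + met, partition="metabolite", label=met)
        for key, met in pairs:
            g.add_edge(PLANT_PREFIX + key, METABOLITE_PREFIX + met)
        return cls(g)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Structural 2-coloring check: every edge joins the two partitions."""
        for node, data in self.graph.nodes(data=True):
            if data.get("partition") not in ("plant", "metabolite"):
                raise InputValidationError(f"node {node!r} lacks a valid partition label")
        for u, v in self.graph.edges():
            pu = self.graph.nodes[u]["partition"]
            pv = self.graph.nodes[v]["partition"]
            if pu == pv:
                raise InputValidationError(
                    f"edge ({u!r}, {v!r}) joins two {pu} nodes — not bipartite"
                )

    # -- accessors ----------------------------------------------------------

    @property
    def plant_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["partition"] == "plant"}

    @property
    def metabolite_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["partition"] == "metabolite"}

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}

    @property
    def n_plants(self) -> int:
        return len(self.plant_nodes)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_nodes)

    def display_name(self, node: str) -> str:
        return self.graph.nodes[node]["label"]

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.plant_nodes == other.plant_nodes
            and self.metabolite_nodes == other.metabolite_nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (f"<BipartiteNetwork {self.n_plants} plants, "
                f"{self.n_metabolites} metabolites, "
                f"{self.graph.number_of_edges()} edges>")


def build_network(assoc: AssociationList) -> BipartiteNetwork:
    """Construct the bipartite network from a non-empty association list.

    One plant node per distinct plant, one metabolite node per distinct
    metabolite, one edge per pair; ``|edges| == |assoc.pairs|`` always holds
    because pairs are already deduplicated.
    """
    if not assoc.pairs:
        raise InputValidationError("cannot build a network from an empty association list")
    return BipartiteNetwork.from_edges(assoc.pairs, assoc.display)


@dataclass
class NetworkStats:
    """Exact node/edge counts and the full degree histogram."""

    n_nodes: int
    n_edges: int
    n_plants: int
    n_metabolites: int
    degree_histogram: dict[int, int]
    max_degree_node: str | None

    def to_json(self, path) -> None:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_plants": self.n_plants,
            "n_metabolites": self.n_metabolites,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "max_degree_node": self.max_degree_node,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")


def network_summary(net: BipartiteNetwork) -> NetworkStats:
    """Deterministic summary; ties for max degree break lexicographically."""
    g = net.graph
    hist: dict[int, int] = {}
    max_node, max_deg = None, -1
    for node in sorted(g.nodes, key=str):
        d = g.degree(node)
        hist[d] = hist.get(d, 0) + 1
        if d > max_deg:
            max_node, max_deg = node, d
    return NetworkStats(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_plants=net.n_plants,
        n_metabolites=net.n_metabolites,
        degree_histogram=hist,
        max_degree_node=max_node,
    )


# -- serialization ----------------------------------------------------------

FORMATS = ("edgelist", "graphml")


def write_network(net: BipartiteNetwork, path, fmt: str = "edgelist") -> None:
    """Write the network as an edge-list TSV or GraphML.

    The edge list has columns ``plant`` (display name) and ``metabolite`` in
    canonical order; GraphML carries ``partition`` and ``label`` node
    attributes.  Both round-trip the node set, edge set and partition exactly
    (bipartite networks built from associations have no isolated nodes).
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = sorted(
            (u[len(PLANT_PREFIX):], v[len(METABOLITE_PREFIX):])
            if u.startswith(PLANT_PREFIX) else
            (v[len(PLANT_PREFIX):], u[len(METABOLITE_PREFIX):])
            for u, v in net.graph.edges()
        )
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("plant\tmetabolite\n")
            for key, met in rows:
                fh.write(f"{net.display_name(PLANT_PREFIX + key)}\t{met}\n")
    elif fmt == "graphml":
        # rebuild in canonical order so output bytes are reproducible
        pairs = []
        for u, v in net.graph.edges():
            if not u.startswith(PLANT_PREFIX):
                u, v = v, u
            pairs.append((u[len(PLANT_PREFIX):], v[len(METABOLITE_PREFIX):]))
        canonical = BipartiteNetwork.from_edges(
            pairs,
            {n[len(PLANT_PREFIX):]: net.display_name(n) for n in net.plant_nodes},
        )
        nx.write_graphml(canonical.graph, path)
    else:
        raise ConfigurationError(f"unknown network format {fmt!r}; expected one of {FORMATS}")


def read_network(path, fmt: str = "edgelist") -> BipartiteNetwork:
    """Read a network previously written by :func:`write_network`."""
    path = Path(path)
    if fmt == "edgelist":
        assoc = read_associations(path, plant_col="plant", metabolite_col="metabolite")
        return BipartiteNetwork.from_edges(assoc.pairs, assoc.display)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        clean = nx.Graph()
        for node, data in g.nodes(data=True):
            clean.add_node(node, partition=data["partition"], label=data["label"])
        clean.add_edges_from(g.edges())
        return BipartiteNetwork(clean)
    raise ConfigurationError(f"unknown network format {fmt!r}; expected one of {FORMATS}")
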