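"""Two-reaction-step path search between metabolites in a reaction network.

The question the search answers: do two metabolites participate in reactions
within two steps of each other?  Starting from the first metabolite, all
reactions reachable in at most ``max_steps`` reaction steps are collected by
breadth-first expansion alternating metabolite -> reaction -> metabolite.
Traversal respects reaction direction (a metabolite enters a reaction through
its substrate side, or either side if the reaction is reversible) and never
passes *through* a hub metabolite — highly connected currency compounds such
as ATP or NADP that would otherwise connect everything to everything.  Hubs
may still appear as co-substrates of traversed reactions, and the target
metabolite is matched against the full participant set (substrates and
products) of every traversed reaction.

A small curated network of methionine / homocysteine metabolism
(transmethylation, transsulfuration, the betaine/choline arm, the
gamma-glutamyl cycle and phosphatidylcholine turnover including the PEMT
reaction) ships with the package, together with a default hub list and a
synonym table mapping panel short names (e.g. "Met", "PC aa C32:1") to
network nodes; lipid species map to class-level nodes, a documented
approximation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "PathResult",
    "DEFAULT_HUBS",
    "load_network",
    "default_network",
    "load_synonyms",
    "default_synonyms",
    "reactions_within_radius",
    "find_path",
    "pairwise_search",
]

DEFAULT_HUBS = frozenset(
    {"ATP", "ADP", "AMP", "NADP", "NADPH", "NAD", "NADH", "H2O", "CO2", "Pi", "PPi", "CoA"}
)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    @property
    def participants(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass
class ReactionNetwork:
    """Bipartite metabolite/reaction graph with a hub-exclusion set."""

    metabolites: set[str]
    reactions: dict[str, Reaction]
    hubs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            dangling = rxn.participants - self.metabolites
            if dangling:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite(s) {sorted(dangling)}"
                )
        unknown_hubs = set(self.hubs) - self.metabolites
        if unknown_hubs:
            raise ValueError(f"hubs not in metabolite set: {sorted(unknown_hubs)}")
        # forward index: metabolite -> reaction ids it can enter
        self._entries: dict[str, list[str]] = {m: [] for m in self.metabolites}
        for rid in sorted(self.reactions):
            rxn = self.reactions[rid]
            for m in rxn.substrates:
                self._entries[m].append(rid)
            if rxn.reversible:
                for m in rxn.products - rxn.substrates:
                    self._entries[m].append(rid)

    def entries(self, metabolite: str) -> list[str]:
        """Reaction ids traversable from ``metabolite`` (sorted, direction-aware)."""
        if metabolite not in self.metabolites:
            raise ValueError(f"unknown metabolite {metabolite!r}")
        return list(self._entries[metabolite])

    def outputs(self, reaction_id: str, entered_from: str) -> set[str]:
        """Metabolites produced when traversing a reaction from a given side."""
        rxn = self.reactions[reaction_id]
        if entered_from in rxn.substrates:
            out = set(rxn.products)
            if rxn.reversible:
                out |= rxn.substrates
        else:  # reversible entry through the product side
            out = set(rxn.substrates)
        out.discard(entered_from)
        return out


@dataclass
class PathResult:
    source: str
    target: str
    found: bool
    path: list[str] = field(default_factory=list)  # metabolite, reaction, metabolite, ...
    steps: int = 0
    #: original query names when the search went through a synonym map
    query_source: str | None = None
    query_target: str | None = None

    def __post_init__(self) -> None:
        if self.found and not self.path:
            raise ValueError("found path result requires a non-empty path")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _split(cell) -> frozenset[str]:
    if pd.isna(cell) or str(cell).strip() == "":
        return frozenset()
    parts = [p.strip() for p in str(cell).split(";")]
    if any(p == "" for p in parts):
        raise ValueError(f"empty metabolite name in field {cell!r}")
    return frozenset(parts)


def load_network(
    reactions_path,
    hubs_path=None,
    extra_hubs: Iterable[str] = (),
    use_default_hubs: bool = True,
) -> ReactionNetwork:
    """Load a reaction TSV (reaction_id, substrates, products, reversible).

    Substrates/products are ';'-separated; ``reversible`` is 0/1.  The hub
    set is the default currency-metabolite list (optionally extended by a
    one-name-per-line hubs file and ``extra_hubs``) intersected with the
    metabolites actually present in the network.
    """
    df = pd.read_csv(reactions_path, sep="\t", dtype=str)
    required = {"reaction_id", "substrates", "products", "reversible"}
    if not required.issubset(df.columns):
        raise ValueError(f"reaction table must have columns {sorted(required)}")
    reactions: dict[str, Reaction] = {}
    for _, row in df.iterrows():
        rid = str(row["reaction_id"]).strip()
        if rid in reactions:
            raise ValueError(f"duplicate reaction_id {rid!r}")
        reactions[rid] = Reaction(
            id=rid,
            substrates=_split(row["substrates"]),
            products=_split(row["products"]),
            reversible=str(row["reversible"]).strip() in {"1", "true", "True"},
        )
    metabolites = set().union(*(r.participants for r in reactions.values())) if reactions else set()
    hubs = set(DEFAULT_HUBS) if use_default_hubs else set()
    if hubs_path is not None:
        with open(hubs_path) as fh:
            hubs |= {line.strip() for line in fh if line.strip()}
    hubs |= set(extra_hubs)
    return ReactionNetwork(metabolites=metabolites, reactions=reactions, hubs=hubs & metabolites)


def load_synonyms(path) -> dict[str, str]:
    """Synonym TSV (name, node) -> mapping of panel names to network nodes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["name"], df["node"]))


def _data_path(fname: str):
    return resources.files("telometa").joinpath("data", fname)


def default_network() -> ReactionNetwork:
    """The packaged methionine/homocysteine-metabolism network."""
    with resources.as_file(_data_path("methionine_reactions.tsv")) as p:
        return load_network(p)


def default_synonyms() -> dict[str, str]:
    with resources.as_file(_data_path("panel_synonyms.tsv")) as p:
        return load_synonyms(p)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def reactions_within_radius(net: ReactionNetwork, metabolite: str, radius: int) -> set[str]:
    """Reactions reachable from a metabolite in at most ``radius`` steps.

    Breadth-first, direction-aware, never expanding through a hub metabolite
    (the start metabolite itself is always expanded).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if metabolite not in net.metabolites:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    collected: set[str] = set()
    frontier = {metabolite}
    visited_mets = {metabolite}
    for _ in range(radius):
        next_frontier: set[str] = set()
        for met in sorted(frontier):
            for rid in net.entries(met):
                collected.add(rid)
                for out in net.outputs(rid, met):
                    if out in visited_mets or out in net.hubs:
                        continue
                    next_frontier.add(out)
        visited_mets |= next_frontier
        frontier = next_frontier
        if not frontier:
            break
    return collected


def find_path(net: ReactionNetwork, a: str, b: str, max_steps: int = 2) -> PathResult:
    """Shortest alternating path (by reaction count) from a to b, <= max_steps.

    The target is matched against the full participant set of each traversed
    reaction; intermediates are traversed direction-aware and never through a
    hub.  Ties are broken lexicographically (metabolites, then reaction ids),
    so the returned path is deterministic.
    """
    for m in (a, b):
        if m not in net.metabolites:
            raise ValueError(f"unknown metabolite {m!r}")
    if a == b:
        return PathResult(a, b, True, [a], 0)
    # BFS over metabolites; parent links reconstruct metabolite-reaction paths
    parent: dict[str, tuple[str, str]] = {}
    depth = {a: 0}
    queue = deque([a])
    while queue:
        met = queue.popleft()
        d = depth[met]
        if d >= max_steps:
            continue
        for rid in net.entries(met):
            rxn = net.reactions[rid]
            if b in rxn.participants:
                path = _reconstruct(parent, a, met) + [rid, b]
                return PathResult(a, b, True, path, d + 1)
            for out in sorted(net.outputs(rid, met)):
                if out in depth or out in net.hubs:
                    continue
                depth[out] = d + 1
                parent[out] = (rid, met)
                queue.append(out)
    return PathResult(a, b, False, [], 0)


def _reconstruct(parent: Mapping[str, tuple[str, str]], a: str, met: str) -> list[str]:
    chain: list[str] = [met]
    while met != a:
        rid, prev = parent[met]
        chain.extend([rid, prev])
        met = prev
    return chain[::-1]


def pairwise_search(
    net: ReactionNetwork,
    metabolite_names: Sequence[str],
    max_steps: int = 2,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[list[PathResult], list[str]]:
    """Evaluate every unordered pair of (mapped) metabolites.

    Names are mapped through ``synonyms`` (falling back to the name itself);
    unmapped names are reported, not fatal.  For each pair both search
    directions are tried and the shorter found path kept.  Returns
    (results, unmapped_names).
    """
    synonyms = synonyms or {}
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for name in metabolite_names:
        node = synonyms.get(name, name)
        if node in net.metabolites:
            mapped[name] = node
        else:
            unmapped.append(name)
    names = sorted(mapped)
    results: list[PathResult] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = mapped[names[i]], mapped[names[j]]
            fwd = find_path(net, a, b, max_steps)
            rev = find_path(net, b, a, max_steps)
            best = fwd
            if rev.found and (not fwd.found or rev.steps < fwd.steps):
                best = rev
            best.query_source = names[i]
            best.query_target = names[j]
            results.append(best)
    return results, unmapped
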