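import numpy as np
import pytest

from oracles import enumerate_paths
from telometa.pathway import (
    Reaction,
    ReactionNetwork,
    default_network,
    default_synonyms,
    find_path,
    load_network,
    pairwise_search,
    reactions_within_radius,
)

SIX = ["lysoPC a C17:0", "Met", "Tyr", "PC aa C32:1", "C3-OH", "PC ae C38:4"]


@pytest.fixture(scope="module")
def net():
    return default_network()


def _toy(reactions, hubs=()):
    rxns = {r.id: r for r in reactions}
    mets = set().union(*(r.participants for r in reactions))
    return ReactionNetwork(metabolites=mets, reactions=rxns, hubs=set(hubs) & mets)


def test_packaged_fixture_loads(net):
    assert len(net.metabolites) >= 10
    for m in ("methionine", "homocysteine", "cysteine"):
        assert m in net.metabolites
    assert "ATP" in net.hubs


def test_network_validates_dangling_reference():
    r = Reaction("R1", frozenset({"a"}), frozenset({"b"}))
    with pytest.raises(ValueError, match="ghost"):
        ReactionNetwork(metabolites={"a", "b"}, reactions={
            "R1": r, "R2": Reaction("R2", frozenset({"a"}), frozenset({"ghost"}))
        })


def test_load_network_rejects_duplicate_reaction_ids(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("reaction_id\tsubstrates\tproducts\treversible\n"
                 "R1\ta\tb\t0\nR1\tb\tc\t0\n")
    with pytest.raises(ValueError, match="duplicate"):
        load_network(p)


def test_empty_hub_file_means_no_exclusions(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("reaction_id\tsubstrates\tproducts\treversible\nR1\ta\tb\t0\n")
    hubs = tmp_path / "hubs.txt"
    hubs.write_text("")
    net = load_network(p, hubs, use_default_hubs=False)
    assert net.hubs == set()


def test_radius_one_from_methionine_contains_sam_synthesis(net):
    rxns = reactions_within_radius(net, "methionine", 1)
    assert "R_MAT" in rxns
    assert "R_GNMT" not in rxns  # needs a second step
    assert "R_GNMT" in reactions_within_radius(net, "methionine", 2)


def test_isolated_metabolite_has_empty_radius():
    net = ReactionNetwork(
        metabolites={"a", "b", "island"},
        reactions={"R1": Reaction("R1", frozenset({"a"}), frozenset({"b"}))},
    )
    assert reactions_within_radius(net, "island", 2) == set()


def test_hub_bridge_blocks_expansion():
    # A -> R1 -> ATP -> R2 -> B: with ATP a hub, R2 is unreachable from A
    net = _toy(
        [Reaction("R1", frozenset({"A"}), frozenset({"ATP"})),
         Reaction("R2", frozenset({"ATP"}), frozenset({"B"}))],
        hubs={"ATP"},
    )
    assert reactions_within_radius(net, "A", 2) == {"R1"}
    assert not find_path(net, "A", "B").found


def test_unknown_metabolite_errors(net):
    with pytest.raises(ValueError, match="nonesuch"):
        reactions_within_radius(net, "nonesuch", 1)
    with pytest.raises(ValueError, match="nonesuch"):
        find_path(net, "methionine", "nonesuch")


def test_methionine_to_sah_two_steps_via_sam(net):
    res = find_path(net, "methionine", "S-adenosylhomocysteine")
    assert res.found and res.steps == 2
    assert res.path[0] == "methionine"
    assert res.path[2] == "S-adenosylmethionine"
    assert res.path[-1] == "S-adenosylhomocysteine"


def test_methionine_to_cysteine_beyond_two_steps(net):
    assert not find_path(net, "methionine", "cysteine", max_steps=2).found
    deep = find_path(net, "methionine", "cysteine", max_steps=6)
    assert deep.found and deep.steps == 5  # transsulfuration chain


def test_self_path_trivial(net):
    res = find_path(net, "methionine", "methionine")
    assert res.found and res.steps == 0 and res.path == ["methionine"]


def test_monotone_in_max_steps(net):
    mets = sorted(net.metabolites - net.hubs)
    for a in mets[:8]:
        for b in mets[:8]:
            if find_path(net, a, b, max_steps=1).found:
                assert find_path(net, a, b, max_steps=2).found


def test_find_path_matches_exhaustive_enumeration(net):
    """Breadth-first search agrees with brute-force path enumeration on the
    packaged fixture and on random small networks."""
    mets = sorted(net.metabolites - net.hubs)
    for a in mets:
        for b in mets:
            for k in (1, 2, 3):
                res = find_path(net, a, b, max_steps=k)
                brute = enumerate_paths(net, a, b, k)
                assert res.found == bool(brute), (a, b, k)
                if res.found:
                    assert res.steps == min(brute), (a, b, k)

    rng = np.random.default_rng(0)
    for trial in range(15):
        names = [f"m{i}" for i in range(8)]
        rxns = []
        for j in range(10):
            subs = frozenset(rng.choice(names, size=rng.integers(1, 3), replace=False))
            prods = frozenset(rng.choice(names, size=rng.integers(1, 3), replace=False)) - subs
            if not prods:
                continue
            rxns.append(Reaction(f"R{j}", subs, prods, reversible=bool(rng.random() < 0.3)))
        net_r = _toy(rxns, hubs={"m0"} if trial % 2 else set())
        nodes = sorted(net_r.metabolites - net_r.hubs)
        for a in nodes:
            for b in nodes:
                res = find_path(net_r, a, b, max_steps=2)
                brute = enumerate_paths(net_r, a, b, 2)
                assert res.found == bool(brute), (trial, a, b)
                if res.found:
                    assert res.steps == min(brute)


def test_symmetry_on_fully_reversible_network():
    rng = np.random.default_rng(1)
    names = [f"m{i}" for i in range(7)]
    rxns = []
    for j in range(9):
        subs = frozenset(rng.choice(names, size=2, replace=False))
        prods = frozenset(rng.choice(names, size=2, replace=False)) - subs
        if prods:
            rxns.append(Reaction(f"R{j}", subs, prods, reversible=True))
    net_r = _toy(rxns)
    for a in sorted(net_r.metabolites):
        for b in sorted(net_r.metabolites):
            assert find_path(net_r, a, b, 2).found == find_path(net_r, b, a, 2).found


def test_hub_filtering_never_creates_paths(net):
    unfiltered = ReactionNetwork(metabolites=set(net.metabolites),
                                 reactions=dict(net.reactions), hubs=set())
    mets = sorted(net.metabolites)
    for a in mets[:10]:
        for b in mets[:10]:
            if find_path(net, a, b, 2).found:
                assert find_path(unfiltered, a, b, 2).found


def test_pairwise_search_connects_methionine_to_phosphatidylcholines(net):
    results, unmapped = pairwise_search(net, SIX, synonyms=default_synonyms())
    assert unmapped == ["C3-OH"]  # acylcarnitine absent from this network
    by_pair = {(r.query_source, r.query_target): r for r in results}
    met_pc = [r for (a, b), r in by_pair.items()
              if "Met" in (a, b) and ("PC aa C32:1" in (a, b) or "PC ae C38:4" in (a, b))]
    assert len(met_pc) == 2
    for r in met_pc:
        assert r.found and r.steps == 2
        assert "S-adenosylmethionine" in r.path  # the SAM-consuming PC synthesis link
    hubs_seen = [m for r in results if r.found for m in r.path[2:-1:2]]
    assert not set(hubs_seen) & net.hubs  # no hub intermediates


def test_pairwise_search_trivial_and_unmapped(net):
    results, unmapped = pairwise_search(net, ["Met"], synonyms=default_synonyms())
    assert results == [] and unmapped == []
    results, unmapped = pairwise_search(net, ["Met", "not-a-metabolite"],
                                        synonyms=default_synonyms())
    assert unmapped == ["not-a-metabolite"]
    assert results == []
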