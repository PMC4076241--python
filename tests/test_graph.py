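"""Path finding, subset generation and isolated-species handling."""

import math

import networkx as nx
import pytest

import glyconet as gn
from glyconet.graph import (
    PathwayGraph,
    SubsetConstraints,
    detect_isolated_species,
    path_finding,
    remove_isolated_species,
    subnet_by_num_del,
    subnet_by_spec_del,
    subnet_by_spec_keep,
)
from glyconet.network import Pathway
from glyconet.reactions import Rxn
from glyconet.simulate import random_pathway


def chain_pathway(n=4):
    """A linear n-species pathway of alternating LacNAc extensions."""
    texts = ["GlcNAc"]
    for i in range(1, n):
        texts.append(("Gal(b1,4)" if i % 2 else "GlcNAc(b1,3)") + texts[-1])
    glycans = [gn.parse_linear(t) for t in texts]
    pw = Pathway()
    for g in glycans:
        pw.add_species(g)
    for a, b in zip(glycans, glycans[1:]):
        pw.add_reaction(Rxn(a, b, "enzyme", "transfer"))
    return pw, [g.canonical for g in glycans]


class TestPathFinding:
    def test_zero_length_path(self, case1_master):
        key = sorted(case1_master.species)[0]
        assert path_finding(case1_master, key, key) == [[key]]

    def test_unknown_species_raises(self, case1_master):
        with pytest.raises(KeyError):
            path_finding(case1_master, "nonsense", "nonsense")

    def test_paths_alternate_species_and_reactions(self, case1_master, case1):
        src = case1.glycan("0").canonical
        tgt = case1.glycan("9").canonical
        paths = path_finding(case1_master, src, tgt)
        assert paths
        for p in paths:
            assert p[0] == src and p[-1] == tgt
            species = p[0::2]
            rxns = p[1::2]
            assert len(species) == len(rxns) + 1
            for s, r, t in zip(species, rxns, species[1:]):
                assert r.key[0] == s and r.key[1] == t
            assert len(set(species)) == len(species)  # simple path

    def test_matches_brute_force_oracle_on_random_graphs(self, rng):
        """DFS path enumeration equals networkx's independent implementation."""
        for _ in range(200):
            pw = random_pathway(rng, n_species=int(rng.integers(4, 13)))
            pg = PathwayGraph(pw)
            keys = sorted(pw.species)
            src = keys[int(rng.integers(len(keys)))]
            tgt = keys[int(rng.integers(len(keys)))]
            if src == tgt:
                continue
            mine = path_finding(pg, src, tgt)
            mine_set = {
                tuple(x if isinstance(x, str) else x.key for x in p) for p in mine
            }
            assert len(mine_set) == len(mine)  # no duplicate paths
            oracle = set()
            for nodes, edge_keys in _nx_paths_with_edges(pg.graph, src, tgt):
                t = [nodes[0]]
                for ek, v in zip(edge_keys, nodes[1:]):
                    t += [ek, v]
                oracle.add(tuple(t))
            assert mine_set == oracle

    def test_union_of_paths_is_a_subnetwork(self, case1_master, case1):
        src = case1.glycan("0").canonical
        tgt = case1.glycan("9").canonical
        paths = path_finding(case1_master, src, tgt)
        species = {s for p in paths for s in p[0::2]}
        rxns = {r.key for p in paths for r in p[1::2]}
        assert species <= set(case1_master.species)
        assert rxns <= set(case1_master.reactions)


def _nx_paths_with_edges(graph, src, tgt):
    """All simple node paths expanded over parallel edge keys."""
    out = []
    for nodes in nx.all_simple_paths(graph, src, tgt):
        combos = [[]]
        for u, v in zip(nodes, nodes[1:]):
            edge_keys = [
                graph.edges[u, v, k]["rxn"].key for k in graph[u][v]
            ]
            combos = [c + [ek] for c in combos for ek in edge_keys]
        for c in combos:
            out.append((nodes, c))
    return out


class TestIsolatedSpecies:
    def test_orphan_detected_and_removed(self, db):
        pw, keys = chain_pathway(3)
        orphan = gn.single_residue("Xyl")
        pw.add_species(orphan)
        assert detect_isolated_species(pw) == [orphan.canonical]
        cleaned = remove_isolated_species(pw)
        assert orphan.canonical not in cleaned.species
        assert set(cleaned.reactions) == set(pw.reactions)

    def test_removal_idempotent(self):
        pw, _ = chain_pathway(3)
        pw.add_species(gn.single_residue("Xyl"))
        once = remove_isolated_species(pw)
        twice = remove_isolated_species(once)
        assert set(once.species) == set(twice.species)

    def test_case2_network_fully_connected(self, m5gn, db):
        pw = gn.forward_network([m5gn], ["GnTII", "GnTIII", "GnTIV", "GnTV", "ManII"], db=db)
        assert detect_isolated_species(pw) == []


class TestSpecSubsets:
    def test_keep_all_is_identity(self, case1_master):
        kept = subnet_by_spec_keep(case1_master, set(case1_master.species))
        assert set(kept.species) == set(case1_master.species)
        assert set(kept.reactions) == set(case1_master.reactions)

    def test_delete_nothing_is_identity(self, case1_master):
        out = subnet_by_spec_del(case1_master, set())
        assert set(out.species) == set(case1_master.species)
        assert set(out.reactions) == set(case1_master.reactions)

    def test_delete_neighbors_cascades(self):
        pw, keys = chain_pathway(5)
        out = subnet_by_spec_del(pw, {keys[1]})
        # the chain head lost its only reaction and is pruned as isolated
        assert keys[0] not in out.species
        assert set(out.species) == set(keys[2:])
        assert out.n_reactions == 2

    def test_master_still_connects_after_single_deletion(self, case1_master, case1):
        out = subnet_by_spec_del(case1_master, {case1.glycan("5").canonical})
        paths = path_finding(out, case1.glycan("0").canonical, case1.glycan("9").canonical)
        assert paths

    def test_unknown_key_raises(self, case1_master):
        with pytest.raises(KeyError):
            subnet_by_spec_del(case1_master, {"nope"})
        with pytest.raises(KeyError):
            subnet_by_spec_keep(case1_master, {"nope"})


class TestNumDelSubsets:
    def test_candidate_count_is_binomial(self):
        pw, keys = chain_pathway(5)
        scan = subnet_by_num_del(pw, 1, constraints=SubsetConstraints(forbid_orphans=False, intermediates_internal=False))
        assert scan.n_examined == math.comb(5, 1)
        scan = subnet_by_num_del(pw, 2, protected={keys[0]})
        assert scan.n_examined == math.comb(4, 2)

    def test_results_are_subgraphs(self, case1_master, case1):
        start = case1.glycan("0").canonical
        scan = subnet_by_num_del(case1_master, 3, protected={start})
        assert scan
        for res in list(scan)[:20]:
            sub = res.pathway
            assert set(sub.species) <= set(case1_master.species)
            assert set(sub.reactions) <= set(case1_master.reactions)
            assert res.deleted.isdisjoint(sub.species)

    def test_overdeletion_yields_empty(self):
        pw, keys = chain_pathway(4)
        cons = SubsetConstraints(require={keys[0]}, require_any={keys[-1]})
        scan = subnet_by_num_del(pw, 3, protected={keys[0]}, constraints=cons)
        assert list(scan) == []

    def test_k_out_of_range(self, case1_master):
        with pytest.raises(ValueError):
            subnet_by_num_del(case1_master, 0)
        with pytest.raises(ValueError):
            subnet_by_num_del(case1_master, 100)

    def test_sampling_mode_is_seeded(self, case1_master, rng):
        import numpy as np

        start = sorted(case1_master.species)[0]
        a = subnet_by_num_del(
            case1_master, 4, rng=np.random.default_rng(7), max_samples=50
        )
        b = subnet_by_num_del(
            case1_master, 4, rng=np.random.default_rng(7), max_samples=50
        )
        assert a.n_examined == b.n_examined == 50
        assert [r.deleted for r in a] == [r.deleted for r in b]
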