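"""Greedy clustering and the protein similarity network."""

import numpy as np
import pytest

from evescan._align import align_protein, bit_score, encode_aa, evalue
from evescan.network import (SequenceCluster, build_network,
                             dereplicate_per_genome, export_network,
                             greedy_cluster, import_network,
                             within_genome_diversity)
from evescan.network import _pair_stats
from evescan.simulate import random_nt, random_protein


def _family(rng, n, divergence, length=900, alphabet="ACGT"):
    anc = "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), length)])
    out = {"v0": anc}
    for i in range(1, n):
        s = list(anc)
        k = rng.poisson(divergence * length)
        for p in rng.choice(length, min(k, length), replace=False):
            s[p] = alphabet[rng.integers(len(alphabet))]
        out[f"v{i}"] = "".join(s)
    return out


def _reference_greedy(seqs, min_identity, min_coverage, alphabet):
    """Independently structured greedy reference (same pairwise predicate)."""
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for sid in order:
        for rep in reps:
            _, ident, cov = _pair_stats(seqs[sid], seqs[rep], alphabet)
            if ident >= min_identity and cov >= min_coverage:
                assign[sid] = rep
                break
        else:
            reps.append(sid)
            assign[sid] = sid
    return assign


class TestGreedyCluster:
    def test_identical_sequences_single_cluster(self):
        seqs = {f"s{i}": "ACGTACGTAC" * 10 for i in range(8)}
        clusters = greedy_cluster(seqs, 1.0, 0.9)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == sorted(seqs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        seqs = {}
        for f in range(3):
            fam = _family(rng, 8, 0.05, length=int(rng.integers(300, 600)))
            seqs.update({f"f{f}_{k}": v for k, v in fam.items()})
        got = greedy_cluster(seqs, 0.9, 0.5)
        want = _reference_greedy(seqs, 0.9, 0.5, "nt")
        got_assign = {m: cl.representative for cl in got for m in cl.members}
        assert got_assign == want

    def test_star_family_at_98(self):
        rng = np.random.default_rng(3)
        fam = _family(rng, 20, 0.02)
        clusters = greedy_cluster(fam, 0.98, 0.3)
        got_assign = {m: c.representative for c in clusters for m in c.members}
        assert got_assign == _reference_greedy(fam, 0.98, 0.3, "nt")

    def test_two_unrelated_families_split_at_low_identity(self):
        rng = np.random.default_rng(4)
        f1 = _family(rng, 5, 0.02)
        f2 = _family(rng, 5, 0.02)
        seqs = {**{f"a{k}": v for k, v in f1.items()},
                **{f"b{k}": v for k, v in f2.items()}}
        clusters = greedy_cluster(seqs, 0.25, 0.3)
        assert len(clusters) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        seqs = _family(rng, 12, 0.05)
        clusters = greedy_cluster(seqs, 0.95, 0.5)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted(seqs)
        for c in clusters:
            assert c.representative in c.members

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            greedy_cluster({"a": "ACGT"}, 0.0, 0.5)
        with pytest.raises(ValueError):
            greedy_cluster({}, 0.9, 0.5)


class TestWithinGenomeDiversity:
    def test_identical_copies(self):
        seqs = {f"s{i}": "ACGT" * 100 for i in range(10)}
        df = within_genome_diversity(seqs)
        assert list(df["n_clusters"]) == [1, 1, 1]

    def test_monotone_and_family_collapse(self):
        rng = np.random.default_rng(6)
        fam = _family(rng, 40, 0.03)
        df = within_genome_diversity(fam)
        counts = dict(zip(df["threshold"], df["n_clusters"]))
        assert counts[1.00] >= counts[0.98] >= counts[0.50]
        assert counts[0.98] > 1
        assert counts[0.50] == 1

    def test_two_unrelated_families_at_50(self):
        rng = np.random.default_rng(7)
        f1 = _family(rng, 3, 0.01)
        f2 = _family(rng, 3, 0.01)
        seqs = {**{f"a{k}": v for k, v in f1.items()},
                **{f"b{k}": v for k, v in f2.items()}}
        df = within_genome_diversity(seqs)
        assert int(df[df["threshold"] == 0.50]["n_clusters"].iloc[0]) == 2


class TestDereplicate:
    def test_identical_copies_one_representative(self):
        genomes = {"g1": {f"s{i}": "ACGTA" * 60 for i in range(5)}}
        reps = dereplicate_per_genome(genomes)
        assert len(reps) == 1

    def test_no_cross_genome_merging(self):
        rng = np.random.default_rng(8)
        fam = _family(rng, 3, 0.01)
        genomes = {"g1": dict(fam), "g2": dict(fam)}
        reps = dereplicate_per_genome(genomes)
        assert len(reps) == 2  # one per genome despite identical content

    def test_empty_genome_skipped(self):
        genomes = {"g1": {"a": "ACGT" * 50}, "g2": {}}
        reps = dereplicate_per_genome(genomes)
        assert len(reps) == 1


def _mutate_protein(rng, p, n):
    p = list(p)
    for i in rng.choice(len(p), n, replace=False):
        p[i] = "ARNDCQEGHILKMFPSTWYV"[rng.integers(20)]
    return "".join(p)


class TestNetwork:
    def test_homolog_component_plus_singleton(self):
        rng = np.random.default_rng(9)
        anc = random_protein(250, rng)
        prots = {"a": anc,
                 "b": _mutate_protein(rng, anc, 40),
                 "c": _mutate_protein(rng, anc, 40),
                 "x": random_protein(250, rng)}
        net = build_network(prots)
        comps = net.component_members()
        sizes = sorted(len(v) for v in comps.values())
        assert sizes == [1, 3]
        assert {"a", "b", "c"} in [set(v) for v in comps.values()]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_components_equal_transitive_closure(self, seed):
        """Component labels must equal a brute-force closure of the edge
        predicate computed independently of networkx."""
        rng = np.random.default_rng(10 + seed)
        prots = {}
        for f in range(3):
            anc = random_protein(200, rng)
            for i in range(4):
                prots[f"f{f}_{i}"] = _mutate_protein(rng, anc, 30)
        for i in range(5):
            prots[f"r{i}"] = random_protein(200, rng)
        net = build_network(prots)
        ids = sorted(prots)
        adj = {i: set() for i in ids}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                aln = align_protein(prots[a], prots[b])
                if aln is None:
                    continue
                ev = evalue(aln.score, len(prots[a]), len(prots[b]))
                if ev <= 1e-4 and bit_score(aln.score) >= 6:
                    adj[a].add(b)
                    adj[b].add(a)
        seen = set()
        closure = []
        for start in ids:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            closure.append(comp)
        got = [set(v) for v in net.component_members().values()]
        assert sorted(map(sorted, got)) == sorted(map(sorted, closure))

    def test_edge_symmetry(self):
        rng = np.random.default_rng(12)
        a = random_protein(150, rng)
        b = _mutate_protein(rng, a, 20)
        s1 = align_protein(a, b).score
        s2 = align_protein(b, a).score
        assert s1 == s2

    def test_isolated_node_does_not_change_components(self):
        rng = np.random.default_rng(13)
        anc = random_protein(200, rng)
        prots = {"a": anc, "b": _mutate_protein(rng, anc, 30)}
        before = build_network(prots).component_members()
        prots["z"] = random_protein(200, rng)
        after = build_network(prots).component_members()
        before_sets = sorted(map(sorted, before.values()))
        after_sets = sorted(map(sorted, after.values()))
        assert before_sets == [s for s in after_sets if s != ["z"]]

    def test_export_import_round_trip(self):
        rng = np.random.default_rng(14)
        anc = random_protein(180, rng)
        prots = {"a": anc, "b": _mutate_protein(rng, anc, 25),
                 "x": random_protein(180, rng)}
        net = build_network(prots, node_attributes={"a": {"genome": "g1"}})
        edges, nodes = export_network(net)
        again = import_network(edges, nodes)
        assert set(again.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, again.graph.edges)) == \
            set(map(frozenset, net.graph.edges))
        assert again.components == net.components
        assert len(nodes) == len(prots)  # attribute join drops no node

    def test_fewer_than_two_proteins_rejected(self):
        with pytest.raises(ValueError):
            build_network({"a": "MKV"})

    def test_family_recovery_components(self):
        """k simulated families resolve into exactly k components."""
        rng = np.random.default_rng(15)
        ok = 0
        runs = 5
        for r in range(runs):
            k = 2 + r % 4
            prots = {}
            for f in range(k):
                anc = random_protein(220, rng)
                for i in range(3):
                    prots[f"f{f}_{i}"] = _mutate_protein(rng, anc, 11)
            net = build_network(prots)
            ok += net.n_components == k
        assert ok >= 0.95 * runs
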