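"""Colored motif machinery: enumeration, canonical forms, null model,
significance and cross-map calling."""

import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from oracles import (
    brute_canonical,
    brute_colored_census,
    brute_colored_isomorphic,
    graph_codes,
    random_colored_bipartite,
)
from stressnet.graphs import assert_bipartite, to_bipartite
from stressnet.motifs import (
    canonical_signature,
    common_and_specific,
    decode_signature,
    enumerate_colored_subgraphs,
    monocolor_counts,
    monocolor_mode,
    motif_significance,
    switch_randomize,
)
from stressnet.synthetic import reversible_complex_signature


def bip(edges, kinds):
    g = nx.MultiDiGraph()
    for n, k in kinds.items():
        g.add_node(n, kind=k)
    for u, v, c in edges:
        g.add_edge(u, v, key=c, color=c)
    return g


@pytest.fixture
def single_reaction():
    """m1 -[reactant]-> re1 -[product]-> m2, m3 -[modifier]-> re1."""
    return bip(
        [("m1", "re1", "reactant"), ("re1", "m2", "product"),
         ("m3", "re1", "modifier")],
        {"m1": "molecule", "m2": "molecule", "m3": "molecule",
         "re1": "reaction"},
    )


def sig_to_brute_key(sig):
    """Re-encode an implementation signature through the exhaustive-
    permutation canonical form, for cross-keyed count comparison."""
    kinds, mat = decode_signature(sig)
    g = nx.MultiDiGraph()
    for i, kind in enumerate(kinds):
        g.add_node(i, kind=kind)
    for a, row in enumerate(mat):
        for b, colors in enumerate(row):
            for c in colors:
                g.add_edge(a, b, key=c, color=c)
    kind, code = graph_codes(g)
    return brute_canonical(sorted(g.nodes), kind, code)


class TestEnumeration:
    def test_single_reaction_k4(self, single_reaction):
        counts = enumerate_colored_subgraphs(single_reaction, k=4)
        assert sum(counts.values()) == 1 and len(counts) == 1

    def test_disjoint_copies_share_class(self):
        g = bip(
            [("m1", "r1", "reactant"), ("r1", "m2", "product"),
             ("m3", "r2", "reactant"), ("r2", "m4", "product")],
            {"m1": "molecule", "m2": "molecule", "m3": "molecule",
             "m4": "molecule", "r1": "reaction", "r2": "reaction"},
        )
        counts = enumerate_colored_subgraphs(g, k=3)
        assert list(counts.values()) == [2]

    def test_k_larger_than_graph_empty(self, single_reaction):
        assert enumerate_colored_subgraphs(single_reaction, k=6) == Counter()

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_counts_match_subset_enumeration(self, seed, k):
        rng = np.random.default_rng(seed)
        g = random_colored_bipartite(rng, 6, 6, p=0.25)
        got = enumerate_colored_subgraphs(g, k=k)
        want = brute_colored_census(g, k)
        assert sum(got.values()) == sum(want.values())
        regrouped = Counter()
        for sig, c in got.items():
            regrouped[sig_to_brute_key(sig)] += c
        assert regrouped == want


class TestCanonicalSignature:
    def test_relabeling_invariant(self, single_reaction):
        relabeled = nx.relabel_nodes(
            single_reaction, {"m1": "zz", "m2": "aa", "m3": "qq"})
        assert canonical_signature(single_reaction) == canonical_signature(relabeled)

    def test_edge_reversal_changes_signature(self):
        g1 = bip([("m1", "r1", "reactant")],
                 {"m1": "molecule", "r1": "reaction"})
        g2 = bip([("r1", "m1", "product")],
                 {"m1": "molecule", "r1": "reaction"})
        assert canonical_signature(g1) != canonical_signature(g2)

    def test_color_changes_signature(self):
        g1 = bip([("m1", "r1", "reactant")],
                 {"m1": "molecule", "r1": "reaction"})
        g2 = bip([("m1", "r1", "modifier")],
                 {"m1": "molecule", "r1": "reaction"})
        assert canonical_signature(g1) != canonical_signature(g2)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_permutation_isomorphism(self, seed):
        """Signature equality iff a color/kind-honoring node permutation
        exists (50 random pairs per seed)."""
        rng = np.random.default_rng(1000 + seed)
        pool = []
        while len(pool) < 20:
            g = random_colored_bipartite(rng, 3, 3, p=0.5)
            if g.number_of_nodes() == 6:
                pool.append(g)
        for _ in range(50):
            i = rng.integers(len(pool))
            j = rng.integers(len(pool))
            g1, g2 = pool[i], pool[j]
            same_sig = canonical_signature(g1) == canonical_signature(g2)
            assert same_sig == brute_colored_isomorphic(g1, g2)

    def test_decode_inverts_encoding(self, single_reaction):
        sig = canonical_signature(single_reaction)
        kinds, mat = decode_signature(sig)
        assert sorted(kinds) == ["molecule", "molecule", "molecule", "reaction"]
        n_edges = sum(len(colors) for row in mat for colors in row)
        assert n_edges == 3


class TestSwitchRandomize:
    def per_color_degrees(self, g):
        out = {}
        for u, v, c in g.edges(keys=True):
            out.setdefault((u, "out", c), 0)
            out.setdefault((v, "in", c), 0)
            out[(u, "out", c)] += 1
            out[(v, "in", c)] += 1
        return out

    def test_single_edge_per_color_unchanged(self, single_reaction):
        g2 = switch_randomize(single_reaction, seed=1)
        assert set(g2.edges(keys=True)) == set(single_reaction.edges(keys=True))

    @pytest.mark.parametrize("seed", range(5))
    def test_preserves_per_color_degrees_and_bipartiteness(self, seed, module_map):
        m, _ = module_map
        g = to_bipartite(m)
        g2 = switch_randomize(g, seed=seed)
        assert self.per_color_degrees(g2) == self.per_color_degrees(g)
        assert_bipartite(g2)
        assert set(g2.nodes) == set(g.nodes)

    def test_large_graph_actually_moves_edges(self):
        rng = np.random.default_rng(8)
        g = random_colored_bipartite(rng, 12, 12, p=0.35)
        assert g.number_of_edges() > 100
        g2 = switch_randomize(g, seed=3)
        assert set(g2.edges(keys=True)) != set(g.edges(keys=True))

    def test_reproducible_by_seed(self, module_map):
        m, _ = module_map
        g = to_bipartite(m)
        a = switch_randomize(g, seed=11)
        b = switch_randomize(g, seed=11)
        assert set(a.edges(keys=True)) == set(b.edges(keys=True))


class TestSignificance:
    def test_rare_in_null_significant(self, single_reaction):
        real = Counter({"fake:sig": 6})
        cat = motif_significance(real, single_reaction, n_random=20, seed=0, k=4)
        row = cat.loc["fake:sig"]
        assert row["p"] == 0.0 and row["significant"]
        assert math.isinf(row["z"])

    def test_below_min_count_never_significant(self, single_reaction):
        real = Counter({"fake:sig": 3})
        cat = motif_significance(real, single_reaction, n_random=20, seed=0, k=4)
        assert not cat.loc["fake:sig", "significant"]

    def test_null_equal_real_not_significant(self, single_reaction):
        # the graph admits no swaps, so every null count equals the real one
        counts = enumerate_colored_subgraphs(single_reaction, k=4)
        cat = motif_significance(counts, single_reaction, n_random=10, seed=0, k=4)
        sig = next(iter(counts))
        assert cat.loc[sig, "p"] == 1.0
        assert cat.loc[sig, "z"] == 0.0
        assert not cat.loc[sig, "significant"]

    def test_planted_module_detected(self, module_map):
        from stressnet.graphs import drop_trivial_reactions

        m, gt = module_map
        g = drop_trivial_reactions(to_bipartite(m))
        counts = enumerate_colored_subgraphs(g, k=6)
        sig = reversible_complex_signature(with_trigger=True)
        assert counts[sig] >= len(gt.modules) == 8
        cat = motif_significance(counts, g, n_random=10, seed=5, k=6)
        assert cat.loc[sig, "significant"]


class TestCommonAndSpecific:
    def _catalog(self, sig_flags):
        import pandas as pd

        return pd.DataFrame(
            [dict(signature=s, count=c, null_mean=0.0, null_sd=0.0,
                  z=math.inf, p=0.0, significant=f)
             for s, (c, f) in sig_flags.items()]
        ).set_index("signature")

    def test_identical_catalogs(self):
        cat = self._catalog({"a": (6, True), "b": (9, True), "c": (2, False)})
        common, _ = common_and_specific({"m1": cat, "m2": cat})
        assert common == {"a", "b"}

    def test_one_empty_significant_set_kills_common(self):
        full = self._catalog({"a": (6, True)})
        empty = self._catalog({"a": (6, False)})
        common, _ = common_and_specific({"m1": full, "m2": empty})
        assert common == set()

    def test_shared_planted_signatures(self):
        maps = {
            f"m{i}": self._catalog({"a": (6, True), "b": (7, True),
                                    f"x{i}": (5, True)})
            for i in range(3)
        }
        common, _ = common_and_specific(maps)
        assert common == {"a", "b"}

    def test_reference_membership_modes(self):
        stress = self._catalog({"a": (6, True), "b": (6, True)})
        ref = self._catalog({"a": (6, False), "b": (2, False)})
        cats = {"s1": stress, "s2": stress, "ref": ref}
        _, spec_sig = common_and_specific(
            cats, positives={"ref"}, reference_mode="significant")
        assert spec_sig == set()
        _, spec_freq = common_and_specific(
            cats, positives={"ref"}, reference_mode="frequent")
        assert spec_freq == {"a"}

    def test_negatives_subtract(self):
        stress = self._catalog({"a": (6, True), "b": (6, True)})
        neg = self._catalog({"a": (6, True), "b": (1, False)})
        cats = {"s1": stress, "neg": neg}
        common, spec = common_and_specific(cats, negatives={"neg"})
        assert common == {"a", "b"} and spec == {"b"}


class TestMonocolor:
    def test_single_reaction_collapses_colors(self, single_reaction):
        mono = monocolor_mode(single_reaction)
        assert mono.number_of_nodes() == 4
        assert mono.number_of_edges() == 3
        assert {c for _, _, c in mono.edges(keys=True)} == {"link"}

    def test_class_count_never_exceeds_colored(self, module_map):
        m, _ = module_map
        g = to_bipartite(m)
        colored = enumerate_colored_subgraphs(g, k=4)
        mono = monocolor_counts(g, k=4)
        assert len(mono) <= len(colored)
        assert sum(mono.values()) == sum(colored.values())

    def test_colors_distinguish_what_monocolor_cannot(self):
        """Same topology, different colors: two colored classes but a single
        color-blind class."""
        g1 = bip([("m1", "r1", "reactant"), ("m2", "r1", "reactant"),
                  ("r1", "m3", "product")],
                 {"m1": "molecule", "m2": "molecule", "m3": "molecule",
                  "r1": "reaction"})
        g2 = bip([("m1", "r1", "modifier"), ("m2", "r1", "modifier"),
                  ("r1", "m3", "product")],
                 {"m1": "molecule", "m2": "molecule", "m3": "molecule",
                  "r1": "reaction"})
        assert canonical_signature(g1) != canonical_signature(g2)
        mono1 = monocolor_counts(g1, k=4)
        mono2 = monocolor_counts(g2, k=4)
        assert set(mono1) == set(mono2)
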