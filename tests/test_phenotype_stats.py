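"""Phenotype association tests: contingency, rank, paired and Welch tests
against enumeration / closed-form oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import build_map
from stressnet.controllability import ControllabilityResult, analyze
from stressnet.graphs import to_signaling
from stressnet.map_model import Reaction, Species
from stressnet.phenotype_stats import (
    binary_association,
    critical_genes,
    dosage_sensitivity_report,
    mean_comparison,
    paired_fraction_test,
    rank_association,
    read_annotations,
    write_annotations,
)
from stressnet.synthetic import MapGenParams, gen_annotations, gen_stress_map


def annot(rows):
    df = pd.DataFrame(rows)
    df["stress_phenotypes"] = [frozenset()] * len(df)
    return df.set_index("gene")


def make_annotations(genes_flags):
    return annot([
        dict(gene=g, lethal=False, synthetic_lethal=f,
             negative_gi_count=0, copy_number_limit=100.0)
        for g, f in genes_flags.items()
    ])


class TestCriticalGenes:
    def _map_with_critical(self, critical_ids):
        sp = [
            Species(id="t", name="Tor1", entity_class="protein"),
            Species(id="k", name="Kog1", entity_class="protein"),
            Species(id="c", name="TORC1", entity_class="complex",
                    components=["t", "k"]),
            Species(id="x", name="Xyz1", entity_class="protein"),
        ]
        m = build_map(sp, [Reaction(id="r", reactants=["t"], products=["x"])])
        res = ControllabilityResult(
            matching=set(), drivers=set(), n_drivers=1, f_d=0.25, n_nodes=4,
            critical={s.id: (s.id in critical_ids) for s in sp},
        )
        return m, res

    def test_complex_union(self):
        m, res = self._map_with_critical({"c"})
        crit, noncrit = critical_genes(m, res)
        assert crit == {"TOR1", "KOG1"}
        assert noncrit == {"XYZ1"}

    def test_any_critical_node_suffices(self):
        # TOR1 sits in critical complex c and non-critical monomer t
        m, res = self._map_with_critical({"c"})
        crit, noncrit = critical_genes(m, res)
        assert "TOR1" in crit and "TOR1" not in noncrit

    def test_matches_generator_bookkeeping(self):
        m, gt = gen_stress_map(MapGenParams(
            seed=6, n_stimuli=3, n_targets=5, core_size=2, n_intermediates=6))
        res = analyze(to_signaling(m))
        crit, noncrit = critical_genes(m, res)
        by_id = m.species_by_id
        want = set()
        for v, c in res.critical.items():
            if c and by_id[v].entity_class in ("protein", "complex"):
                want |= by_id[v].gene_symbols
                for comp in by_id[v].components:
                    want |= by_id[comp].gene_symbols
        assert crit == want
        assert not crit & noncrit


class TestBinaryAssociation:
    def test_balanced_table_null(self):
        ann = make_annotations(
            {f"a{i}": i < 10 for i in range(20)} | {f"b{i}": i < 10 for i in range(20)}
        )
        r = binary_association(
            {f"a{i}" for i in range(20)}, {f"b{i}" for i in range(20)},
            ann, "synthetic_lethal")
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.table == [[10, 10], [10, 10]]

    def test_margins_equal_group_sizes(self):
        ann = make_annotations({f"g{i}": i % 3 == 0 for i in range(30)})
        a = {f"g{i}" for i in range(12)}
        b = {f"g{i}" for i in range(12, 30)}
        r = binary_association(a, b, ann, "synthetic_lethal")
        assert sum(r.table[0]) == 12 and sum(r.table[1]) == 18

    def test_fisher_matches_hypergeometric_enumeration(self):
        # table [[8,2],[1,9]]: enumerate the conditional distribution
        ann = make_annotations(
            {f"a{i}": i < 8 for i in range(10)} | {f"b{i}": i < 1 for i in range(10)}
        )
        r = binary_association(
            {f"a{i}" for i in range(10)}, {f"b{i}" for i in range(10)},
            ann, "synthetic_lethal", method="fisher")
        assert r.table == [[8, 2], [1, 9]]
        # two-sided Fisher p: sum of all tables with probability <= observed
        n, k_row, k_col = 20, 10, 9
        rv = stats.hypergeom(n, k_col, k_row)
        p_obs = rv.pmf(8)
        want = sum(rv.pmf(x) for x in range(0, 10)
                   if rv.pmf(x) <= p_obs * (1 + 1e-9))
        assert r.p == pytest.approx(want)

    def test_chi2_and_fisher_agree_on_large_cells(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            flags = {f"a{i}": bool(rng.random() < 0.5) for i in range(80)}
            flags |= {f"b{i}": bool(rng.random() < 0.3) for i in range(80)}
            ann = make_annotations(flags)
            a = {g for g in flags if g.startswith("a")}
            b = {g for g in flags if g.startswith("b")}
            chi = binary_association(a, b, ann, "synthetic_lethal")
            if min(min(row) for row in chi.table) < 10:
                continue
            fis = binary_association(a, b, ann, "synthetic_lethal",
                                     method="fisher")
            assert (chi.p < 0.05) == (fis.p < 0.05)

    def test_empty_margin_degenerate(self):
        ann = make_annotations({"a": False, "b": False})
        r = binary_association({"a"}, {"b"}, ann, "synthetic_lethal")
        assert r.degenerate and math.isnan(r.p)

    def test_overlapping_groups_rejected(self):
        ann = make_annotations({"a": True})
        with pytest.raises(ValueError, match="disjoint"):
            binary_association({"a"}, {"a"}, ann, "synthetic_lethal")


class TestRankAssociation:
    def _ann_values(self, values):
        return annot([
            dict(gene=g, lethal=False, synthetic_lethal=False,
                 negative_gi_count=v, copy_number_limit=100.0)
            for g, v in values.items()
        ])

    def test_identical_distributions_maximal_p(self):
        ann = self._ann_values({"a1": 1, "a2": 2, "a3": 3,
                                "b1": 1, "b2": 2, "b3": 3})
        r = rank_association({"a1", "a2", "a3"}, {"b1", "b2", "b3"}, ann)
        assert r.p == pytest.approx(1.0)

    def test_extreme_separation_exact_p(self):
        ann = self._ann_values({"a1": 1, "a2": 2, "a3": 3,
                                "b1": 10, "b2": 11, "b3": 12})
        r = rank_association({"a1", "a2", "a3"}, {"b1", "b2", "b3"}, ann)
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_rejection_rate_matches_permutation_test(self):
        """Normal-approximation rejections track the exact permutation test
        on shifted lognormal samples."""
        rng = np.random.default_rng(7)
        agree = 0
        trials = 30
        for _ in range(trials):
            xa = np.exp(rng.normal(0.8, 0.5, 6))
            xb = np.exp(rng.normal(0.0, 0.5, 6))
            ann = self._ann_values(
                {f"a{i}": v for i, v in enumerate(xa)}
                | {f"b{i}": v for i, v in enumerate(xb)}
            )
            r = rank_association({f"a{i}" for i in range(6)},
                                 {f"b{i}" for i in range(6)}, ann)
            # exact permutation p for the rank-sum statistic
            allv = np.concatenate([xa, xb])
            ranks = stats.rankdata(allv)
            obs = ranks[:6].sum()
            n = len(allv)
            count = total = 0
            for comb in combinations(range(n), 6):
                s = ranks[list(comb)].sum()
                total += 1
                count += abs(s - 6 * (n + 1) / 2) >= abs(obs - 6 * (n + 1) / 2) - 1e-9
            p_exact = count / total
            agree += (r.p < 0.05) == (p_exact < 0.05)
        assert agree >= trials - 2

    def test_all_missing_degenerate(self):
        ann = annot([dict(gene="a", lethal=False, synthetic_lethal=False,
                          negative_gi_count=0, copy_number_limit=1.0)])
        r = rank_association({"zz"}, {"a"}, ann)
        assert r.degenerate


class TestPairedAndWelch:
    def test_equal_pairs(self):
        r = paired_fraction_test([(0.4, 0.4)] * 6)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_fraction_test([(0.5, 0.4)] * 6)
        assert r.degenerate and math.isnan(r.p)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(1)
        pairs = rng.random((6, 2))
        r = paired_fraction_test(pairs)
        d = pairs[:, 0] - pairs[:, 1]
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert r.statistic == pytest.approx(t)
        assert r.p == pytest.approx(p)

    def test_welch_equal_groups(self):
        ann = annot([
            dict(gene=g, lethal=False, synthetic_lethal=False,
                 negative_gi_count=0, copy_number_limit=v)
            for g, v in [("a1", 1.0), ("a2", 2.0), ("b1", 1.0), ("b2", 2.0)]
        ])
        r = mean_comparison({"a1", "a2"}, {"b1", "b2"}, ann)
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        rng = np.random.default_rng(4)
        xa, xb = rng.normal(10, 3, 8), rng.normal(8, 1, 5)
        ann = annot([
            dict(gene=f"a{i}", lethal=False, synthetic_lethal=False,
                 negative_gi_count=0, copy_number_limit=v)
            for i, v in enumerate(xa)
        ] + [
            dict(gene=f"b{i}", lethal=False, synthetic_lethal=False,
                 negative_gi_count=0, copy_number_limit=v)
            for i, v in enumerate(xb)
        ])
        r = mean_comparison({f"a{i}" for i in range(8)},
                            {f"b{i}" for i in range(5)}, ann)
        va, vb = xa.var(ddof=1) / 8, xb.var(ddof=1) / 5
        t = (xa.mean() - xb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 7 + vb ** 2 / 4)
        p = 2 * stats.t.sf(abs(t), df)
        assert r.statistic == pytest.approx(t)
        assert r.p == pytest.approx(p)


class TestDosageSensitivity:
    def _ann_limits(self, limits):
        return annot([
            dict(gene=g, lethal=False, synthetic_lethal=False,
                 negative_gi_count=0, copy_number_limit=v)
            for g, v in limits.items()
        ])

    def test_no_sensitive_genes(self):
        ann = self._ann_limits({f"g{i}": 100.0 for i in range(10)})
        rep = dosage_sensitivity_report(
            {f"g{i}" for i in range(5)}, {f"g{i}" for i in range(5, 10)}, ann)
        assert rep["core_fraction"] == 0.0 and rep["non_core_fraction"] == 0.0
        assert rep["fisher_p"] == pytest.approx(1.0)

    def test_core_enrichment_fractions(self):
        """7 of 76 core genes vs 23 of 564 non-core genes below the limit."""
        limits = {f"c{i}": (5.0 if i < 7 else 50.0) for i in range(76)}
        limits |= {f"n{i}": (5.0 if i < 23 else 50.0) for i in range(564)}
        ann = self._ann_limits(limits)
        rep = dosage_sensitivity_report(
            {g for g in limits if g.startswith("c")},
            {g for g in limits if g.startswith("n")}, ann)
        assert rep["core_fraction"] == pytest.approx(7 / 76)    # 9.2%
        assert rep["non_core_fraction"] == pytest.approx(23 / 564)  # 4.1%
        assert round(100 * rep["core_fraction"], 1) == 9.2
        assert round(100 * rep["non_core_fraction"], 1) == 4.1

    def test_fisher_matches_hypergeometric(self):
        rng = np.random.default_rng(9)
        limits = {f"c{i}": float(np.exp(rng.normal(2, 1.5))) for i in range(15)}
        limits |= {f"n{i}": float(np.exp(rng.normal(3, 1.5))) for i in range(25)}
        ann = self._ann_limits(limits)
        rep = dosage_sensitivity_report(
            {g for g in limits if g.startswith("c")},
            {g for g in limits if g.startswith("n")}, ann)
        (a, b), (c, d) = rep["table"]
        rv = stats.hypergeom(a + b + c + d, a + c, a + b)
        p_obs = rv.pmf(a)
        want = sum(rv.pmf(x) for x in range(0, min(a + b, a + c) + 1)
                   if rv.pmf(x) <= p_obs * (1 + 1e-9))
        assert rep["fisher_p"] == pytest.approx(want)


class TestAnnotationsIO:
    def test_roundtrip(self, tmp_path):
        ann = gen_annotations([f"G{i}" for i in range(10)],
                              critical={"G1", "G2"}, seed=0)
        p = tmp_path / "ann.tsv"
        write_annotations(ann, p)
        back = read_annotations(p)
        assert list(back.index) == list(ann.index)
        assert (back["lethal"] == ann["lethal"]).all()
        assert (back["negative_gi_count"] == ann["negative_gi_count"]).all()
        assert np.allclose(back["copy_number_limit"], ann["copy_number_limit"])
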