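#!/usr/bin/env python
"""Structural controllability of the synthetic map panel.

Maximum matching → driver nodes and f_D per map, critical-node
classification by single-node removal, and the two enrichment comparisons:
critical fractions among high- vs low-bow-tie-score molecules and among
complexes vs monomeric proteins (paired across maps when non-degenerate).
"""

import importlib
from pathlib import Path

import pandas as pd

from stressnet.bowtie import SourceTargetSpec, bowtie_scores
from stressnet.controllability import (
    analyze,
    criticality_summaries,
    write_controllability_tsv,
)
from stressnet.graphs import to_signaling
from stressnet.map_model import collapse_states
from stressnet.phenotype_stats import paired_fraction_test

sim = importlib.import_module("01_simulate_maps")
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rows, pairs_b, pairs_cls = [], [], []
    for m, gt in sim.panel():
        g = to_signaling(m)
        res = analyze(g)
        write_controllability_tsv(res, m, OUT / f"control_{m.name}.tsv")
        merge = collapse_states(m)
        scores = bowtie_scores(g, SourceTargetSpec.from_map(m), merge=merge)
        s = criticality_summaries(res, scores, m, merge=merge)
        rows.append(dict(
            map=m.name, N=res.n_nodes, matching=len(res.matching),
            N_D=res.n_drivers, f_D=round(res.f_d, 3),
            n_critical=sum(res.critical.values()),
            crit_frac_high_b=s["critical_fraction_high_b"],
            crit_frac_low_b=s["critical_fraction_low_b"],
            crit_frac_complex=s["critical_fraction_complexes"],
            crit_frac_protein=s["critical_fraction_proteins"],
        ))
        if s["n_high_b"] and s["n_low_b"]:
            pairs_b.append((s["critical_fraction_high_b"],
                            s["critical_fraction_low_b"]))
        if s["n_complexes"] and s["n_proteins"]:
            pairs_cls.append((s["critical_fraction_complexes"],
                              s["critical_fraction_proteins"]))
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "controllability.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    for label, pairs in (("high vs low bow-tie score", pairs_b),
                         ("complexes vs proteins", pairs_cls)):
        if len(pairs) >= 2:
            r = paired_fraction_test(pairs)
            verdict = ("degenerate (constant difference)" if r.degenerate
                       else f"t={r.statistic:.3f}, p={r.p:.4f}")
            print(f"paired comparison, critical fraction {label}: {verdict}")


if __name__ == "__main__":
    main()
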