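#!/usr/bin/env python
"""Gene-level phenotype associations for the synthetic map panel.

Critical genes (genes of at least one critical protein/complex node) are
compared with non-critical map genes on synthetic annotation tables whose
effect sizes are configurable: synthetic-lethality enrichment (chi-square
and Fisher), negative genetic-interaction counts (Mann-Whitney), lethality
(null by construction) and gTOW dosage sensitivity (copy-number limit ≤ 10,
Fisher).
"""

import importlib
from pathlib import Path

from stressnet.controllability import analyze
from stressnet.graphs import to_signaling
from stressnet.phenotype_stats import (
    binary_association,
    critical_genes,
    dosage_sensitivity_report,
    rank_association,
    write_annotations,
    write_tests_tsv,
)
from stressnet.synthetic import gen_annotations

sim = importlib.import_module("01_simulate_maps")
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    m, gt = sim.panel()[0]
    res = analyze(to_signaling(m))
    crit, noncrit = critical_genes(m, res)
    print(f"{m.name}: {len(crit)} critical genes, {len(noncrit)} non-critical")

    ann = gen_annotations(
        sorted(crit | noncrit), critical=crit,
        p_lethal=0.2,
        p_synthetic_lethal_given_critical=0.6,
        p_synthetic_lethal_given_noncritical=0.3,
        gi_rate_critical=4.0, gi_rate_noncritical=1.0,
        seed=0,
    )
    write_annotations(ann, OUT / "annotations_synthetic.tsv")

    results = [
        binary_association(crit, noncrit, ann, "lethal",
                           name="lethality:chi2"),
        binary_association(crit, noncrit, ann, "synthetic_lethal",
                           name="synthetic_lethality:chi2"),
        binary_association(crit, noncrit, ann, "synthetic_lethal",
                           method="fisher", name="synthetic_lethality:fisher"),
        rank_association(crit, noncrit, ann,
                         name="negative_gi_count:mannwhitney"),
    ]
    write_tests_tsv(results, OUT / "phenotype_tests.tsv")
    for r in results:
        print(f"  {r.comparison}: stat={r.statistic:.3f} p={r.p:.2e} "
              f"(n={r.n_a}/{r.n_b})")

    rep = dosage_sensitivity_report(crit, noncrit, ann, limit_threshold=10)
    print(f"  dosage-sensitive (limit<=10): critical "
          f"{rep['core_sensitive']}/{rep['core_total']} "
          f"({100 * rep['core_fraction']:.1f}%) vs non-critical "
          f"{rep['non_core_sensitive']}/{rep['non_core_total']} "
          f"({100 * rep['non_core_fraction']:.1f}%), "
          f"Fisher p={rep['fisher_p']:.3f}")


if __name__ == "__main__":
    main()
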