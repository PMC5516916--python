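# stressnet

Network analyses of curated molecular interaction maps: bow-tie scoring,
structural controllability, and colored network-motif discovery, for
CellDesigner/SBML process-description maps of signaling pathways (the kind
built for stress-response, EGFR, TLR or mTOR signaling). The package is
aimed at systems biologists who have such a map — or want to simulate one —
and need to answer three architectural questions:

1. **Does the pathway have a bow-tie structure?** With external stimuli as
   sources S and responsive mRNAs as targets T, the *bow-tie score*

       b(m) = #{simple S→T paths containing m} / #{simple S→T paths}

   (directed simple paths, ≤ 30 edges) measures how much of the total
   signal flow funnels through molecule m. Molecules with b(m) > 0.2 are
   candidate bow-tie cores; a weighted variant multiplies each path by the
   |log₂ fold change| of its target mRNA to find the cores carrying signal
   under a specific condition.

2. **How is the network controlled?** In the structural-controllability
   framework, the minimum number of independently actuated *driver nodes*
   is N_D = max(N − |M|, 1), with M a maximum matching of the out-copy /
   in-copy bipartite representation (Hopcroft–Karp). A node whose removal
   strictly increases the driver fraction f_D = N_D/N is *critical*: it is
   a non-redundant transmitter connecting regulators to their targets.
   Critical nodes can be confronted with gene-level phenotypes (viability,
   synthetic lethality, negative genetic interactions, gTOW copy-number
   limits) through the built-in contingency/rank/paired tests.

3. **Which local wiring patterns recur?** The map becomes a bipartite
   graph (molecules and reactions both nodes) with three edge colors —
   reactant, product, modifier — and every connected induced six-node
   subgraph is enumerated exhaustively and scored against color-preserving
   edge-switch randomizations. A class is a *motif* when p < 0.05, z > 2
   and it occurs at least five times. Colored analysis separates patterns
   (e.g., reversible complex formation vs redundant catalysis by one
   enzyme) that a color-blind census cannot distinguish.

A synthetic-map generator (`stressnet.synthetic`) plants layered bow-tie
maps with known cores, reversible inhibitor-complex modules, expression
tables and annotation tables, so the whole pipeline is testable without
any external download.

## Worked example

Generate a synthetic stress-response map and analyze it from the shell:

```
$ stressnet simulate --seed 2 --out demo.xml
wrote demo.xml (127 species, 130 reactions)

$ stressnet bowtie demo.xml --out demo_bowtie.tsv
10640 connecting paths; wrote demo_bowtie.tsv

$ stressnet control demo.xml --out demo_control.tsv
N=127 |M|=44 N_D=83 f_D=0.654; wrote demo_control.tsv
```

The score table is sorted by b; the planted five-molecule core cascade
tops it with b = 1.0 (every stimulus→mRNA path crosses it), and is flagged
`is_core`:

```
molecule_key    b    betweenness  degree  role      is_core
protein:CORE0   1.0  0.0960       21      molecule  True
protein:CORE3   1.0  0.1004        2      molecule  True
...
```

`f_D=0.654` says roughly two thirds of nodes need independent control —
synthetic maps carry many source-like gene/component nodes that each
demand a driver. The same calls are available from Python
(`gen_stress_map`, `bowtie_scores`, `drivers_and_fd`, `critical_nodes`,
`enumerate_colored_subgraphs`, `motif_significance`, `run_pipeline`).

The numbered scripts under `analysis/` run the full study on a six-map
synthetic panel and write their tables to `results/`:
`01_simulate_maps.py` (map statistics), `02_bowtie_scores.py` (score
distributions: each map ends with 5 molecules at b ∈ (0.5, 1], 40 below
0.2, and score/betweenness R² ≈ 0.96), `03_controllability.py` (f_D ≈ 0.62
per map; critical fraction 1.0 among high-score molecules vs ≈ 0.15 among
the rest, paired p < 0.001; complexes vs monomers paired p ≈ 1e-4),
`04_motifs.py` (the planted reversible complex-formation module is a
significant six-node motif in all six maps and survives in the cross-map
common set), `05_phenotype_associations.py` (synthetic-lethality
enrichment of critical genes, χ² p ≈ 3e-3; negative-interaction counts,
Mann–Whitney p ≈ 5e-5).

## Layout

```
src/stressnet/      map_model, sbml_io, graphs, bowtie, controllability,
                    motifs, phenotype_stats, synthetic, pipeline, cli
analysis/           numbered narrative drivers over the package
tests/              pytest suite with independent brute-force oracles
scripts/            acceptance.py
docs/methods.md     models, parameter choices, limitations
```
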