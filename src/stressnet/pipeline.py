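"""End-to-end pipeline: summary → bow-tie → controllability → motifs →
phenotype statistics per map, then cross-map aggregation.

Defaults follow the analysis conventions used throughout the package: path
length cap 30 edges, bow-tie core threshold 0.2, six-node motifs against
100 color-preserving randomizations.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bowtie import (
    BowtieScores,
    SourceTargetSpec,
    bowtie_scores,
    score_r2,
    weighted_bowtie_scores,
    write_scores_tsv,
    DEFAULT_PATH_CAP,
)
from .controllability import (
    analyze,
    criticality_summaries,
    write_controllability_tsv,
)
from .graphs import drop_trivial_reactions, to_bipartite, to_signaling
from .map_model import MolecularMap, collapse_states, map_summary
from .motifs import (
    common_and_specific,
    enumerate_colored_subgraphs,
    motif_significance,
    write_catalog,
)
from .phenotype_stats import paired_fraction_test
from .sbml_io import read_celldesigner


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and map."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; defaults are the standard analysis
    parameters (max_len 30, core threshold 0.2, motif size 6, 100 nulls)."""

    maps: list = field(default_factory=list)  # paths or MolecularMap objects
    sidecar: dict | str | None = None
    expression: dict = field(default_factory=dict)  # map name -> pd.Series
    max_len: int = 30
    core_threshold: float = 0.2
    motif_k: int = 6
    n_random: int = 100
    seed: int = 0
    path_cap: int = DEFAULT_PATH_CAP
    out_dir: str | Path = "stressnet_out"


def _load_maps(config: RunConfig) -> list[MolecularMap]:
    maps = []
    for item in config.maps:
        if isinstance(item, MolecularMap):
            maps.append(item)
        else:
            maps.append(read_celldesigner(item, config=config.sidecar))
    if not maps:
        raise PipelineError("stage load: no maps given")
    return maps


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every map and write the report bundle.

    Outputs per map: summary, bow-tie scores (weighted when an expression
    table is supplied), controllability and motif-catalog TSVs.  Cross-map:
    the binned score-distribution table, paired criticality comparisons and
    the common-motif set.  A JSON manifest records parameters, versions,
    seeds and truncation flags.  Any stage failure aborts with the stage
    name; partial outputs stay on disk next to a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {"maps": {}, "manifest": None}
    stage = "load"
    try:
        maps = _load_maps(config)
        scores_by_map: dict[str, BowtieScores] = {}
        catalogs: dict[str, pd.DataFrame] = {}
        crit_pairs_b: list[tuple[float, float]] = []
        crit_pairs_cls: list[tuple[float, float]] = []
        truncated: dict[str, bool] = {}

        for m in maps:
            name = m.name or f"map{len(bundle['maps'])}"
            mdir = out / name
            mdir.mkdir(exist_ok=True)
            per: dict = {}

            stage = f"summary[{name}]"
            summary = map_summary(m)
            summary.to_csv(mdir / "summary.tsv", sep="\t", index=False)
            per["summary"] = summary

            stage = f"bowtie[{name}]"
            g = to_signaling(m)
            spec = SourceTargetSpec.from_map(m, max_len=config.max_len)
            merge = collapse_states(m)
            expr = config.expression.get(name)
            if expr is not None:
                scores = weighted_bowtie_scores(
                    g, spec, expr, merge=merge, path_cap=config.path_cap
                )
            else:
                scores = bowtie_scores(g, spec, merge=merge,
                                       path_cap=config.path_cap)
            from .bowtie import call_cores

            call_cores(scores, threshold=config.core_threshold)
            write_scores_tsv(scores, mdir / "bowtie.tsv")
            scores_by_map[name] = scores
            truncated[name] = scores.truncated
            per["bowtie"] = scores

            stage = f"controllability[{name}]"
            control = analyze(g)
            write_controllability_tsv(control, m, mdir / "controllability.tsv")
            (mdir / "controllability.json").write_text(json.dumps(dict(
                N=control.n_nodes, matching=len(control.matching),
                N_D=control.n_drivers, f_d=control.f_d,
            ), indent=1))
            summ = criticality_summaries(
                control, scores, m, merge=merge, threshold=config.core_threshold
            )
            per["controllability"] = control
            per["criticality"] = summ
            if summ["n_high_b"] and summ["n_low_b"]:
                crit_pairs_b.append(
                    (summ["critical_fraction_high_b"], summ["critical_fraction_low_b"])
                )
            if summ["n_complexes"] and summ["n_proteins"]:
                crit_pairs_cls.append(
                    (summ["critical_fraction_complexes"],
                     summ["critical_fraction_proteins"])
                )

            stage = f"motifs[{name}]"
            bip = drop_trivial_reactions(to_bipartite(m))
            counts = enumerate_colored_subgraphs(bip, k=config.motif_k)
            catalog = motif_significance(
                counts, bip, n_random=config.n_random, seed=config.seed,
                k=config.motif_k,
            )
            write_catalog(catalog, mdir / "motifs.tsv")
            catalogs[name] = catalog
            per["motifs"] = catalog

            bundle["maps"][name] = per

        stage = "aggregate"
        table2 = table2_report(scores_by_map)
        table2.to_csv(out / "score_distribution.tsv", sep="\t", index=False)
        bundle["score_distribution"] = table2

        common, _ = common_and_specific(catalogs)
        bundle["common_motifs"] = sorted(common)
        (out / "common_motifs.json").write_text(
            json.dumps(sorted(common), indent=1)
        )

        bundle["paired_tests"] = {}
        if len(crit_pairs_b) >= 2:
            bundle["paired_tests"]["critical_high_vs_low_b"] = (
                paired_fraction_test(crit_pairs_b, "critical_high_vs_low_b")
            )
        if len(crit_pairs_cls) >= 2:
            bundle["paired_tests"]["critical_complex_vs_protein"] = (
                paired_fraction_test(crit_pairs_cls, "critical_complex_vs_protein")
            )

        stage = "manifest"
        manifest = dict(
            package_version=__version__,
            python=platform.python_version(),
            parameters=dict(
                max_len=config.max_len, core_threshold=config.core_threshold,
                motif_k=config.motif_k, n_random=config.n_random,
                path_cap=config.path_cap,
            ),
            seed=config.seed,
            maps=sorted(scores_by_map),
            truncation=truncated,
            wall_time_s=round(time.time() - t0, 3),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc


def table2_report(scores_by_map: dict[str, BowtieScores]) -> pd.DataFrame:
    """Binned bow-tie score distribution per map.

    Bins follow the strict-threshold phrasing of the core calls: (0.5, 1.0]
    (member keys listed), (0.2, 0.5], (0, 0.2), exactly 0 — plus the
    score/betweenness R².  Only molecule-role keys (not path endpoints) are
    binned; counts sum to the number of scored merged molecules.
    """
    rows = []
    for name, scores in scores_by_map.items():
        t = scores.table[scores.table["role"] == "molecule"]
        b = t["b"]
        members = sorted(t.index[b > 0.5])
        rows.append(dict(
            map=name,
            n_05_10=int((b > 0.5).sum()),
            members_05_10=";".join(members),
            n_02_05=int(((b > 0.2) & (b <= 0.5)).sum()),
            n_lt_02=int(((b > 0) & (b <= 0.2)).sum()),
            n_zero=int((b == 0).sum()),
            r2=score_r2(scores),
        ))
    return pd.DataFrame(rows)
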