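"""Gene-level phenotype associations for controllability/bow-tie classes.

Maps network classifications (critical vs non-critical genes, bow-tie core
vs non-core genes) onto experimental annotations — single-deletion
viability, synthetic lethality, negative genetic-interaction counts and
gTOW (genetic tug-of-war) copy-number limits — and runs the comparison
tests: chi-square / Fisher exact on binary flags, Mann-Whitney U on counts,
paired t across per-map fraction pairs, and Welch's t on continuous values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .controllability import ControllabilityResult
from .map_model import MolecularMap, genes_of

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "lethal", "synthetic_lethal", "negative_gi_count", "copy_number_limit",
    "stress_phenotypes",
]


@dataclass
class TestResult:
    """One comparison: statistic, p, group sizes, optional 2×2 table."""

    comparison: str
    statistic: float
    p: float
    n_a: int
    n_b: int
    table: list[list[int]] | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# annotation tables

def read_annotations(path) -> pd.DataFrame:
    """TSV (gene, lethal, synthetic_lethal, negative_gi_count,
    copy_number_limit, stress_phenotypes semicolon-separated), indexed by
    gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    for col in ("lethal", "synthetic_lethal"):
        df[col] = df[col].astype(bool)
    df["negative_gi_count"] = df["negative_gi_count"].astype(int)
    if (df["negative_gi_count"] < 0).any():
        raise ValueError("negative_gi_count must be >= 0")
    cnl = df["copy_number_limit"]
    if (cnl.dropna() <= 0).any():
        raise ValueError("copy_number_limit must be positive when present")
    df["stress_phenotypes"] = (
        df["stress_phenotypes"].fillna("").map(
            lambda s: frozenset(x for x in str(s).split(";") if x)
        )
    )
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out["stress_phenotypes"] = out["stress_phenotypes"].map(
        lambda s: ";".join(sorted(s))
    )
    out.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene classification

def critical_genes(
    m: MolecularMap, control: ControllabilityResult
) -> tuple[frozenset[str], frozenset[str]]:
    """(critical, non-critical) gene sets.

    A gene is critical when at least one critical protein or complex node
    contains it; the non-critical universe is the genes of all other
    protein/complex nodes in the map, minus the critical set.
    """
    by_id = m.species_by_id
    crit_nodes = {
        v for v, c in control.critical.items()
        if c and v in by_id and by_id[v].entity_class in ("protein", "complex")
    }
    other_nodes = {
        s.id for s in m.species
        if s.entity_class in ("protein", "complex") and s.id not in crit_nodes
    }
    crit = genes_of(m, crit_nodes)
    noncrit = genes_of(m, other_nodes) - crit
    return frozenset(crit), frozenset(noncrit)


def _annotated(genes, annotations: pd.DataFrame) -> list[str]:
    present = [g for g in sorted(genes) if g in annotations.index]
    dropped = len(genes) - len(present)
    if dropped:
        log.info("%d/%d genes unannotated, excluded from test", dropped, len(genes))
    return present


# ---------------------------------------------------------------------------
# tests

def binary_association(
    group_a, group_b, annotations: pd.DataFrame, flag: str,
    method: str = "chi2", name: str = "",
) -> TestResult:
    """2×2 association of group membership × boolean annotation ``flag``.

    ``method="chi2"``: Pearson chi-square without continuity correction;
    ``method="fisher"``: two-sided Fisher exact.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = _annotated(group_a, annotations)
    b = _annotated(group_b, annotations)
    if not a or not b:
        raise ValueError("both groups must contain annotated genes")
    fa = annotations.loc[a, flag].astype(bool)
    fb = annotations.loc[b, flag].astype(bool)
    table = [[int(fa.sum()), int((~fa).sum())],
             [int(fb.sum()), int((~fb).sum())]]
    name = name or f"{flag}:{method}"
    col_tot = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in col_tot:
        return TestResult(name, math.nan, math.nan, len(a), len(b),
                          table=table, degenerate=True)
    if method == "chi2":
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif method == "fisher":
        stat, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(name, float(stat), float(p), len(a), len(b), table=table)


def rank_association(
    group_a, group_b, annotations: pd.DataFrame, value: str = "negative_gi_count",
    name: str = "",
) -> TestResult:
    """Two-tailed Mann-Whitney U on a numeric annotation; exact null
    distribution for combined n ≤ 20, tie-corrected normal approximation
    otherwise."""
    xa = annotations.loc[_annotated(group_a, annotations), value].dropna().to_numpy(float)
    xb = annotations.loc[_annotated(group_b, annotations), value].dropna().to_numpy(float)
    name = name or f"{value}:mannwhitney"
    if len(xa) == 0 or len(xb) == 0:
        return TestResult(name, math.nan, math.nan, len(xa), len(xb), degenerate=True)
    ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
    method = "exact" if (len(xa) + len(xb) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return TestResult(name, float(res.statistic), float(min(res.pvalue, 1.0)),
                      len(xa), len(xb))


def paired_fraction_test(pairs, name: str = "paired_fractions") -> TestResult:
    """Paired two-tailed t-test on per-map (fractionA, fractionB) pairs."""
    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[0] < 2 or not np.isfinite(arr).all():
        raise ValueError("need >= 2 finite (fractionA, fractionB) pairs")
    diff = arr[:, 0] - arr[:, 1]
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff, 0):  # identical pairs: no difference at all
            return TestResult(name, 0.0, 1.0, len(diff), len(diff),
                              degenerate=True)
        # constant nonzero difference: t is undefined (0 denominator)
        return TestResult(name, math.nan, math.nan, len(diff), len(diff),
                          degenerate=True)
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return TestResult(name, float(t), float(p), len(diff), len(diff))


def mean_comparison(
    group_a, group_b, annotations: pd.DataFrame, value: str = "copy_number_limit",
    name: str = "",
) -> TestResult:
    """Welch's two-tailed t-test (unequal variances, Welch–Satterthwaite
    degrees of freedom) on a continuous annotation."""
    xa = annotations.loc[_annotated(group_a, annotations), value].dropna().to_numpy(float)
    xb = annotations.loc[_annotated(group_b, annotations), value].dropna().to_numpy(float)
    name = name or f"{value}:welch"
    if len(xa) < 2 or len(xb) < 2:
        return TestResult(name, math.nan, math.nan, len(xa), len(xb), degenerate=True)
    if np.allclose(np.concatenate([xa, xb]).std(), 0):
        return TestResult(name, 0.0, 1.0, len(xa), len(xb), degenerate=True)
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return TestResult(name, float(t), float(p), len(xa), len(xb))


def dosage_sensitivity_report(
    core_genes, non_core_genes, annotations: pd.DataFrame,
    limit_threshold: float = 10.0,
) -> dict:
    """Fraction of each group with a gTOW copy-number limit at or below the
    threshold, plus a two-sided Fisher exact p on the 2×2."""
    def sensitive(genes):
        vals = annotations.loc[
            _annotated(genes, annotations), "copy_number_limit"
        ].dropna()
        return int((vals <= limit_threshold).sum()), len(vals)

    k_core, n_core = sensitive(core_genes)
    k_non, n_non = sensitive(non_core_genes)
    if n_core == 0 or n_non == 0:
        raise ValueError("copy_number_limit required for >= 1 gene per group")
    table = [[k_core, n_core - k_core], [k_non, n_non - k_non]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return dict(
        core_sensitive=k_core, core_total=n_core,
        core_fraction=k_core / n_core,
        non_core_sensitive=k_non, non_core_total=n_non,
        non_core_fraction=k_non / n_non,
        fisher_p=float(p), table=table, limit_threshold=limit_threshold,
    )


def write_tests_tsv(results: list[TestResult], path) -> None:
    import json
    from pathlib import Path

    rows = [
        dict(comparison=r.comparison, statistic=r.statistic, p=r.p,
             n_A=r.n_a, n_B=r.n_b, degenerate=r.degenerate)
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    tables = {r.comparison: r.table for r in results if r.table is not None}
    Path(path).with_suffix(".tables.json").write_text(json.dumps(tables, indent=1))
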