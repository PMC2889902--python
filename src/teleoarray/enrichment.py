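"""GO over-representation against a custom array background.

Two historical styles are supported through one machinery: a plain
one-sided Fisher (hypergeometric upper tail) with raw p-values and a low
gene-count floor, and the more conservative EASE score, which removes one
gene from the list-with-term cell before taking the tail — so EASE p-values
are never smaller than Fisher's. Fold enrichment is term frequency in the
list over term frequency in the background. Any gene -> label map (e.g.
tissue annotations) runs through the same functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentStyle:
    """Parameter bundle for one analysis style."""

    min_gene_count: int = 4
    ease_offset: int = 1  # 0 = plain Fisher
    significance: float = 0.05
    multiple_testing: str = "fdr-pct"  # none | bh | fdr-pct

    @classmethod
    def david(cls) -> "EnrichmentStyle":
        return cls(min_gene_count=4, ease_offset=1, multiple_testing="fdr-pct")

    @classmethod
    def gostat(cls) -> "EnrichmentStyle":
        return cls(min_gene_count=3, ease_offset=0, multiple_testing="none")


def _closure(terms, ancestors: dict[str, set[str]] | None):
    out = set()
    for term in terms:
        out.add(term)
        if ancestors:
            out |= ancestors.get(term, set())
    return out


def term_table(
    gene_list,
    background,
    gene_to_terms: dict[str, set[str]],
    min_gene_count: int = 4,
    ancestors: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-term 2x2 margins: list-with-term vs background-with-term.

    The gene list must be a subset of the background (the background is the
    set of array genes carrying annotation, not the genome). Terms whose
    list count falls below ``min_gene_count`` are dropped. When an ancestor
    map is given, a gene annotated to a term counts for all its ancestors.
    """
    gene_list = list(dict.fromkeys(gene_list))
    background = set(background)
    stray = set(gene_list) - background
    if stray:
        raise ValueError(f"gene list not contained in background: {sorted(stray)[:5]}")
    list_total, bg_total = len(gene_list), len(background)
    list_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    listed = set(gene_list)
    for gene in background:
        terms = _closure(gene_to_terms.get(gene, ()), ancestors)
        for term in terms:
            bg_counts[term] = bg_counts.get(term, 0) + 1
            if gene in listed:
                list_counts[term] = list_counts.get(term, 0) + 1
    rows = [
        {
            "term": term,
            "list_count": count,
            "list_total": list_total,
            "bg_count": bg_counts[term],
            "bg_total": bg_total,
        }
        for term, count in sorted(list_counts.items())
        if count >= min_gene_count
    ]
    return pd.DataFrame(
        rows, columns=["term", "list_count", "list_total", "bg_count", "bg_total"]
    )


def ease_fisher(
    list_count: int,
    list_total: int,
    bg_count: int,
    bg_total: int,
    ease_offset: int = 0,
) -> float:
    """One-sided hypergeometric upper-tail p, optionally EASE-penalized.

    The EASE score removes ``ease_offset`` genes (classically one) from the
    list-with-term cell, floored at zero, before taking
    P(X >= k) with X ~ Hypergeom(bg_total, bg_count, list_total). Degenerate
    margins or an empty cell give p = 1.
    """
    if min(list_count, list_total, bg_count, bg_total) < 0:
        raise ValueError("cell counts must be nonnegative")
    k = max(0, list_count - ease_offset)
    if k == 0 or list_total == 0 or bg_count == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, bg_total, bg_count, list_total))


def fold_enrichment(
    list_count: int, list_total: int, bg_count: int, bg_total: int
) -> float:
    """(list frequency of the term) / (background frequency of the term)."""
    if bg_count == 0:
        raise ZeroDivisionError("term absent from the background")
    return (list_count / list_total) / (bg_count / bg_total)


def correct_multiple(p_values, method: str = "bh"):
    """Adjust p-values: ``none``, ``bh`` (step-up), or ``fdr-pct`` (BH x 100)."""
    p = pd.Series(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        adjusted = p.copy()
    elif method in ("bh", "fdr-pct"):
        if p.empty:
            adjusted = p.copy()
        else:
            adjusted = pd.Series(
                multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index
            )
        if method == "fdr-pct":
            adjusted = adjusted * 100.0
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return adjusted


def enrich(
    gene_list,
    background,
    gene_to_terms: dict[str, set[str]],
    style: EnrichmentStyle | None = None,
    ancestors: dict[str, set[str]] | None = None,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full enrichment table, stable-sorted by p-value.

    Columns mirror the classic report layout: term, name, count, percent of
    the list, p-value, fold enrichment, and the multiplicity-adjusted column
    (absent for style ``none``).
    """
    style = style or EnrichmentStyle.david()
    table = term_table(
        gene_list, background, gene_to_terms, style.min_gene_count, ancestors
    )
    if table.empty:
        return pd.DataFrame(
            columns=["term", "name", "count", "percent", "p_value", "fold_enrichment", "fdr"]
        )
    table = table.copy()
    table["p_value"] = [
        ease_fisher(r.list_count, r.list_total, r.bg_count, r.bg_total, style.ease_offset)
        for r in table.itertuples()
    ]
    table["fold_enrichment"] = [
        fold_enrichment(r.list_count, r.list_total, r.bg_count, r.bg_total)
        for r in table.itertuples()
    ]
    table["count"] = table["list_count"]
    table["percent"] = 100.0 * table["list_count"] / table["list_total"]
    table["name"] = table["term"].map(term_names or {}).fillna("")
    table["fdr"] = correct_multiple(table["p_value"], style.multiple_testing)
    table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return table[
        ["term", "name", "count", "percent", "p_value", "fold_enrichment", "fdr"]
    ]


def read_gene_map(path: str) -> dict[str, set[str]]:
    """Two-column TSV (gene, label) -> gene -> set of labels."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "label"], comment="#")
    out: dict[str, set[str]] = {}
    for gene, label in zip(frame["gene"], frame["label"]):
        out.setdefault(str(gene), set()).add(str(label))
    return out


def ancestors_from_obo(path: str) -> dict[str, set[str]]:
    """Term -> ancestor closure over is_a/part_of edges of an OBO ontology."""
    import obonet

    graph = obonet.read_obo(path)
    closure: dict[str, set[str]] = {}

    def walk(term: str) -> set[str]:
        if term in closure:
            return closure[term]
        parents: set[str] = set()
        for _, parent, key in graph.out_edges(term, keys=True):
            if key in ("is_a", "part_of"):
                parents.add(parent)
                parents |= walk(parent)
        closure[term] = parents
        return parents

    for term in graph.nodes:
        walk(term)
    return closure
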