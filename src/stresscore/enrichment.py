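"""Fisher's exact over-representation tests with BH-FDR correction.

One engine serves every enrichment question in the pipeline: TF content
of core sets, per-family TF enrichment, term enrichment, hub/core
overlap, and module-by-gene-set tables.  The one-sided p-value is the
upper hypergeometric tail P(X >= overlap) for the 2x2 table defined by a
query set and an annotation set inside a common gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import ValidationError

TIER_ENRICHED = "enriched"
TIER_NEAR = "near-enriched"
TIER_NS = "ns"


@dataclass
class EnrichmentResult:
    query: str
    annotation: str
    a: int  # in query and annotated
    b: int  # in query, not annotated
    c: int  # not in query, annotated
    d: int  # neither
    odds_ratio: float
    p_value: float
    adjusted_p: float = float("nan")
    tier: str = TIER_NS

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def _tier(adj_p: float) -> str:
    if adj_p < 0.05:
        return TIER_ENRICHED
    if adj_p < 0.1:
        return TIER_NEAR
    return TIER_NS


def fisher_enrichment(
    query: set[str],
    annotated: set[str],
    universe: set[str],
    query_label: str = "query",
    annotation_label: str = "annotation",
) -> EnrichmentResult:
    """One-sided (over-representation) Fisher/hypergeometric test.

    p = P(X >= |query & annotated|) where X is hypergeometric with the
    table's margins.  The odds ratio is the plain cross-product ratio,
    with infinity permitted.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not query:
        raise ValidationError("query set must be non-empty")
    bad = sorted(set(query) - universe)
    if bad:
        raise ValidationError(f"query genes outside universe: {bad[:10]}")
    bad = sorted(set(annotated) - universe)
    if bad:
        raise ValidationError(f"annotated genes outside universe: {bad[:10]}")

    N = len(universe)
    n = len(query)
    K = len(set(annotated))
    a = len(set(query) & set(annotated))
    b = n - a
    c = K - a
    d = N - n - c
    p = float(hypergeom.sf(a - 1, N, K, n))
    p = min(p, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c) if (b * c) else (np.inf if a * d else np.nan)
    return EnrichmentResult(
        query=query_label,
        annotation=annotation_label,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(odds),
        p_value=p,
    )


def fdr_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def propagate_to_ancestors(
    term_to_genes: dict[str, frozenset[str]],
    term_parents: dict[str, tuple[str, ...]],
) -> dict[str, frozenset[str]]:
    """Add each term's genes to all of its ancestors (classic-style input prep)."""
    out = {t: set(g) for t, g in term_to_genes.items()}

    def ancestors(term: str, seen: set[str]) -> set[str]:
        result: set[str] = set()
        for parent in term_parents.get(term, ()):  # cycles guarded by `seen`
            if parent not in seen:
                seen.add(parent)
                result.add(parent)
                result |= ancestors(parent, seen)
        return result

    for term, genes in term_to_genes.items():
        for anc in ancestors(term, {term}):
            out.setdefault(anc, set()).update(genes)
    return {t: frozenset(g) for t, g in out.items()}


def enrichment_table(
    gene_sets: dict[str, set[str]],
    annotations: dict[str, set[str]],
    universe: set[str],
    term_parents: dict[str, tuple[str, ...]] | None = None,
    correction_scope: str = "within_query",
) -> pd.DataFrame:
    """Test every (gene set, annotation) pair; BH-correct and tier the results.

    Per-term tests are independent Fisher tests (the "classic" scheme);
    when ``term_parents`` is given, annotations are first propagated to
    all ancestor terms.  ``correction_scope`` is ``within_query``
    (BH across annotations separately for each query set, the default) or
    ``global``.
    """
    if correction_scope not in ("within_query", "global"):
        raise ValueError("correction_scope must be 'within_query' or 'global'")
    universe = set(universe)
    if term_parents:
        annotations = propagate_to_ancestors(
            {t: frozenset(g) for t, g in annotations.items()}, term_parents
        )
    ann_in_universe = {
        label: set(genes) & universe for label, genes in annotations.items()
    }
    results: list[EnrichmentResult] = []
    for qlabel in sorted(gene_sets):
        for alabel in sorted(ann_in_universe):
            results.append(
                fisher_enrichment(
                    gene_sets[qlabel],
                    ann_in_universe[alabel],
                    universe,
                    query_label=qlabel,
                    annotation_label=alabel,
                )
            )
    df = pd.DataFrame(
        {
            "query": [r.query for r in results],
            "annotation": [r.annotation for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    if correction_scope == "global":
        df["adjusted_p"] = fdr_adjust(df["p_value"].tolist())
    else:
        df["adjusted_p"] = np.nan
        for qlabel in df["query"].unique():
            mask = df["query"] == qlabel
            df.loc[mask, "adjusted_p"] = fdr_adjust(df.loc[mask, "p_value"].tolist())
    df["tier"] = [_tier(q) for q in df["adjusted_p"]]
    return df


def hub_core_overlap_test(
    hubs: set[str], core: set[str], universe: set[str]
) -> EnrichmentResult:
    """Is the core set over-represented among hub genes? (delegates to Fisher)."""
    return fisher_enrichment(
        core, hubs, universe, query_label="core", annotation_label="hubs"
    )
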