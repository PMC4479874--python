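"""Regulation analyses on a CCRN.

How do cells avoid competition between proteins that bind the same interface?
The analyses here test three mechanisms:

* transcriptional divergence — competitive pairs should be less co-expressed
  (lower Pearson correlation of expression profiles) than cooperative pairs;
* alternative splicing — species-specific proteins should be enriched among
  multi-isoform proteins, and their interaction domains should carry more
  alternatively spliced / variant residues;
* competition strength — ranking competitive edges by the surface area buried
  at the shared interface (dASA) and removing the weak ones should sharpen
  the splicing enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ccrn.ccrn_construction import CCRN, Relation, RelationshipEdge
from ccrn.statistics import (
    ContingencyTable2x2,
    Direction,
    TestResult,
    fisher_exact_one_tailed,
    wilcoxon_rank_sum_one_tailed,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionComparison:
    test: TestResult
    median_competitive: float
    median_cooperative: float
    n_competitive: int
    n_cooperative: int


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    p_value: float


@dataclass(frozen=True)
class CompetitionStrength:
    edge: RelationshipEdge
    mean_delta_asa: float

    def __post_init__(self) -> None:
        if self.mean_delta_asa < 0:
            raise ValueError("mean_delta_asa must be non-negative")


# ---------------------------------------------------------------------------
# Expression divergence
# ---------------------------------------------------------------------------

def pair_pcc(
    protein_a: str,
    protein_b: str,
    gene_map: Mapping[str, Sequence[str]],
    gene_pcc: Mapping[frozenset, float],
) -> float | None:
    """Expression correlation of a protein pair via its gene identifiers.

    A protein may map to several gene IDs; the pair's value is the arithmetic
    mean of the correlations over all gene-ID combinations with an available
    value.  Returns ``None`` when no combination has a value (the pair is
    excluded from comparisons).
    """
    genes_a = gene_map.get(protein_a, ())
    genes_b = gene_map.get(protein_b, ())
    values = []
    for ga in genes_a:
        for gb in genes_b:
            if ga == gb:
                continue
            v = gene_pcc.get(frozenset((ga, gb)))
            if v is not None:
                values.append(v)
    if not values:
        return None
    return float(np.mean(values))


def gene_pcc_from_matrix(expression: pd.DataFrame) -> dict[frozenset, float]:
    """All pairwise Pearson correlations from a genes x samples matrix."""
    mat = expression.to_numpy(dtype=float)
    genes = list(expression.index)
    corr = np.corrcoef(mat)
    out: dict[frozenset, float] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            v = corr[i, j]
            if np.isfinite(v):
                out[frozenset((genes[i], genes[j]))] = float(v)
    return out


def compare_pair_expression(
    net: CCRN,
    gene_map: Mapping[str, Sequence[str]],
    gene_pcc: Mapping[frozenset, float],
    alternative: Direction = Direction.Y_GREATER,
) -> ExpressionComparison:
    """One-tailed Wilcoxon on competitive-pair vs cooperative-pair PCCs.

    With the default ``y_greater`` alternative, sample x holds competitive
    pairs and sample y cooperative pairs, testing whether competitive pairs
    are *less* co-expressed.  Pairs without an available correlation are
    excluded (and logged).
    """
    comp, coop = [], []
    skipped = 0
    for e in net.edges():
        v = pair_pcc(e.protein_a, e.protein_b, gene_map, gene_pcc)
        if v is None:
            skipped += 1
            continue
        (comp if e.relation is Relation.COMPETITIVE else coop).append(v)
    if skipped:
        logger.info("compare_pair_expression: %d pairs without PCC excluded", skipped)
    if len(comp) < 2 or len(coop) < 2:
        raise ValueError("need at least 2 pairs with PCC in each relation class")
    test = wilcoxon_rank_sum_one_tailed(comp, coop, alternative)
    return ExpressionComparison(
        test=test,
        median_competitive=float(np.median(comp)),
        median_cooperative=float(np.median(coop)),
        n_competitive=len(comp),
        n_cooperative=len(coop),
    )


# ---------------------------------------------------------------------------
# Alternative splicing / isoforms
# ---------------------------------------------------------------------------

def isoform_enrichment(
    specific: Iterable[str],
    nonspecific: Iterable[str],
    isoform_counts: Mapping[str, int],
) -> EnrichmentResult:
    """Are multi-isoform proteins enriched among the species-specific set?

    Builds the 2x2 table (rows: isoform count > 1 vs = 1; columns: specific
    vs non-specific) and applies the one-tailed Fisher's exact test for
    enrichment of multi-isoform proteins among the specific group.  Proteins
    without an isoform count are excluded (and logged).
    """
    specific, nonspecific = set(specific), set(nonspecific)
    if not specific or not nonspecific:
        raise ValueError("both groups must be non-empty")

    def split(group: set[str]) -> tuple[int, int]:
        multi = single = missing = 0
        for p in group:
            c = isoform_counts.get(p)
            if c is None:
                missing += 1
            elif c > 1:
                multi += 1
            else:
                single += 1
        if missing:
            logger.info("isoform_enrichment: %d proteins without counts excluded", missing)
        return multi, single

    multi_s, single_s = split(specific)
    multi_n, single_n = split(nonspecific)
    table = ContingencyTable2x2(a=multi_s, b=multi_n, c=single_s, d=single_n)
    p = fisher_exact_one_tailed(table, alternative="greater")
    return EnrichmentResult(table=table, p_value=p)


def _interval_union(intervals: Iterable[tuple[int, int]]) -> set[int]:
    residues: set[int] = set()
    for start, end in intervals:
        if start > end:
            raise ValueError(f"invalid interval [{start}, {end}]")
        residues.update(range(start, end + 1))
    return residues


def annotated_fraction(
    domain_intervals: Iterable[tuple[int, int]],
    annotation_intervals: Iterable[tuple[int, int]],
) -> float | None:
    """Fraction of interaction-domain residues covered by an annotation.

    Both interval lists are 1-based closed intervals on the same protein.
    Returns ``None`` (undefined) for an empty domain union.
    """
    domain = _interval_union(domain_intervals)
    if not domain:
        return None
    annotation = _interval_union(annotation_intervals)
    return len(domain & annotation) / len(domain)


def domain_type_comparison(
    specific: Iterable[str],
    nonspecific: Iterable[str],
    domain_map: Mapping[str, Iterable[str]],
) -> tuple[TestResult, float, float]:
    """Do specific proteins carry more distinct domain types?

    One-tailed Wilcoxon (specific greater) on per-protein distinct domain-type
    counts; also returns the fraction of proteins with more than 2 domain
    types in each group.
    """
    specific, nonspecific = list(specific), list(nonspecific)
    if not specific or not nonspecific:
        raise ValueError("both groups must be non-empty")
    counts_s = [len(set(domain_map.get(p, ()))) for p in specific]
    counts_n = [len(set(domain_map.get(p, ()))) for p in nonspecific]
    test = wilcoxon_rank_sum_one_tailed(counts_s, counts_n, Direction.X_GREATER)
    frac_s = sum(1 for c in counts_s if c > 2) / len(counts_s)
    frac_n = sum(1 for c in counts_n if c > 2) / len(counts_n)
    return test, frac_s, frac_n


# ---------------------------------------------------------------------------
# Competition strength (dASA) filtering
# ---------------------------------------------------------------------------

def competitive_edge_strengths(
    net: CCRN,
    interaction_delta_asa: Mapping[tuple[str, str], float],
    aggregation: str = "max_jaccard",
) -> list[CompetitionStrength]:
    """Mean dASA of the two competitor-common interactions behind each edge.

    ``interaction_delta_asa`` maps unordered (protein, protein) pairs of the
    underlying PPI network to their buried surface area.  With the default
    aggregation the common protein of the maximal-Jaccard evidence entry
    defines the edge's strength; ``aggregation='mean'`` averages over all
    evidence entries instead.
    """
    if aggregation not in ("max_jaccard", "mean"):
        raise ValueError("aggregation must be 'max_jaccard' or 'mean'")

    def interaction(a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        if key not in interaction_delta_asa:
            raise KeyError(key)
        return interaction_delta_asa[key]

    out = []
    missing = []
    for e in net.edges(Relation.COMPETITIVE):
        try:
            if aggregation == "max_jaccard":
                common = max(e.evidence, key=lambda cj: cj[1])[0]
                strength = 0.5 * (
                    interaction(e.protein_a, common) + interaction(e.protein_b, common)
                )
            else:
                per_common = [
                    0.5 * (interaction(e.protein_a, c) + interaction(e.protein_b, c))
                    for c, _ in e.evidence
                ]
                strength = float(np.mean(per_common))
        except KeyError as exc:
            missing.append((e.pair, exc.args[0]))
            continue
        out.append(CompetitionStrength(edge=e, mean_delta_asa=strength))
    if missing:
        raise ValueError(
            f"dASA missing for {len(missing)} competitive edges, e.g. {missing[:3]}"
        )
    return out


def strength_filter_scan(
    net: CCRN,
    strengths: Sequence[CompetitionStrength],
    specific: Iterable[str],
    nonspecific: Iterable[str],
    isoform_counts: Mapping[str, int],
    removal_fractions: Sequence[float] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1)),
) -> pd.DataFrame:
    """Splicing enrichment as weak competitive edges are progressively removed.

    For each removal fraction f the f weakest competitive edges (by mean dASA)
    are dropped, the specific proteins still incident to a competitive edge
    are re-collected, and the isoform enrichment test is re-run against the
    unchanged non-specific group.  At f = 1 no competitive edge remains and
    the p-value is undefined (NaN).
    """
    specific = set(specific)
    nonspecific = set(nonspecific)
    comp_edges = net.edges(Relation.COMPETITIVE)
    by_pair = {s.edge.pair: s.mean_delta_asa for s in strengths}
    missing = [e.pair for e in comp_edges if e.pair not in by_pair]
    if missing:
        raise ValueError(f"strength missing for competitive edges: {missing[:5]}")
    ordered = sorted(comp_edges, key=lambda e: (by_pair[e.pair], e.pair))  # weakest first
    n = len(ordered)
    rows = []
    for f in removal_fractions:
        if not 0 <= f <= 1:
            raise ValueError("removal fractions must lie in [0, 1]")
        n_removed = int(round(f * n))
        kept = ordered[n_removed:]
        incident = {p for e in kept for p in e.pair}
        spec_kept = specific & incident
        row = {"removal_fraction": float(f), "n_competitive_edges": len(kept),
               "n_specific_with_competition": len(spec_kept)}
        try:
            result = isoform_enrichment(spec_kept, nonspecific, isoform_counts)
            row["p_value"] = result.p_value
        except ValueError:
            row["p_value"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
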