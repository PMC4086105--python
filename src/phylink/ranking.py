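"""Two-key candidate ranking: Hamming distance first, Pearson second.

Candidates are ordered by evolutionary similarity (Hamming distance,
ascending) and, within equal distance, by expression correlation
(Pearson r, descending). Candidates with low correlation (r < 0.2 by
default) are dropped before ranking — note this discards anti-correlated
genes by design, since any negative r is below the cutoff. Exact
(distance, r) ties are broken by gene identifier so the order is a total
order and results are bit-reproducible.

There is deliberately no composite numeric score blending the two keys:
the order is lexicographic, with evolution always dominating expression.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

from .expression import CorrelationRecord
from .profiles import DistanceRecord

__all__ = ["RankingConfig", "RankedCandidate", "rank_candidates",
           "rank_candidates_evolution_only"]


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of the filter-and-rank scheme.

    min_corr
        Candidates with r below this (or with undefined r) are excluded;
        default 0.2.
    top_n
        Output list length; default 125.
    missing_expression_policy
        ``"exclude"`` (default) drops candidates absent from the
        expression atlas; ``"keep_with_sentinel"`` retains them with an
        undefined r, sorted after all real-r candidates of equal Hamming
        distance.
    """

    min_corr: float = 0.2
    top_n: int = 125
    missing_expression_policy: str = "exclude"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_corr <= 1.0):
            raise ValueError(f"min_corr must be in [0, 1], got {self.min_corr!r}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n!r}")
        if self.missing_expression_policy not in ("exclude", "keep_with_sentinel"):
            raise ValueError(
                "missing_expression_policy must be 'exclude' or "
                f"'keep_with_sentinel', got {self.missing_expression_policy!r}"
            )


@dataclass(frozen=True)
class RankedCandidate:
    """One output row: gene, its two sort keys, and its 1-based rank."""

    gene: str
    hamming: int
    r: float
    rank: int


def _is_undefined(r: float | None) -> bool:
    return r is None or math.isnan(r)


def rank_candidates(
    query_gene: str,
    distances: Sequence[DistanceRecord],
    correlations: Sequence[CorrelationRecord],
    config: RankingConfig = RankingConfig(),
) -> list[RankedCandidate]:
    """Filter and rank candidates for one query gene.

    Steps, in order: (1) drop candidates with r < min_corr, undefined r,
    or — under the default exclude policy — no expression record at all;
    (2) sort by Hamming distance ascending; (3) within equal distance, by
    r descending; (4) exact ties by gene id ascending; (5) truncate to
    top_n; (6) assign 1-based ranks.
    """
    corr_by_gene: dict[str, float] = {}
    for rec in correlations:
        if rec.gene_a != query_gene:
            raise ValueError(
                f"correlation record for query {rec.gene_a!r}, expected {query_gene!r}"
            )
        if rec.gene_b == query_gene:
            raise ValueError("the query gene must not appear among its candidates")
        corr_by_gene[rec.gene_b] = rec.r

    keyed: list[tuple[tuple, str, int, float]] = []
    for rec in distances:
        if rec.gene_a != query_gene:
            raise ValueError(
                f"distance record for query {rec.gene_a!r}, expected {query_gene!r}"
            )
        if rec.gene_b == query_gene:
            raise ValueError("the query gene must not appear among its candidates")
        gene, h = rec.gene_b, rec.hamming
        r = corr_by_gene.get(gene)
        if gene not in corr_by_gene:
            if config.missing_expression_policy == "exclude":
                continue
            # sentinel candidates sort after all real-r ones of equal hamming
            keyed.append(((h, 1, 0.0, gene), gene, h, math.nan))
            continue
        if _is_undefined(r) or r < config.min_corr:
            continue
        keyed.append(((h, 0, -r, gene), gene, h, r))

    keyed.sort(key=lambda item: item[0])
    return [
        RankedCandidate(gene=g, hamming=h, r=r, rank=i)
        for i, (_, g, h, r) in enumerate(keyed[: config.top_n], start=1)
    ]


def rank_candidates_evolution_only(
    query_gene: str,
    distances: Sequence[DistanceRecord],
    top_n: int = 125,
) -> list[RankedCandidate]:
    """Rank by Hamming distance alone: no correlation filter or key.

    Ties are broken by gene identifier; r is reported as the undefined
    sentinel since expression evidence was not consulted.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n!r}")
    recs = []
    for rec in distances:
        if rec.gene_a != query_gene:
            raise ValueError(
                f"distance record for query {rec.gene_a!r}, expected {query_gene!r}"
            )
        if rec.gene_b == query_gene:
            raise ValueError("the query gene must not appear among its candidates")
        recs.append((rec.hamming, rec.gene_b))
    recs.sort()
    return [
        RankedCandidate(gene=g, hamming=h, r=math.nan, rank=i)
        for i, (h, g) in enumerate(recs[:top_n], start=1)
    ]
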