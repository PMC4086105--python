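"""Binary phyletic profiles and pairwise Hamming distances.

A gene's phyletic profile is a binary vector over a fixed, ordered species
universe: coordinate *s* is 1 when the gene's profile-HMM search finds, in
species *s*, at least one domain with conditional E-value strictly below
the presence threshold (default 1e-7). Genes under shared selective
pressure tend to be retained or lost in the same lineages, so a small
Hamming distance between two profiles is evidence of co-evolution.

The threshold comparison is a strict ``<``: a domain at exactly the
threshold does NOT call presence. E-value ties at the cutoff occur in
practice, so this choice is load-bearing and tested explicitly.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import HomologyHit, SpeciesUniverse

__all__ = [
    "DEFAULT_EVALUE_THRESHOLD",
    "PhyleticProfileMatrix",
    "DistanceRecord",
    "build_profiles",
    "hamming_distance",
    "distances_to_query",
]

DEFAULT_EVALUE_THRESHOLD = 1e-7


@dataclass(frozen=True)
class DistanceRecord:
    """Hamming distance between one candidate gene and the query."""

    gene_a: str
    gene_b: str
    hamming: int


@dataclass
class PhyleticProfileMatrix:
    """Gene x species presence/absence matrix with its provenance.

    ``bits`` is a ``(n_genes, universe.size)`` uint8 array over {0, 1};
    ``evalue_threshold`` records the presence rule used to build it.
    """

    genes: list[str]
    universe: SpeciesUniverse
    bits: np.ndarray
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape != (len(self.genes), self.universe.size):
            raise ValueError(
                f"bits shape {self.bits.shape} does not match "
                f"{len(self.genes)} genes x {self.universe.size} species"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile cells must be 0 or 1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in profile matrix")
        self._row_index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.bits[self._row_index[gene]]

    def __contains__(self, gene: object) -> bool:
        return gene in self._row_index

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.genes, columns=list(self.universe.taxa))

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        universe: SpeciesUniverse | None = None,
        evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    ) -> "PhyleticProfileMatrix":
        """Build from a labelled binary DataFrame (columns = taxa).

        When ``universe`` is given, columns are reordered to match it and
        must agree as a set; otherwise column order defines the universe.
        """
        if universe is None:
            universe = SpeciesUniverse([str(c) for c in df.columns])
        else:
            if set(map(str, df.columns)) != set(universe.taxa):
                raise ValueError("matrix columns do not match the species universe")
            df = df[list(universe.taxa)]
        return cls(
            genes=[str(g) for g in df.index],
            universe=universe,
            bits=df.to_numpy(dtype=np.uint8),
            evalue_threshold=evalue_threshold,
        )


def build_profiles(
    hits: Iterable[HomologyHit],
    universe: SpeciesUniverse,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
    gene_roster: Sequence[str] | None = None,
    policy: str = "skip",
) -> PhyleticProfileMatrix:
    """Collapse per-domain hits into a binary presence/absence matrix.

    Cell (g, s) is 1 iff some hit of gene *g* in species *s* has
    ``domain_evalue < threshold`` (strict). Aggregation over domains and
    paralogous targets is a plain OR, so hit order is irrelevant.

    Parameters
    ----------
    hits
        Parsed homology hits (one per domain row).
    universe
        Species defining the profile coordinates.
    threshold
        Presence E-value cutoff; a hit at exactly the threshold is absent.
    gene_roster
        Optional full gene list; roster genes with no qualifying hits get
        all-zero rows instead of being dropped, and the roster fixes row
        order. Without a roster, rows are the sorted query genes seen.
    policy
        ``"skip"`` ignores hits whose species is outside the universe;
        ``"strict"`` raises on the first such hit.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    if policy not in ("skip", "strict"):
        raise ValueError(f"policy must be 'skip' or 'strict', got {policy!r}")

    present: set[tuple[str, str]] = set()
    seen_genes: set[str] = set()
    for hit in hits:
        if hit.target_species not in universe:
            if policy == "strict":
                raise ValueError(
                    f"hit for gene {hit.query_gene!r} references species "
                    f"{hit.target_species!r} outside the universe"
                )
            continue
        seen_genes.add(hit.query_gene)
        if hit.domain_evalue < threshold:
            present.add((hit.query_gene, hit.target_species))

    if gene_roster is not None:
        genes = list(gene_roster)
        if len(set(genes)) != len(genes):
            raise ValueError("gene_roster contains duplicates")
    else:
        genes = sorted(seen_genes)

    bits = np.zeros((len(genes), universe.size), dtype=np.uint8)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, species in present:
        gi = gene_index.get(gene)
        if gi is not None:
            bits[gi, universe.index_of(species)] = 1
    return PhyleticProfileMatrix(
        genes=genes, universe=universe, bits=bits, evalue_threshold=threshold
    )


def hamming_distance(profile_a: np.ndarray, profile_b: np.ndarray) -> int:
    """Number of coordinates at which two equal-length binary vectors differ."""
    a = np.asarray(profile_a)
    b = np.asarray(profile_b)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def distances_to_query(
    query_gene: str,
    matrix: PhyleticProfileMatrix,
    exclude_all_zero: bool = False,
) -> list[DistanceRecord]:
    """Hamming distance from the query to every other gene in the matrix.

    The self-pair is excluded. With ``exclude_all_zero=True``, genes whose
    profile is all zeros are dropped from the candidate pool: such a
    profile's distance to the query equals the query's presence count and
    carries no co-evolution signal.
    """
    if query_gene not in matrix:
        raise KeyError(f"query gene {query_gene!r} is not a row of the matrix")
    q = matrix.row(query_gene)
    diffs = np.count_nonzero(matrix.bits != q[np.newaxis, :], axis=1)
    nonzero = matrix.bits.any(axis=1)
    records = []
    for i, gene in enumerate(matrix.genes):
        if gene == query_gene:
            continue
        if exclude_all_zero and not nonzero[i]:
            continue
        records.append(DistanceRecord(query_gene, gene, int(diffs[i])))
    return records
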