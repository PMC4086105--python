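"""Readers and writers for the external formats the pipeline touches.

Everything downstream works on in-memory types built here: homology hits
parsed from HMMER3 per-domain tabular output (the ``domtblout`` dialect),
a species universe defining the coordinate system of phyletic profiles,
labelled gene x column matrices from TSV, and gene-set collections from
GMT files. Identifiers are opaque, case-sensitive strings throughout; no
symbol-to-ID conversion is ever attempted.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "HomologyHit",
    "SpeciesUniverse",
    "GeneSetCollection",
    "DomtbloutResult",
    "ParseDiagnostic",
    "read_domtblout",
    "read_species_universe",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "write_ranked_results",
    "read_ranked_results",
    "read_taxon_map",
]

#: Minimum column count of a HMMER3 per-domain table row (22 numbered
#: columns plus the free-text description).
DOMTBLOUT_MIN_COLS = 23

# 0-based column indices in the per-domain table.
_COL_TARGET_NAME = 0
_COL_QUERY_NAME = 3
_COL_FULL_EVALUE = 6
_COL_DOM_C_EVALUE = 11


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class HomologyHit:
    """One domain match of a gene's profile HMM against a target proteome.

    ``domain_evalue`` is the per-domain conditional E-value used by the
    presence rule; ``full_evalue`` is the full-sequence E-value, retained
    for provenance but not consulted when calling presence.
    """

    query_gene: str
    target_species: str
    domain_evalue: float
    full_evalue: float

    def __post_init__(self) -> None:
        if not self.query_gene or not self.target_species:
            raise ValueError("query_gene and target_species must be non-empty")
        if not (self.domain_evalue > 0 and self.full_evalue > 0):
            raise ValueError(
                f"E-values must be positive, got domain={self.domain_evalue!r} "
                f"full={self.full_evalue!r}"
            )


class SpeciesUniverse:
    """Ordered, immutable list of taxa defining profile coordinates.

    The ordering is fixed at construction and gives each taxon a stable
    column index in every phyletic profile built against this universe.
    """

    def __init__(self, taxa: Sequence[str]):
        taxa = tuple(taxa)
        if not taxa:
            raise ValueError("species universe must contain at least one taxon")
        seen: dict[str, int] = {}
        for i, t in enumerate(taxa):
            if t in seen:
                raise ValueError(
                    f"duplicate taxon {t!r} at positions {seen[t]} and {i}"
                )
            seen[t] = i
        self._taxa = taxa
        self._index = seen

    @property
    def taxa(self) -> tuple[str, ...]:
        return self._taxa

    @property
    def size(self) -> int:
        return len(self._taxa)

    def index_of(self, taxon: str) -> int:
        return self._index[taxon]

    def __contains__(self, taxon: object) -> bool:
        return taxon in self._index

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self):
        return iter(self._taxa)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpeciesUniverse) and other._taxa == self._taxa

    def __repr__(self) -> str:
        return f"SpeciesUniverse(size={self.size})"


@dataclass
class GeneSetCollection:
    """Mapping of annotation term -> member genes, with descriptions.

    Local stand-in for web-service annotation clusters: a flat collection
    of named gene sets, typically loaded from a GMT file.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")

    def terms_for(self, gene: str) -> frozenset[str]:
        """All terms annotating ``gene`` (empty set if unannotated)."""
        return frozenset(t for t, gs in self.sets.items() if gene in gs)

    def build_gene_index(self) -> dict[str, frozenset[str]]:
        """Invert the collection into gene -> terms for repeated lookup."""
        idx: dict[str, set[str]] = {}
        for term, genes in self.sets.items():
            for g in genes:
                idx.setdefault(g, set()).add(term)
        return {g: frozenset(ts) for g, ts in idx.items()}

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class ParseDiagnostic:
    """A skipped input line with its 1-based line number and reason."""

    line_number: int
    reason: str


@dataclass
class DomtbloutResult:
    """Parsed hits plus per-line diagnostics for skipped rows.

    Under ``policy="skip"`` every non-comment line becomes either a hit or
    a diagnostic, so ``len(hits) + len(diagnostics)`` equals the number of
    data lines.
    """

    hits: list[HomologyHit]
    diagnostics: list[ParseDiagnostic]

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _default_taxon_resolver(target_name: str) -> str | None:
    """Taxon = second '|'-delimited token of the target sequence name.

    Proteome FASTA header conventions vary; this default suits headers of
    the shape ``seqid|taxon|...`` and can be replaced by an explicit
    mapping or callable.
    """
    tokens = target_name.split("|")
    if len(tokens) >= 2 and tokens[1]:
        return tokens[1]
    return None


def read_domtblout(
    path: str | Path,
    taxon_map: Mapping[str, str] | Callable[[str], str | None] | None = None,
    policy: str = "skip",
) -> DomtbloutResult:
    """Parse a HMMER3 per-domain tabular file into homology hits.

    One :class:`HomologyHit` is produced per data line (one line per
    matched domain; best-domain aggregation happens later, in the profiles
    module). Lines starting with ``#`` are comments.

    Parameters
    ----------
    path
        Path to the per-domain table.
    taxon_map
        How to resolve a target sequence name to a taxon: a mapping, a
        callable returning the taxon (or None when unresolvable), or None
        for the default "second '|'-delimited token" rule.
    policy
        ``"skip"`` (default) collects malformed lines and unresolvable
        targets as diagnostics; ``"strict"`` raises on the first problem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such domtblout file: {path}")
    if policy not in ("skip", "strict"):
        raise ValueError(f"policy must be 'skip' or 'strict', got {policy!r}")

    if taxon_map is None:
        resolve: Callable[[str], str | None] = _default_taxon_resolver
    elif callable(taxon_map):
        resolve = taxon_map
    else:
        mapping = dict(taxon_map)
        resolve = mapping.get

    hits: list[HomologyHit] = []
    diagnostics: list[ParseDiagnostic] = []

    def problem(lineno: int, reason: str) -> None:
        if policy == "strict":
            raise FormatError(f"{path}:{lineno}: {reason}")
        diagnostics.append(ParseDiagnostic(lineno, reason))

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < DOMTBLOUT_MIN_COLS:
                problem(lineno, f"expected >= {DOMTBLOUT_MIN_COLS} columns, got {len(cols)}")
                continue
            target_name = cols[_COL_TARGET_NAME]
            query_gene = cols[_COL_QUERY_NAME]
            try:
                full_evalue = float(cols[_COL_FULL_EVALUE])
                domain_evalue = float(cols[_COL_DOM_C_EVALUE])
            except ValueError:
                problem(lineno, f"unparseable E-value fields: "
                                f"{cols[_COL_FULL_EVALUE]!r} / {cols[_COL_DOM_C_EVALUE]!r}")
                continue
            taxon = resolve(target_name)
            if taxon is None:
                problem(lineno, f"no resolvable taxon for target {target_name!r}")
                continue
            try:
                hits.append(HomologyHit(query_gene, taxon, domain_evalue, full_evalue))
            except ValueError as exc:
                problem(lineno, str(exc))

    return DomtbloutResult(hits=hits, diagnostics=diagnostics)


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read an explicit two-column (sequence name, taxon) TSV mapping."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields")
            mapping[parts[0]] = parts[1]
    return mapping


def read_species_universe(path: str | Path) -> SpeciesUniverse:
    """Read a one-taxon-per-line universe file, preserving file order.

    Blank lines and ``#`` comments are ignored. A repeated taxon is fatal,
    with both line numbers reported.
    """
    taxa: list[str] = []
    first_line: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            taxon = raw.strip()
            if not taxon or taxon.startswith("#"):
                continue
            if taxon in first_line:
                raise FormatError(
                    f"{path}: duplicate taxon {taxon!r} on lines "
                    f"{first_line[taxon]} and {lineno}"
                )
            first_line[taxon] = lineno
            taxa.append(taxon)
    if not taxa:
        raise FormatError(f"{path}: empty species universe")
    return SpeciesUniverse(taxa)


def read_matrix_tsv(
    path: str | Path,
    kind: str = "real",
    missing: str = "fail",
) -> pd.DataFrame:
    """Read a labelled gene x column matrix from TSV.

    First row holds column labels, first column gene identifiers. For
    ``kind="binary"`` every cell must be exactly 0 or 1 and missing cells
    are fatal; for ``kind="real"`` the ``missing`` policy is either
    ``"fail"`` (default) or ``"drop-gene"``.
    """
    if kind not in ("binary", "real"):
        raise ValueError(f"kind must be 'binary' or 'real', got {kind!r}")
    if missing not in ("fail", "drop-gene"):
        raise ValueError(f"missing policy must be 'fail' or 'drop-gene', got {missing!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicate gene rows: {', '.join(map(str, dup))}")
    na = df.isna()
    if na.any().any():
        r, c = np.argwhere(na.to_numpy())[0]
        if kind == "binary" or missing == "fail":
            raise FormatError(
                f"{path}: missing cell at ({df.index[r]!r}, {df.columns[c]!r})"
            )
        df = df.loc[~na.any(axis=1)]
    if kind == "binary":
        vals = df.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: non-binary cell {vals[r, c]!r} at "
                f"({df.index[r]!r}, {df.columns[c]!r})"
            )
        df = df.astype(np.uint8)
    else:
        df = df.astype(float)
    return df


def write_matrix_tsv(path: str | Path, df: pd.DataFrame) -> None:
    """Write a labelled matrix as TSV (inverse of :func:`read_matrix_tsv`)."""
    df.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: term TAB description TAB gene TAB ...

    Duplicate genes within a line are deduplicated. A line with no member
    genes is fatal (every set must be non-empty).
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f"at least one gene"
                )
            term, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = genes
            descriptions[term] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    """Write a gene-set collection in GMT format (sorted for determinism)."""
    with Path(path).open("w") as fh:
        for term in sorted(collection.sets):
            desc = collection.descriptions.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def write_ranked_results(path: str | Path, results: Sequence) -> None:
    """Write ranked candidates as TSV with 1-based ranks.

    Columns: rank, gene, hamming_distance, pearson_r. Floats are printed
    with six decimals; an undefined correlation prints as ``NA``.
    """
    with Path(path).open("w") as fh:
        fh.write("rank\tgene\thamming_distance\tpearson_r\n")
        for i, cand in enumerate(results, start=1):
            r = cand.r
            r_str = "NA" if r is None or (isinstance(r, float) and math.isnan(r)) else f"{r:.6f}"
            fh.write(f"{i}\t{cand.gene}\t{cand.hamming}\t{r_str}\n")


def read_ranked_results(path: str | Path) -> pd.DataFrame:
    """Read a ranked-results TSV back into a DataFrame (``NA`` -> NaN)."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"rank": int, "gene": str, "hamming_distance": int},
    )
    expected = ["rank", "gene", "hamming_distance", "pearson_r"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df
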