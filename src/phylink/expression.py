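"""Expression-matrix normalization and per-gene-pair Pearson correlation.

A tissue-wide expression atlas (genes x tissues/cell lines) supplies the
co-expression evidence that refines the evolutionary ranking. Raw
intensity matrices are log2-transformed and quantile-normalized; matrices
declared pre-normalized are accepted as-is. Probe-level background
correction and probe-to-gene summarization are out of scope: inputs are
gene-level.

Undefined correlations (a constant expression vector) are propagated as a
NaN sentinel, never coerced to 0 — zero has ranking meaning, the sentinel
means "no usable co-expression evidence".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "UNDEFINED_CORRELATION",
    "ExpressionMatrix",
    "CorrelationRecord",
    "log2_transform",
    "quantile_normalize",
    "pearson",
    "correlations_to_query",
]

#: Sentinel for an undefined Pearson correlation (constant vector).
UNDEFINED_CORRELATION = float("nan")

_STATES = ("raw", "log2", "log2+quantile")


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation between one candidate gene and the query."""

    gene_a: str
    gene_b: str
    r: float


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued matrix with its normalization state.

    ``normalization_state`` only moves forward: raw -> log2 ->
    log2+quantile. The underlying DataFrame index holds gene identifiers,
    columns hold sample labels.
    """

    values: pd.DataFrame
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.normalization_state not in _STATES:
            raise ValueError(
                f"normalization_state must be one of {_STATES}, "
                f"got {self.normalization_state!r}"
            )
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def row(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def __contains__(self, gene: object) -> bool:
        return gene in self.values.index


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Apply cell -> log2(cell + offset); state moves raw -> log2.

    A non-positive shifted cell is fatal, with its coordinates reported.
    """
    if m.normalization_state != "raw":
        raise ValueError(
            f"log2_transform requires a raw matrix, got state "
            f"{m.normalization_state!r}"
        )
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset!r}")
    shifted = m.values.to_numpy(dtype=float) + offset
    bad = shifted <= 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value after offset at "
            f"({m.values.index[r]!r}, {m.values.columns[c]!r}): "
            f"{m.values.iat[r, c]} + {offset}"
        )
    out = pd.DataFrame(np.log2(shifted), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, normalization_state="log2")


def _quantile_normalize_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    # Ties within a column receive the mean of the reference distribution
    # over their tied ranks (average-ties convention).
    _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
    csum = np.concatenate(([0.0], np.cumsum(reference)))
    starts = np.concatenate(([0], np.cumsum(counts[:-1])))
    group_mean = (csum[starts + counts] - csum[starts]) / counts
    return group_mean[inverse]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean order-statistic distribution.

    After normalization the sorted values of each column are identical and
    equal to the across-column mean of order statistics. Row and column
    labels are unchanged; state moves log2 -> log2+quantile (a raw matrix
    is accepted when the caller opts out of the log transform). A
    single-column matrix is returned unchanged with a warning. The
    operation is idempotent.
    """
    if m.normalization_state == "log2+quantile":
        raise ValueError("matrix is already quantile-normalized")
    if m.values.shape[1] == 1:
        warnings.warn(
            "quantile normalization of a single-column matrix is a no-op",
            UserWarning,
            stacklevel=2,
        )
        return ExpressionMatrix(values=m.values.copy(), normalization_state="log2+quantile")
    vals = m.values.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = _quantile_normalize_column(vals[:, j], reference)
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=df, normalization_state="log2+quantile")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson product-moment correlation of two vectors.

    Returns the NaN sentinel when either vector is constant (undefined
    correlation); downstream ranking treats the sentinel as "not
    co-expressed".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return UNDEFINED_CORRELATION
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlations_to_query(query_gene: str, m: ExpressionMatrix) -> list[CorrelationRecord]:
    """Pearson correlation of the query against every other gene in the atlas.

    Genes absent from the matrix simply yield no record; a constant query
    or candidate row yields the NaN sentinel.
    """
    if query_gene not in m:
        raise KeyError(f"query gene {query_gene!r} is not a row of the expression matrix")
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError(f"need at least 3 samples, got {vals.shape[1]}")
    genes = m.genes
    qi = genes.index(query_gene)
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    q = centered[qi]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ q) / (norms * norms[qi])
    r = np.clip(r, -1.0, 1.0)
    if norms[qi] == 0:
        r = np.full(len(genes), np.nan)
    else:
        r[norms == 0] = np.nan
    return [
        CorrelationRecord(query_gene, g, float(r[i]))
        for i, g in enumerate(genes)
        if i != qi
    ]
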