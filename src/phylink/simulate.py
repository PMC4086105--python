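"""Synthetic data with planted co-evolution/co-expression structure.

The generator emulates the pipeline's four input kinds — homology hit
tables, phyletic profile matrices, tissue-wide expression matrices and
gene-set annotations — around a common ground truth: functional modules
whose members share an evolutionary history and an expression program.

Profiles: each module draws a template presence vector with
Bernoulli(profile_template_density) coordinates; members copy the
template with independent per-coordinate bit flips at rate ``flip_noise``
(so the expected within-module pairwise Hamming distance is
``2 * n_species * flip_noise * (1 - flip_noise)``). Background genes draw
i.i.d. Bernoulli(background_density) coordinates. No phylogenetic tree is
simulated — the method scored here is tree-free, so correlated gene loss
along lineages would add realism without changing what the tests probe.

Expression: a one-factor model per module. Member value =
sqrt(rho) * module_factor + sqrt(1 - rho) * noise, giving a theoretical
within-module Pearson correlation of exactly ``module_expression_rho``;
background genes are pure noise.

Hits: the inverse of profile construction, for round-trip testing. Every
1-cell yields a hit with a domain E-value sampled log-uniformly below the
threshold; a configurable fraction of 0-cells yields decoy hits at or
above the threshold, so tests can confirm that the presence rule — not
mere hit existence — drives the profile. E-values are sampled, never
computed from sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .formats import GeneSetCollection, HomologyHit, SpeciesUniverse
from .profiles import DEFAULT_EVALUE_THRESHOLD, PhyleticProfileMatrix

__all__ = [
    "SimulationConfig",
    "simulate_profiles",
    "simulate_expression",
    "simulate_hits",
    "simulate_annotations",
    "write_domtblout",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module generator.

    Defaults describe a desk-scale benchmark: 182 species (a full
    eukaryotic proteome panel), 20 modules of 10 genes each plus 300
    background genes, mild profile noise (2% per-coordinate flips) and a
    strong shared expression program (rho = 0.7) measured over 100
    tissue/cell-line samples.
    """

    n_species: int = 182
    n_genes: int = 500
    n_modules: int = 20
    module_size: int = 10
    profile_template_density: float = 0.5
    flip_noise: float = 0.02
    background_density: float = 0.5
    n_samples: int = 100
    module_expression_rho: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules x {self.module_size} genes exceed "
                f"n_genes={self.n_genes}"
            )
        for name, lo, hi in (
            ("profile_template_density", 0.0, 1.0),
            ("background_density", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValueError(f"{name} must be in ({lo}, {hi}), got {v!r}")
        if not (0.0 <= self.flip_noise < 0.5):
            raise ValueError(f"flip_noise must be in [0, 0.5), got {self.flip_noise!r}")
        if not (0.0 <= self.module_expression_rho < 1.0):
            raise ValueError(
                f"module_expression_rho must be in [0, 1), got "
                f"{self.module_expression_rho!r}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd!r}")

    @property
    def n_background(self) -> int:
        return self.n_genes - self.n_modules * self.module_size


def _gene_names(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def gene_roster(config: SimulationConfig) -> tuple[list[str], dict[str, int], list[str]]:
    """Deterministic gene naming: module genes first, then background.

    Returns (all genes in row order, membership map gene -> module index,
    background gene list).
    """
    genes = _gene_names(config)
    membership: dict[str, int] = {}
    k = 0
    for m in range(config.n_modules):
        for _ in range(config.module_size):
            membership[genes[k]] = m
            k += 1
    return genes, membership, genes[k:]


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[PhyleticProfileMatrix, dict[str, int]]:
    """Draw a planted-module phyletic profile matrix.

    Returns the matrix (module genes first, background genes after) and
    the membership map from module gene to 0-based module index.
    """
    rng = np.random.default_rng(config.seed)
    genes, membership, background = gene_roster(config)
    universe = SpeciesUniverse([f"taxon{j:03d}" for j in range(1, config.n_species + 1)])
    bits = np.empty((config.n_genes, config.n_species), dtype=np.uint8)
    row = 0
    for _ in range(config.n_modules):
        template = rng.random(config.n_species) < config.profile_template_density
        for _ in range(config.module_size):
            flips = rng.random(config.n_species) < config.flip_noise
            bits[row] = np.logical_xor(template, flips)
            row += 1
    n_bg = len(background)
    bits[row:] = rng.random((n_bg, config.n_species)) < config.background_density
    matrix = PhyleticProfileMatrix(
        genes=genes, universe=universe, bits=bits,
        evalue_threshold=DEFAULT_EVALUE_THRESHOLD,
    )
    return matrix, membership


def simulate_expression(
    config: SimulationConfig,
    membership: dict[str, int],
    baseline: float = 8.0,
) -> ExpressionMatrix:
    """Draw a one-factor-per-module expression matrix (log2 scale).

    Values are centred on ``baseline`` (a typical log2 intensity) and
    scaled by ``noise_sd``; the within-module correlation is
    ``module_expression_rho`` by construction. The returned matrix is
    declared ``log2`` so pipelines may still quantile-normalize it.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config)
    factors = rng.standard_normal((config.n_modules, config.n_samples))
    rho = config.module_expression_rho
    values = np.empty((config.n_genes, config.n_samples))
    for i, g in enumerate(genes):
        noise = rng.standard_normal(config.n_samples)
        m = membership.get(g)
        if m is None:
            signal = noise
        else:
            signal = math.sqrt(rho) * factors[m] + math.sqrt(1.0 - rho) * noise
        values[i] = baseline + config.noise_sd * signal
    samples = [f"sample{j:03d}" for j in range(1, config.n_samples + 1)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(values=df, normalization_state="log2")


def simulate_hits(
    profile_matrix: PhyleticProfileMatrix,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    decoy_fraction: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
) -> list[HomologyHit]:
    """Emit homology hits whose thresholded profile is exactly the input.

    Every 1-cell produces a hit with domain E-value log-uniform in
    [threshold * 1e-20, threshold); each 0-cell independently produces,
    with probability ``decoy_fraction``, a decoy hit with domain E-value
    log-uniform in [threshold, threshold * 1e4] — at or above the cutoff,
    so decoys can never flip a 0-cell to 1 under the strict ``<`` rule.
    """
    if not (0.0 <= decoy_fraction <= 1.0):
        raise ValueError(f"decoy_fraction must be in [0, 1], got {decoy_fraction!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    log_thr = math.log10(evalue_threshold)
    hits: list[HomologyHit] = []
    taxa = profile_matrix.universe.taxa
    for gi, gene in enumerate(profile_matrix.genes):
        row = profile_matrix.bits[gi]
        for si, taxon in enumerate(taxa):
            if row[si]:
                exp = rng.uniform(log_thr - 20.0, log_thr)
                ev = 10.0**exp
                if ev >= evalue_threshold:  # guard against rounding up to the cutoff
                    ev = evalue_threshold / 10.0
                hits.append(HomologyHit(gene, taxon, ev, ev))
            elif decoy_fraction and rng.random() < decoy_fraction:
                ev = 10.0 ** rng.uniform(log_thr, log_thr + 4.0)
                if ev < evalue_threshold:
                    ev = evalue_threshold
                hits.append(HomologyHit(gene, taxon, ev, ev))
    return hits


def write_domtblout(path: str | Path, hits: list[HomologyHit]) -> None:
    """Write hits as a HMMER3-style per-domain table.

    Target names are ``seq|<taxon>|sim`` so the default taxon-resolution
    rule (second '|'-delimited token) recovers the species. Only the
    columns the pipeline reads carry signal; the rest hold plausible
    filler so the row satisfies the 23-column convention.
    """
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain -------------\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        for h in hits:
            target = f"seq|{h.target_species}|sim"
            fh.write(
                f"{target} - 350 {h.query_gene} - 300 "
                f"{h.full_evalue:.3g} 100.0 0.1 1 1 "
                f"{h.domain_evalue:.17g} {h.domain_evalue:.17g} "
                f"95.0 0.1 1 300 10 310 5 320 0.95 simulated\n"
            )


def simulate_annotations(
    membership: dict[str, int],
    terms_per_module: int = 3,
    annotation_noise: float = 0.3,
    rng_seed: int | np.random.Generator = 0,
    background_genes: list[str] | None = None,
) -> GeneSetCollection:
    """Module-derived gene-set annotations with optional background noise.

    Each module receives ``terms_per_module`` dedicated terms covering all
    its members. With probability ``annotation_noise`` each background
    gene is additionally sprinkled into one random term, emulating the
    incidental annotations real background genes carry.
    """
    if not (0.0 <= annotation_noise <= 1.0):
        raise ValueError(f"annotation_noise must be in [0, 1], got {annotation_noise!r}")
    if terms_per_module < 1:
        raise ValueError(f"terms_per_module must be >= 1, got {terms_per_module!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    modules: dict[int, list[str]] = {}
    for gene, m in membership.items():
        modules.setdefault(m, []).append(gene)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    term_names: list[str] = []
    for m in sorted(modules):
        for t in range(terms_per_module):
            term = f"M{m:02d}_T{t}"
            sets[term] = set(modules[m])
            descriptions[term] = f"planted module {m} term {t}"
            term_names.append(term)
    if background_genes and annotation_noise > 0:
        for gene in background_genes:
            if rng.random() < annotation_noise:
                term = term_names[int(rng.integers(len(term_names)))]
                sets[term].add(gene)
    return GeneSetCollection(
        sets={t: frozenset(g) for t, g in sets.items()},
        descriptions=descriptions,
    )
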