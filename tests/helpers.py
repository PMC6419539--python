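"""Shared test helpers: independent oracles and small constructors.

The oracles here deliberately avoid the package's own numerical paths:
log-entropy weighting is recomputed densely with scalar loops, and
hypergeometric tails are summed in exact integer arithmetic.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np
import scipy.sparse as sp

from litcohesion import synthetic_data as sd
from litcohesion.corpus_lsi import ConceptSpace, TermGeneMatrix


def naive_log_entropy(counts: np.ndarray) -> np.ndarray:
    """Dense scalar-loop reimplementation of log-entropy weighting."""
    counts = np.asarray(counts, dtype=float)
    n_terms, n_genes = counts.shape
    out = np.zeros_like(counts)
    for i in range(n_terms):
        total = counts[i].sum()
        entropy = 0.0
        for j in range(n_genes):
            if counts[i, j] > 0:
                p = counts[i, j] / total
                entropy += p * math.log2(p)
        g = 1.0 + entropy / math.log2(n_genes)
        for j in range(n_genes):
            out[i, j] = g * math.log2(1.0 + counts[i, j])
    return out


def fisher_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-integer right-tail Fisher p: sum of hypergeometric terms."""
    total, successes, draws = a + b + c + d, a + c, a + b
    xmax = min(successes, draws)
    numerator = sum(
        comb(successes, x) * comb(total - successes, draws - x)
        for x in range(a, xmax + 1)
    )
    return numerator / comb(total, draws)


def hypergeom_tail_oracle(universe: int, category: int, drawn: int, overlap: int) -> float:
    """Exact-integer P(X >= overlap) when drawing ``drawn`` from ``universe``
    containing ``category`` successes."""
    xmax = min(category, drawn)
    numerator = sum(
        comb(category, x) * comb(universe - category, drawn - x)
        for x in range(overlap, xmax + 1)
    )
    return numerator / comb(universe, drawn)


def make_term_matrix(counts: np.ndarray, weighted: bool = False) -> TermGeneMatrix:
    counts = np.asarray(counts, dtype=float)
    n_terms, n_genes = counts.shape
    return TermGeneMatrix(
        terms=[f"term{i:03d}" for i in range(n_terms)],
        genes=[f"gene{j:03d}" for j in range(n_genes)],
        counts=sp.csr_matrix(counts),
        weighted=weighted,
    )


def space_from_vectors(vectors: np.ndarray, genes=None) -> ConceptSpace:
    vectors = np.asarray(vectors, dtype=float)
    if genes is None:
        genes = [f"gene{j:03d}" for j in range(vectors.shape[0])]
    sv = np.sort(np.linalg.norm(vectors, axis=0))[::-1]
    return ConceptSpace(genes=list(genes), vectors=vectors, singular_values=sv)


TINY = dict(
    n_genes=120, n_modules=3, module_size=20, vocab_size=400, module_vocab_size=40,
    doc_length_mean=80.0, signal_term_fraction=0.75, n_strains=20,
    n_signal_probes_per_module=2, n_noise_probes=6, probe_noise_sd=0.2,
    expression_noise_sd=0.1, gold_dropout=0.1, gold_contamination=0.1, seed=0,
)


def tiny_config(**overrides) -> sd.SyntheticConfig:
    merged = dict(TINY)
    merged.update(overrides)
    return sd.SyntheticConfig(**merged)


def random_count_matrix(rng: np.random.Generator, n_terms: int, n_genes: int,
                        duplicate_last_gene: bool = False) -> np.ndarray:
    """A sparse-ish random count matrix with no zero rows or columns.

    ``duplicate_last_gene`` copies the first gene's document onto the last
    gene (identical PMID sets occur in real corpora), making the matrix
    rank-deficient so that a rank min(dims)-1 SVD is lossless.
    """
    counts = rng.poisson(1.0, size=(n_terms, n_genes)).astype(float)
    counts[rng.integers(0, n_terms, size=n_genes), np.arange(n_genes)] += 1.0
    counts[np.arange(n_terms), rng.integers(0, n_genes, size=n_terms)] += 1.0
    if duplicate_last_gene:
        counts[:, -1] = counts[:, 0]
    return counts
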