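"""Gene-document corpus, log-entropy weighted term-gene matrix, truncated-SVD
concept space, and gene-gene cosine similarities.

The representation follows the standard latent-semantic-indexing recipe:

1. Per-gene documents are concatenations of abstract texts, ordered by
   ascending PMID.
2. The term-by-gene count matrix is weighted entry-wise as
   ``w_ij = g_i * log2(1 + f_ij)`` where the global weight
   ``g_i = 1 + sum_j p_ij log2(p_ij) / log2(n)`` (``p_ij = f_ij / sum_j f_ij``)
   down-weights terms spread evenly across the ``n`` gene documents;
   ``g_i`` lies in ``[0, 1]``.
3. A rank-``k`` truncated SVD produces per-gene concept vectors
   ``gene j -> (sigma_1 v_j1, ..., sigma_k v_jk)``; gene-gene similarity is
   the cosine between these vectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from ._util import natural_key, rng_for
from .errors import (
    CohesionUndefinedError,
    ConfigurationError,
    LitCohesionError,
    ParseError,
    PipelineError,
    UndefinedSimilarityError,
)

logger = logging.getLogger(__name__)

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
_MIN_TOKEN_LEN = 3
_stopwords_cache: frozenset | None = None


# ---------------------------------------------------------------------------
# corpus construction
# ---------------------------------------------------------------------------

@dataclass
class GeneCorpus:
    """Per-gene literature documents plus gene <-> PMID links.

    ``genes`` is the ordered gene universe; every listed gene has a document.
    """

    documents: dict
    pmids: dict
    genes: list

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.documents


def read_gene2pubmed(path) -> dict:
    """Parse a gene2pubmed-style TSV (tax_id, GeneID, PubMed_ID) into a
    gene -> PMID-set multimap. ``#``-prefixed header lines are permitted;
    duplicate (gene, pmid) rows collapse.
    """
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >= 3 tab-separated columns", path=path, line=lineno)
            gene = fields[1].strip()
            pmid_raw = fields[2].strip()
            try:
                pmid = int(pmid_raw)
            except ValueError:
                raise ParseError(
                    f"PMID {pmid_raw!r} is not an integer", path=path, line=lineno
                ) from None
            if not gene:
                raise ParseError("empty GeneID", path=path, line=lineno)
            out.setdefault(gene, set()).add(pmid)
    return out


def read_pmid_text(path) -> dict:
    """Parse a pmid<TAB>text table into pmid -> text."""
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t", 1)
            if len(fields) != 2:
                raise ParseError("expected pmid<TAB>text", path=path, line=lineno)
            try:
                pmid = int(fields[0])
            except ValueError:
                raise ParseError(
                    f"PMID {fields[0]!r} is not an integer", path=path, line=lineno
                ) from None
            out[pmid] = fields[1]
    return out


def build_documents(gene_pmids: dict, pmid_text: dict) -> GeneCorpus:
    """Concatenate available abstract texts into one document per gene.

    Texts are joined by single spaces, PMIDs in ascending numeric order.
    PMIDs without text are skipped (counted); genes whose every PMID lacks
    text are excluded from the universe with a warning.
    """
    documents: dict = {}
    pmids_kept: dict = {}
    n_missing = 0
    n_dropped_genes = 0
    for gene in sorted(gene_pmids, key=natural_key):
        ordered = sorted(gene_pmids[gene])
        texts = []
        kept = set()
        for pmid in ordered:
            text = pmid_text.get(pmid)
            if text is None:
                n_missing += 1
                continue
            texts.append(text)
            kept.add(pmid)
        if not texts:
            n_dropped_genes += 1
            continue
        documents[gene] = " ".join(texts)
        pmids_kept[gene] = frozenset(kept)
    if n_missing:
        logger.info("build_documents: %d gene-PMID links had no text", n_missing)
    if n_dropped_genes:
        logger.warning(
            "build_documents: %d genes had no retrievable text and were excluded",
            n_dropped_genes,
        )
    return GeneCorpus(documents=documents, pmids=pmids_kept, genes=list(documents))


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def default_stopwords() -> frozenset:
    global _stopwords_cache
    if _stopwords_cache is None:
        text = resources.files("litcohesion.data").joinpath("stopwords.txt").read_text()
        _stopwords_cache = frozenset(w.strip() for w in text.splitlines() if w.strip())
    return _stopwords_cache


def tokenize(text: str, stopwords=None) -> list:
    """Lowercase, split on non-alphanumeric runs, drop tokens shorter than 3
    characters, pure numbers, and stopwords."""
    if stopwords is None:
        stopwords = default_stopwords()
    tokens = _TOKEN_SPLIT.split(text.lower())
    return [
        t for t in tokens
        if len(t) >= _MIN_TOKEN_LEN and not t.isdigit() and t not in stopwords
    ]


# ---------------------------------------------------------------------------
# term-gene matrix
# ---------------------------------------------------------------------------

@dataclass
class TermGeneMatrix:
    """Sparse term-by-gene matrix: rows are terms, columns are genes."""

    terms: list
    genes: list
    counts: sp.csr_matrix
    weighted: bool = False

    @property
    def shape(self):
        return self.counts.shape


def build_term_matrix(
    corpus: GeneCorpus,
    min_gene_frequency: int = 2,
    stopwords=None,
) -> TermGeneMatrix:
    """Count terms per gene document.

    The vocabulary keeps terms occurring in at least ``min_gene_frequency``
    distinct gene documents, sorted lexicographically. Genes left with no
    counted term are dropped from the universe with a warning.
    """
    if not corpus.genes:
        raise PipelineError("build_term_matrix", "corpus is empty")
    per_gene_counts = []
    doc_freq: dict = {}
    for gene in corpus.genes:
        counts: dict = {}
        for token in tokenize(corpus.documents[gene], stopwords=stopwords):
            counts[token] = counts.get(token, 0) + 1
        per_gene_counts.append(counts)
        for term in counts:
            doc_freq[term] = doc_freq.get(term, 0) + 1

    vocab = sorted(t for t, df in doc_freq.items() if df >= min_gene_frequency)
    if not vocab:
        raise PipelineError(
            "build_term_matrix",
            f"vocabulary is empty after min_gene_frequency={min_gene_frequency} filtering",
        )
    term_index = {t: i for i, t in enumerate(vocab)}

    rows, cols, data = [], [], []
    kept_genes = []
    n_dropped = 0
    for gene, counts in zip(corpus.genes, per_gene_counts):
        entries = [(term_index[t], c) for t, c in counts.items() if t in term_index]
        if not entries:
            n_dropped += 1
            continue
        j = len(kept_genes)
        kept_genes.append(gene)
        for i, c in entries:
            rows.append(i)
            cols.append(j)
            data.append(float(c))
    if n_dropped:
        logger.warning(
            "build_term_matrix: %d genes had no vocabulary term and were dropped", n_dropped
        )
    if not kept_genes:
        raise PipelineError("build_term_matrix", "no gene survived vocabulary filtering")
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(vocab), len(kept_genes)), dtype=np.float64
    )
    return TermGeneMatrix(terms=vocab, genes=kept_genes, counts=mat, weighted=False)


def log_entropy_weight(raw: TermGeneMatrix) -> TermGeneMatrix:
    """Apply log-entropy weighting to a raw count matrix.

    ``w_ij = g_i * log2(1 + f_ij)`` with global weight
    ``g_i = 1 + sum_j p_ij log2(p_ij) / log2(n)``, ``p_ij = f_ij / sum_j f_ij``
    and ``n`` the number of genes. Zero counts contribute nothing to the
    entropy sum. A term occurring once in every gene gets ``g_i = 0``; a term
    confined to a single gene gets ``g_i = 1``.
    """
    if raw.weighted:
        raise ConfigurationError("matrix is already weighted")
    n_terms, n_genes = raw.counts.shape
    if n_genes < 2:
        raise ConfigurationError("log-entropy weighting requires at least 2 genes (n >= 2)")
    coo = raw.counts.tocoo()
    row_sums = np.asarray(raw.counts.sum(axis=1)).ravel()
    p = coo.data / row_sums[coo.row]
    entropy = np.zeros(n_terms)
    np.add.at(entropy, coo.row, p * np.log2(p))
    g = 1.0 + entropy / np.log2(n_genes)
    g = np.clip(g, 0.0, 1.0)
    data = g[coo.row] * np.log2(1.0 + coo.data)
    weighted = sp.csr_matrix(
        (data, (coo.row, coo.col)), shape=raw.counts.shape, dtype=np.float64
    )
    return TermGeneMatrix(terms=list(raw.terms), genes=list(raw.genes),
                          counts=weighted, weighted=True)


def global_weights(raw: TermGeneMatrix) -> np.ndarray:
    """The per-term global entropy weights ``g_i`` alone (for inspection)."""
    n_terms, n_genes = raw.counts.shape
    if n_genes < 2:
        raise ConfigurationError("log-entropy weighting requires at least 2 genes (n >= 2)")
    coo = raw.counts.tocoo()
    row_sums = np.asarray(raw.counts.sum(axis=1)).ravel()
    p = coo.data / row_sums[coo.row]
    entropy = np.zeros(n_terms)
    np.add.at(entropy, coo.row, p * np.log2(p))
    return np.clip(1.0 + entropy / np.log2(n_genes), 0.0, 1.0)


# ---------------------------------------------------------------------------
# concept space
# ---------------------------------------------------------------------------

@dataclass
class ConceptSpace:
    """Reduced-rank gene vectors (rows) and the singular values of the
    decomposition, non-increasing."""

    genes: list
    vectors: np.ndarray
    singular_values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self._index

    def vector(self, gene) -> np.ndarray:
        try:
            return self.vectors[self._index[gene]]
        except KeyError:
            raise LitCohesionError(f"gene {gene!r} is not in the concept space") from None

    def unit_vectors(self, rows=None) -> np.ndarray:
        v = self.vectors if rows is None else self.vectors[rows]
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            idx = np.flatnonzero(norms == 0)[0]
            gene = self.genes[idx if rows is None else rows[idx]]
            raise UndefinedSimilarityError(f"gene {gene!r} has a zero-norm vector")
        return v / norms[:, None]

    def save(self, path, params: dict | None = None) -> None:
        path = Path(path)
        np.savez(
            path,
            genes=np.array(self.genes, dtype=object),
            vectors=self.vectors,
            singular_values=self.singular_values,
        )
        if params is not None:
            import json

            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(params, indent=2, sort_keys=True, default=str))

    @classmethod
    def load(cls, path) -> "ConceptSpace":
        with np.load(path, allow_pickle=True) as npz:
            return cls(
                genes=[str(g) for g in npz["genes"]],
                vectors=np.asarray(npz["vectors"], dtype=np.float64),
                singular_values=np.asarray(npz["singular_values"], dtype=np.float64),
            )


# dense LAPACK below this size: exact, deterministic, and faster than ARPACK
_DENSE_SVD_LIMIT = 800


def truncated_svd(weighted: TermGeneMatrix, k: int = 500, seed: int = 0) -> ConceptSpace:
    """Rank-``k`` truncated SVD of the (weighted) term-gene matrix.

    Gene vectors are the singular-value-scaled right singular vectors. ``k``
    greater than ``min(dims) - 1`` is clamped with a warning. Signs are
    canonicalized (largest-magnitude entry of each left singular vector is
    positive) so repeated runs produce identical output.
    """
    if k < 1:
        raise ConfigurationError("SVD rank k must be >= 1")
    n_terms, n_genes = weighted.counts.shape
    max_k = min(n_terms, n_genes) - 1
    if max_k < 1:
        raise ConfigurationError("matrix too small for a truncated SVD")
    if k > max_k:
        logger.warning("truncated_svd: clamping k from %d to %d (matrix %dx%d)",
                       k, max_k, n_terms, n_genes)
        k = max_k

    if min(n_terms, n_genes) <= _DENSE_SVD_LIMIT:
        u, s, vt = np.linalg.svd(weighted.counts.toarray(), full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        rng = rng_for(seed, "svd")
        v0 = rng.standard_normal(min(n_terms, n_genes))
        try:
            u, s, vt = svds(weighted.counts, k=k, v0=v0)
        except Exception as exc:  # pragma: no cover - solver failure surface
            raise LitCohesionError(
                f"sparse SVD failed on {n_terms}x{n_genes} matrix: {exc}"
            ) from exc
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]

    # canonical signs for reproducibility
    flip = u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])] < 0
    u[:, flip] *= -1
    vt[flip] *= -1

    vectors = vt.T * s
    return ConceptSpace(genes=list(weighted.genes), vectors=vectors,
                        singular_values=s.copy())


def build_space(
    corpus: GeneCorpus,
    rank: int = 500,
    min_gene_frequency: int = 2,
    seed: int = 0,
    stopwords=None,
) -> ConceptSpace:
    """Convenience chain: corpus -> counts -> log-entropy weights -> SVD."""
    raw = build_term_matrix(corpus, min_gene_frequency=min_gene_frequency,
                            stopwords=stopwords)
    return truncated_svd(log_entropy_weight(raw), k=rank, seed=seed)


# ---------------------------------------------------------------------------
# similarities
# ---------------------------------------------------------------------------

def cosine(space: ConceptSpace, gene_a, gene_b) -> float:
    """Cosine similarity between two genes' concept vectors."""
    va, vb = space.vector(gene_a), space.vector(gene_b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0:
        raise UndefinedSimilarityError(f"gene {gene_a!r} has a zero-norm vector")
    if nb == 0:
        raise UndefinedSimilarityError(f"gene {gene_b!r} has a zero-norm vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


@dataclass
class CosineSet:
    """All pairwise cosines for the in-corpus part of a gene set."""

    values: np.ndarray
    genes: list
    coverage: float


def pairwise_cosines(space: ConceptSpace, gene_set) -> CosineSet:
    """One cosine per unordered pair of in-corpus genes.

    Genes absent from the corpus are dropped; the returned coverage is the
    fraction of distinct input genes found in the corpus.
    """
    requested = sorted(set(gene_set), key=natural_key)
    if not requested:
        raise CohesionUndefinedError("empty gene set")
    present = [g for g in requested if g in space]
    coverage = len(present) / len(requested)
    if len(present) < 2:
        raise CohesionUndefinedError(
            f"need >= 2 in-corpus genes, found {len(present)} of {len(requested)}"
        )
    rows = [space._index[g] for g in present]
    un = space.unit_vectors(rows=np.asarray(rows))
    gram = un @ un.T
    iu = np.triu_indices(len(present), k=1)
    values = np.clip(gram[iu], -1.0, 1.0)
    return CosineSet(values=values, genes=present, coverage=coverage)
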