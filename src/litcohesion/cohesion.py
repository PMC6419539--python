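"""Literature cohesion p-value (LPv) for gene sets.

Given a concept space, the score asks whether the pairwise cosine
similarities within a gene set exceed a background threshold ``T`` (a
percentile of all background pairwise cosines) more often than chance:

* draw ``n`` samples of ``k`` cosines from the set's own pairwise cosines;
  ``A``/``B`` are the average counts at/above and below ``T``;
* draw ``N`` samples of ``k`` cosines from the background pool; ``C``/``D``
  are the analogous averages;
* a right-tailed Fisher's exact test on the rounded 2x2 table
  ``[[A, B], [C, D]]`` yields ``p``; the score is ``-log10(p)``, higher
  meaning more cohesive.

Within each draw, sampling is without replacement, so the count of cosines
at/above ``T`` in one draw is exactly hypergeometric; the implementation
draws those counts from the equivalent hypergeometric law directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up, seed_sequence
from .corpus_lsi import ConceptSpace, pairwise_cosines
from .errors import ConfigurationError, LitCohesionError

__all__ = [
    "LPvConfig",
    "BackgroundThreshold",
    "LPvResult",
    "estimate_threshold",
    "sample_counts",
    "fisher_right_tail",
    "fisher_point_mass",
    "lpv",
]


@dataclass(frozen=True)
class LPvConfig:
    """Sampling parameters for the cohesion test (defaults follow the
    k <= 50, n = N ~ 1000, 95th-percentile convention)."""

    percentile: float = 95.0
    k: int = 50
    n: int = 1000
    N: int = 1000
    background_pair_budget: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.percentile < 100:
            raise ConfigurationError("percentile must satisfy 0 < percentile < 100")
        if self.k < 1:
            raise ConfigurationError("sample size k must be >= 1")
        if self.n < 1 or self.N < 1:
            raise ConfigurationError("draw counts n and N must be >= 1")
        if self.background_pair_budget < 1:
            raise ConfigurationError("background_pair_budget must be >= 1")


@dataclass
class BackgroundThreshold:
    """The background cosine threshold ``T`` plus the pool it came from."""

    T: float
    mode: str  # "exact" | "sampled"
    n_pairs: int
    seed: int
    percentile: float
    pool: np.ndarray = field(repr=False)


@dataclass
class LPvResult:
    A: int
    B: int
    C: int
    D: int
    raw_counts: tuple  # unrounded (A, B, C, D) averages, kept for audit
    p: float
    neg_log10: float
    coverage: float
    n_genes_used: int
    k_used: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "A": self.A, "B": self.B, "C": self.C, "D": self.D,
            "raw_counts": list(self.raw_counts),
            "p": self.p, "neg_log10": self.neg_log10,
            "coverage": self.coverage, "n_genes_used": self.n_genes_used,
            "k_used": self.k_used, "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# background threshold
# ---------------------------------------------------------------------------

def _sample_distinct_pairs(n: int, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample ``budget`` distinct unordered pairs (as codes i*n+j,
    i < j) out of the n*(n-1)/2 possible, without materializing all of them."""
    want = budget
    codes = np.empty(0, dtype=np.int64)
    while codes.size < want:
        m = max(4 * (want - codes.size), 1024)
        i = rng.integers(0, n, size=m, dtype=np.int64)
        j = rng.integers(0, n, size=m, dtype=np.int64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        keep = lo < hi
        new = lo[keep] * n + hi[keep]
        codes = np.unique(np.concatenate([codes, new]))
    if codes.size > want:
        idx = rng.choice(codes.size, size=want, replace=False)
        codes = codes[np.sort(idx)]
    return codes


def estimate_threshold(space: ConceptSpace, config: LPvConfig) -> BackgroundThreshold:
    """Estimate ``T`` as the configured percentile of background pairwise
    cosines.

    If the total pair count fits in ``background_pair_budget`` all pairs are
    enumerated ("exact" mode); otherwise that many distinct pairs are sampled
    uniformly ("sampled" mode). The percentile uses linear interpolation
    between order statistics.
    """
    n = len(space)
    if n < 2:
        raise LitCohesionError("background threshold needs a corpus of >= 2 genes")
    total_pairs = n * (n - 1) // 2
    un = space.unit_vectors()
    if total_pairs <= config.background_pair_budget:
        mode = "exact"
        chunks = []
        block = max(1, min(n, 2_000_000 // max(n, 1) + 1))
        for start in range(0, n - 1, block):
            stop = min(start + block, n - 1)
            g = un[start:stop] @ un.T
            for local, row in enumerate(range(start, stop)):
                chunks.append(g[local, row + 1:])
        pool = np.clip(np.concatenate(chunks), -1.0, 1.0)
    else:
        mode = "sampled"
        rng = np.random.default_rng(seed_sequence(config.seed, "background-threshold"))
        codes = _sample_distinct_pairs(n, config.background_pair_budget, rng)
        i, j = codes // n, codes % n
        pool = np.clip(np.einsum("ij,ij->i", un[i], un[j]), -1.0, 1.0)
    T = float(np.percentile(pool, config.percentile))
    return BackgroundThreshold(
        T=T, mode=mode, n_pairs=int(pool.size), seed=config.seed,
        percentile=config.percentile, pool=pool,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_counts(cosines, T: float, k: int, n_draws: int, seed=0) -> tuple:
    """Average (above, below) counts over ``n_draws`` samples of ``k``
    cosines drawn without replacement.

    ``k`` is reduced to the multiset size when the set is smaller ("k <= 50");
    in that degenerate case every draw is the full multiset and the averages
    are deterministic. ``avg_above + avg_below == k_eff`` exactly.
    """
    values = np.asarray(cosines, dtype=np.float64)
    if values.size == 0:
        raise LitCohesionError("cannot sample from an empty cosine multiset")
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    k_eff = min(int(k), values.size)
    if k_eff < 1:
        raise ConfigurationError("sample size k must be >= 1")
    n_above = int(np.count_nonzero(values >= T))
    if k_eff == values.size:
        avg_above = float(n_above)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        counts = rng.hypergeometric(n_above, values.size - n_above, k_eff, size=n_draws)
        avg_above = float(np.mean(counts))
    return avg_above, k_eff - avg_above


# ---------------------------------------------------------------------------
# Fisher's exact test, right tail
# ---------------------------------------------------------------------------

_lf_cache = np.array([math.lgamma(i + 1) for i in range(256)])


def _log_factorials(n_max: int) -> np.ndarray:
    global _lf_cache
    if n_max >= _lf_cache.size:
        _lf_cache = np.array([math.lgamma(i + 1) for i in range(n_max + 256)])
    return _lf_cache


def _check_counts(*counts) -> tuple:
    out = []
    for c in counts:
        ci = int(c)
        if ci != c or ci < 0:
            raise ConfigurationError(f"table entries must be non-negative integers, got {c!r}")
        out.append(ci)
    return tuple(out)


def _sf_vector(total: int, successes: int, draws: int) -> np.ndarray:
    """P(X >= a) for a = 0..draws with X ~ Hypergeometric(total, successes,
    draws), via a reversed cumulative sum of the pmf (stable for tiny tails)."""
    lf = _log_factorials(total)
    xmin = max(0, draws + successes - total)
    xmax = min(successes, draws)
    x = np.arange(xmin, xmax + 1)
    logpmf = (
        lf[successes] - lf[x] - lf[successes - x]
        + lf[total - successes] - lf[draws - x] - lf[total - successes - draws + x]
        - (lf[total] - lf[draws] - lf[total - draws])
    )
    tails = np.cumsum(np.exp(logpmf)[::-1])[::-1]
    out = np.zeros(draws + 1)
    out[xmin: xmax + 1] = np.minimum(tails, 1.0)
    out[: xmin + 1] = 1.0  # P(X >= xmin) is exactly 1
    return out


def fisher_right_tail(a, b, c, d) -> float:
    """Right-tailed Fisher's exact p-value for the 2x2 table [[a, b], [c, d]]:
    ``P(X >= a)`` with ``X ~ Hypergeometric(total=a+b+c+d, successes=a+c,
    draws=a+b)``. ``a = 0`` gives 1 by construction."""
    a, b, c, d = _check_counts(a, b, c, d)
    total, successes, draws = a + b + c + d, a + c, a + b
    xmin = max(0, draws + successes - total)
    if a <= xmin:
        return 1.0
    xmax = min(successes, draws)
    lf = _log_factorials(total)
    x = np.arange(a, xmax + 1)
    logpmf = (
        lf[successes] - lf[x] - lf[successes - x]
        + lf[total - successes] - lf[draws - x] - lf[total - successes - draws + x]
        - (lf[total] - lf[draws] - lf[total - draws])
    )
    return float(min(1.0, np.sum(np.exp(logpmf[::-1]))))


def fisher_point_mass(a, b, c, d) -> float:
    """The single-table hypergeometric probability of the observed table
    (the literal printed form of the test statistic), for comparison."""
    a, b, c, d = _check_counts(a, b, c, d)
    total, successes, draws = a + b + c + d, a + c, a + b
    if a < max(0, draws + successes - total) or a > min(successes, draws):
        return 0.0
    lf = _log_factorials(total)
    logp = (
        lf[successes] - lf[a] - lf[successes - a]
        + lf[total - successes] - lf[draws - a] - lf[total - successes - draws + a]
        - (lf[total] - lf[draws] - lf[total - draws])
    )
    return float(min(1.0, math.exp(logp)))


# ---------------------------------------------------------------------------
# LPv
# ---------------------------------------------------------------------------

def lpv(
    space: ConceptSpace,
    gene_set,
    threshold: BackgroundThreshold,
    config: LPvConfig,
    point_mass: bool = False,
    salt: str = "",
) -> LPvResult:
    """Literature cohesion p-value for one gene set.

    ``salt`` disambiguates the RNG stream when many sets are scored under one
    config (e.g. per probe and window in the pipeline). The averaged counts
    are rounded to nearest integer (.5 up) before the exact test; margins are
    preserved by deriving B and D from the rounded A and C. Unrounded
    averages stay available in ``raw_counts``.
    """
    cs = pairwise_cosines(space, gene_set)
    k_eff = min(config.k, cs.values.size)
    rng_set = np.random.default_rng(seed_sequence(config.seed, f"lpv-set:{salt}"))
    rng_bg = np.random.default_rng(seed_sequence(config.seed, f"lpv-background:{salt}"))
    A_f, B_f = sample_counts(cs.values, threshold.T, k_eff, config.n, rng_set)
    C_f, D_f = sample_counts(threshold.pool, threshold.T, k_eff, config.N, rng_bg)
    A = round_half_up(A_f)
    B = k_eff - A
    C = round_half_up(C_f)
    D = k_eff - C
    p = fisher_point_mass(A, B, C, D) if point_mass else fisher_right_tail(A, B, C, D)
    p = max(p, 5e-324)
    return LPvResult(
        A=A, B=B, C=C, D=D,
        raw_counts=(A_f, B_f, C_f, D_f),
        p=p,
        neg_log10=-math.log10(p),
        coverage=cs.coverage,
        n_genes_used=len(cs.genes),
        k_used=k_eff,
        significant=p < 0.05,
    )
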