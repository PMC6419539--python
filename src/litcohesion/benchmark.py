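"""Scoring of co-expression windows: gold-standard F-measure, category
enrichment, multiple-testing adjustment, cohesion-vs-F correlation,
exon/intron separation, and probe quality classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohesion import fisher_right_tail
from .errors import ConfigurationError, DegenerateCorrelationError, LitCohesionError

CLASSIFY_MODES = ("mean_neglog", "fixed")


@dataclass
class BenchmarkRecord:
    """One probe x window scoring row."""

    probe_id: str
    region: str
    window_size: int
    precision: float | None = None
    recall: float | None = None
    f_measure: float | None = None
    lpv_p: float | None = None
    neg_log10: float | None = None
    enrichment_p: dict | None = None
    enrichment_p_adjusted: dict | None = None


def precision_recall_f(window, gold) -> tuple:
    """Precision, recall and balanced F (F1) of a window against a gold
    standard; F = 0 when the overlap is empty."""
    w, g = set(window), set(gold)
    if not w:
        raise LitCohesionError("window is empty")
    if not g:
        raise LitCohesionError("gold standard is empty")
    overlap = len(w & g)
    precision = overlap / len(w)
    recall = overlap / len(g)
    f = 0.0 if overlap == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def enrichment_pvalue(window, category, universe) -> float:
    """Right-tail hypergeometric p of drawing >= |window & category| category
    genes when drawing |window| genes from the universe."""
    u = set(universe)
    w = set(window) & u
    if not w:
        raise LitCohesionError("window does not intersect the universe")
    cat = set(category) & u
    if not cat:
        raise LitCohesionError("category does not intersect the universe")
    overlap = len(w & cat)
    return fisher_right_tail(
        overlap, len(w) - overlap, len(cat) - overlap,
        len(u) - len(cat) - len(w) + overlap,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def correlate_lpv_f(neg_log10_values, f_values) -> float:
    """Pearson r between -log10(LPv) and F over probes at one window size."""
    x = np.asarray(neg_log10_values, dtype=float)
    y = np.asarray(f_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise LitCohesionError(f"need >= 3 probes with finite values, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError("one of the variables is constant")
    return float(stats.pearsonr(x, y).statistic)


def rank_sum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value. Exact when the combined sample is
    small (n <= 20) and tie-free; normal approximation with tie correction
    otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise LitCohesionError("each group needs >= 2 values")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def classify_probes(neg_log10_by_probe: dict, mode: str = "mean_neglog",
                    threshold: float | None = None) -> tuple:
    """Flag probes as high/low quality.

    ``mean_neglog`` recomputes the threshold as the dataset mean of
    -log10(LPv) (the published 6.42-style cutoff is a dataset statistic, not
    a constant); ``fixed`` uses the given threshold. A probe is "high" iff
    strictly above the threshold.
    """
    if mode not in CLASSIFY_MODES:
        raise ConfigurationError(f"mode must be one of {CLASSIFY_MODES}")
    if len(neg_log10_by_probe) < 2:
        raise LitCohesionError("classification needs >= 2 probes")
    values = np.asarray(list(neg_log10_by_probe.values()), dtype=float)
    if mode == "mean_neglog":
        threshold = float(np.mean(values))
    elif threshold is None:
        raise ConfigurationError("fixed mode requires an explicit threshold")
    labels = {
        probe: ("high" if v > threshold else "low")
        for probe, v in neg_log10_by_probe.items()
    }
    return labels, float(threshold)
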