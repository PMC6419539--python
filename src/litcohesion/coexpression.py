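"""Seed-probe co-expression rankings and top-N gene windows.

Given a probes-x-strains expression matrix, genes are ranked by the Pearson
correlation of their best probe with a seed probe, and nested windows of the
top 100-1000 (configurable) co-expressed genes are extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from ._util import natural_key
from .errors import ConfigurationError, LitCohesionError

logger = logging.getLogger(__name__)

RANK_MODES = ("abs", "positive")


@dataclass
class ExpressionDataset:
    """Expression values (probes x strains, NaN = missing) plus a probe
    annotation mapping every probe to a target gene and a region label."""

    values: pd.DataFrame
    annotation: pd.DataFrame
    min_present: float = 0.8

    def __post_init__(self):
        if self.values.shape[1] < 3:
            raise ConfigurationError("expression dataset needs >= 3 strains")
        missing = set(self.values.index) - set(self.annotation.index)
        if missing:
            raise ConfigurationError(
                f"annotation does not cover {len(missing)} probes "
                f"(e.g. {sorted(missing)[:3]})"
            )
        bad = ~self.annotation["region"].isin(_io.VALID_REGIONS)
        if bad.any():
            raise ConfigurationError(
                f"region must be one of {_io.VALID_REGIONS}"
            )

    @classmethod
    def from_files(cls, expression_path, annotation_path, min_present: float = 0.8):
        return cls(
            values=_io.read_expression(expression_path),
            annotation=_io.read_annotation(annotation_path),
            min_present=min_present,
        )

    @property
    def probes(self) -> list:
        return list(self.values.index)

    @property
    def strains(self) -> list:
        return list(self.values.columns)

    def present_fraction(self, probe) -> float:
        row = self.values.loc[probe].to_numpy(dtype=float)
        return float(np.isfinite(row).mean())

    def usable(self, probe) -> bool:
        return self.present_fraction(probe) >= self.min_present

    def usable_probes(self) -> list:
        frac = np.isfinite(self.values.to_numpy(dtype=float)).mean(axis=1)
        return [p for p, f in zip(self.values.index, frac) if f >= self.min_present]

    def gene_of(self, probe) -> str:
        return str(self.annotation.loc[probe, "gene_id"])

    def region_of(self, probe) -> str:
        return str(self.annotation.loc[probe, "region"])


def _pearson_pairwise(x: np.ndarray, y: np.ndarray, min_complete: int) -> float | None:
    """Pearson r over pairwise-complete entries; None when undefined."""
    ok = np.isfinite(x) & np.isfinite(y)
    if int(ok.sum()) < min_complete:
        return None
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0:
        return None
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def probe_correlations(dataset: ExpressionDataset, seed_probe, min_complete: int = 3) -> dict:
    """Pearson r between the seed probe and every other usable probe over
    pairwise-complete strains. Pairs with fewer than ``min_complete``
    complete strains or zero variance are excluded (counted in the log)."""
    if seed_probe not in dataset.values.index:
        raise LitCohesionError(f"seed probe {seed_probe!r} is not in the dataset")
    if not dataset.usable(seed_probe):
        raise LitCohesionError(
            f"seed probe {seed_probe!r} is unusable "
            f"(present fraction {dataset.present_fraction(seed_probe):.2f} "
            f"< {dataset.min_present})"
        )
    mat = dataset.values.to_numpy(dtype=float)
    probes = list(dataset.values.index)
    seed_idx = probes.index(seed_probe)
    seed_row = mat[seed_idx]
    if not np.isfinite(seed_row).all() or np.nanstd(seed_row) == 0:
        if np.nanstd(seed_row[np.isfinite(seed_row)]) == 0:
            raise LitCohesionError(f"seed probe {seed_probe!r} has zero variance")

    usable = set(dataset.usable_probes())
    out: dict = {}
    n_excluded = 0
    all_finite = np.isfinite(mat).all()
    if all_finite:
        sx = seed_row - seed_row.mean()
        denom_x = np.sqrt((sx * sx).sum())
        if denom_x == 0:
            raise LitCohesionError(f"seed probe {seed_probe!r} has zero variance")
        centered = mat - mat.mean(axis=1, keepdims=True)
        denom_y = np.sqrt((centered * centered).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = (centered @ sx) / (denom_y * denom_x)
        for i, probe in enumerate(probes):
            if i == seed_idx or probe not in usable:
                continue
            if denom_y[i] == 0 or not np.isfinite(rs[i]):
                n_excluded += 1
                continue
            out[probe] = float(np.clip(rs[i], -1.0, 1.0))
    else:
        for i, probe in enumerate(probes):
            if i == seed_idx or probe not in usable:
                continue
            r = _pearson_pairwise(seed_row, mat[i], min_complete)
            if r is None:
                n_excluded += 1
                continue
            out[probe] = r
    if n_excluded:
        logger.info("probe_correlations(%s): %d probes excluded as undefined",
                    seed_probe, n_excluded)
    return out


def collapse_to_genes(correlations: dict, annotation: pd.DataFrame,
                      exclude_gene=None) -> dict:
    """Per gene keep the probe with maximal |r| (ties: smaller probe id);
    drop the seed probe's own target gene."""
    gene_ids = annotation["gene_id"]
    best: dict = {}
    for probe in sorted(correlations, key=natural_key):
        gene = str(gene_ids.loc[probe])
        if exclude_gene is not None and gene == str(exclude_gene):
            continue
        r = correlations[probe]
        if gene not in best or abs(r) > abs(best[gene][0]):
            best[gene] = (r, probe)
    return best


def _ranked_genes(gene_correlations: dict, rank_by: str = "abs") -> list:
    if rank_by not in RANK_MODES:
        raise ConfigurationError(f"rank_by must be one of {RANK_MODES}")
    if rank_by == "abs":
        key = lambda item: (-abs(item[1][0]), natural_key(item[0]))  # noqa: E731
    else:
        key = lambda item: (-item[1][0], natural_key(item[0]))  # noqa: E731
    return [(g, r, probe) for g, (r, probe) in sorted(gene_correlations.items(), key=key)]


def top_window(gene_correlations: dict, size: int, rank_by: str = "abs",
               name: str = "window") -> _io.GeneSet:
    """The ``size`` genes with the largest |r| (or signed r), with a
    deterministic gene-id tie-break. Returns all genes with a warning when
    fewer than ``size`` are available."""
    if size < 1:
        raise ConfigurationError("window size must be >= 1")
    ranked = _ranked_genes(gene_correlations, rank_by=rank_by)
    if len(ranked) < size:
        logger.warning("top_window: only %d genes available for window of %d",
                       len(ranked), size)
    chosen = ranked[:size]
    return _io.GeneSet(name=name, genes=frozenset(g for g, _, _ in chosen),
                       description=f"top {len(chosen)} co-expressed genes")


@dataclass
class WindowSeries:
    """Nested top-N windows for one seed probe, smallest first."""

    seed_probe: str
    sizes: list
    windows: list
    ranking: list = field(repr=False)  # [(gene, r, source probe), ...]


def window_series(dataset: ExpressionDataset, seed_probe, sizes=None,
                  rank_by: str = "abs", min_complete: int = 3) -> WindowSeries:
    """Windows at each requested size from a single shared ranking, so each
    smaller window is a subset of every larger one."""
    if sizes is None:
        sizes = list(range(100, 1001, 100))
    sizes = [int(s) for s in sizes]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ConfigurationError("window sizes must be strictly increasing")
    corr = probe_correlations(dataset, seed_probe, min_complete=min_complete)
    genes = collapse_to_genes(corr, dataset.annotation,
                              exclude_gene=dataset.gene_of(seed_probe))
    ranking = _ranked_genes(genes, rank_by=rank_by)
    windows = []
    for size in sizes:
        if len(ranking) < size:
            logger.warning("window_series(%s): only %d genes for window of %d",
                           seed_probe, len(ranking), size)
        chosen = ranking[:size]
        windows.append(_io.GeneSet(
            name=f"{seed_probe}_top{size}",
            genes=frozenset(g for g, _, _ in chosen),
            description=f"top {len(chosen)} genes co-expressed with {seed_probe}",
        ))
    return WindowSeries(seed_probe=str(seed_probe), sizes=sizes, windows=windows,
                        ranking=ranking)
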