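"""End-to-end workflow: corpus/space -> per-probe co-expression windows ->
LPv + F-measure + enrichment -> dataset-level correlations, exon/intron
separation and probe quality flags, all driven by one config and one seed."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, benchmark, cohesion, coexpression, corpus_lsi, io as _io
from . import synthetic_data
from ._util import derive_seed, file_digest, natural_key
from .errors import (
    ConfigurationError,
    DegenerateCorrelationError,
    LitCohesionError,
    PipelineError,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based workflow configuration (one YAML document)."""

    expression: Path
    annotation: Path
    out_dir: Path
    seed: int = 0
    space: Path | None = None
    gene2pubmed: Path | None = None
    abstracts: Path | None = None
    rank: int = 500
    min_gene_freq: int = 2
    gold_standards: list = field(default_factory=list)
    categories: list = field(default_factory=list)
    window_sizes: list = field(default_factory=lambda: list(range(100, 1001, 100)))
    rank_by: str = "abs"
    seed_probes: list | None = None
    lpv: cohesion.LPvConfig = field(default_factory=cohesion.LPvConfig)
    config_path: Path | None = None

    def __post_init__(self):
        sizes = [int(s) for s in self.window_sizes]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ConfigurationError("window_sizes must be strictly increasing")
        self.window_sizes = sizes
        if self.space is None and (self.gene2pubmed is None or self.abstracts is None):
            raise ConfigurationError(
                "config needs either a prebuilt 'space' or corpus inputs "
                "('gene2pubmed' and 'abstracts')"
            )
        for path in self._input_paths():
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")

    def _input_paths(self) -> list:
        paths = [self.expression, self.annotation]
        if self.space is not None:
            paths.append(self.space)
        else:
            paths.extend([self.gene2pubmed, self.abstracts])
        paths.extend(self.gold_standards)
        paths.extend(self.categories)
        return [Path(p) for p in paths]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _resolve(p):
            return base / p if p is not None else None

        corpus = raw.get("corpus") or {}
        lpv_kwargs = dict(raw.get("lpv") or {})
        lpv_kwargs.setdefault("seed", derive_seed(int(raw.get("seed", 0)), "lpv"))
        return cls(
            expression=_resolve(raw["expression"]),
            annotation=_resolve(raw["annotation"]),
            out_dir=base / raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            space=_resolve(raw.get("space")),
            gene2pubmed=_resolve(corpus.get("gene2pubmed")),
            abstracts=_resolve(corpus.get("abstracts")),
            rank=int(corpus.get("rank", 500)),
            min_gene_freq=int(corpus.get("min_gene_freq", 2)),
            gold_standards=[_resolve(p) for p in raw.get("gold_standards", [])],
            categories=[_resolve(p) for p in raw.get("categories", [])],
            window_sizes=raw.get("window_sizes", list(range(100, 1001, 100))),
            rank_by=raw.get("rank_by", "abs"),
            seed_probes=raw.get("seed_probes"),
            lpv=cohesion.LPvConfig(**lpv_kwargs),
            config_path=path,
        )


class _Stage:
    """Context manager tagging failures with the stage name and logging time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage=%s status=start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is None:
            logger.info("stage=%s status=done elapsed=%.2fs", self.name, elapsed)
            return False
        if isinstance(exc, PipelineError):
            return False
        raise PipelineError(self.name, str(exc)) from exc


def peak_window(f_by_size: dict) -> int:
    """The smallest window size attaining the maximum finite F."""
    finite = {int(s): f for s, f in f_by_size.items()
              if f is not None and math.isfinite(f)}
    if not finite:
        raise LitCohesionError("no window has a finite F-measure")
    best = max(finite.values())
    return min(s for s, f in finite.items() if f == best)


def _score_windows(space, threshold, lpv_config, dataset, seed_probes,
                   window_sizes, rank_by, golds, categories, universe):
    """Per-probe window series scored with LPv, gold F and enrichment."""
    lpv_rows, f_rows, enr_rows = [], [], []
    for probe in seed_probes:
        series = coexpression.window_series(dataset, probe, sizes=window_sizes,
                                            rank_by=rank_by)
        region = dataset.region_of(probe)
        for size, window in zip(series.sizes, series.windows):
            try:
                result = cohesion.lpv(space, window.genes, threshold, lpv_config,
                                      salt=f"{probe}:{size}")
            except LitCohesionError as exc:
                logger.warning("lpv undefined for probe=%s size=%d: %s",
                               probe, size, exc)
                continue
            lpv_rows.append({
                "probe": probe, "region": region, "window_size": size,
                "n_window": len(window), "coverage": result.coverage,
                "A": result.A, "B": result.B, "C": result.C, "D": result.D,
                "p": result.p, "neg_log10": result.neg_log10,
                "significant": result.significant,
            })
            for gold in golds:
                precision, recall, f = benchmark.precision_recall_f(window.genes,
                                                                    gold.genes)
                f_rows.append({
                    "probe": probe, "region": region, "window_size": size,
                    "gold": gold.name, "precision": precision, "recall": recall,
                    "f_measure": f,
                })
            if categories:
                ps = []
                for cat in categories:
                    try:
                        ps.append(benchmark.enrichment_pvalue(window.genes,
                                                              cat.genes, universe))
                    except LitCohesionError:
                        ps.append(1.0)
                adjusted = benchmark.bh_adjust(ps)
                for cat, p_raw, p_adj in zip(categories, ps, adjusted):
                    enr_rows.append({
                        "probe": probe, "region": region, "window_size": size,
                        "category": cat.name, "p": p_raw, "p_bh": float(p_adj),
                    })
    return (pd.DataFrame(lpv_rows),
            pd.DataFrame(f_rows),
            pd.DataFrame(enr_rows))


def _summarize(lpv_df, f_df, window_sizes, golds):
    summary: dict = {}
    # LPv-F correlation per gold and window size, plus pooled
    if not f_df.empty:
        merged = f_df.merge(lpv_df[["probe", "window_size", "neg_log10"]],
                            on=["probe", "window_size"])
        corr: dict = {}
        pooled: dict = {}
        for gold in sorted({g.name for g in golds}):
            sub_gold = merged[merged["gold"] == gold]
            per_size = {}
            for size in window_sizes:
                sub = sub_gold[sub_gold["window_size"] == size]
                try:
                    per_size[str(size)] = benchmark.correlate_lpv_f(
                        sub["neg_log10"], sub["f_measure"])
                except (LitCohesionError, DegenerateCorrelationError):
                    per_size[str(size)] = None
            corr[gold] = per_size
            try:
                pooled[gold] = benchmark.correlate_lpv_f(
                    sub_gold["neg_log10"], sub_gold["f_measure"])
            except (LitCohesionError, DegenerateCorrelationError):
                pooled[gold] = None
        summary["lpv_f_pearson"] = corr
        summary["lpv_f_pearson_pooled"] = pooled

        # per-probe peak windows (per gold) and their mean
        peaks: dict = {}
        for gold in sorted({g.name for g in golds}):
            sub_gold = f_df[f_df["gold"] == gold]
            per_probe = {}
            for probe, grp in sub_gold.groupby("probe"):
                try:
                    per_probe[probe] = peak_window(
                        dict(zip(grp["window_size"], grp["f_measure"])))
                except LitCohesionError:
                    continue
            peaks[gold] = {
                "per_probe": per_probe,
                "mean": (float(np.mean(list(per_probe.values())))
                         if per_probe else None),
            }
        summary["peak_window"] = peaks

    # exon/intron separation per window size and on per-probe means
    rank_sum: dict = {}
    for size in window_sizes:
        sub = lpv_df[lpv_df["window_size"] == size]
        exon = sub.loc[sub["region"] == "exon", "neg_log10"].to_numpy()
        intron = sub.loc[sub["region"] == "intron", "neg_log10"].to_numpy()
        if exon.size >= 2 and intron.size >= 2:
            rank_sum[str(size)] = benchmark.rank_sum_compare(exon, intron)
        else:
            rank_sum[str(size)] = None
    means = lpv_df.groupby("probe").agg(
        neg_log10=("neg_log10", "mean"), region=("region", "first"))
    exon_m = means.loc[means["region"] == "exon", "neg_log10"].to_numpy()
    intron_m = means.loc[means["region"] == "intron", "neg_log10"].to_numpy()
    rank_sum["probe_mean"] = (
        benchmark.rank_sum_compare(exon_m, intron_m)
        if exon_m.size >= 2 and intron_m.size >= 2 else None
    )
    summary["rank_sum_exon_intron"] = rank_sum

    # probe quality flags from the mean -log10(LPv) cutoff
    quality: dict = {"mode": "mean_neglog"}
    if len(means) >= 2:
        labels, cutoff = benchmark.classify_probes(means["neg_log10"].to_dict())
        quality["threshold"] = cutoff
        quality["per_probe"] = {
            p: {"mean_neg_log10": float(means.loc[p, "neg_log10"]),
                "region": str(means.loc[p, "region"]), "flag": labels[p]}
            for p in sorted(labels, key=natural_key)
        }
    per_size_flags: dict = {}
    for size in window_sizes:
        sub = lpv_df[lpv_df["window_size"] == size]
        if len(sub) >= 2:
            labels, cutoff = benchmark.classify_probes(
                dict(zip(sub["probe"], sub["neg_log10"])))
            per_size_flags[str(size)] = {"threshold": cutoff, "flags": labels}
    quality["per_window_size"] = per_size_flags
    summary["probe_quality"] = quality
    return summary


def run_workflow(config: RunConfig) -> dict:
    """Execute the full workflow and write records, summary and manifest to
    the configured output directory. Deterministic given config and seed."""
    out = _io.ensure_dir(config.out_dir)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        return _run_workflow_inner(config, out)
    except PipelineError as exc:
        failed_marker.write_text(f"{exc.stage}\n{exc}\n")
        raise


def _run_workflow_inner(config: RunConfig, out: Path) -> dict:
    with _Stage("concept-space"):
        if config.space is not None:
            space = corpus_lsi.ConceptSpace.load(config.space)
        else:
            gene_pmids = corpus_lsi.read_gene2pubmed(config.gene2pubmed)
            pmid_text = corpus_lsi.read_pmid_text(config.abstracts)
            corpus = corpus_lsi.build_documents(gene_pmids, pmid_text)
            space = corpus_lsi.build_space(
                corpus, rank=config.rank, min_gene_frequency=config.min_gene_freq,
                seed=derive_seed(config.seed, "svd"),
            )

    lpv_config = config.lpv
    with _Stage("background-threshold"):
        threshold = cohesion.estimate_threshold(space, lpv_config)

    with _Stage("expression"):
        dataset = coexpression.ExpressionDataset.from_files(
            config.expression, config.annotation)
        if config.seed_probes is not None:
            seed_probes = [str(p) for p in config.seed_probes]
            missing = [p for p in seed_probes if p not in dataset.values.index]
            if missing:
                raise LitCohesionError(f"seed probes not in dataset: {missing[:5]}")
        else:
            seed_probes = dataset.usable_probes()
        seed_probes = sorted(seed_probes, key=natural_key)

    with _Stage("gene-sets"):
        golds = [gs for path in config.gold_standards for gs in _io.read_gmt(path)]
        categories = [gs for path in config.categories for gs in _io.read_gmt(path)]
        universe = sorted({str(g) for g in dataset.annotation["gene_id"]},
                          key=natural_key)
        if not golds:
            logger.warning("no gold standards configured: F-measure and "
                           "correlation stages will be skipped")

    with _Stage("score-windows"):
        lpv_df, f_df, enr_df = _score_windows(
            space, threshold, lpv_config, dataset, seed_probes,
            config.window_sizes, config.rank_by, golds, categories, universe)
        if lpv_df.empty:
            raise LitCohesionError("no probe/window could be scored")

    with _Stage("summarize"):
        summary = _summarize(lpv_df, f_df, config.window_sizes, golds)
        summary["threshold"] = {
            "T": threshold.T, "mode": threshold.mode, "n_pairs": threshold.n_pairs,
            "percentile": threshold.percentile,
        }
        summary["n_probes"] = len(seed_probes)
        summary["window_sizes"] = config.window_sizes
        summary["seed"] = config.seed

    with _Stage("write-output"):
        lpv_df.to_csv(out / "records.tsv", sep="\t", index=False)
        if not f_df.empty:
            f_df.to_csv(out / "fmeasure.tsv", sep="\t", index=False)
        if not enr_df.empty:
            enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float))
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "lpv": dataclasses.asdict(lpv_config),
            "window_sizes": config.window_sizes,
            "rank_by": config.rank_by,
            "inputs": {str(p): file_digest(p) for p in config._input_paths()},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    return {"summary": summary, "records": lpv_df, "fmeasure": f_df,
            "enrichment": enr_df, "out_dir": out}


# ---------------------------------------------------------------------------
# in-memory synthetic benchmark (used by tests and the acceptance script)
# ---------------------------------------------------------------------------

def run_synthetic_benchmark(
    config: synthetic_data.SyntheticConfig,
    window_sizes=None,
    lpv_config: cohesion.LPvConfig | None = None,
    rank: int = 100,
) -> dict:
    """Generate a synthetic dataset and score every designed probe.

    Each probe's windows are scored with LPv and with precision/recall/F
    against the gold standard of the probe's own target module (ground truth
    is known), giving a per-probe benchmark table analogous to scoring seed
    probes against matched gold standards.
    """
    if window_sizes is None:
        window_sizes = [config.module_size]
    if lpv_config is None:
        lpv_config = cohesion.LPvConfig(seed=derive_seed(config.seed, "lpv"))

    corpus, truth = synthetic_data.generate_corpus(config)
    space = corpus_lsi.build_space(corpus, rank=rank,
                                   seed=derive_seed(config.seed, "svd"))
    threshold = cohesion.estimate_threshold(space, lpv_config)
    dataset, _ = synthetic_data.generate_expression(config, truth)
    golds = {
        module_id: synthetic_data.generate_gold_standard(
            truth, module_id, config.gold_dropout, config.gold_contamination,
            config.seed)
        for module_id in truth.modules
    }

    rows = []
    for probe in sorted(truth.probes, key=natural_key):
        info = truth.probes[probe]
        module_id = (info.source if info.source != "noise"
                     else truth.module_of(info.gene_id))
        gold = golds[module_id]
        series = coexpression.window_series(dataset, probe, sizes=window_sizes)
        for size, window in zip(series.sizes, series.windows):
            result = cohesion.lpv(space, window.genes, threshold, lpv_config,
                                  salt=f"{probe}:{size}")
            precision, recall, f = benchmark.precision_recall_f(window.genes,
                                                                gold.genes)
            rows.append({
                "probe": probe, "region": info.region, "source": info.source,
                "module": module_id, "gold": gold.name, "window_size": size,
                "p": result.p, "neg_log10": result.neg_log10,
                "A": result.A, "C": result.C,
                "precision": precision, "recall": recall, "f_measure": f,
            })
    records = pd.DataFrame(rows)
    return {"records": records, "truth": truth, "space": space,
            "threshold": threshold, "dataset": dataset, "golds": golds}
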