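"""Synthetic corpora, expression matrices, probe annotations and gold
standards with known planted structure.

The generator plants ``n_modules`` disjoint functional modules. Module genes
share module-private vocabulary in their literature documents (mixing
proportion ``signal_term_fraction``) and track a latent per-module activity
signal across strains through "exonic" probes, while "intronic" probes are
pure noise. Gold standards are dropout/contamination-corrupted copies of the
planted modules. Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus_lsi, io as _io
from ._util import natural_key, rng_for, stable_digest
from .coexpression import ExpressionDataset
from .errors import ConfigurationError, ConsistencyError, LitCohesionError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 500
    n_modules: int = 4
    module_size: int = 50
    vocab_size: int = 2000
    module_vocab_size: int = 150
    doc_length_mean: float = 150.0
    signal_term_fraction: float = 0.75
    n_strains: int = 40
    n_signal_probes_per_module: int = 3
    n_noise_probes: int = 12
    probe_noise_sd: float = 0.2
    expression_noise_sd: float = 0.1
    gold_dropout: float = 0.1
    gold_contamination: float = 0.1
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes, "n_modules": self.n_modules,
            "module_size": self.module_size, "vocab_size": self.vocab_size,
            "module_vocab_size": self.module_vocab_size,
            "n_strains": self.n_strains,
            "n_signal_probes_per_module": self.n_signal_probes_per_module,
            "n_noise_probes": self.n_noise_probes,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a count >= 1, got {value!r}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("n_modules * module_size <= n_genes is violated")
        if self.module_vocab_size * self.n_modules > self.vocab_size:
            raise ConfigurationError(
                "module_vocab_size * n_modules <= vocab_size is violated"
            )
        for name in ("signal_term_fraction", "gold_dropout", "gold_contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("doc_length_mean", "probe_noise_sd", "expression_noise_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v!r}")

    @property
    def background_vocab_size(self) -> int:
        return self.vocab_size - self.n_modules * self.module_vocab_size

    def digest(self) -> str:
        return stable_digest(dataclasses.asdict(self))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


@dataclass(frozen=True)
class ProbeInfo:
    gene_id: str
    region: str  # "exon" | "intron"
    source: str  # module id or "noise"


@dataclass
class ModuleTruth:
    """Ground truth of a synthetic dataset: gene universe, module membership,
    latent strain activities, and the designed probe layout."""

    genes: tuple
    modules: dict  # module_id -> tuple of member genes
    activities: dict  # module_id -> np.ndarray over strains
    probes: dict  # probe_id -> ProbeInfo
    config_digest: str

    def module_of(self, gene) -> str | None:
        for module_id, members in self.modules.items():
            if gene in members:
                return module_id
        return None

    def to_json(self, path) -> None:
        payload = {
            "genes": list(self.genes),
            "modules": {m: list(v) for m, v in self.modules.items()},
            "activities": {m: [float(x) for x in v] for m, v in self.activities.items()},
            "probes": {p: dataclasses.asdict(info) for p, info in self.probes.items()},
            "config_digest": self.config_digest,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "ModuleTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=tuple(payload["genes"]),
            modules={m: tuple(v) for m, v in payload["modules"].items()},
            activities={m: np.asarray(v, dtype=float)
                        for m, v in payload["activities"].items()},
            probes={p: ProbeInfo(**info) for p, info in payload["probes"].items()},
            config_digest=payload["config_digest"],
        )


def _gene_ids(config: SyntheticConfig) -> list:
    return [f"g{i:05d}" for i in range(config.n_genes)]


def _vocab(config: SyntheticConfig):
    module_terms = [
        np.array([f"mt{m}_{i:04d}" for i in range(config.module_vocab_size)])
        for m in range(config.n_modules)
    ]
    background = np.array([f"bt{i:05d}" for i in range(config.background_vocab_size)])
    return module_terms, background


def generate_corpus(config: SyntheticConfig):
    """Generate a gene-document corpus with planted module vocabulary.

    Tokens of a module gene come from the module's private vocabulary with
    probability ``signal_term_fraction`` and from the shared background
    vocabulary otherwise; background genes draw background terms only.
    Document lengths are Poisson with the configured mean, truncated at >= 1.
    Returns the corpus and the ground truth (membership, latent activities,
    probe layout).
    """
    needs_background = (
        config.signal_term_fraction < 1.0
        or config.n_genes > config.n_modules * config.module_size
    )
    if config.background_vocab_size < 1 and needs_background:
        raise ConfigurationError(
            "background vocabulary is empty but background terms are needed "
            "(module_vocab_size * n_modules == vocab_size)"
        )
    genes = _gene_ids(config)
    module_terms, background_terms = _vocab(config)
    module_ids = [f"m{j}" for j in range(config.n_modules)]
    modules = {
        module_ids[j]: tuple(genes[j * config.module_size:(j + 1) * config.module_size])
        for j in range(config.n_modules)
    }
    gene_pmids, pmid_text = _generate_documents(config)
    corpus = corpus_lsi.build_documents(gene_pmids, pmid_text)

    rng_act = rng_for(config.seed, "activity")
    activities = {
        module_id: rng_act.standard_normal(config.n_strains)
        for module_id in module_ids
    }

    probes: dict = {}
    for j, module_id in enumerate(module_ids):
        members = modules[module_id]
        for p in range(config.n_signal_probes_per_module):
            gene = members[p % len(members)]
            probes[f"{gene}_ex{p // len(members)}"] = ProbeInfo(
                gene_id=gene, region="exon", source=module_id)
    all_module_genes = [g for module_id in module_ids for g in modules[module_id]]
    for q in range(config.n_noise_probes):
        gene = all_module_genes[q % len(all_module_genes)]
        rep = q // len(all_module_genes)
        probes[f"{gene}_in{rep}"] = ProbeInfo(gene_id=gene, region="intron",
                                              source="noise")

    truth = ModuleTruth(
        genes=tuple(genes),
        modules=modules,
        activities=activities,
        probes=probes,
        config_digest=config.digest(),
    )
    return corpus, truth


def generate_expression(config: SyntheticConfig, truth: ModuleTruth):
    """Realize the expression matrix for a ground truth.

    Signal ("exon") probes follow their module's latent activity plus
    per-gene loading noise (SD ``expression_noise_sd``, shared across a
    gene's rows) and per-probe measurement noise (SD ``probe_noise_sd``);
    noise ("intron") probes are i.i.d. standard normal. Every gene also gets
    one gene-level expression row (id ``<gene>_x``) so that co-expression
    windows are gene sets: module genes track their module, background genes
    are noise. Returns the dataset and its probe annotation table.
    """
    if truth.config_digest != config.digest():
        raise ConsistencyError("truth was generated under a different config")
    rng = rng_for(config.seed, "expression")
    strains = [f"s{i:03d}" for i in range(config.n_strains)]
    gene_module = {g: m for m, members in truth.modules.items() for g in members}

    # per-gene loading noise, shared by all rows of a module gene
    gene_load = {
        g: rng.normal(0.0, config.expression_noise_sd, size=config.n_strains)
        for g in truth.genes if g in gene_module
    }

    rows, index, annot = [], [], []
    for gene in truth.genes:
        module_id = gene_module.get(gene)
        if module_id is not None:
            row = (truth.activities[module_id] + gene_load[gene]
                   + rng.normal(0.0, config.probe_noise_sd, size=config.n_strains))
        else:
            row = rng.standard_normal(config.n_strains)
        rows.append(row)
        index.append(f"{gene}_x")
        annot.append((f"{gene}_x", gene, "exon"))

    for probe_id in truth.probes:
        info = truth.probes[probe_id]
        if info.source == "noise":
            row = rng.standard_normal(config.n_strains)
        else:
            row = (truth.activities[info.source] + gene_load[info.gene_id]
                   + rng.normal(0.0, config.probe_noise_sd, size=config.n_strains))
        rows.append(row)
        index.append(probe_id)
        annot.append((probe_id, info.gene_id, info.region))

    values = pd.DataFrame(np.vstack(rows), index=index, columns=strains)
    annotation = pd.DataFrame(annot, columns=["probe_id", "gene_id", "region"]
                              ).set_index("probe_id")
    dataset = ExpressionDataset(values=values, annotation=annotation)
    return dataset, annotation


def generate_gold_standard(truth: ModuleTruth, module_id: str,
                           gold_dropout: float, gold_contamination: float,
                           seed: int) -> _io.GeneSet:
    """A corrupted copy of one module: members retained with probability
    ``1 - gold_dropout``, plus ``round(gold_contamination * module_size)``
    contaminant genes drawn uniformly from non-members."""
    if module_id not in truth.modules:
        raise LitCohesionError(f"unknown module {module_id!r}")
    if not 0.0 <= gold_dropout <= 1.0 or not 0.0 <= gold_contamination <= 1.0:
        raise ConfigurationError("gold_dropout and gold_contamination must lie in [0, 1]")
    members = truth.modules[module_id]
    rng = rng_for(seed, f"gold:{module_id}")
    keep = rng.random(len(members)) < (1.0 - gold_dropout)
    retained = {g for g, k in zip(members, keep) if k}
    n_contaminants = round(gold_contamination * len(members))
    pool = sorted(set(truth.genes) - set(members), key=natural_key)
    contaminants = set()
    if n_contaminants > 0:
        if n_contaminants > len(pool):
            raise ConfigurationError("not enough non-member genes for contamination")
        contaminants = set(rng.choice(pool, size=n_contaminants, replace=False).tolist())
    return _io.GeneSet(
        name=f"gs_{module_id}",
        genes=frozenset(retained | contaminants),
        description=(f"module {module_id} with dropout={gold_dropout} "
                     f"contamination={gold_contamination}"),
    )


def generate_categories(truth: ModuleTruth, extra_fraction: float = 0.5,
                        seed: int = 0) -> list:
    """Annotation-category stand-ins: each module's members plus a tail of
    random non-member genes (so enrichment is strong but not trivial)."""
    categories = []
    for module_id in sorted(truth.modules, key=natural_key):
        members = set(truth.modules[module_id])
        rng = rng_for(seed, f"category:{module_id}")
        pool = sorted(set(truth.genes) - members, key=natural_key)
        n_extra = min(len(pool), round(extra_fraction * len(members)))
        extra = set(rng.choice(pool, size=n_extra, replace=False).tolist()) if n_extra else set()
        categories.append(_io.GeneSet(
            name=f"cat_{module_id}",
            genes=frozenset(members | extra),
            description=f"module {module_id} plus {n_extra} bystander genes",
        ))
    return categories


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def simulate_to_directory(config: SyntheticConfig, out_dir, seed: int | None = None) -> dict:
    """Generate a full synthetic dataset and write every artifact as text.

    Produces the corpus (gene2pubmed.tsv + abstracts.tsv), expression matrix,
    probe annotation, gold standards, categories, ground truth JSON, a config
    echo, and a ready-to-run workflow config (run.yaml). Returns the path map.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = _io.ensure_dir(out_dir)

    corpus, truth = generate_corpus(config)
    with open(out / "gene2pubmed.tsv", "w", encoding="utf-8") as fh:
        fh.write("#tax_id\tGeneID\tPubMed_ID\n")
        for gene in corpus.genes:
            for pmid in sorted(corpus.pmids[gene]):
                fh.write(f"10090\t{gene}\t{pmid}\n")
    _, pmid_text = _generate_documents(config)
    with open(out / "abstracts.tsv", "w", encoding="utf-8") as fh:
        for pmid in sorted(pmid_text):
            fh.write(f"{pmid}\t{pmid_text[pmid]}\n")

    dataset, annotation = generate_expression(config, truth)
    _io.write_expression(dataset.values, out / "expression.tsv")
    _io.write_annotation(annotation, out / "probes.tsv")

    golds = [
        generate_gold_standard(truth, module_id, config.gold_dropout,
                               config.gold_contamination, config.seed)
        for module_id in sorted(truth.modules, key=natural_key)
    ]
    _io.write_gmt(golds, out / "gold_standards.gmt")
    _io.write_gmt(generate_categories(truth, seed=config.seed), out / "categories.gmt")
    truth.to_json(out / "truth.json")
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))

    sizes = sorted({max(10, config.module_size // 2), config.module_size,
                    2 * config.module_size, 4 * config.module_size})
    run_cfg = {
        "seed": config.seed,
        "out_dir": "results",
        "corpus": {
            "gene2pubmed": "gene2pubmed.tsv",
            "abstracts": "abstracts.tsv",
            "rank": 100,
            "min_gene_freq": 2,
        },
        "expression": "expression.tsv",
        "annotation": "probes.tsv",
        "seed_probes": sorted(truth.probes, key=natural_key),
        "gold_standards": ["gold_standards.gmt"],
        "categories": ["categories.gmt"],
        "window_sizes": sizes,
        "rank_by": "abs",
        "lpv": {"percentile": 95.0, "k": 50, "n": 1000, "N": 1000,
                "background_pair_budget": 1_000_000},
    }
    (out / "run.yaml").write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    logger.info("simulate: wrote synthetic dataset to %s", out)
    return {name: out / name for name in (
        "gene2pubmed.tsv", "abstracts.tsv", "expression.tsv", "probes.tsv",
        "gold_standards.gmt", "categories.gmt", "truth.json", "config.yaml",
        "run.yaml",
    )}


def _generate_documents(config: SyntheticConfig):
    """The seeded token stream behind generate_corpus: per-gene tokens split
    into per-PMID chunks. Deterministic given the config (and its seed)."""
    genes = _gene_ids(config)
    module_terms, background_terms = _vocab(config)
    module_ids = [f"m{j}" for j in range(config.n_modules)]
    gene_module = {}
    for j, module_id in enumerate(module_ids):
        for g in genes[j * config.module_size:(j + 1) * config.module_size]:
            gene_module[g] = module_id
    rng = rng_for(config.seed, "corpus")
    lengths = np.maximum(1, rng.poisson(config.doc_length_mean, size=config.n_genes))
    pmid_counter = 100_000
    gene_pmids: dict = {}
    pmid_text: dict = {}
    s = config.signal_term_fraction
    for gi, gene in enumerate(genes):
        length = int(lengths[gi])
        module_id = gene_module.get(gene)
        if module_id is not None and s > 0:
            from_module = rng.random(length) < s
            mod_idx = rng.integers(0, config.module_vocab_size, size=length)
            if config.background_vocab_size >= 1:
                bg_idx = rng.integers(0, config.background_vocab_size, size=length)
                bg_tokens = background_terms[bg_idx]
            else:
                bg_tokens = module_terms[int(module_id[1:])][mod_idx]
            tokens = np.where(from_module,
                              module_terms[int(module_id[1:])][mod_idx], bg_tokens)
        else:
            tokens = background_terms[rng.integers(0, config.background_vocab_size,
                                                   size=length)]
        n_pm = min(length, int(rng.integers(1, 4)))
        pmids = set()
        for chunk in np.array_split(tokens, n_pm):
            pmid_counter += 1
            pmid_text[pmid_counter] = " ".join(chunk.tolist())
            pmids.add(pmid_counter)
        gene_pmids[gene] = pmids
    return gene_pmids, pmid_text
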