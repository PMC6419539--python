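"""Readers and writers for the plain-text formats used across the pipeline.

Formats: GMT gene sets, expression TSV (first column probe id, header row of
strain names, empty cell = missing), probe annotation TSV
(probe_id<TAB>gene_id<TAB>region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import ParseError
from ._util import natural_key

VALID_REGIONS = ("exon", "intron")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT row)."""

    name: str
    genes: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes, key=natural_key))

    def __contains__(self, gene) -> bool:
        return gene in self.genes


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT row needs name, description and at least one gene",
                    path=path, line=lineno,
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError("GMT row has an empty gene list", path=path, line=lineno)
            sets.append(GeneSet(name=name, genes=genes, description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes, key=natural_key))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_expression(path) -> pd.DataFrame:
    """Probes x strains matrix; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="", index_label="probe_id")


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation: index probe_id, columns gene_id and region."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"probe_id", "gene_id", "region"}
    if not expected.issubset(df.columns):
        raise ParseError(
            f"annotation must have columns {sorted(expected)}, got {list(df.columns)}",
            path=path,
        )
    bad = ~df["region"].isin(VALID_REGIONS)
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(
            f"region must be one of {VALID_REGIONS}, got {df.loc[bad.idxmax(), 'region']!r}",
            path=path, line=lineno,
        )
    return df.set_index("probe_id")


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
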