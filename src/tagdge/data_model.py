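"""Domain types and tab-separated readers/writers for tag-count experiments.

The on-disk formats are deliberately minimal, UTF-8 and tab-delimited with
``#`` comment lines:

* **count table** — gene rows x sample columns; the first two columns are
  ``gene_id`` and ``length_bp``, every remaining column is one sequencing
  library of non-negative integer tag counts.
* **annotation map** — one ``gene_id<TAB>term_id`` pair per line with an
  optional human-readable label and, for pathway (KEGG) maps, optional
  level-1/level-2 category labels.
* **result tables** — one record per row; :func:`write_table` /
  :func:`read_table` round-trip any of the package's record dataclasses.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConfigurationError",
    "GeneModel",
    "TagLibrary",
    "ExpressionMatrix",
    "AnnotationMap",
    "QpcrMeasurement",
    "NAMESPACES",
    "read_count_table",
    "write_count_table",
    "read_annotation_map",
    "write_annotation_map",
    "read_design",
    "write_table",
    "read_table",
]

NAMESPACES = ("GO_BP", "GO_CC", "GO_MF", "KEGG")

_INT_RE = re.compile(r"[+-]?\d+")


class FormatError(ValueError):
    """A file violates the expected tab-separated layout or cell types."""


class ConfigurationError(ValueError):
    """An option or label does not match the loaded data."""


@dataclass(frozen=True)
class GeneModel:
    """A gene (or assembled unigene) with its model length in bases."""

    gene_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise FormatError(f"gene {self.gene_id}: length_bp must be >= 1, got {self.length_bp}")


@dataclass
class TagLibrary:
    """One sequencing library: per-gene tag counts plus sample metadata.

    ``total_tags`` is the library depth (the N of RPKM and the N1/N2 of the
    exact pairwise test) and always equals the sum of ``counts``.
    """

    sample_id: str
    counts: dict[str, int]
    genotype: str = ""
    treatment: str = ""
    replicate: int = 1
    total_tags: int = field(default=-1)

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise FormatError(f"library {self.sample_id}: negative count for gene {g}")
        total = sum(self.counts.values())
        if self.total_tags < 0:
            self.total_tags = total
        elif self.total_tags != total:
            raise FormatError(
                f"library {self.sample_id}: stored total_tags {self.total_tags} "
                f"!= sum of counts {total}"
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of normalized expression values (RPKM units)."""

    values: pd.DataFrame  # index: gene_id, columns: sample_id, float64

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("expression values must be finite and non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AnnotationMap:
    """Gene -> term multimap for one annotation namespace.

    ``universe`` — the set of all annotated genes — is the background N of
    the hypergeometric enrichment test.
    """

    namespace: str
    term_genes: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    levels: dict[str, tuple[str, str]] = field(default_factory=dict)  # KEGG only

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ConfigurationError(
                f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}"
            )
        for term, genes in self.term_genes.items():
            if not genes:
                raise ConfigurationError(f"term {term}: empty gene set")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.term_genes)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well pair: target and reference Ct for one sample."""

    sample_id: str
    target_gene: str
    reference_gene: str
    ct_target: float
    ct_reference: float
    group: str = ""  # "control" or "treatment"

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_count_table(path: str | Path) -> tuple[list[GeneModel], list[TagLibrary]]:
    """Read a gene x sample tag-count TSV.

    The first two columns are ``gene_id`` and ``length_bp``; each further
    column is one library. Counts must be non-negative integers — missing or
    fractional cells are an error rather than silently imputed, because a
    wrong library total corrupts the exact test.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least gene_id and length_bp columns")
    gene_col, len_col = df.columns[:2]
    sample_cols = list(df.columns[2:])

    genes: list[GeneModel] = []
    seen: set[str] = set()
    lengths: list[int] = []
    for i, (gid, ln) in enumerate(zip(df[gene_col], df[len_col])):
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene_id {gid!r} at data row {i + 1}")
        seen.add(gid)
        if not _INT_RE.fullmatch(ln.strip() or ""):
            raise FormatError(f"{path}: non-integer length {ln!r} at row {i + 1} (gene {gid})")
        length = int(ln)
        if length < 1:
            raise FormatError(f"{path}: length {length} < 1 at row {i + 1} (gene {gid})")
        genes.append(GeneModel(gid, length))
        lengths.append(length)

    libraries: list[TagLibrary] = []
    for col in sample_cols:
        counts: dict[str, int] = {}
        for i, (gid, cell) in enumerate(zip(df[gene_col], df[col])):
            s = cell.strip()
            if not _INT_RE.fullmatch(s or ""):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {i + 1}, column {col!r}"
                )
            c = int(s)
            if c < 0:
                raise FormatError(f"{path}: negative count at row {i + 1}, column {col!r}")
            counts[gid] = c
        libraries.append(TagLibrary(sample_id=col, counts=counts))
    return genes, libraries


def write_count_table(
    genes: Sequence[GeneModel], libraries: Sequence[TagLibrary], path: str | Path
) -> None:
    """Write genes x libraries to the count-table TSV format."""
    data = {"gene_id": [g.gene_id for g in genes], "length_bp": [g.length_bp for g in genes]}
    for lib in libraries:
        missing = [g.gene_id for g in genes if g.gene_id not in lib.counts]
        if missing:
            raise ConfigurationError(
                f"library {lib.sample_id} lacks counts for {len(missing)} genes "
                f"(first: {missing[0]})"
            )
        data[lib.sample_id] = [lib.counts[g.gene_id] for g in genes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_annotation_map(path: str | Path, namespace: str) -> AnnotationMap:
    """Read a gene -> term map: ``gene<TAB>term[<TAB>label[<TAB>lvl1<TAB>lvl2]]``."""
    if namespace not in NAMESPACES:
        raise ConfigurationError(
            f"unknown namespace {namespace!r}; expected one of {NAMESPACES}"
        )
    amap = AnnotationMap(namespace=namespace)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            gene, term = parts[0], parts[1]
            amap.term_genes.setdefault(term, set()).add(gene)
            if len(parts) >= 3 and parts[2]:
                amap.labels[term] = parts[2]
            if len(parts) >= 5 and (parts[3] or parts[4]):
                amap.levels[term] = (parts[3], parts[4])
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(amap.term_genes):
            label = amap.labels.get(term, "")
            lvl = amap.levels.get(term)
            for gene in sorted(amap.term_genes[term]):
                fields = [gene, term, label]
                if lvl is not None:
                    fields += [lvl[0], lvl[1]]
                fh.write("\t".join(fields) + "\n")


def read_design(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a design TSV mapping sample_id -> (condition, replicate)."""
    df = _read_tsv(path)
    need = {"sample_id", "condition", "replicate"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: design file needs columns {sorted(need)}")
    out: dict[str, tuple[str, int]] = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = (row["condition"], int(row["replicate"]))
    return out


def write_table(records: Iterable, path: str | Path) -> None:
    """Write a list of record dataclasses (or dicts) as a headed TSV.

    Floats are written at full round-trip precision so that
    ``read_table(write_table(x)) == x``.
    """
    rows = []
    for r in records:
        rows.append(dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r))
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, cls=None) -> list:
    """Read a TSV written by :func:`write_table`.

    With ``cls`` (a dataclass), cells are coerced to the declared field types
    and instances are returned; otherwise plain dicts of strings.
    """
    try:
        df = _read_tsv(path)
    except pd.errors.EmptyDataError:
        return []
    if cls is None:
        return [dict(row) for _, row in df.iterrows()]
    hints = {f.name: f.type for f in dataclasses.fields(cls)}
    casts = {"int": int, "float": float, "str": str, "bool": lambda s: s == "True"}
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for name, raw in row.items():
            if name not in hints:
                continue
            t = hints[name]
            tname = t if isinstance(t, str) else getattr(t, "__name__", "str")
            kwargs[name] = casts.get(tname, str)(raw)
        out.append(cls(**kwargs))
    return out
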