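"""Correlation-thresholded co-expression ("protein-protein interaction") network.

Every gene pair is scored by the sample Pearson correlation of its
expression profiles; an edge is kept when |R| exceeds a threshold (default
0.99) and the Benjamini–Hochberg FDR of the correlation test falls below a
cap (default 0.05). The p-value model is the standard exact-under-normality
t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom. Genes
with zero expression variance have no defined correlation and are excluded
up front (and logged). The resulting graph is simple and undirected, with
edges in canonical (gene_a < gene_b) order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import t as t_dist

from .data_model import ExpressionMatrix
from .pairwise_deg import bh_fdr

__all__ = ["CoexpressionEdge", "pearson_r", "correlation_p", "build_network", "write_sif"]

log = logging.getLogger(__name__)


@dataclass
class CoexpressionEdge:
    gene_a: str
    gene_b: str
    r: float
    p_raw: float
    q_fdr: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("edges must be in canonical order gene_a < gene_b")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length profiles (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: zero-variance profile")
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def correlation_p(r, n: int):
    """Two-sided p for a Pearson correlation from n samples (t transform)."""
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    r = np.asarray(r, dtype=float)
    if (np.abs(r) > 1).any():
        raise ValueError("|r| must be <= 1")
    with np.errstate(divide="ignore"):
        tval = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * t_dist.sf(np.abs(tval), df=n - 2))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def build_network(
    expr: ExpressionMatrix,
    r_min: float = 0.99,
    q_max: float = 0.05,
    genes: Sequence[str] | None = None,
) -> list[CoexpressionEdge]:
    """All gene-pair edges with |R| > ``r_min`` and BH-FDR < ``q_max``.

    ``genes`` optionally restricts the node set (e.g. to protein-coding
    DEGs). FDR is computed across every tested pair, not only the kept
    ones. Output is sorted by (gene_a, gene_b).
    """
    df = expr.values
    if genes is not None:
        df = df.loc[[g for g in df.index if g in set(genes)]]
    n_samples = df.shape[1]
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {n_samples}")

    X = df.to_numpy(dtype=float)
    variable = X.std(axis=1) > 0.0
    n_const = int((~variable).sum())
    if n_const:
        log.info("build_network: %d zero-variance genes excluded", n_const)
    X = X[variable]
    ids = [g for g, keep in zip(df.index, variable) if keep]
    if len(ids) < 2:
        return []

    R = np.clip(np.corrcoef(X), -1.0, 1.0)
    iu, ju = np.triu_indices(len(ids), k=1)
    r = R[iu, ju]
    p = correlation_p(r, n_samples)
    q = bh_fdr(np.atleast_1d(p))

    keep = (np.abs(r) > r_min) & (q < q_max)
    edges = []
    for i, j, rv, pv, qv in zip(iu[keep], ju[keep], r[keep], p[keep], q[keep]):
        a, b = sorted((ids[i], ids[j]))
        edges.append(CoexpressionEdge(a, b, float(rv), float(pv), float(qv)))
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def write_sif(edges: Sequence[CoexpressionEdge], path) -> None:
    """Simple-interaction-format export for graph viewers: `a co b` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in edges:
            fh.write(f"{e.gene_a}\tco\t{e.gene_b}\n")
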