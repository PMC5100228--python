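"""Exact two-library differential-expression screen (Audic–Claverie test).

A gene with x tags in a library of N1 total tags and y tags in a library of
N2 total tags is tested against the null of equal underlying transcript
proportion. Conditional on x, the null distribution of y is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

a negative-binomial law with x+1 "successes" and success probability
N1/(N1+N2). The two-sided p-value doubles the smaller tail of the partial
sum S = sum_{i=0..y} p(i|x): 2S when S <= 0.5, else 2(1-S), clamped to
[0, 1]. Multiple testing across genes is controlled by Benjamini–Hochberg
FDR; calls additionally require a minimum |log2 fold change| on RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

from .data_model import GeneModel, TagLibrary
from .normalization import rpkm

__all__ = [
    "DEGRecord",
    "ac_conditional_prob",
    "ac_two_sided_p",
    "bh_fdr",
    "screen_pairwise",
    "ZERO_EXPRESSION_SUBSTITUTE",
]

# expression value substituted for zeros before taking log ratios, so every
# log2 fold change is finite; shared with the group (noise-distribution) screen
ZERO_EXPRESSION_SUBSTITUTE = 0.001


def _validate_counts(x, y, n1, n2) -> None:
    x, y = np.asarray(x), np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("tag counts must be non-negative")
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("library totals must be >= 1")


def ac_conditional_prob(x, y, n1, n2):
    """Null probability p(y|x) of observing y tags given x (see module docs).

    Evaluated in log-space via log-gamma; accepts scalars or arrays.
    """
    _validate_counts(x, y, n1, n2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.asarray(n2, dtype=float) / np.asarray(n1, dtype=float)
    logp = (
        y * np.log(r)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(r)
    )
    p = np.exp(logp)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _lower_tail(x, y, n1, n2):
    """S = sum_{i=0..y} p(i|x), via the regularized incomplete beta identity.

    Conditional on x, y is negative-binomial(x+1, N1/(N1+N2)), whose CDF at y
    is I_p(x+1, y+1) with p = N1/(N1+N2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p = n1 / (n1 + n2)
    return betainc(x + 1.0, y + 1.0, np.broadcast_to(p, np.broadcast_shapes(x.shape, y.shape, p.shape)))


def ac_two_sided_p(x, y, n1, n2):
    """Two-sided exact p-value: 2S if S <= 0.5 else 2(1-S), clamped to [0, 1].

    The upper branch 1-S = sum_{i>y} p(i|x) is evaluated directly through
    the symmetry I_p(a, b) = 1 - I_{1-p}(b, a) of the regularized
    incomplete beta function, avoiding cancellation when S is close to 1.
    """
    _validate_counts(x, y, n1, n2)
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    n1_a = np.asarray(n1, dtype=float)
    n2_a = np.asarray(n2, dtype=float)
    s = _lower_tail(x, y, n1, n2)
    shape = np.broadcast_shapes(x_a.shape, y_a.shape, n1_a.shape, n2_a.shape)
    q = np.broadcast_to(n2_a / (n1_a + n2_a), shape)
    upper = betainc(
        np.broadcast_to(y_a, shape) + 1.0, np.broadcast_to(x_a, shape) + 1.0, q
    )
    # s + upper = 1 exactly in real arithmetic; renormalizing by their sum
    # removes the last-ulp drift of the beta evaluations, so symmetric cases
    # (x = y with equal totals) give p = 1.0 exactly
    total = s + upper
    p = np.where(s <= upper, 2.0 * s / total, 2.0 * upper / total)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clamped to 1. Depends only on the
    multiset of p-values, so tie order is observationally irrelevant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class DEGRecord:
    """Per-gene result of the pairwise exact test."""

    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    log2_ratio: float  # log2(RPKM_2 / RPKM_1), zeros substituted
    p_raw: float
    q_fdr: float
    direction: str  # "up" | "down" | "ns"


def screen_pairwise(
    lib1: TagLibrary,
    lib2: TagLibrary,
    genes: Sequence[GeneModel],
    q_max: float = 0.001,
    min_abs_log2: float = 1.0,
) -> list[DEGRecord]:
    """Test every gene between two libraries; call up/down at the thresholds.

    ``up`` means higher in ``lib2`` (log2 ratio = log2(RPKM2/RPKM1) >=
    ``min_abs_log2`` at q <= ``q_max``); ``down`` the mirror; otherwise
    ``ns``. Zero RPKM values are substituted with
    :data:`ZERO_EXPRESSION_SUBSTITUTE` before the ratio so it stays finite.
    """
    if not genes:
        raise ValueError("empty gene catalog")
    gid = [g.gene_id for g in genes]
    try:
        x = np.array([lib1.counts[g] for g in gid], dtype=np.int64)
        y = np.array([lib2.counts[g] for g in gid], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"gene {e.args[0]!r} missing from a library") from None
    n1, n2 = lib1.total_tags, lib2.total_tags

    p_raw = np.atleast_1d(ac_two_sided_p(x, y, n1, n2))
    q = bh_fdr(p_raw)

    lengths = np.array([g.length_bp for g in genes], dtype=float)
    r1 = 1e6 * x / (n1 * lengths / 1e3)
    r2 = 1e6 * y / (n2 * lengths / 1e3)
    r1 = np.where(r1 == 0.0, ZERO_EXPRESSION_SUBSTITUTE, r1)
    r2 = np.where(r2 == 0.0, ZERO_EXPRESSION_SUBSTITUTE, r2)
    l2 = np.log2(r2 / r1)

    records = []
    for i, g in enumerate(gid):
        if q[i] <= q_max and l2[i] >= min_abs_log2:
            direction = "up"
        elif q[i] <= q_max and l2[i] <= -min_abs_log2:
            direction = "down"
        else:
            direction = "ns"
        records.append(
            DEGRecord(
                gene_id=g,
                x=int(x[i]),
                y=int(y[i]),
                n1=n1,
                n2=n2,
                log2_ratio=float(l2[i]),
                p_raw=float(p_raw[i]),
                q_fdr=float(q[i]),
                direction=direction,
            )
        )
    return records
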