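"""Replicate-aware group screen against an empirical (M, D) noise distribution.

For two expression values the signal statistics are M = log2(x1/x2) (zeros
substituted with 0.001 so the log is defined) and D = |x1 - x2| on the
original values. The *noise distribution* pools (M, D) over every gene and
every unordered within-condition replicate pair — it captures how large
fold changes and absolute differences get between biological replicates
that share a condition. A gene's between-condition signal (M, D), computed
on condition means, is then scored by the fraction of noise points it
strictly dominates (|M_noise| < |M_signal| and D_noise < D_signal); genes
whose score exceeds a probability threshold (default 0.8) are called.
Two replicates in a single condition are sufficient to build the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .data_model import ConfigurationError, ExpressionMatrix
from .pairwise_deg import ZERO_EXPRESSION_SUBSTITUTE

__all__ = [
    "NoiseDistribution",
    "GroupDEGRecord",
    "md_pair",
    "build_noise_distribution",
    "de_probability",
    "screen_group",
]


@dataclass
class NoiseDistribution:
    """Pooled (M, D) pairs from within-condition replicate contrasts."""

    m: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.m.shape != self.d.shape:
            raise ValueError("m and d must have equal length")
        if self.d.size and (self.d < 0).any():
            raise ValueError("D values must be non-negative")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.m.tolist(), self.d.tolist()))

    def __len__(self) -> int:
        return self.m.size


@dataclass
class GroupDEGRecord:
    gene_id: str
    m_signal: float
    d_signal: float
    prob_de: float
    called: bool


def md_pair(x1: float, x2: float) -> tuple[float, float]:
    """(M, D) for one pair of expression values.

    M uses the 0.001 zero substitution; D is computed on the original,
    pre-substitution values (|x1 - x2| is well-defined at zero).
    """
    if x1 < 0 or x2 < 0 or not (np.isfinite(x1) and np.isfinite(x2)):
        raise ValueError("expression values must be finite and non-negative")
    a = x1 if x1 > 0 else ZERO_EXPRESSION_SUBSTITUTE
    b = x2 if x2 > 0 else ZERO_EXPRESSION_SUBSTITUTE
    return float(np.log2(a / b)), float(abs(x1 - x2))


def _md_vector(v1: np.ndarray, v2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.where(v1 > 0, v1, ZERO_EXPRESSION_SUBSTITUTE)
    b = np.where(v2 > 0, v2, ZERO_EXPRESSION_SUBSTITUTE)
    return np.log2(a / b), np.abs(v1 - v2)


def _groups(expr: ExpressionMatrix, condition_of: Callable[[str], str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in expr.samples:
        groups.setdefault(condition_of(s), []).append(s)
    return groups


def build_noise_distribution(
    expr: ExpressionMatrix,
    condition_of: Callable[[str], str],
    conditions: Sequence[str] | None = None,
) -> NoiseDistribution:
    """Pool (M, D) over all genes and all within-condition replicate pairs.

    ``conditions`` restricts the pooling scope (default: every condition in
    the matrix).
    """
    groups = _groups(expr, condition_of)
    if conditions is not None:
        groups = {c: groups[c] for c in conditions if c in groups}
    ms, ds = [], []
    for _cond, samples in sorted(groups.items()):
        for s1, s2 in combinations(samples, 2):
            v1 = expr.values[s1].to_numpy(dtype=float)
            v2 = expr.values[s2].to_numpy(dtype=float)
            m, d = _md_vector(v1, v2)
            ms.append(m)
            ds.append(d)
    if not ms:
        raise ValueError("no condition has >= 2 replicates; cannot build noise distribution")
    return NoiseDistribution(m=np.concatenate(ms), d=np.concatenate(ds))


def de_probability(m: float, d: float, noise: NoiseDistribution) -> float:
    """Fraction of noise points strictly dominated by the signal (m, d)."""
    if len(noise) == 0:
        raise ValueError("empty noise distribution")
    dominated = (np.abs(noise.m) < abs(m)) & (noise.d < d)
    return float(dominated.mean())


def _de_probabilities(m: np.ndarray, d: np.ndarray, noise: NoiseDistribution) -> np.ndarray:
    """Vectorized dominance fractions, chunked to bound memory."""
    if len(noise) == 0:
        raise ValueError("empty noise distribution")
    am = np.abs(m)[:, None]
    out = np.empty(m.size, dtype=float)
    nm, nd = np.abs(noise.m)[None, :], noise.d[None, :]
    chunk = max(1, int(2e7) // max(1, len(noise)))
    for i in range(0, m.size, chunk):
        sl = slice(i, i + chunk)
        dom = (nm < am[sl]) & (nd < d[sl, None])
        out[sl] = dom.mean(axis=1)
    return out


def screen_group(
    expr: ExpressionMatrix,
    condition_of: Callable[[str], str],
    cond_a: str,
    cond_b: str,
    q_threshold: float = 0.8,
    noise: NoiseDistribution | None = None,
) -> list[GroupDEGRecord]:
    """Screen cond_a vs cond_b: signal from condition means, null from replicates.

    ``m_signal`` = log2(mean_a / mean_b). A precomputed ``noise``
    distribution may be supplied to control the pooling scope; by default it
    is built from the two contrasted conditions.
    """
    groups = _groups(expr, condition_of)
    for c in (cond_a, cond_b):
        if c not in groups:
            raise ConfigurationError(f"unknown condition label {c!r}")
    if noise is None:
        noise = build_noise_distribution(expr, condition_of, conditions=[cond_a, cond_b])

    mean_a = expr.values[groups[cond_a]].mean(axis=1).to_numpy(dtype=float)
    mean_b = expr.values[groups[cond_b]].mean(axis=1).to_numpy(dtype=float)
    m, d = _md_vector(mean_a, mean_b)
    prob = _de_probabilities(m, d, noise)
    return [
        GroupDEGRecord(
            gene_id=g,
            m_signal=float(m[i]),
            d_signal=float(d[i]),
            prob_de=float(prob[i]),
            called=bool(prob[i] >= q_threshold),
        )
        for i, g in enumerate(expr.genes)
    ]
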