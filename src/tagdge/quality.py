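"""Illumina base-quality <-> error-rate conversion on the log-odds scale.

The sequencing protocol this package models scores a base call with
``SQ = -10 * log10(E / (1 - E))`` where E is the per-base error
probability. This is a log-*odds* (logistic) scale, not the standard Phred
scale ``Q = -10 log10 E``: at SQ = 0 the odds are 1 and E = 0.5. Inverting,

    Y = 10 ** (-SQ / 10)        (the error odds)
    E = Y / (1 + Y)

Both directions are pure numeric utilities; no read filtering is attached.
"""

from __future__ import annotations

import math

__all__ = ["error_rate_from_quality", "quality_from_error"]


def error_rate_from_quality(sq: float) -> float:
    """Error probability E in (0, 0.5] for a base-quality value ``sq >= 0``.

    Strictly decreasing in ``sq``; sq = 0 maps to E = 0.5 (even odds).
    """
    if not math.isfinite(sq) or sq < 0:
        raise ValueError(f"base quality must be finite and >= 0, got {sq}")
    y = 10.0 ** (-sq / 10.0)
    return y / (1.0 + y)


def quality_from_error(e: float) -> float:
    """Base quality SQ = -10*log10(e/(1-e)) for an error probability in (0, 0.5]."""
    if not (0.0 < e <= 0.5) or not math.isfinite(e):
        raise ValueError(f"error rate must lie in (0, 0.5], got {e}")
    return -10.0 * math.log10(e / (1.0 - e))
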