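"""RPKM expression quantification.

RPKM = 10^6 * C / (N * L / 10^3), with C the tags uniquely assigned to the
gene, N the library's total assigned tags and L the gene length in bases.
Depth-invariant by construction: scaling C and N together leaves it fixed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, GeneModel, TagLibrary, ConfigurationError

__all__ = ["rpkm", "rpkm_matrix"]


def rpkm(c: float, n: float, l: float) -> float:
    """Reads per kilobase of gene model per million assigned reads.

    ``n`` (library total) and ``l`` (gene length, bp) must be >= 1; a
    zero-depth library is rejected rather than pseudocounted.
    """
    if n < 1:
        raise ValueError(f"library total must be >= 1, got {n}")
    if l < 1:
        raise ValueError(f"gene length must be >= 1, got {l}")
    if c < 0:
        raise ValueError(f"count must be >= 0, got {c}")
    return 1e6 * c / (n * l / 1e3)


def rpkm_matrix(libraries: Sequence[TagLibrary], genes: Sequence[GeneModel]) -> ExpressionMatrix:
    """RPKM for every gene in every library, as a gene x sample matrix."""
    if not genes:
        raise ValueError("empty gene catalog")
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    cols: dict[str, np.ndarray] = {}
    for lib in libraries:
        if lib.total_tags < 1:
            raise ValueError(f"library {lib.sample_id} has zero total tags")
        missing = [g for g in gene_ids if g not in lib.counts]
        if missing:
            raise ConfigurationError(
                f"library {lib.sample_id} lacks counts for gene {missing[0]!r} "
                f"({len(missing)} missing)"
            )
        counts = np.array([lib.counts[g] for g in gene_ids], dtype=float)
        cols[lib.sample_id] = 1e6 * counts / (lib.total_tags * lengths / 1e3)
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(values=df)
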