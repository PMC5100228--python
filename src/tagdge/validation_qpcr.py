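"""Relative quantification by the 2^-ddCt method and RNA-Seq concordance.

ddCt = (Ct_target - Ct_reference)_treatment - (Ct_target - Ct_reference)_control;
fold change = 2^-ddCt. The sequencing result is "validated" when the qPCR
fold change points the same way as the RNA-Seq log2 ratio, so concordance
is the fraction of shared genes with matching sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import QpcrMeasurement

__all__ = ["RelativeExpression", "delta_delta_ct", "concordance", "relative_expression_from_table"]


@dataclass
class RelativeExpression:
    target_gene: str
    treatment_label: str
    fold_change: float
    ddct: float


def delta_delta_ct(
    ct_t_trt: float,
    ct_r_trt: float,
    ct_t_ctl: float,
    ct_r_ctl: float,
    target_gene: str = "",
    treatment_label: str = "",
) -> RelativeExpression:
    """2^-ddCt relative expression of a target gene, treatment vs control."""
    for v in (ct_t_trt, ct_r_trt, ct_t_ctl, ct_r_ctl):
        if not math.isfinite(v):
            raise ValueError(f"Ct values must be finite, got {v}")
    ddct = (ct_t_trt - ct_r_trt) - (ct_t_ctl - ct_r_ctl)
    return RelativeExpression(
        target_gene=target_gene,
        treatment_label=treatment_label,
        fold_change=2.0 ** (-ddct),
        ddct=ddct,
    )


def relative_expression_from_table(
    measurements: Sequence[QpcrMeasurement], treatment_label: str = "treatment"
) -> list[RelativeExpression]:
    """ddCt per target from raw well measurements grouped control/treatment.

    Replicate Ct values are averaged (arithmetic mean of cycles) within each
    (target, group) before the contrast.
    """
    by_gene: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for m in measurements:
        by_gene.setdefault(m.target_gene, {}).setdefault(m.group, []).append(
            (m.ct_target, m.ct_reference)
        )
    out = []
    for gene in sorted(by_gene):
        groups = by_gene[gene]
        if "control" not in groups or "treatment" not in groups:
            raise ValueError(f"target {gene}: need both control and treatment measurements")
        ct_t_ctl, ct_r_ctl = (float(np.mean(v)) for v in zip(*groups["control"]))
        ct_t_trt, ct_r_trt = (float(np.mean(v)) for v in zip(*groups["treatment"]))
        out.append(
            delta_delta_ct(
                ct_t_trt, ct_r_trt, ct_t_ctl, ct_r_ctl,
                target_gene=gene, treatment_label=treatment_label,
            )
        )
    return out


def concordance(
    qpcr: Sequence[RelativeExpression], rnaseq_log2: Mapping[str, float]
) -> float:
    """Fraction of shared genes whose qPCR and RNA-Seq directions agree.

    Direction is sign(log2 fold change); an exactly-zero log ratio is
    concordant only with zero.
    """
    shared = [q for q in qpcr if q.target_gene in rnaseq_log2]
    if not shared:
        raise ValueError("no genes shared between qPCR results and RNA-Seq ratios")
    agree = 0
    for q in shared:
        s_q = np.sign(math.log2(q.fold_change))
        s_r = np.sign(rnaseq_log2[q.target_gene])
        agree += int(s_q == s_r)
    return agree / len(shared)
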