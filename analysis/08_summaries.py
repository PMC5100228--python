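"""Clustered log2-ratio heatmap matrix and Venn partitions of DEG sets."""

import json

import numpy as np
import pandas as pd

from _config import CONTRASTS, OUT

from tagdge.data_model import read_table
from tagdge.pairwise_deg import DEGRecord
from tagdge.pipeline import cluster_expression, venn_partition


def main() -> None:
    ratios: dict[str, dict[str, float]] = {}
    up_sets: dict[str, set] = {}
    down_sets: dict[str, set] = {}
    q_best: dict[str, float] = {}
    for name, _ctl, _trt in CONTRASTS:
        records = read_table(OUT / f"deg_{name}.tsv", DEGRecord)
        ratios[name] = {r.gene_id: r.log2_ratio for r in records}
        up_sets[name] = {r.gene_id for r in records if r.direction == "up"}
        down_sets[name] = {r.gene_id for r in records if r.direction == "down"}
        for r in records:
            if r.direction != "ns":
                q_best[r.gene_id] = min(q_best.get(r.gene_id, 1.0), r.q_fdr)

    heat_genes = sorted(q_best, key=lambda g: (q_best[g], g))[:200]
    mat = pd.DataFrame({n: [ratios[n][g] for g in heat_genes] for n, _a, _b in CONTRASTS},
                       index=pd.Index(heat_genes, name="gene_id"))
    order, _ = cluster_expression(mat)
    out = mat.loc[order].copy()
    out["mean_sign"] = np.sign(out.mean(axis=1)).astype(int)
    out.to_csv(OUT / "heatmap.tsv", sep="\t", float_format="%.6g")
    print(f"heatmap matrix: {len(order)} DEGs in dendrogram leaf order")

    cr_contrasts = ["ZS758_Cr_vs_Ck", "Zheda622_Cr_vs_Ck", "ZS758_CrGSH_vs_Ck"]
    venn = {
        "up": venn_partition({n: up_sets[n] for n in cr_contrasts}),
        "down": venn_partition({n: down_sets[n] for n in cr_contrasts}),
    }
    with open(OUT / "venn.json", "w", encoding="utf-8") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
    shared = venn["up"]["ZS758_Cr_vs_Ck&Zheda622_Cr_vs_Ck"]
    print(f"venn: {shared} up-regulated DEGs shared by both cultivars under chromium alone")


if __name__ == "__main__":
    main()
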