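"""Co-expression network over the chromium DEGs plus the planted module.

Edges require |R| > 0.99 and FDR < 0.05 across all tested pairs; reports
how much of the planted co-expression module is recovered.
"""

import pandas as pd

from _config import DATA, OUT

from tagdge.coexpr_network import build_network, write_sif
from tagdge.data_model import ExpressionMatrix, read_table, write_table
from tagdge.pairwise_deg import DEGRecord
from tagdge.synthetic_data import read_truth


def main() -> None:
    expr = ExpressionMatrix(pd.read_csv(OUT / "rpkm.tsv", sep="\t", index_col=0))
    records = read_table(OUT / "deg_ZS758_Cr_vs_Ck.tsv", DEGRecord)
    truth = read_truth(DATA)
    nodes = {r.gene_id for r in records if r.direction != "ns"} | truth.module_genes
    edges = build_network(expr, r_min=0.99, q_max=0.05, genes=nodes)
    write_table(edges, OUT / "network_edges.tsv")
    write_sif(edges, OUT / "network.sif")
    mod = truth.module_genes
    within = sum(e.gene_a in mod and e.gene_b in mod for e in edges)
    cross = sum((e.gene_a in mod) != (e.gene_b in mod) for e in edges)
    print(f"network: {len(nodes)} candidate nodes, {len(edges)} edges at |R|>0.99, FDR<0.05")
    print(f"planted module: {within}/10 within-module edges, {cross} cross-module edges")


if __name__ == "__main__":
    main()
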