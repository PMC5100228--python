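"""Validate the sequencing calls with simulated 2^-ddCt qPCR assays."""

from _config import DATA, OUT, STUDY

from tagdge.data_model import read_table, write_table
from tagdge.pairwise_deg import DEGRecord
from tagdge.synthetic_data import read_truth, simulate_qpcr
from tagdge.validation_qpcr import concordance, relative_expression_from_table


def main() -> None:
    truth = read_truth(DATA)
    measurements = simulate_qpcr(truth, n_targets=10, seed=STUDY.seed + 1)
    rel = relative_expression_from_table(measurements, treatment_label="ZS758_Cr_vs_Ck")
    write_table(rel, OUT / "qpcr_relative_expression.tsv")
    records = read_table(OUT / "deg_ZS758_Cr_vs_Ck.tsv", DEGRecord)
    ratios = {r.gene_id: r.log2_ratio for r in records}
    conc = concordance(rel, ratios)
    print(f"qPCR assays for {len(rel)} planted DE genes")
    print(f"sign concordance with RNA-Seq log2 ratios: {conc:.2f}")


if __name__ == "__main__":
    main()
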