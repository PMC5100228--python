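"""Quantify expression as RPKM from the simulated count table."""

from _config import DATA, OUT

from tagdge.data_model import read_count_table
from tagdge.normalization import rpkm_matrix


def main() -> None:
    genes, libraries = read_count_table(DATA / "counts.tsv")
    expr = rpkm_matrix(libraries, genes)
    expr.values.to_csv(OUT / "rpkm.tsv", sep="\t", float_format="%.6g")
    col = expr.values.iloc[:, 0]
    print(f"RPKM matrix: {expr.values.shape[0]} genes x {expr.values.shape[1]} libraries")
    print(f"{col.name}: median {col.median():.1f} RPKM, max {col.max():.0f} RPKM")


if __name__ == "__main__":
    main()
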