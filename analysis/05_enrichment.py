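"""GO/KEGG term enrichment of the chromium-response DEG set, plus the
WEGO-style GO-domain tabulation of up- and down-regulated genes."""

from _config import DATA, OUT

from tagdge.data_model import read_annotation_map, read_table
from tagdge.data_model import write_table
from tagdge.enrichment import enrich, wego_tabulate
from tagdge.pairwise_deg import DEGRecord


def main() -> None:
    records = read_table(OUT / "deg_ZS758_Cr_vs_Ck.tsv", DEGRecord)
    up = {r.gene_id for r in records if r.direction == "up"}
    down = {r.gene_id for r in records if r.direction == "down"}
    deg = up | down
    print(f"ZS758 chromium response: {len(deg)} DEGs ({len(up)} up, {len(down)} down)")

    for ns in ("GO_BP", "KEGG"):
        amap = read_annotation_map(DATA / f"annotation_{ns}.tsv", ns)
        results = enrich(deg, amap, alpha=0.05)
        write_table(results, OUT / f"enrich_ZS758_Cr_vs_Ck_{ns}.tsv")
        top = results[0]
        print(
            f"{ns}: {sum(r.significant for r in results)} significant of {len(results)} terms; "
            f"top: {top.term_id} (corrected p = {top.p_bonferroni:.2e}, "
            f"rich factor {top.rich_factor:.2f})"
        )

    go_maps = [read_annotation_map(DATA / f"annotation_{ns}.tsv", ns)
               for ns in ("GO_BP", "GO_CC", "GO_MF")]
    wego = wego_tabulate(go_maps, {"up": up, "down": down})
    wego.to_csv(OUT / "wego_ZS758_Cr_vs_Ck.tsv", sep="\t", index=False)
    print(f"WEGO tabulation: {len(wego)} (namespace, term, set) rows")


if __name__ == "__main__":
    main()
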