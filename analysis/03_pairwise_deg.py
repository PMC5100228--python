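"""Exact pairwise DEG screens for every configured contrast.

Uses one library per condition (replicate 1), mirroring unreplicated tag
profiling, and reports recovery of the planted truth for the chromium
contrasts.
"""

from _config import CONTRASTS, DATA, OUT

from tagdge.data_model import read_count_table, write_table
from tagdge.pairwise_deg import screen_pairwise
from tagdge.synthetic_data import read_truth


def main() -> None:
    genes, libraries = read_count_table(DATA / "counts.tsv")
    by_id = {lib.sample_id: lib for lib in libraries}
    truth = read_truth(DATA)
    planted = set(truth.de_genes)
    for name, ctl, trt in CONTRASTS:
        records = screen_pairwise(by_id[f"{ctl}_r1"], by_id[f"{trt}_r1"], genes)
        write_table(records, OUT / f"deg_{name}.tsv")
        called = {r.gene_id for r in records if r.direction != "ns"}
        up = sum(r.direction == "up" for r in records)
        line = f"{name}: {up} up, {len(called) - up} down"
        if trt.endswith("_Cr") and ctl.endswith("_Ck"):
            rec = len(called & planted) / len(planted)
            line += f"  (recovers {rec:.0%} of planted DE genes)"
        print(line)


if __name__ == "__main__":
    main()
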