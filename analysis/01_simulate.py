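"""Simulate the two-cultivar x three-treatment tag-count experiment.

Writes the count table, design, annotation maps and ground truth that every
later driver reads, and reports what was planted.
"""

from _config import DATA, STUDY

from tagdge.data_model import write_annotation_map, write_count_table
from tagdge.synthetic_data import simulate_experiment, write_truth


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    genes, libraries, annotations, truth = simulate_experiment(STUDY)
    write_count_table(genes, libraries, DATA / "counts.tsv")
    with open(DATA / "design.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\treplicate\n")
        for lib in libraries:
            fh.write(f"{lib.sample_id}\t{lib.genotype}_{lib.treatment}\t{lib.replicate}\n")
    for ns, amap in annotations.items():
        write_annotation_map(amap, DATA / f"annotation_{ns}.tsv")
    write_truth(truth, DATA)
    n_up = sum(v > 0 for v in truth.de_genes.values())
    print(
        f"simulated {len(genes)} genes x {len(libraries)} libraries "
        f"(~{libraries[0].total_tags:,} tags each)"
    )
    print(
        f"planted: {len(truth.de_genes)} DE genes ({n_up} up in Cr), "
        f"term {truth.enriched_term}, {len(truth.module_genes)}-gene module"
    )


if __name__ == "__main__":
    main()
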