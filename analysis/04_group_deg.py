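"""Replicate-aware group screens against the pooled (M, D) noise distribution."""

import pandas as pd

from _config import CONTRASTS, DATA, OUT

from tagdge.data_model import ExpressionMatrix, read_design, write_table
from tagdge.group_deg import build_noise_distribution, screen_group


def main() -> None:
    expr = ExpressionMatrix(pd.read_csv(OUT / "rpkm.tsv", sep="\t", index_col=0))
    design = read_design(DATA / "design.tsv")
    condition_of = lambda s: design[s][0]  # noqa: E731
    noise = build_noise_distribution(expr, condition_of)
    print(f"noise distribution: {len(noise):,} pooled within-condition (M, D) pairs")
    for name, ctl, trt in CONTRASTS:
        records = screen_group(expr, condition_of, trt, ctl, noise=noise)
        write_table(records, OUT / f"group_{name}.tsv")
        called = sum(r.called for r in records)
        print(f"{name}: {called} genes with differential-expression probability >= 0.8")


if __name__ == "__main__":
    main()
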