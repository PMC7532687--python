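"""Paired tumor-vs-normal differential expression (eRNA and gene), global
and subgroup contrasts of the global eRNA statistic, and genome-instability
summaries with their correlation to global eRNA expression."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_de


def main():
    args = parse_args(__doc__)
    stage_de(args.workdir, run_config(args.seed))
    de = pd.read_csv(args.workdir / "de_ernas.tsv", sep="\t")
    up = ((de.log2fc >= 2) & (de.fdr < 0.05)).sum()
    down = ((de.log2fc <= -2) & (de.fdr < 0.05)).sum()
    print(f"eRNA DE: {up} up / {down} down at |log2FC|>=2, FDR<0.05 "
          f"(of {len(de)} transcribed intergenic eRNAs)")
    groups = pd.read_csv(args.workdir / "group_tests.tsv", sep="\t")
    gl = groups[groups.test == "global_tumor_vs_normal"].iloc[0]
    print(f"global eRNA expression, tumor vs normal (signed-rank): "
          f"p = {gl.p:.3g}")
    burden = pd.read_csv(args.workdir / "burden_correlation.tsv", sep="\t")
    for _, r in burden.iterrows():
        print(f"  global eRNA vs {r.burden}: rho = {r.rho:+.3f}, p = {r.p:.3g}")


if __name__ == "__main__":
    main()
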