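"""Preranked gene-set enrichment of the co-expression-derived gene ranking
against the bundled gene sets (permutation p and pooled-NES FDR)."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_gsea


def main():
    args = parse_args(__doc__)
    stage_gsea(args.workdir, run_config(args.seed))
    res = pd.read_csv(args.workdir / "gsea_results.tsv", sep="\t")
    print("preranked GSEA:")
    for _, r in res.sort_values("p").iterrows():
        print(f"  {r.set_name:>12} (n={r['size']}): ES = {r.es:+.3f}, "
              f"NES = {r.nes:+.2f}, p = {r.p:.3g}, FDR = {r.fdr:.3g}")


if __name__ == "__main__":
    main()
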