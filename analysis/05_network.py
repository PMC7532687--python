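"""Genome-wide eRNA-gene Spearman co-expression network in tumor samples:
edge calling (|rho| >= 0.2, FDR < 0.05), enhancer-TSS distances, cis
enrichment within 1 Mbp, driver-gene-set over-representation, and the
composite gene ranking."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_network


def main():
    args = parse_args(__doc__)
    stage_network(args.workdir, run_config(args.seed))
    edges = pd.read_csv(args.workdir / "edges.tsv", sep="\t")
    co = edges[edges.coexpressed]
    print(f"network: {len(edges)} pairs tested, {len(co)} co-expressed "
          f"({co.erna_id.nunique()} eRNAs x {co.gene_id.nunique()} genes)")
    enr = pd.read_csv(args.workdir / "enrichment.tsv", sep="\t") \
        .set_index("analysis")
    cis = enr.loc["cis_1mbp"]
    print(f"cis enrichment (<=1 Mbp): ER = {cis.enrichment_ratio:.2f}, "
          f"p = {cis.p:.3g}")
    for name in enr.index:
        if name.startswith("overrep_"):
            r = enr.loc[name]
            print(f"  {name[8:]}: ER = {r.enrichment_ratio:.2f}, p = {r.p:.3g}")


if __name__ == "__main__":
    main()
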