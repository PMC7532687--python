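"""Consensus-cluster tumor samples over the functional-eRNA expression
profile (resampled Ward on Pearson distance) and characterise the clusters
by mutations, copy-number burden and demographics."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_cluster


def main():
    args = parse_args(__doc__)
    stage_cluster(args.workdir, run_config(args.seed))
    ks = pd.read_csv(args.workdir / "kselect.tsv", sep="\t")
    chosen = int(ks.loc[ks.chosen, "k"].iloc[0])
    print("consensus CDF area by k:")
    for _, r in ks.iterrows():
        mark = " <- chosen" if r.chosen else ""
        print(f"  k={int(r.k)}: area {r.cdf_area:.3f}, "
              f"delta {r.delta_area:.3f}{mark}")
    assign = pd.read_csv(args.workdir / "assignments.tsv", sep="\t")
    sizes = assign.cluster.value_counts().sort_index()
    print("cluster sizes:", dict(sizes))
    char = pd.read_csv(args.workdir / "characterization.tsv", sep="\t")
    hits = char[(char.p < 0.05) & (char.test != "skipped")]
    print(f"{len(hits)} cluster associations at p < 0.05; strongest:")
    for _, r in hits.nsmallest(5, "p").iterrows():
        where = f" (cluster {int(r.cluster)})" if pd.notna(r.cluster) else ""
        print(f"  {r.attribute}{where}: {r.test} p = {r.p:.3g}")


if __name__ == "__main__":
    main()
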