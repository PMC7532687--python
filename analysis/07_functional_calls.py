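"""Call functional eRNA-gene pairs through the three-criterion cascade:
DE eRNA, positive cis correlation within 1 Mbp, direction-matched DE gene
above the 0.5 TPM floor."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_call


def main():
    args = parse_args(__doc__)
    stage_call(args.workdir, run_config(args.seed))
    calls = pd.read_csv(args.workdir / "functional_calls.tsv", sep="\t")
    pairs = pd.read_csv(args.workdir / "functional_pairs.tsv", sep="\t")
    up = (calls.direction == "up").sum()
    down = (calls.direction == "down").sum()
    print(f"functional eRNAs: {len(calls)} ({up} up, {down} down) "
          f"from {len(pairs)} evaluated cis-candidate pairs")
    truth = args.workdir / "cohort" / "truth" / "planted_pairs.tsv"
    if truth.exists():
        tset = set(map(tuple, pd.read_csv(truth, sep="\t").values))
        called = set(map(tuple,
                         pairs.loc[pairs.functional,
                                   ["erna_id", "gene_id"]].values))
        tp = len(called & tset)
        print(f"vs planted truth: recall {tp / len(tset):.2f}, "
              f"precision {tp / max(len(called), 1):.2f}")


if __name__ == "__main__":
    main()
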