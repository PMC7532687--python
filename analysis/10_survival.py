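"""Associate the eRNA-based clusters with outcome: Cox proportional-hazards
contrasts (adjusted for age, gender, smoking; crude alongside) and
Kaplan-Meier / log-rank comparisons for OS, DFI and PFI."""

import pandas as pd

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_survive


def main():
    args = parse_args(__doc__)
    stage_survive(args.workdir, run_config(args.seed))
    surv = pd.read_csv(args.workdir / "survival_results.tsv", sep="\t")
    for ep in ("os", "dfi", "pfi"):
        sub = surv[(surv.endpoint == ep) & (surv.model == "adjusted")]
        if sub.empty:
            continue
        print(f"{ep.upper()}:")
        for _, r in sub.iterrows():
            print(f"  {r.contrast}: HR {r.hr:.2f} "
                  f"[{r.ci_low:.2f}-{r.ci_high:.2f}], p = {r.p:.3g}")
    lr = pd.read_csv(args.workdir / "logrank.tsv", sep="\t")
    for _, r in lr.iterrows():
        print(f"log-rank {r.endpoint.upper()}: chi2 = {r.statistic:.2f}, "
              f"p = {r.p:.3g}")


if __name__ == "__main__":
    main()
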