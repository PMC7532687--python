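"""Generate the synthetic paired tumor/normal cohort with planted truth.

Writes the cohort (enhancer sources, gene model, count matrices, copy-number
segments, mutations, clinical follow-up, gene sets, truth tables) under
results/analysis/cohort/.
"""

from _workspace import parse_args
from ernascope import SimConfig
from ernascope.pipeline import stage_simulate


def main():
    args = parse_args(__doc__)
    cfg = SimConfig(seed=args.seed)
    stage_simulate(args.workdir, cfg)
    print(f"cohort written -> {args.workdir}/cohort")
    print(f"  {cfg.n_pairs} tumor/normal pairs, {cfg.n_enhancers} enhancers, "
          f"{cfg.n_genes} genes over {cfg.n_chromosomes} chromosomes")
    print(f"  planted: {cfg.n_functional_up} up / {cfg.n_functional_down} down "
          f"functional pairs ({cfg.n_cna_driven} CNA-driven), "
          f"{cfg.n_clusters} expression subtypes, "
          f"cluster-{cfg.n_clusters} hazard ratio {cfg.hazard_ratio_cluster3}")


if __name__ == "__main__":
    main()
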