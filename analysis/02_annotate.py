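"""Build the enhancer catalog (two-source support filter) and classify each
enhancer as exonic, intronic or intergenic against the gene model."""

import json

from _workspace import parse_args, run_config
from ernascope.pipeline import stage_annotate


def main():
    args = parse_args(__doc__)
    stage_annotate(args.workdir, run_config(args.seed))
    counts = json.loads((args.workdir / "annotation_summary.json").read_text())
    print(f"catalog: {counts['total']} enhancers supported by both sources")
    for cls in ("exonic", "intergenic", "intronic"):
        print(f"  {cls}: {counts[cls]}")


if __name__ == "__main__":
    main()
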