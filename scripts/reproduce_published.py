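"""Apply the published analysis settings to a processed LFQ sheet.

Point this at a MaxQuant-style proteinGroups export (e.g. a sheet of a
supplementary workbook saved as TSV) plus a design file mapping each LFQ
column suffix to experimental/control, and it runs the exact published
chain — remove reverse/contaminant/only-by-site records, groups with < 2
quantified values in one group and groups with < 2 razor peptides; log2;
deterministic lowest-of-detection imputation; pooled two-sided t-test —
and prints the number of significant proximity interactors
(log2 FC > 1, p < 0.05) with the top of the hit list.

Usage:
    python scripts/reproduce_published.py --protein-groups sheet.tsv \
        --design design.tsv --output-dir results/published [--column-map map.yaml]
"""

import argparse

import yaml

from turboprox.enrichment import significant_set
from turboprox.pipeline import RunConfig, run_enrichment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--protein-groups", required=True)
    parser.add_argument("--design", required=True)
    parser.add_argument("--output-dir", default="results/published")
    parser.add_argument(
        "--column-map",
        help="YAML mapping of logical -> actual column names for re-exported "
        "sheets whose headers differ from raw proteinGroups.txt",
    )
    args = parser.parse_args()

    column_map = {}
    if args.column_map:
        with open(args.column_map, encoding="utf-8") as fh:
            column_map = yaml.safe_load(fh) or {}

    config = RunConfig(
        protein_groups=args.protein_groups,
        design=args.design,
        output_dir=args.output_dir,
        min_razor=2,
        min_group_values=2,
        imputation="lod",
        min_log2_fc=1.0,
        max_p=0.05,
        column_map=column_map,
    )
    results = run_enrichment(config)
    hits = significant_set(results["lod"])
    print(f"significant proximity interactors: {len(hits)}")
    for gid in hits[:10]:
        print(f"  {gid}")
    print(f"full tables written to {args.output_dir}")


if __name__ == "__main__":
    main()
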