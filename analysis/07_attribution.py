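"""Append each microbial network cluster to the accepted base model,
enumerate significant climate-to-cluster pathways, multiply coefficients
into composite effects, and attribute each cluster's explained variation to
temperature-only, precipitation-only and joint pathways (plus the
within-location random share and the unexplained remainder), aggregated by
cluster relative size per compartment.
"""
from _common import parse_args

from rhizoclim.pipeline import stage_attribute, stage_report


def main() -> None:
    args, cfg = parse_args(__doc__)
    res = stage_attribute(args.out, cfg)
    agg = res["aggregated"].pivot(index="compartment", columns="category",
                                  values="share")
    print(agg.round(3).to_string())
    report = stage_report(args.out, cfg)
    print(f"\nreport written to {report}")


if __name__ == "__main__":
    main()
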