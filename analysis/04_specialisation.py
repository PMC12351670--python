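"""Habitat specialisation: rarefy each marker to its smallest sample size,
score the specialisation index SI = sigma/mu - K/N per ASV, and summarise
community-weighted mean SI per sample and compartment.
"""
from _common import parse_args

from rhizoclim.pipeline import stage_si


def main() -> None:
    args, cfg = parse_args(__doc__)
    res = stage_si(args.out, cfg)
    for comp, d in res.items():
        si = d["si"]
        print(f"{comp}: {len(si)} ASVs scored; "
              f"SI median {si['SI'].median():.3f}, "
              f"IQR [{si['SI'].quantile(.25):.3f}, {si['SI'].quantile(.75):.3f}]")
        print(f"  community CWM SI mean over samples: {d['cwm'].mean():.3f}")


if __name__ == "__main__":
    main()
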