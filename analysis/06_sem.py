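"""Fit the base climate-pathway structural equation model (random-intercept
equations, d-separation basis set, Fisher's C) and reduce it by AICc-guided
backward elimination.
"""
from _common import parse_args

from rhizoclim.pipeline import stage_sem


def main() -> None:
    args, cfg = parse_args(__doc__)
    base, _ = stage_sem(args.out, cfg)
    print(base.coefficients.round(4).to_string(index=False))
    verdict = "accepted" if base.accepted else "rejected"
    print(f"\nFisher's C = {base.fisher_c:.2f} on {base.df_c} df, "
          f"p = {base.p_c:.3f} ({verdict}); AICc = {base.aicc:.2f}, "
          f"K = {base.n_params}")


if __name__ == "__main__":
    main()
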