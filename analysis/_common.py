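"""Shared argument handling for the analysis drivers."""
import argparse
from pathlib import Path

from rhizoclim.pipeline import PipelineConfig
from rhizoclim.synth import GeneratorConfig


def parse_args(description: str):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    cfg = PipelineConfig(generator=GeneratorConfig(seed=args.seed),
                         seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    return args, cfg
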