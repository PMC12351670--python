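"""Infer the joint prokaryote+fungal signed co-occurrence network per
compartment (neighbourhood selection, StARS at instability 0.05 with 45
penalties and 300 subsample replications), cluster it with the signed
spin-glass algorithm, and compute cluster summaries, density tests,
inter-cluster correlations, climate models and specialist/generalist labels.
"""
from _common import parse_args

from rhizoclim.pipeline import stage_cluster, stage_network


def main() -> None:
    args, cfg = parse_args(__doc__)
    nets = stage_network(args.out, cfg)
    for comp, net in nets.items():
        pos = int((net.edges["sign"] > 0).sum())
        print(f"{comp}: {net.n_edges} edges ({pos} positive), "
              f"lambda {net.lambda_selected:.4f}, "
              f"instability {net.instability_at_selection:.4f}")
    clusters = stage_cluster(args.out, cfg, nets)
    for comp, d in clusters.items():
        part = d["partition"]
        print(f"{comp}: {len(part.cluster_ids)} clusters, "
              f"within-cluster edge share {d['density']['statistic']:.3f} "
              f"(p = {d['density']['p_value']:.4f} vs rewired nulls)")
        print(d["labels"][["label", "mean_cwm_si"]].to_string())


if __name__ == "__main__":
    main()
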