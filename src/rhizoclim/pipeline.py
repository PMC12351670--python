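"""End-to-end orchestration: simulate -> filter -> community -> networks ->
clusters -> specialisation -> seasonal -> SEM -> attribution -> report.

Each stage is a function over a working directory: it reads the previous
stages' TSV outputs, computes, writes its own outputs, and records them (with
SHA-256 hashes) in the run manifest.  Everything is deterministic given the
seed in the configuration, so re-running a stage reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, seasonal, specialisation
from .attribution import (AttributionResult, aggregate_attribution,
                          explained_fractions, per_variable_contributions)
from .io_tables import (AsvCountTable, SampleMetadata, filter_low_reads,
                        network_prefilter, read_asv_table, read_metadata,
                        write_asv_table, write_metadata)
from .lmm import fit_lmm
from .network import (cluster_abundances, cluster_climate_model,
                      cluster_density_test, intercluster_correlations,
                      spinglass_cluster, stars_select, summarize_partition,
                      SignedNetwork)
from .sem import PathModel, SemEngine
from .synth import (DEFAULT_DAG, GeneratorConfig, SyntheticDataset,
                    generate_all)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "community", "seasonal", "si", "network",
          "cluster", "sem", "attribute", "report"]

COMPARTMENTS = ("rhizosphere", "root")
MARKERS = ("16S", "ITS")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # filtering (rare-read and prevalence thresholds)
    min_asv_reads: int = 100
    min_sample_reads: int = 1000
    net_min_asv_reads: int = 100
    net_min_prevalence: int = 6
    # network estimation
    n_lambda: int = 45
    stars_threshold: float = 0.05
    stars_replications: int = 300
    subsample_ratio: float = 0.8
    gamma_pos: float = 1.0
    gamma_neg: float = 1.0
    spinglass_runs: int = 10
    density_test_random: int = 199
    # community
    shannon_iterations: int = 1000
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0

    def seeded(self, label: str) -> int:
        """Stable per-stage sub-seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def default_base_model() -> PathModel:
    """Hypothesised climate-pathway topology for the base model.

    Temperature and precipitation enter as design exogenous variables whose
    pairing is fixed by the factorial layout, hence the declared correlated
    error exempting them from the d-sep basis set.
    """
    equations: dict[str, list[str]] = {}
    for parent, child, _ in DEFAULT_DAG:
        equations.setdefault(child, []).append(parent)
    return PathModel(
        equations=equations,
        correlated={frozenset(("temperature", "precipitation"))},
    )


def climate_candidates(base: PathModel) -> list[str]:
    """Candidate parents for microbial responses: climate plus every base
    node reachable from a climate driver (climate-unrelated nodes excluded)."""
    g = base.dag()
    reachable: set[str] = set()
    import networkx as nx
    for s in ("temperature", "precipitation"):
        if s in g:
            reachable |= nx.descendants(g, s)
    return ["temperature", "precipitation", *sorted(reachable)]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, workdir: Path, config: PipelineConfig):
        self.path = Path(workdir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config": _config_dict(config), "stages": {},
                         "warnings": []}

    def record(self, stage: str, outputs: list[Path], warnings=()):
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        self.data["warnings"].extend(warnings)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _config_dict(cfg) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (tuple, list)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        return o
    return enc(cfg)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(workdir: Path, cfg: PipelineConfig) -> SyntheticDataset:
    """Generate and write the synthetic study inputs (sensor series are
    regenerated on demand by the seasonal stage; they are large and fully
    determined by the seed)."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ds = generate_all(cfg.generator, with_sensors=False)
    write_metadata(ds.metadata, workdir / "metadata.tsv")
    ds.covariates.to_csv(workdir / "covariates.tsv", sep="\t")
    outputs = [workdir / "metadata.tsv", workdir / "covariates.tsv"]
    for comp in COMPARTMENTS:
        p = workdir / f"counts_{comp}.tsv"
        write_asv_table(ds.tables[comp], p)
        ds.tables[comp].marker.rename("marker").to_csv(
            workdir / f"marker_{comp}.tsv", sep="\t", index_label="asv_id")
        outputs += [p, workdir / f"marker_{comp}.tsv"]
    truth_path = workdir / "ground_truth.json"
    truth_path.write_text(json.dumps(_config_dict(ds.truth), indent=1,
                                     sort_keys=True))
    outputs.append(truth_path)
    Manifest(workdir, cfg).record("simulate", outputs)
    return ds


def _load_table(workdir: Path, comp: str) -> AsvCountTable:
    t = read_asv_table(Path(workdir) / f"counts_{comp}.tsv")
    marker = pd.read_csv(Path(workdir) / f"marker_{comp}.tsv", sep="\t",
                         index_col=0)["marker"]
    return AsvCountTable(counts=t.counts, marker=marker)


def _load_meta(workdir: Path) -> SampleMetadata:
    return read_metadata(Path(workdir) / "metadata.tsv")


def stage_filter(workdir: Path, cfg: PipelineConfig) -> dict[str, AsvCountTable]:
    workdir = Path(workdir)
    out = {}
    outputs = []
    for comp in COMPARTMENTS:
        table = _load_table(workdir, comp)
        filtered = filter_low_reads(table, cfg.min_asv_reads,
                                    cfg.min_sample_reads)
        p = workdir / f"filtered_{comp}.tsv"
        write_asv_table(filtered, p)
        outputs.append(p)
        out[comp] = filtered
    Manifest(workdir, cfg).record("filter", outputs)
    return out


def _marker_subtable(table: AsvCountTable, marker: str) -> AsvCountTable:
    ids = [a for a in table.asv_ids if table.marker.loc[a] == marker]
    return table.subset(asvs=ids)


def stage_community(workdir: Path, cfg: PipelineConfig) -> dict:
    """clr, PERMANOVA on location centroids, Shannon diversity, overlap."""
    workdir = Path(workdir)
    meta = _load_meta(workdir)
    loc = meta.location_of()
    perm_rows, div_frames = [], []
    tables = {c: read_asv_table(workdir / f"filtered_{c}.tsv")
              for c in COMPARTMENTS}
    markers = {c: pd.read_csv(workdir / f"marker_{c}.tsv", sep="\t",
                              index_col=0)["marker"] for c in COMPARTMENTS}
    cov = pd.read_csv(workdir / "covariates.tsv", sep="\t", index_col=0)
    for comp in COMPARTMENTS:
        table = AsvCountTable(counts=tables[comp].counts,
                              marker=markers[comp].reindex(
                                  tables[comp].counts.columns))
        for marker in MARKERS:
            sub = _marker_subtable(table, marker)
            clr = community.clr_transform(sub)
            cents = community.location_centroids(clr, loc)
            dm = pd.DataFrame(
                np.sqrt(((cents.values[:, None, :]
                          - cents.values[None, :, :]) ** 2).sum(-1)),
                index=cents.index, columns=cents.index)
            cov_loc = cov.groupby("location_id")[
                ["temperature", "precipitation"]].mean()
            perm = community.permanova_centroids(
                dm, cov_loc, n_permutations=cfg.n_permutations,
                seed=cfg.seeded(f"permanova:{comp}:{marker}"))
            perm["compartment"] = comp
            perm["marker"] = marker
            perm_rows.append(perm)
            div = community.shannon_multirarefy(
                sub, n_iterations=cfg.shannon_iterations,
                seed=cfg.seeded(f"shannon:{comp}:{marker}"))
            div["compartment"] = comp
            div["marker"] = marker
            div_frames.append(div)
    overlap_rows = []
    for marker in MARKERS:
        a = _marker_subtable(AsvCountTable(counts=tables["rhizosphere"].counts,
                                           marker=markers["rhizosphere"]),
                             marker)
        b = _marker_subtable(AsvCountTable(counts=tables["root"].counts,
                                           marker=markers["root"]), marker)
        ov = community.taxa_overlap(a, b)
        ov["marker"] = marker
        overlap_rows.append(ov)
    permanova = pd.concat(perm_rows, ignore_index=True)
    diversity = pd.concat(div_frames, ignore_index=True)
    overlap = pd.DataFrame(overlap_rows)
    permanova.to_csv(workdir / "permanova.tsv", sep="\t", index=False)
    diversity.to_csv(workdir / "diversity.tsv", sep="\t", index=False)
    overlap.to_csv(workdir / "taxa_overlap.tsv", sep="\t", index=False)
    Manifest(workdir, cfg).record("community", [
        workdir / "permanova.tsv", workdir / "diversity.tsv",
        workdir / "taxa_overlap.tsv"])
    return {"permanova": permanova, "diversity": diversity, "overlap": overlap}


def stage_seasonal(workdir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    """Re-derive location-level climate covariates from the sensor series."""
    workdir = Path(workdir)
    ds = generate_all(cfg.generator, with_sensors=True)
    series = seasonal.exclude_failed_years(ds.sensors)
    rows = []
    for lid in ds.location_truth.index:
        rows.append({
            "location_id": lid,
            "season_start_days": seasonal.growing_season_start(
                series, pd.Timestamp(cfg.generator.sampling_date).year,
                cfg.generator.sampling_date, location_id=lid),
            "winter_veg_temp": seasonal.winter_vegetation_temperature(
                series, location_id=lid),
            "mean_soil_moisture": seasonal.mean_soil_moisture(
                series, location_id=lid),
            "circadian_cv": seasonal.circadian_cv(series, location_id=lid),
        })
    derived = pd.DataFrame(rows).set_index("location_id")
    derived["season_start_target"] = ds.location_truth["season_start"]
    derived["circadian_cv_target"] = ds.location_truth["circadian_cv"]
    derived.to_csv(workdir / "seasonal_covariates.tsv", sep="\t")
    Manifest(workdir, cfg).record("seasonal",
                                  [workdir / "seasonal_covariates.tsv"])
    return derived


def stage_si(workdir: Path, cfg: PipelineConfig) -> dict:
    """Rarefaction (per marker, to the smallest sample size), SI, CWM."""
    workdir = Path(workdir)
    out = {}
    outputs = []
    for comp in COMPARTMENTS:
        table = _load_table_filtered(workdir, comp)
        si_frames, rarefied_parts = [], []
        for marker in MARKERS:
            sub = _marker_subtable(table, marker)
            depth = int(sub.sample_totals().min())
            rare = community.rarefy(sub, depth,
                                    seed=cfg.seeded(f"rarefy:{comp}:{marker}"))
            si = specialisation.specialisation_index(
                rare, k_habitat=len(set(_load_meta(workdir)
                                        .table["location_id"])))
            si["marker"] = marker
            si_frames.append(si)
            rarefied_parts.append(rare.counts)
        si_all = pd.concat(si_frames)
        rarefied = pd.concat(rarefied_parts, axis=1).fillna(0).astype(int)
        rare_table = AsvCountTable(counts=rarefied)
        cwm = specialisation.cwm_si(rare_table, si_all)
        si_all.to_csv(workdir / f"si_{comp}.tsv", sep="\t")
        cwm.to_frame().to_csv(workdir / f"cwm_si_{comp}.tsv", sep="\t",
                              index_label="sample_id")
        rarefied.to_csv(workdir / f"rarefied_{comp}.tsv", sep="\t",
                        index_label="sample_id")
        outputs += [workdir / f"si_{comp}.tsv", workdir / f"cwm_si_{comp}.tsv",
                    workdir / f"rarefied_{comp}.tsv"]
        out[comp] = {"si": si_all, "cwm": cwm, "rarefied": rare_table}
    Manifest(workdir, cfg).record("si", outputs)
    return out


def _load_table_filtered(workdir: Path, comp: str) -> AsvCountTable:
    t = read_asv_table(Path(workdir) / f"filtered_{comp}.tsv")
    marker = pd.read_csv(Path(workdir) / f"marker_{comp}.tsv", sep="\t",
                         index_col=0)["marker"].reindex(t.counts.columns)
    return AsvCountTable(counts=t.counts, marker=marker)


def stage_network(workdir: Path, cfg: PipelineConfig) -> dict[str, SignedNetwork]:
    """Joint prokaryote+fungal signed network per compartment."""
    workdir = Path(workdir)
    nets = {}
    outputs = []
    for comp in COMPARTMENTS:
        table = _load_table_filtered(workdir, comp)
        pre = network_prefilter(table, cfg.net_min_asv_reads,
                                cfg.net_min_prevalence)
        clr = community.clr_transform(pre)
        net = stars_select(
            clr, n_lambda=cfg.n_lambda,
            subsample_ratio=cfg.subsample_ratio,
            n_replications=cfg.stars_replications,
            instability_threshold=cfg.stars_threshold,
            seed=cfg.seeded(f"stars:{comp}"))
        p = workdir / f"network_{comp}.tsv"
        net.edges.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        nets[comp] = net
    Manifest(workdir, cfg).record("network", outputs)
    return nets


def stage_cluster(workdir: Path, cfg: PipelineConfig,
                  nets: dict[str, SignedNetwork] | None = None) -> dict:
    workdir = Path(workdir)
    meta = _load_meta(workdir)
    loc = meta.location_of()
    out = {}
    outputs = []
    for comp in COMPARTMENTS:
        table = _load_table_filtered(workdir, comp)
        if nets is None:
            edges = pd.read_csv(workdir / f"network_{comp}.tsv", sep="\t")
            nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
            net = SignedNetwork(node_ids=nodes, edges=edges)
        else:
            net = nets[comp]
        part = spinglass_cluster(
            net, gamma_pos=cfg.gamma_pos, gamma_neg=cfg.gamma_neg,
            n_runs=cfg.spinglass_runs, seed=cfg.seeded(f"spinglass:{comp}"))
        sub = table.subset(asvs=[a for a in net.node_ids])
        part.summary = summarize_partition(part, sub)
        density = cluster_density_test(net, part,
                                       n_random=cfg.density_test_random,
                                       seed=cfg.seeded(f"density:{comp}"))
        ab = cluster_abundances(sub, part)
        corr = intercluster_correlations(ab, loc)
        climate = []
        md = meta.table.set_index("sample_id")
        for cid in ab.columns:
            try:
                cm = cluster_climate_model(
                    ab[cid], md["temperature"], md["precipitation"], loc)
                cm["cluster_id"] = cid
                climate.append(cm)
            except Exception as exc:   # degenerate cluster
                logger.warning("climate model failed for %s/%s: %s",
                               comp, cid, exc)
        climate = pd.concat(climate, ignore_index=True)
        # specialist / generalist labels from SI CWMs
        si = pd.read_csv(workdir / f"si_{comp}.tsv", sep="\t", index_col=0)
        rarefied = AsvCountTable(counts=pd.read_csv(
            workdir / f"rarefied_{comp}.tsv", sep="\t", index_col=0))
        community_cwm = specialisation.cwm_si(rarefied, si)
        cluster_cwm = {}
        for cid in part.cluster_ids:
            members = [a for a in part.members(cid) if a in si.index]
            if members:
                cluster_cwm[cid] = specialisation.cwm_si(rarefied, si, members)
        labels = specialisation.classify_clusters(cluster_cwm, community_cwm)
        part.assignments.to_frame("cluster_id").to_csv(
            workdir / f"partition_{comp}.tsv", sep="\t", index_label="node")
        part.summary.join(labels["label"]).to_csv(
            workdir / f"cluster_summary_{comp}.tsv", sep="\t")
        ab.to_csv(workdir / f"cluster_abundance_{comp}.tsv", sep="\t",
                  index_label="sample_id")
        corr.to_csv(workdir / f"cluster_correlations_{comp}.tsv", sep="\t",
                    index=False)
        climate.to_csv(workdir / f"cluster_climate_{comp}.tsv", sep="\t",
                       index=False)
        outputs += [workdir / f"partition_{comp}.tsv",
                    workdir / f"cluster_summary_{comp}.tsv",
                    workdir / f"cluster_abundance_{comp}.tsv",
                    workdir / f"cluster_correlations_{comp}.tsv",
                    workdir / f"cluster_climate_{comp}.tsv"]
        out[comp] = {"partition": part, "abundances": ab, "labels": labels,
                     "density": density, "correlations": corr,
                     "climate": climate}
    Manifest(workdir, cfg).record("cluster", outputs)
    return out


def stage_sem(workdir: Path, cfg: PipelineConfig) -> tuple[PathModel, SemEngine]:
    """Fit and reduce the base climate-pathway model."""
    workdir = Path(workdir)
    cov = pd.read_csv(workdir / "covariates.tsv", sep="\t", index_col=0)
    data = cov.reset_index()
    # attach cluster abundances for the attribution stage
    for comp in COMPARTMENTS:
        p = workdir / f"cluster_abundance_{comp}.tsv"
        if p.exists():
            ab = pd.read_csv(p, sep="\t", index_col=0)
            ab.columns = [f"{comp}_{c}" for c in ab.columns]
            data = data.join(ab.reset_index(drop=True))
    engine = SemEngine(data)
    base = engine.backward_eliminate(default_base_model())
    edges = base.coefficients.copy()
    edges.to_csv(workdir / "sem_base_edges.tsv", sep="\t", index=False)
    fit = {
        "fisher_c": base.fisher_c, "df": base.df_c, "p_value": base.p_c,
        "aicc": base.aicc, "n_params": base.n_params, "n_obs": base.n_obs,
        "accepted": bool(base.accepted),
        "marginal_r2": {k: v[0] for k, v in base.r2.items()},
        "conditional_r2": {k: v[1] for k, v in base.r2.items()},
    }
    (workdir / "sem_base_fit.json").write_text(
        json.dumps(fit, indent=1, sort_keys=True))
    Manifest(workdir, cfg).record("sem", [workdir / "sem_base_edges.tsv",
                                          workdir / "sem_base_fit.json"])
    return base, engine


def stage_attribute(workdir: Path, cfg: PipelineConfig,
                    base: PathModel | None = None,
                    engine: SemEngine | None = None) -> dict:
    """Append each cluster to the base model and attribute its variation."""
    workdir = Path(workdir)
    if base is None or engine is None:
        base, engine = stage_sem(workdir, cfg)
    candidates = climate_candidates(base)
    results: dict[str, list[AttributionResult]] = {}
    rows = []
    for comp in COMPARTMENTS:
        summary = pd.read_csv(workdir / f"cluster_summary_{comp}.tsv",
                              sep="\t", index_col=0)
        comp_results = []
        for cid, srow in summary.iterrows():
            response = f"{comp}_{cid}"
            model = engine.append_response(base, response, candidates,
                                           require_accepted=False)
            rel = float(srow["relative_size"])
            if response in model.r2:
                res = explained_fractions(response, model,
                                          cluster_relative_size=rel,
                                          alpha=cfg.alpha,
                                          on_empty="unexplained")
            else:
                # every candidate edge eliminated: explained share is zero,
                # the location intercept still absorbs its share
                icc_fit = fit_lmm(
                    engine.column(response,
                                  model.transforms.get(response, "identity")),
                    np.ones((len(engine.raw), 1)), engine.groups)
                icc = icc_fit.sigma2_b / (icc_fit.sigma2_b + icc_fit.sigma2_e)
                res = AttributionResult(
                    response_id=response, paths=pd.DataFrame(
                        columns=["path", "category", "composite_effect",
                                 "abs_effect", "mediator"]),
                    category_shares={c: 0.0 for c in
                                     ("temperature_only", "precipitation_only",
                                      "joint")},
                    random_share=float(icc), unexplained_share=1.0 - float(icc),
                    marginal_r2=0.0, conditional_r2=float(icc),
                    cluster_relative_size=rel)
            comp_results.append(res)
            for cat, share in res.shares().items():
                rows.append({"compartment": comp, "cluster_id": cid,
                             "category": cat, "share": share,
                             "relative_size": rel})
            per_var = per_variable_contributions(res)
            for var, val in per_var.items():
                rows.append({"compartment": comp, "cluster_id": cid,
                             "category": f"mediator:{var}", "share": val,
                             "relative_size": rel})
        results[comp] = comp_results
    detail = pd.DataFrame(rows)
    agg_rows = []
    for comp, rs in results.items():
        agg = aggregate_attribution(rs)
        for cat, share in agg.items():
            agg_rows.append({"compartment": comp, "category": cat,
                             "share": share})
    aggregated = pd.DataFrame(agg_rows)
    detail.to_csv(workdir / "attribution_detail.tsv", sep="\t", index=False)
    aggregated.to_csv(workdir / "attribution_aggregated.tsv", sep="\t",
                      index=False)
    Manifest(workdir, cfg).record("attribute", [
        workdir / "attribution_detail.tsv",
        workdir / "attribution_aggregated.tsv"])
    return {"detail": detail, "aggregated": aggregated, "results": results}


def stage_report(workdir: Path, cfg: PipelineConfig) -> Path:
    workdir = Path(workdir)
    lines = ["# Pipeline report", ""]
    fit = json.loads((workdir / "sem_base_fit.json").read_text())
    lines += [
        "## Base path model",
        f"- Fisher's C = {fit['fisher_c']:.2f} on {fit['df']} df, "
        f"p = {fit['p_value']:.3f} ({'accepted' if fit['accepted'] else 'rejected'})",
        f"- AICc = {fit['aicc']:.2f}, K = {fit['n_params']}, n = {fit['n_obs']}",
        "",
    ]
    for comp in COMPARTMENTS:
        summary = pd.read_csv(workdir / f"cluster_summary_{comp}.tsv",
                              sep="\t", index_col=0)
        lines.append(f"## {comp.capitalize()} network")
        lines.append(f"- {len(summary)} clusters; labels: "
                     + ", ".join(f"{c}={summary.loc[c, 'label']}"
                                 for c in summary.index))
        lines.append("")
    agg = pd.read_csv(workdir / "attribution_aggregated.tsv", sep="\t")
    lines.append("## Attribution (cluster-size weighted)")
    for comp in COMPARTMENTS:
        sub = agg[agg["compartment"] == comp]
        parts = ", ".join(f"{r.category}={r.share:.3f}"
                          for r in sub.itertuples())
        lines.append(f"- {comp}: {parts}")
    p = workdir / "report.md"
    p.write_text("\n".join(lines) + "\n")
    Manifest(workdir, cfg).record("report", [p])
    return p


def run_all(cfg: PipelineConfig, workdir) -> dict:
    """simulate -> ... -> report; returns the in-memory stage results."""
    workdir = Path(workdir)
    ds = stage_simulate(workdir, cfg)
    tables = stage_filter(workdir, cfg)
    comm = stage_community(workdir, cfg)
    seas = stage_seasonal(workdir, cfg)
    si = stage_si(workdir, cfg)
    nets = stage_network(workdir, cfg)
    clusters = stage_cluster(workdir, cfg, nets)
    base, engine = stage_sem(workdir, cfg)
    attrib = stage_attribute(workdir, cfg, base, engine)
    report = stage_report(workdir, cfg)
    return {"dataset": ds, "tables": tables, "community": comm,
            "seasonal": seas, "si": si, "networks": nets,
            "clusters": clusters, "base_model": base, "engine": engine,
            "attribution": attrib, "report": report}
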