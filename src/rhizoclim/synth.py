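"""Synthetic emulation of the climate-grid study, with known ground truth.

The generator declares a ground-truth path DAG (standardized linear-Gaussian
structural equations with a location random intercept), lays it over a
3-temperature x 4-precipitation factorial grid of 12 locations x 8 plants,
and derives from it:

* a covariate table (season start, winter vegetation temperature, soil
  moisture and its circadian fluctuation, plant covers, diversity, soil
  chemistry) on physical scales via affine maps of the standardized latents;
* sensor time series (daily soil temperature sinusoids whose spring 2.5 C
  crossing reproduces each location's season start; hourly soil moisture
  with a diel cycle reproducing the circadian CV; winter canopy temperature);
* per-compartment ASV count tables: cluster latents respond to declared
  covariates, ASV log-abundances add cluster latents, specialist ASVs get
  location-concentrated offsets, and counts are drawn multinomially with
  log-normal sequencing depth (an overdispersed, Dirichlet-multinomial-like
  model).

Default coefficient signs follow the study system: temperature advances and
precipitation delays the start of the growing season (coded as days since
soil defrost, so T has a positive and P a negative coefficient), an early
season lowers soil pH, temperature raises forb cover which raises NO3,
warm vegetation winters raise bryophyte and lower litter cover, and shrub
cover damps the circadian soil-moisture cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AsvCountTable, SampleMetadata

# ---------------------------------------------------------------------------
# ground-truth DAG (parent, child, standardized coefficient)
# ---------------------------------------------------------------------------

DEFAULT_DAG: list[tuple[str, str, float]] = [
    ("temperature", "season_start", 0.55),
    ("precipitation", "season_start", -0.45),
    ("temperature", "winter_veg_temp", 0.50),
    ("precipitation", "winter_veg_temp", 0.40),
    ("precipitation", "mean_soil_moisture", 0.60),
    ("temperature", "forb_cover", 0.55),
    ("season_start", "shrub_cover", -0.50),
    ("season_start", "plant_shannon", -0.45),
    ("season_start", "soil_pH", -0.60),
    ("winter_veg_temp", "bryophyte_cover", 0.50),
    ("winter_veg_temp", "litter_cover", -0.50),
    ("forb_cover", "NO3", 0.50),
    ("plant_shannon", "PO4", 0.45),
    ("shrub_cover", "circadian_cv", -0.45),
    ("winter_veg_temp", "circadian_cv", 0.40),
]

# affine maps from standardized latents to physical scales
PHYSICAL_MAPS: dict[str, tuple[float, float]] = {
    "season_start": (60.0, 15.0),          # days since soil defrost
    "winter_veg_temp": (-2.0, 1.5),        # degrees C
    "mean_soil_moisture": (0.35, 0.06),    # volumetric fraction
    "circadian_cv": (0.18, 0.05),          # dimensionless
    "forb_cover": (25.0, 7.0),             # percent
    "shrub_cover": (20.0, 6.0),
    "bryophyte_cover": (30.0, 8.0),
    "litter_cover": (15.0, 5.0),
    "festuca_cover": (18.0, 5.0),
    "plant_shannon": (2.0, 0.35),          # nats
    "soil_pH": (5.8, 0.35),
    "NO3": (6.0, 2.0),                     # mg per kg dry soil
    "PO4": (8.0, 2.5),
}

# cluster -> {covariate: coefficient on the cluster latent}
RHIZOSPHERE_EFFECTS: dict[str, dict[str, float]] = {
    "c1": {"season_start": 0.9},
    "c2": {"soil_pH": -0.9},
    "c3": {"bryophyte_cover": -0.7},
    "c4": {"forb_cover": 0.7},
    "c5": {"mean_soil_moisture": 0.7},
}
ROOT_EFFECTS: dict[str, dict[str, float]] = {
    "c1": {"season_start": 0.8},
    "c2": {"soil_pH": -0.8},
    "c3": {"temperature": -0.6},
    "c4": {"precipitation": 0.6},
}


@dataclass
class CommunityConfig:
    """One compartment's planted community."""

    effects: dict[str, dict[str, float]]
    asvs_per_cluster: int = 10
    specialist_fraction: float = 0.4      # fraction of clusters planted specialist
    specialist_offset_sd: float = 2.0     # among-location log-abundance SD
    cluster_latent_sd: float = 0.5        # residual SD of the cluster latent
    asv_noise_sd: float = 0.35            # per-sample overdispersion (log scale)
    asv_base_sd: float = 0.8              # spread of ASV mean log-abundances
    fraction_16s: float = 0.6
    depth_meanlog: float = np.log(2e4)
    depth_sdlog: float = 0.25

    @property
    def n_clusters(self) -> int:
        return len(self.effects)

    def specialist_clusters(self) -> set[str]:
        k = int(round(self.specialist_fraction * self.n_clusters))
        return set(list(self.effects)[:k])


@dataclass
class GeneratorConfig:
    temperature_levels: tuple = (6.5, 8.5, 10.5)        # degrees C
    precipitation_levels: tuple = (600, 1200, 2000, 2700)  # mm per year
    samples_per_location: int = 8
    dag: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_DAG))
    intercept_sd_share: float = 0.25  # location-intercept share of residual SD
    noise_only: tuple = ("festuca_cover",)
    rhizosphere: CommunityConfig = field(
        default_factory=lambda: CommunityConfig(effects=dict(RHIZOSPHERE_EFFECTS)))
    root: CommunityConfig = field(
        default_factory=lambda: CommunityConfig(
            effects=dict(ROOT_EFFECTS), depth_meanlog=np.log(8e3)))
    sensor_years: tuple = tuple(range(2015, 2021))
    sampling_date: str = "2020-07-15"
    moisture_noise_sd: float = 0.01
    soil_temp_noise_sd: float = 0.0
    failure_months: list = field(default_factory=list)  # (loc, sensor, year, [months])
    seed: int = 0


@dataclass
class SyntheticDataset:
    metadata: SampleMetadata
    covariates: pd.DataFrame          # physical scales, per sample
    covariates_z: pd.DataFrame        # standardized latents, per sample
    location_truth: pd.DataFrame      # per-location physical targets
    tables: dict[str, AsvCountTable]  # compartment -> counts
    sensors: pd.DataFrame | None
    truth: dict


# ---------------------------------------------------------------------------
# design and covariates
# ---------------------------------------------------------------------------

def generate_design(config: GeneratorConfig) -> SampleMetadata:
    """Full factorial temperature x precipitation grid of locations."""
    rows = []
    loc = 0
    for t in config.temperature_levels:
        for p in config.precipitation_levels:
            loc += 1
            lid = f"L{loc:02d}"
            for i in range(config.samples_per_location):
                rows.append({
                    "sample_id": f"{lid}_S{i + 1}",
                    "location_id": lid,
                    "temperature": float(t),
                    "precipitation": float(p),
                    "individual_index": i + 1,
                })
    return SampleMetadata(pd.DataFrame(rows))


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def topological_children(dag) -> list[str]:
    """Children in an order where every parent precedes its child."""
    children = {}
    for parent, child, _ in dag:
        children.setdefault(child, []).append((parent, _))
    placed = {"temperature", "precipitation"}
    order = []
    pending = dict(children)
    while pending:
        ready = [c for c, ps in pending.items()
                 if all(p in placed for p, _ in ps)]
        if not ready:
            raise ValueError("ground-truth DAG contains a cycle")
        for c in sorted(ready):
            order.append(c)
            placed.add(c)
            del pending[c]
    return order


def generate_covariates(
    config: GeneratorConfig, metadata: SampleMetadata, rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Sample covariates from the ground-truth structural equations.

    Residual variances are solved so every standardized node has unit
    population variance (exact bookkeeping via the recursively built
    covariance matrix), which makes the declared coefficients the true
    standardized effects.
    """
    md = metadata.table
    n = len(md)
    locs = md["location_id"].to_numpy()
    uniq_locs = pd.unique(locs)
    loc_idx = pd.Series(range(len(uniq_locs)), index=uniq_locs)[locs].to_numpy()

    z = pd.DataFrame(index=md["sample_id"])
    z["temperature"] = _zscore(md["temperature"].to_numpy())
    z["precipitation"] = _zscore(md["precipitation"].to_numpy())
    loc_component: dict[str, np.ndarray] = {}  # per-location latent means

    # population covariance bookkeeping
    cov = {("temperature", "temperature"): 1.0,
           ("precipitation", "precipitation"): 1.0,
           ("temperature", "precipitation"): 0.0,
           ("precipitation", "temperature"): 0.0}
    parents_of: dict[str, list[tuple[str, float]]] = {}
    for p, c, b in config.dag:
        parents_of.setdefault(c, []).append((p, b))

    resid = {}
    for child in topological_children(config.dag):
        ps = parents_of[child]
        var_struct = 0.0
        for p1, b1 in ps:
            for p2, b2 in ps:
                var_struct += b1 * b2 * cov[(p1, p2)]
        resid_var = 1.0 - var_struct
        if resid_var <= 0.01:
            raise ValueError(f"{child}: structural variance >= 1; shrink coefficients")
        sd_b = config.intercept_sd_share * np.sqrt(resid_var)
        sd_e = np.sqrt(resid_var - sd_b ** 2)
        resid[child] = (resid_var, sd_b, sd_e)
        fixed = np.zeros(n)
        for p, b in ps:
            fixed += b * z[p].to_numpy()
        b_loc = rng.normal(0.0, sd_b, size=len(uniq_locs))
        vals = fixed + b_loc[loc_idx] + rng.normal(0.0, sd_e, size=n)
        z[child] = vals
        # location-level latent mean: fixed part + intercept, per location
        fx = pd.Series(fixed + b_loc[loc_idx], index=locs)
        loc_component[child] = fx.groupby(level=0).mean().reindex(uniq_locs).to_numpy()
        # extend covariance
        new_cov = {}
        for v in {a for a, _ in cov}:
            c_val = sum(b * cov[(p, v)] for p, b in ps)
            new_cov[(child, v)] = c_val
            new_cov[(v, child)] = c_val
        cov.update(new_cov)
        cov[(child, child)] = 1.0

    for name in config.noise_only:
        z[name] = rng.normal(0.0, 1.0, size=n)

    phys = pd.DataFrame(index=md["sample_id"])
    phys["location_id"] = locs
    phys["temperature"] = md["temperature"].to_numpy()
    phys["precipitation"] = md["precipitation"].to_numpy()
    for name, (off, scale) in PHYSICAL_MAPS.items():
        if name in z.columns:
            phys[name] = off + scale * z[name].to_numpy()

    loc_truth = pd.DataFrame(index=pd.Index(uniq_locs, name="location_id"))
    for name in ("season_start", "winter_veg_temp", "mean_soil_moisture",
                 "circadian_cv"):
        off, scale = PHYSICAL_MAPS[name]
        loc_truth[name] = off + scale * loc_component[name]
    loc_truth["season_start"] = loc_truth["season_start"].round().astype(int)
    loc_truth["circadian_cv"] = loc_truth["circadian_cv"].clip(lower=0.03)

    truth = {
        "dag": [{"parent": p, "child": c, "coefficient": b}
                for p, c, b in config.dag],
        "residual_variances": {k: v[0] for k, v in resid.items()},
        "intercept_sd": {k: v[1] for k, v in resid.items()},
        "residual_sd": {k: v[2] for k, v in resid.items()},
    }
    return phys, z, loc_truth, truth


# ---------------------------------------------------------------------------
# sensor series
# ---------------------------------------------------------------------------

def generate_sensor_series(
    config: GeneratorConfig, location_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format sensor series consistent with the location targets."""
    sampling = pd.Timestamp(config.sampling_date)
    frames = []
    for lid, row in location_truth.iterrows():
        # daily soil temperature in the sampling year: sinusoid with its
        # strict 2.5 C exceedance on the target day-of-year
        d_cross = sampling.dayofyear - int(row["season_start"])
        days = pd.date_range(f"{sampling.year}-01-01", sampling, freq="D")
        doy = days.dayofyear.to_numpy()
        temp = 2.5 + 8.0 * np.sin(2 * np.pi * (doy - d_cross + 0.5) / 365.0)
        if config.soil_temp_noise_sd > 0:
            temp = temp + rng.normal(0, config.soil_temp_noise_sd, len(temp))
        frames.append(pd.DataFrame({
            "location_id": lid, "sensor_id": "st1", "timestamp": days,
            "variable": "soil_temperature_C", "value": temp}))

        # daily canopy temperature across years: equals the winter target in
        # Jan-Mar, warmer outside the window
        cdays = pd.date_range(f"{config.sensor_years[0]}-01-01",
                              f"{config.sensor_years[-1]}-12-31", freq="D")
        cdoy = cdays.dayofyear.to_numpy()
        canopy = row["winter_veg_temp"] + 14.0 * np.maximum(
            0.0, np.sin(2 * np.pi * (cdoy - 105) / 365.0))
        frames.append(pd.DataFrame({
            "location_id": lid, "sensor_id": "ct1", "timestamp": cdays,
            "variable": "canopy_temperature_C", "value": canopy}))

        # hourly soil moisture, two sensors with opposite calibration offsets
        hours = pd.date_range(f"{config.sensor_years[0]}-01-01",
                              f"{config.sensor_years[-1]}-12-31 23:00",
                              freq="h")
        hod = hours.hour.to_numpy()
        amp = row["circadian_cv"] * row["mean_soil_moisture"] * np.sqrt(2.0)
        diel = amp * np.sin(2 * np.pi * hod / 24.0)
        for sid, offset in (("sm1", 0.01), ("sm2", -0.01)):
            vals = (row["mean_soil_moisture"] + offset + diel
                    + rng.normal(0, config.moisture_noise_sd, len(hours)))
            frames.append(pd.DataFrame({
                "location_id": lid, "sensor_id": sid, "timestamp": hours,
                "variable": "soil_moisture_vol", "value": vals}))
    series = pd.concat(frames, ignore_index=True)

    for loc, sensor, year, months in config.failure_months:
        ts = series["timestamp"]
        drop = ((series["location_id"] == loc)
                & (series["sensor_id"] == sensor)
                & (ts.dt.year == year)
                & (ts.dt.month.isin(list(months))))
        series = series[~drop]
    return series.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ASV counts
# ---------------------------------------------------------------------------

def generate_asv_tables(
    config: GeneratorConfig,
    covariates_z: pd.DataFrame,
    metadata: SampleMetadata,
    rng: np.random.Generator,
) -> tuple[dict[str, AsvCountTable], dict]:
    """Per-compartment count tables with planted clusters and specialists."""
    md = metadata.table
    locs = md["location_id"].to_numpy()
    uniq_locs = pd.unique(locs)
    loc_idx = pd.Series(range(len(uniq_locs)), index=uniq_locs)[locs].to_numpy()
    n = len(md)
    tables: dict[str, AsvCountTable] = {}
    truth: dict = {}

    for compartment, cc in (("rhizosphere", config.rhizosphere),
                            ("root", config.root)):
        specialists = cc.specialist_clusters()
        asv_ids, markers, cluster_of, spec_flag = [], [], {}, {}
        log_ab = []
        for cid, effects in cc.effects.items():
            latent = rng.normal(0.0, cc.cluster_latent_sd, size=n)
            for var, coef in effects.items():
                latent = latent + coef * covariates_z[var].to_numpy()
            is_spec = cid in specialists
            for j in range(cc.asvs_per_cluster):
                aid = f"{compartment[:4]}_{cid}_a{j + 1}"
                asv_ids.append(aid)
                cluster_of[aid] = cid
                spec_flag[aid] = is_spec
                markers.append("16S" if j < cc.fraction_16s * cc.asvs_per_cluster
                               else "ITS")
                base = rng.normal(0.0, cc.asv_base_sd)
                if is_spec:
                    u = rng.normal(0.0, cc.specialist_offset_sd,
                                   size=len(uniq_locs))
                    # centre multiplicatively: specialists concentrate reads
                    # across locations without being more abundant overall
                    u -= np.log(np.mean(np.exp(u)))
                else:
                    u = np.zeros(len(uniq_locs))
                noise = rng.normal(0.0, cc.asv_noise_sd, size=n)
                log_ab.append(base + latent + u[loc_idx] + noise)
        A = np.column_stack(log_ab)
        # softmax composition per sample, multinomial counts at log-normal depth
        A = A - A.max(axis=1, keepdims=True)
        comp = np.exp(A)
        comp /= comp.sum(axis=1, keepdims=True)
        depths = np.maximum(
            rng.lognormal(cc.depth_meanlog, cc.depth_sdlog, size=n), 500
        ).astype(int)
        counts = np.empty((n, len(asv_ids)), dtype=np.int64)
        for s in range(n):
            counts[s] = rng.multinomial(depths[s], comp[s])
        table = AsvCountTable(
            counts=pd.DataFrame(counts, index=md["sample_id"].to_numpy(),
                                columns=asv_ids),
            marker=pd.Series(markers, index=asv_ids),
            compartment=pd.Series(compartment, index=md["sample_id"].to_numpy()),
        )
        tables[compartment] = table
        truth[compartment] = {
            "cluster_of": cluster_of,
            "specialist_clusters": sorted(specialists),
            "generalist_clusters": sorted(set(cc.effects) - specialists),
            "specialist_asv": spec_flag,
            "cluster_effects": cc.effects,
        }
    return tables, truth


# ---------------------------------------------------------------------------
# one-call generation
# ---------------------------------------------------------------------------

def generate_all(config: GeneratorConfig | None = None,
                 with_sensors: bool = True) -> SyntheticDataset:
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    r_cov, r_sensor, r_asv = rng.spawn(3)
    metadata = generate_design(config)
    phys, z, loc_truth, cov_truth = generate_covariates(config, metadata, r_cov)
    sensors = (generate_sensor_series(config, loc_truth, r_sensor)
               if with_sensors else None)
    tables, community_truth = generate_asv_tables(config, z, metadata, r_asv)
    return SyntheticDataset(
        metadata=metadata,
        covariates=phys,
        covariates_z=z,
        location_truth=loc_truth,
        tables=tables,
        sensors=sensors,
        truth={"covariates": cov_truth, "community": community_truth},
    )
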