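"""Tabular inputs and outputs: ASV count tables, sample metadata, sensor series.

Canonical interchange is TSV: count tables with samples as rows and a header
row of ASV ids, metadata keyed by ``sample_id``, and sensor data in long
format (location_id, sensor_id, timestamp, variable, value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "location_id", "temperature", "precipitation"]
SENSOR_COLUMNS = ["location_id", "sensor_id", "timestamp", "variable", "value"]
SENSOR_VARIABLES = {"soil_temperature_C", "soil_moisture_vol", "canopy_temperature_C"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvCountTable:
    """Integer sample x ASV count matrix with marker and compartment labels.

    counts: DataFrame indexed by sample_id, columns are ASV ids.
    marker: per-ASV Series with values in {"16S", "ITS"} (optional).
    compartment: per-sample Series, {"rhizosphere", "root"} (optional).
    taxonomy: optional per-ASV rank strings.
    """

    counts: pd.DataFrame
    marker: pd.Series | None = None
    compartment: pd.Series | None = None
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate ASV ids")
        vals = c.to_numpy()
        if vals.size and (vals < 0).any():
            bad = c.columns[np.argwhere(vals < 0)[0][1]]
            raise ValidationError(f"negative count in ASV {bad!r}")
        if not np.issubdtype(vals.dtype, np.integer):
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise ValidationError("non-integer counts")
            self.counts = c.astype(np.int64)
        if self.marker is not None:
            self.marker = self.marker.reindex(c.columns)
            bad = set(self.marker.dropna()) - {"16S", "ITS"}
            if bad:
                raise ValidationError(f"unknown marker labels: {sorted(bad)}")
        if self.compartment is not None:
            self.compartment = self.compartment.reindex(c.index)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def asv_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset(self, samples=None, asvs=None) -> "AsvCountTable":
        c = self.counts
        if samples is not None:
            c = c.loc[list(samples)]
        if asvs is not None:
            c = c.loc[:, list(asvs)]
        return AsvCountTable(
            counts=c.copy(),
            marker=self.marker.loc[c.columns].copy() if self.marker is not None else None,
            compartment=self.compartment.loc[c.index].copy() if self.compartment is not None else None,
            taxonomy=self.taxonomy.loc[c.columns].copy() if self.taxonomy is not None else None,
        )

    def equals(self, other: "AsvCountTable") -> bool:
        if not self.counts.equals(other.counts):
            return False
        for a, b in ((self.marker, other.marker), (self.compartment, other.compartment)):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        return True


@dataclass
class SampleMetadata:
    """Per-sample design information for the climate grid."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        per_sample = self.table.groupby("sample_id")["location_id"].nunique()
        if (per_sample > 1).any():
            raise ValidationError("a sample maps to more than one location")

    def location_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["location_id"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(path, format: str = "tsv") -> AsvCountTable:
    """Read a samples x ASVs count table.

    TSV layout: header row of ASV ids, first column sample ids.  Raises a
    :class:`ValidationError` on negative or non-integer entries.
    """
    if format == "biom":
        raise NotImplementedError(
            "BIOM input is not supported in this build; convert to TSV "
            "(samples as rows, ASVs as columns)")
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    from pathlib import Path as _P
    if not _P(path).exists():
        raise ValidationError(f"count table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed count table {path}: {exc}") from exc
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ValidationError(f"non-numeric counts in columns {bad[:3]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AsvCountTable(counts=df)


def write_asv_table(table: AsvCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "location_id": str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_sensor_series(path) -> pd.DataFrame:
    """Long-format sensor series; timestamps parsed, order validated."""
    df = pd.read_csv(path, sep="\t", dtype={"location_id": str, "sensor_id": str})
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sensor series missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    bad = set(df["variable"]) - SENSOR_VARIABLES
    if bad:
        raise ValidationError(f"unknown sensor variables: {sorted(bad)}")
    check = df.groupby(["location_id", "sensor_id", "variable"])["timestamp"]
    if not check.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
        raise ValidationError("timestamps not strictly increasing per sensor")
    return df


def write_sensor_series(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_low_reads(
    table: AsvCountTable,
    min_asv_reads: int = 100,
    min_sample_reads: int = 1000,
    blank_asvs: set | None = None,
    exclude_samples: set | None = None,
) -> AsvCountTable:
    """Remove contaminant/rare ASVs and shallow samples.

    Single fixed pass: blank-listed ASVs first, then ASVs with total reads
    below ``min_asv_reads``, then samples with total reads below
    ``min_sample_reads`` (evaluated once, after the ASV passes).  An explicit
    ``exclude_samples`` list supports manual outlier removal.
    """
    if min_asv_reads < 0 or min_sample_reads < 0:
        raise ValueError("thresholds must be >= 0")
    c = table.counts
    if exclude_samples:
        c = c.loc[[s for s in c.index if s not in set(exclude_samples)]]
    if blank_asvs:
        c = c.loc[:, [a for a in c.columns if a not in set(blank_asvs)]]
    asv_keep = c.columns[c.sum(axis=0) >= min_asv_reads]
    c = c[asv_keep]
    sample_keep = c.index[c.sum(axis=1) >= min_sample_reads]
    if len(sample_keep) == 0:
        raise ValidationError("filtering removed every sample")
    result = table.subset(samples=sample_keep, asvs=asv_keep)
    dropped = len(table.sample_ids) - len(sample_keep)
    if dropped:
        logger.info("filter_low_reads dropped %d sample(s)", dropped)
    return result


def network_prefilter(
    table: AsvCountTable,
    min_asv_reads: int = 100,
    min_prevalence_samples: int = 6,
) -> AsvCountTable:
    """Keep ASVs with total reads >= threshold and prevalence (samples with
    count > 0) >= threshold, for network estimation."""
    c = table.counts
    totals = c.sum(axis=0)
    prevalence = (c > 0).sum(axis=0)
    keep = c.columns[(totals >= min_asv_reads) & (prevalence >= min_prevalence_samples)]
    return table.subset(asvs=keep)
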