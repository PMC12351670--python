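"""Habitat specialisation index (SI) and generalist/specialist classification.

SI of ASV i over rarefied counts:

    SI_i = sigma_i / mu_i - K / N_i

the coefficient of variation of the ASV's rarefied reads across samples,
minus K/N as a correction for under-sampling of rare ASVs (K = number of
habitat classes, here locations; N_i = the ASV's total rarefied reads).
Habitat specialists concentrate their reads in few samples (high CV);
generalists spread evenly (low CV).  Community-weighted means (CWM) of SI
summarise a sample, and network clusters are labelled specialist,
generalist or unspecified by comparing their per-sample CWM distribution
with the community-wide mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_tables import AsvCountTable, ValidationError

logger = logging.getLogger(__name__)


def specialisation_index(
    rarefied: AsvCountTable,
    k_habitat: int,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-ASV SI on a table rarefied to a common depth.

    ``ddof=1`` uses the sample standard deviation; exposed because the index
    definition does not pin the estimator.  ASVs with zero reads after
    rarefaction are excluded with a warning rather than scored.
    """
    if k_habitat < 1:
        raise ValueError("k_habitat must be >= 1")
    c = rarefied.counts
    totals = c.sum(axis=1)
    if totals.nunique() != 1:
        raise ValidationError(
            "input is not rarefied to a common depth (unequal sample sums)")
    mat = c.to_numpy(dtype=float)
    mu = mat.mean(axis=0)
    keep = mu > 0
    if (~keep).any():
        logger.warning("specialisation_index excluded %d zero-read ASV(s)",
                       int((~keep).sum()))
    mat = mat[:, keep]
    mu = mu[keep]
    sigma = mat.std(axis=0, ddof=ddof)
    n_tot = mat.sum(axis=0)
    si = sigma / mu - k_habitat / n_tot
    return pd.DataFrame({
        "asv_id": np.asarray(c.columns)[keep],
        "SI": si,
        "sigma": sigma,
        "mu": mu,
        "N": n_tot.astype(int),
        "K": k_habitat,
    }).set_index("asv_id")


def cwm_si(
    rarefied: AsvCountTable,
    si: pd.DataFrame,
    asv_subset=None,
) -> pd.Series:
    """Community-weighted mean SI per sample.

    Weights are the sample's rarefied reads over ``asv_subset`` (default: all
    scored ASVs).  Samples with zero subset reads return NaN.
    """
    scored = si.index
    if asv_subset is not None:
        scored = [a for a in asv_subset if a in si.index]
        if not scored:
            raise ValidationError("empty ASV subset for CWM")
    w = rarefied.counts.reindex(columns=scored, fill_value=0).to_numpy(dtype=float)
    vals = si.loc[scored, "SI"].to_numpy()
    tot = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (w @ vals) / tot
    cwm[tot == 0] = np.nan
    return pd.Series(cwm, index=rarefied.counts.index, name="cwm_si")


def classify_clusters(
    cluster_cwm: dict[str, pd.Series],
    community_cwm: pd.Series,
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Label each cluster generalist / specialist / unspecified.

    The community-wide reference is the mean over samples of the all-ASV CWM.
    A cluster whose interquartile range of per-sample CWM values contains the
    reference is ``unspecified``; otherwise it is ``specialist`` if its mean
    CWM lies above the reference and ``generalist`` if below.
    """
    ref = float(community_cwm.dropna().mean())
    rows = []
    for cid, series in cluster_cwm.items():
        vals = series.dropna().to_numpy()
        if len(vals) < 4:
            raise ValidationError(
                f"cluster {cid}: need >= 4 CWM values for a robust IQR")
        q1, q3 = np.quantile(vals, [0.25, 0.75], method=quartile_method)
        mean = float(vals.mean())
        if q1 <= ref <= q3:
            label = "unspecified"
        elif mean > ref:
            label = "specialist"
        else:
            label = "generalist"
        rows.append({"cluster_id": cid, "label": label, "mean_cwm_si": mean,
                     "q1": q1, "q3": q3, "community_mean_si": ref})
    return pd.DataFrame(rows).set_index("cluster_id")
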