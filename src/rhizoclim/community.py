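"""Compositional normalisation, rarefaction diversity, overlap and PERMANOVA.

The count tables are compositional: only relative information is meaningful.
Ordination-scale analyses therefore use the centred log-ratio (clr)
transform, pairing Euclidean geometry on clr values with the Aitchison
distance.  Alpha diversity uses Shannon entropy averaged over repeated
rarefactions so that library-size differences cannot masquerade as
diversity differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import AsvCountTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    values: pd.DataFrame  # samples x ASVs, rows sum to ~0

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def asv_ids(self):
        return list(self.values.columns)


def clr_transform(table: AsvCountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centred log-ratio transform of counts + pseudocount.

    value[s, i] = ln(c[s, i] + pc) - mean_i ln(c[s, .] + pc); each row sums
    to zero, removing the arbitrary sequencing-depth scale.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = table.counts
    if c.size == 0:
        raise ValidationError("empty count table")
    logs = np.log(c.to_numpy(dtype=float) + pseudocount)
    vals = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(vals, index=c.index, columns=c.columns))


def rarefy(table: AsvCountTable, depth: int, seed) -> AsvCountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning.  Uses the
    multivariate hypergeometric distribution, i.e. drawing reads without
    replacement from the observed pool.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    c = table.counts
    totals = c.sum(axis=1)
    keep = totals.index[totals >= depth]
    if len(keep) == 0:
        raise ValidationError(f"no sample has >= {depth} reads")
    if len(keep) < len(c):
        logger.warning("rarefy dropped %d sample(s) below depth %d",
                       len(c) - len(keep), depth)
    sub = c.loc[keep].to_numpy()
    out = np.empty_like(sub)
    for r in range(sub.shape[0]):
        out[r] = rng.multivariate_hypergeometric(sub[r], depth)
    res = pd.DataFrame(out, index=keep, columns=c.columns)
    return AsvCountTable(
        counts=res,
        marker=table.marker.copy() if table.marker is not None else None,
        compartment=table.compartment.loc[keep].copy()
        if table.compartment is not None else None,
        taxonomy=table.taxonomy.copy() if table.taxonomy is not None else None,
    )


def shannon_multirarefy(
    table: AsvCountTable,
    depth: int | None = None,
    n_iterations: int = 1000,
    seed=0,
) -> pd.DataFrame:
    """Mean Shannon entropy (nats) over repeated rarefactions per sample.

    ``depth`` defaults to the smallest sample total.  Returns a DataFrame
    with columns sample_id, shannon, rarefaction_depth, n_iterations.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    c = table.counts
    if depth is None:
        depth = int(c.sum(axis=1).min())
    rng = np.random.default_rng(seed)
    totals = c.sum(axis=1)
    keep = totals.index[totals >= depth]
    if len(keep) == 0:
        raise ValidationError(f"no sample has >= {depth} reads")
    mat = c.loc[keep].to_numpy()
    acc = np.zeros(len(keep))
    for r in range(mat.shape[0]):
        draws = rng.multivariate_hypergeometric(mat[r], depth,
                                                size=n_iterations)
        p = draws / depth
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        acc[r] = h.mean()
    return pd.DataFrame({
        "sample_id": keep,
        "shannon": acc,
        "rarefaction_depth": depth,
        "n_iterations": n_iterations,
    })


def taxa_overlap(set_a: AsvCountTable, set_b: AsvCountTable) -> dict:
    """Percent taxa shared of the union, and of each table present in the other.

    A taxon counts as present if its total reads are > 0.
    """
    a = {t for t, tot in set_a.asv_totals().items() if tot > 0}
    b = {t for t, tot in set_b.asv_totals().items() if tot > 0}
    if not a and not b:
        raise ValidationError("both taxa sets are empty")
    union = a | b
    inter = a & b
    return {
        "pct_shared_of_union": 100.0 * len(inter) / len(union),
        "pct_a_in_b": 100.0 * len(inter) / len(a) if a else float("nan"),
        "pct_b_in_a": 100.0 * len(inter) / len(b) if b else float("nan"),
        "n_a": len(a), "n_b": len(b), "n_shared": len(inter),
    }


# ---------------------------------------------------------------------------
# PERMANOVA on location centroids
# ---------------------------------------------------------------------------

def location_centroids(clr: ClrMatrix, location_of: pd.Series) -> pd.DataFrame:
    """Per-location mean of clr rows (the units tested by the PERMANOVA)."""
    locs = location_of.reindex(clr.values.index)
    return clr.values.groupby(locs).mean()


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def permanova_centroids(
    distance_matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    terms: list[str] | None = None,
    interaction: bool = True,
    n_permutations: int = 999,
    seed=0,
    permutations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA with continuous covariates.

    McArdle-Anderson decomposition: Gower-centred squared distances are
    partitioned by the hat matrices of the sequentially growing design
    temperature, precipitation, temperature x precipitation.  Permutation
    p-values shuffle the unit labels, with the observed statistic included
    in the null set.
    """
    if terms is None:
        terms = ["temperature", "precipitation"]
    cov = covariates.loc[distance_matrix.index]
    n = len(cov)
    cols = [np.ones(n)]
    names = []
    z = {}
    for t in terms:
        v = cov[t].to_numpy(dtype=float)
        z[t] = (v - v.mean()) / v.std()
        cols.append(z[t])
        names.append(t)
    if interaction:
        cols.append(z[terms[0]] * z[terms[1]])
        names.append(f"{terms[0]}:{terms[1]}")
    X = np.column_stack(cols)
    k = X.shape[1]
    if k > n - 1:
        raise ValidationError("more model terms than centroids - 1")
    d2 = distance_matrix.to_numpy(dtype=float) ** 2
    G = _gower_center(d2)
    ss_total = float(np.trace(G))

    def seq_ss(order: np.ndarray) -> tuple[np.ndarray, float]:
        Gp = G[np.ix_(order, order)]
        ss = np.empty(len(names))
        prev = float(np.ones(n) @ Gp @ np.ones(n)) / n  # intercept-only fit SS
        for j in range(len(names)):
            Q, _ = np.linalg.qr(X[:, : j + 2])
            cur = float(np.einsum("ij,jk,ki->", Q.T, Gp, Q))
            ss[j] = cur - prev
            prev = cur
        ss_res = max(ss_total - prev, 0.0)   # guard numerical cancellation
        return ss, ss_res

    ident = np.arange(n)
    ss_obs, ss_res = seq_ss(ident)
    df_res = n - k
    with np.errstate(divide="ignore"):
        f_obs = (ss_obs / 1.0) / (ss_res / df_res)

    if permutations is not None:
        # explicit permutation set (e.g. exhaustive); identity supplies the
        # observed statistic, so exclude it from the extra count
        perms = [np.asarray(p) for p in permutations
                 if not np.array_equal(p, ident)]
        exceed = np.ones(len(names))
        for perm in perms:
            ss_p, ss_res_p = seq_ss(perm)
            exceed += (ss_p / (ss_res_p / df_res)) >= f_obs
        pvals = exceed / (len(perms) + 1)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.ones(len(names))  # observed included in the null set
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ss_p, ss_res_p = seq_ss(perm)
            f_p = ss_p / (ss_res_p / df_res)
            exceed += f_p >= f_obs
        pvals = exceed / (n_permutations + 1)
    return pd.DataFrame({
        "term": names,
        "ss": ss_obs,
        "pseudo_F": f_obs,
        "p_value": pvals,
        "df": 1,
        "df_residual": df_res,
    })
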