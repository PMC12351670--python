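"""Signed co-occurrence networks: neighbourhood selection, StARS, spin-glass.

The conditional-dependence graph over clr abundances is estimated by
neighbourhood selection: each ASV's clr profile is lasso-regressed on all
others along a common log-spaced penalty path, and an edge joins i and j
when either directed coefficient is non-zero (OR symmetrisation).  The
penalty is chosen by StARS: edge selection frequencies over many
without-replacement subsamples give a per-penalty instability
mean(2 theta (1 - theta)); after monotonisation from the sparse end the
densest graph whose instability stays below the target (default 0.05) is
selected — favouring the least regularisation that is still stable.
Edge signs come from the mean of the two directed lasso coefficients at the
selected penalty; pairs whose coefficients are non-zero with opposite signs
are dropped with a warning.

Clustering minimises the signed spin-glass Hamiltonian

    H = - sum_{i<j} [w+_ij - g+ p+_ij] d(c_i,c_j)
        + sum_{i<j} [w-_ij - g- p-_ij] d(c_i,c_j)

with configuration-model null expectations p per sign layer: positive edges
attract, negative edges repel co-assignment, and no cluster count is fixed.
Optimisation is simulated annealing (geometric cooling, several restarts)
in a numba kernel with an explicit xorshift RNG for bit-for-bit
reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .community import ClrMatrix
from .io_tables import AsvCountTable, ValidationError
from .lmm import fit_lmm
from .sem import apply_transform, choose_transform

logger = logging.getLogger(__name__)


@dataclass
class SignedNetwork:
    node_ids: list[str]
    edges: pd.DataFrame           # node_a, node_b, sign {+1,-1}, weight
    lambda_selected: float = float("nan")
    instability_at_selection: float = float("nan")
    lambda_path: np.ndarray | None = None
    instability_path: np.ndarray | None = None
    threshold_met: bool = True

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense signed weight matrix (weights carry their sign)."""
        idx = {v: i for i, v in enumerate(self.node_ids)}
        A = np.zeros((len(self.node_ids),) * 2)
        for _, r in self.edges.iterrows():
            i, j = idx[r["node_a"]], idx[r["node_b"]]
            A[i, j] = A[j, i] = r["sign"] * abs(r["weight"])
        return A


@dataclass
class ClusterPartition:
    assignments: pd.Series        # node_id -> cluster_id (c1, c2, ... by size)
    hamiltonian: float
    summary: pd.DataFrame | None = None

    def members(self, cluster_id: str) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.assignments.unique(), key=lambda c: int(c[1:]))


# ---------------------------------------------------------------------------
# neighbourhood selection
# ---------------------------------------------------------------------------

def _standardized(clr: ClrMatrix) -> np.ndarray:
    X = clr.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValidationError(
            f"constant clr column for ASV {clr.values.columns[zero[0]]!r}")
    return (X - X.mean(axis=0)) / sd


def lambda_grid(X: np.ndarray, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    """Log-spaced penalties from the smallest lambda giving an empty graph."""
    n = X.shape[0]
    C = np.abs(X.T @ X) / n
    np.fill_diagonal(C, 0.0)
    lam_max = float(C.max())
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


@njit(cache=False)
def _lasso_path_gram(G, lambdas, tol, max_iter):
    """Neighbourhood lasso paths for every node from one Gram matrix.

    Coordinate descent on the covariance updates: for node j the problem is
    min_w (1/2n)||x_j - X_{-j} w||^2 + lambda ||w||_1 with unit-diagonal
    G = X'X/n.  Warm starts along the decreasing penalty path; soft
    thresholding yields exact zeros.  Returns coefs[l, j, i] = coefficient
    of node i in node j's regression at lambdas[l].
    """
    p = G.shape[0]
    nl = len(lambdas)
    coefs = np.zeros((nl, p, p))
    for j in range(p):
        w = np.zeros(p)
        r = G[:, j].copy()          # residual correlations c - G w
        for l in range(nl):
            lam = lambdas[l]
            for _ in range(max_iter):
                max_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    gkk = G[k, k]
                    rho = r[k] + gkk * w[k]
                    if rho > lam:
                        new = (rho - lam) / gkk
                    elif rho < -lam:
                        new = (rho + lam) / gkk
                    else:
                        new = 0.0
                    d = new - w[k]
                    if d != 0.0:
                        w[k] = new
                        for m in range(p):
                            r[m] -= G[m, k] * d
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta < tol:
                    break
            coefs[l, j] = w
    return coefs


def _mb_edges(X: np.ndarray, lambdas: np.ndarray):
    """Per-lambda OR-symmetrised edge indicators and directed coefficients.

    Returns (edges, coefs): edges is (n_lambda, p, p) boolean (symmetric),
    coefs is (n_lambda, p, p) with coefs[l, j, i] = coefficient of node i in
    node j's lasso at lambda l.
    """
    n, p = X.shape
    G = X.T @ X / n
    coefs = _lasso_path_gram(G, np.ascontiguousarray(lambdas, dtype=float),
                             1e-6, 1000)
    nz = coefs != 0
    edges = nz | nz.transpose(0, 2, 1)
    return edges, coefs


def mb_lambda_path(
    clr: ClrMatrix,
    n_lambda: int = 45,
    lambda_min_ratio: float = 0.01,
):
    """Edge sets along the penalty path on the full data."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    X = _standardized(clr)
    if X.shape[0] < 10:
        raise ValidationError("need at least 10 samples for network estimation")
    lambdas = lambda_grid(X, n_lambda, lambda_min_ratio)
    edges, coefs = _mb_edges(X, lambdas)
    return lambdas, edges, coefs


def stars_select(
    clr: ClrMatrix,
    n_lambda: int = 45,
    subsample_ratio: float = 0.8,
    n_replications: int = 300,
    instability_threshold: float = 0.05,
    seed=0,
    lambda_min_ratio: float = 0.01,
) -> SignedNetwork:
    """StARS-selected signed network from clr abundances."""
    if n_replications < 2:
        raise ValueError("n_replications must be >= 2")
    if not 0 < subsample_ratio < 1:
        raise ValueError("subsample_ratio must be in (0, 1)")
    X = _standardized(clr)
    n, p = X.shape
    lambdas = lambda_grid(X, n_lambda, lambda_min_ratio)
    m = int(np.floor(subsample_ratio * n))
    rng = np.random.default_rng(seed)
    freq = np.zeros((n_lambda, p, p))
    for _ in range(n_replications):
        idx = rng.choice(n, size=m, replace=False)
        Xs = X[idx]
        Xs = (Xs - Xs.mean(axis=0)) / np.where(Xs.std(axis=0) > 0,
                                               Xs.std(axis=0), 1.0)
        edges, _ = _mb_edges(Xs, lambdas)
        freq += edges
    theta = freq / n_replications
    iu = np.triu_indices(p, k=1)
    instab = np.array([(2 * theta[l][iu] * (1 - theta[l][iu])).mean()
                       for l in range(n_lambda)])
    mono = np.maximum.accumulate(instab)  # non-decreasing toward dense
    ok = np.flatnonzero(mono <= instability_threshold)
    if len(ok):
        sel = int(ok.max())   # densest graph still under the threshold
        met = True
    else:
        sel = int(np.argmin(mono))
        met = False
        logger.warning("no lambda satisfies instability threshold %.3g; "
                       "returning the most stable lambda", instability_threshold)
    # final edge set and signs at the selected lambda on the full data
    edges_full, coefs_full = _mb_edges(X, lambdas[sel:sel + 1])
    E, B = edges_full[0], coefs_full[0]
    rows, dropped = [], 0
    names = list(clr.values.columns)
    for i, j in zip(*np.triu_indices(p, k=1)):
        if not E[i, j]:
            continue
        bij, bji = B[i, j], B[j, i]
        if bij * bji < 0:
            dropped += 1
            continue
        w = 0.5 * (bij + bji)
        rows.append({"node_a": names[i], "node_b": names[j],
                     "sign": int(np.sign(w)) if w != 0 else 1,
                     "weight": float(w)})
    if dropped:
        logger.warning("dropped %d sign-conflicting edge pair(s)", dropped)
    return SignedNetwork(
        node_ids=names,
        edges=pd.DataFrame(rows, columns=["node_a", "node_b", "sign", "weight"]),
        lambda_selected=float(lambdas[sel]),
        instability_at_selection=float(mono[sel]),
        lambda_path=lambdas,
        instability_path=mono,
        threshold_met=met,
    )


# ---------------------------------------------------------------------------
# signed spin-glass clustering
# ---------------------------------------------------------------------------

def signed_hamiltonian(net: SignedNetwork, labels: np.ndarray,
                       gamma_pos: float = 1.0, gamma_neg: float = 1.0) -> float:
    """Exact Hamiltonian of a labelling (used by the annealer and oracles)."""
    A = net.adjacency()
    wp = np.clip(A, 0, None)
    wn = np.clip(-A, 0, None)
    h = 0.0
    for W, gamma, sign in ((wp, gamma_pos, -1.0), (wn, gamma_neg, +1.0)):
        two_m = W.sum()
        if two_m == 0:
            continue
        s = W.sum(axis=1)
        within_w = 0.0
        null = 0.0
        for c in np.unique(labels):
            mask = labels == c
            within_w += W[np.ix_(mask, mask)].sum() / 2.0
            sc = s[mask]
            null += (sc.sum() ** 2 - (sc ** 2).sum()) / 2.0
        h += sign * (within_w - gamma * null / two_m)
    return float(h)


@njit(cache=False)
def _xorshift(state):
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=False)
def _anneal(indptr, indices, wpos, wneg, spos, sneg, two_mp, two_mn,
            gamma_p, gamma_n, n_states, t_start, t_end, cooling,
            sweeps_per_t, seed):
    n = len(indptr) - 1
    state = np.uint64(seed * np.uint64(2685821657736338717) + np.uint64(1))
    spins = np.empty(n, dtype=np.int64)
    for i in range(n):
        state = _xorshift(state)
        spins[i] = int(state % np.uint64(n_states))
    Sp = np.zeros(n_states)
    Sn = np.zeros(n_states)
    for i in range(n):
        Sp[spins[i]] += spos[i]
        Sn[spins[i]] += sneg[i]
    inv_mp = 1.0 / two_mp if two_mp > 0 else 0.0
    inv_mn = 1.0 / two_mn if two_mn > 0 else 0.0
    t = t_start
    while t > t_end:
        for _ in range(sweeps_per_t * n):
            state = _xorshift(state)
            i = int(state % np.uint64(n))
            state = _xorshift(state)
            b = int(state % np.uint64(n_states))
            a = spins[i]
            if b == a:
                continue
            kpa = 0.0; kpb = 0.0; kna = 0.0; knb = 0.0
            for e in range(indptr[i], indptr[i + 1]):
                j = indices[e]
                cj = spins[j]
                if cj == a:
                    kpa += wpos[e]; kna += wneg[e]
                elif cj == b:
                    kpb += wpos[e]; knb += wneg[e]
            fa = (-kpa + gamma_p * spos[i] * (Sp[a] - spos[i]) * inv_mp
                  + kna - gamma_n * sneg[i] * (Sn[a] - sneg[i]) * inv_mn)
            fb = (-kpb + gamma_p * spos[i] * Sp[b] * inv_mp
                  + knb - gamma_n * sneg[i] * Sn[b] * inv_mn)
            dh = fb - fa
            accept = dh <= 0.0
            if not accept:
                state = _xorshift(state)
                u = (state >> np.uint64(11)) / 9007199254740992.0
                accept = u < np.exp(-dh / t)
            if accept:
                spins[i] = b
                Sp[a] -= spos[i]; Sp[b] += spos[i]
                Sn[a] -= sneg[i]; Sn[b] += sneg[i]
        t *= cooling
    return spins


def spinglass_cluster(
    net: SignedNetwork,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
    n_runs: int = 10,
    seed=0,
    t_start: float = 1.0,
    t_end: float = 0.01,
    cooling: float = 0.99,
    sweeps_per_t: int = 25,
    max_states: int | None = None,
) -> ClusterPartition:
    """Best-of-``n_runs`` annealed signed spin-glass partition."""
    if net.n_edges == 0 and len(net.node_ids) == 0:
        raise ValidationError("empty network")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = len(net.node_ids)
    idx = {v: i for i, v in enumerate(net.node_ids)}
    # CSR with both edge directions
    nb = [[] for _ in range(n)]
    for _, r in net.edges.iterrows():
        i, j = idx[r["node_a"]], idx[r["node_b"]]
        w = abs(float(r["weight"]))
        s = int(r["sign"])
        nb[i].append((j, w if s > 0 else 0.0, w if s < 0 else 0.0))
        nb[j].append((i, w if s > 0 else 0.0, w if s < 0 else 0.0))
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + len(nb[i])
    indices = np.zeros(indptr[-1], dtype=np.int64)
    wpos = np.zeros(indptr[-1])
    wneg = np.zeros(indptr[-1])
    for i in range(n):
        for k, (j, wp, wn) in enumerate(nb[i]):
            indices[indptr[i] + k] = j
            wpos[indptr[i] + k] = wp
            wneg[indptr[i] + k] = wn
    spos = np.zeros(n)
    sneg = np.zeros(n)
    for i in range(n):
        spos[i] = wpos[indptr[i]:indptr[i + 1]].sum()
        sneg[i] = wneg[indptr[i]:indptr[i + 1]].sum()
    two_mp, two_mn = spos.sum(), sneg.sum()
    n_states = min(n, max_states) if max_states else n

    # geometric cooling; sweeps folded into the kernel loop
    n_temps = int(np.ceil(np.log(t_end / t_start) / np.log(cooling)))
    rng = np.random.default_rng(seed)
    best_labels, best_h = None, np.inf
    for run in range(n_runs):
        sub_seed = int(rng.integers(1, 2 ** 62))
        spins = _run_schedule(indptr, indices, wpos, wneg, spos, sneg,
                              two_mp, two_mn, gamma_pos, gamma_neg, n_states,
                              t_start, t_end, cooling, sweeps_per_t, sub_seed)
        h = signed_hamiltonian(net, spins, gamma_pos, gamma_neg)
        if h < best_h - 1e-12:
            best_h, best_labels = h, spins.copy()
    labels = _canonical_labels(best_labels)
    assignments = pd.Series([f"c{k}" for k in labels], index=net.node_ids,
                            name="cluster_id")
    return ClusterPartition(assignments=assignments, hamiltonian=best_h)


def _run_schedule(indptr, indices, wpos, wneg, spos, sneg, two_mp, two_mn,
                  gamma_p, gamma_n, n_states, t_start, t_end, cooling,
                  sweeps_per_t, seed):
    # kernel iterates one long geometric schedule internally
    spins = _anneal(indptr, indices, wpos, wneg, spos, sneg, two_mp, two_mn,
                    gamma_p, gamma_n, n_states, t_start, t_end * 1.0,
                    cooling, sweeps_per_t, np.uint64(seed))
    return spins


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending member count (ties by first node)."""
    uniq, counts = np.unique(labels, return_counts=True)
    first = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first[u]))
    remap = {u: k + 1 for k, u in enumerate(order)}
    return np.array([remap[u] for u in labels])


def summarize_partition(
    partition: ClusterPartition,
    table: AsvCountTable,
) -> pd.DataFrame:
    """Per-cluster relative size, marker fractions, unique-ASV counts."""
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    rows = []
    for cid in partition.cluster_ids:
        members = partition.members(cid)
        share = float(rel[members].sum(axis=1).mean())
        n16 = nits = 0
        if table.marker is not None:
            mk = table.marker.loc[members]
            n16 = int((mk == "16S").sum())
            nits = int((mk == "ITS").sum())
        if table.marker is not None:
            m16 = [a for a in members if table.marker.loc[a] == "16S"]
            p_frac = (float(rel[m16].sum(axis=1).mean()) / share
                      if share > 0 else 0.0)
        else:
            p_frac = float("nan")
        rows.append({
            "cluster_id": cid,
            "n_asvs": len(members),
            "relative_size": share,
            "prokaryote_fraction": p_frac,
            "fungal_fraction": 1.0 - p_frac if p_frac == p_frac else float("nan"),
            "n_unique_prokaryote_asvs": n16,
            "n_unique_fungal_asvs": nits,
        })
    return pd.DataFrame(rows).set_index("cluster_id")


# ---------------------------------------------------------------------------
# cluster statistics
# ---------------------------------------------------------------------------

@njit(cache=False)
def _rewire_within_fracs(a, b, labels, n_nodes, n_random, swaps, seed):
    """Within-cluster edge shares for degree-preserving rewired null networks."""
    n_edges = len(a)
    fracs = np.empty(n_random)
    state = np.uint64(seed * np.uint64(6364136223846793005) + np.uint64(7))
    present = np.zeros(n_nodes * n_nodes, dtype=np.bool_)
    for r in range(n_random):
        ra = a.copy()
        rb = b.copy()
        present[:] = False
        for e in range(n_edges):
            lo, hi = (ra[e], rb[e]) if ra[e] < rb[e] else (rb[e], ra[e])
            present[lo * n_nodes + hi] = True
        done = 0
        attempts = 0
        while done < swaps and attempts < 20 * swaps:
            attempts += 1
            state = _xorshift(state)
            i = int(state % np.uint64(n_edges))
            state = _xorshift(state)
            j = int(state % np.uint64(n_edges))
            if i == j:
                continue
            x1, y1, x2, y2 = ra[i], rb[i], ra[j], rb[j]
            if (x1 == x2 or x1 == y2 or y1 == x2 or y1 == y2):
                continue
            lo1, hi1 = (x1, y2) if x1 < y2 else (y2, x1)
            lo2, hi2 = (x2, y1) if x2 < y1 else (y1, x2)
            k1 = lo1 * n_nodes + hi1
            k2 = lo2 * n_nodes + hi2
            if present[k1] or present[k2]:
                continue
            olo1, ohi1 = (x1, y1) if x1 < y1 else (y1, x1)
            olo2, ohi2 = (x2, y2) if x2 < y2 else (y2, x2)
            present[olo1 * n_nodes + ohi1] = False
            present[olo2 * n_nodes + ohi2] = False
            present[k1] = True
            present[k2] = True
            rb[i] = y2
            rb[j] = y1
            done += 1
        same = 0
        for e in range(n_edges):
            if labels[ra[e]] == labels[rb[e]]:
                same += 1
        fracs[r] = same / n_edges
    return fracs


def cluster_density_test(
    net: SignedNetwork,
    partition: ClusterPartition,
    n_random: int = 999,
    seed=0,
    swaps_per_edge: int = 10,
) -> dict:
    """Within-cluster edge share against degree-preserving rewired networks.

    Null networks shuffle edge endpoints with double-edge swaps (signs travel
    with their edges, so the signed degree sequence is preserved); the
    empirical p includes the observed network in the null set.
    """
    if n_random < 99:
        raise ValueError("n_random must be >= 99")
    e = net.edges
    if len(e) < 2:
        raise ValidationError("network too small to rewire")
    idx = {v: i for i, v in enumerate(net.node_ids)}
    a = e["node_a"].map(idx).to_numpy(dtype=np.int64)
    b = e["node_b"].map(idx).to_numpy(dtype=np.int64)
    lab_codes = pd.Categorical(
        partition.assignments.reindex(net.node_ids)).codes.astype(np.int64)
    obs = float((lab_codes[a] == lab_codes[b]).mean())
    null_stats = _rewire_within_fracs(
        a, b, lab_codes, len(net.node_ids), n_random,
        swaps_per_edge * len(e), np.uint64(int(seed) + 1))
    count = 1 + int((null_stats >= obs).sum())  # observed included
    sd = null_stats.std(ddof=1)
    z = (obs - null_stats.mean()) / sd if sd > 0 else np.inf
    return {"statistic": obs, "z": float(z),
            "p_value": count / (n_random + 1), "n_random": n_random}


def cluster_abundances(
    table: AsvCountTable,
    partition: ClusterPartition,
) -> pd.DataFrame:
    """Per-sample summed relative reads of each cluster's ASVs."""
    missing = set(partition.assignments.index) - set(table.asv_ids)
    if missing:
        raise ValidationError(
            f"partition nodes missing from the table: {sorted(missing)[:3]}")
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    out = {}
    for cid in partition.cluster_ids:
        out[cid] = rel[partition.members(cid)].sum(axis=1)
    return pd.DataFrame(out, index=table.counts.index)


def intercluster_correlations(
    cluster_ab: pd.DataFrame,
    location_ids: pd.Series,
    auto_transform: bool = True,
) -> pd.DataFrame:
    """Random-intercept regressions between all unordered cluster pairs.

    Each pair regresses the first cluster (canonical order) on the second;
    both are transformed (normality ladder) and standardized.  Bonferroni
    multiplies raw p by the number of successfully fitted pairs, capped at 1.
    """
    groups = location_ids.reindex(cluster_ab.index).to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValidationError("need >= 2 locations")
    cols = list(cluster_ab.columns)
    n = len(cluster_ab)
    ones = np.ones(n)

    def prep(name: str) -> np.ndarray:
        y = cluster_ab[name].to_numpy(dtype=float)
        if auto_transform:
            tname = choose_transform(y, ones[:, None], groups)
            y = apply_transform(y, tname)
        sd = y.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"cluster {name} has zero variance")
        return (y - y.mean()) / sd

    prepped = {c: prep(c) for c in cols}
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            y, x = prepped[cols[i]], prepped[cols[j]]
            try:
                fit = fit_lmm(y, np.column_stack([ones, x]), groups)
            except np.linalg.LinAlgError:
                logger.warning("singular fit for pair (%s, %s); excluded",
                               cols[i], cols[j])
                rows.append({"cluster_a": cols[i], "cluster_b": cols[j],
                             "slope": np.nan, "p_value": np.nan,
                             "excluded": True})
                continue
            rows.append({"cluster_a": cols[i], "cluster_b": cols[j],
                         "slope": float(fit.params[1]),
                         "p_value": float(fit.pvalues[1]), "excluded": False})
    df = pd.DataFrame(rows)
    m = int((~df["excluded"]).sum())
    df["p_adjusted"] = np.where(df["excluded"], np.nan,
                                np.minimum(df["p_value"] * m, 1.0))
    return df


def cluster_climate_model(
    cluster_abundance: pd.Series,
    temperature: pd.Series,
    precipitation: pd.Series,
    location_ids: pd.Series,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Climate effects on a cluster via a logit-scale random-intercept model.

    Approximates a beta GLMM: the (0,1) abundance is clamped to
    [eps, 1-eps], logit-transformed and regressed on standardized
    temperature, precipitation and their product with a location intercept.
    """
    ab = cluster_abundance.to_numpy(dtype=float)
    if np.allclose(ab, ab[0]):
        raise ValidationError("degenerate abundance: all values equal")
    y = np.clip(ab, eps, 1 - eps)
    y = np.log(y / (1 - y))
    idx = cluster_abundance.index
    t = temperature.reindex(idx).to_numpy(dtype=float)
    p = precipitation.reindex(idx).to_numpy(dtype=float)
    tz = (t - t.mean()) / t.std()
    pz = (p - p.mean()) / p.std()
    X = np.column_stack([np.ones(len(y)), tz, pz, tz * pz])
    fit = fit_lmm(y, X, location_ids.reindex(idx).to_numpy(),
                  exog_names=["Intercept", "temperature", "precipitation",
                              "temperature:precipitation"])
    return pd.DataFrame({
        "term": fit.exog_names,
        "estimate": fit.params,
        "se": fit.bse,
        "p_value": fit.pvalues,
    })
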