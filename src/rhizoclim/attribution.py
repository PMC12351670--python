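"""Composite pathway effect sizes and explained-variation attribution.

Given a fitted path model with a microbial response appended, every simple
directed path from temperature or precipitation to the response is
enumerated over the retained (significant) edges.  A path's composite
effect is the product of the standardized coefficients along it.  Paths are
classified by the ancestry of their first mediator: if both climate drivers
are ancestors of that mediator the path is *joint*; otherwise it carries
its source's label.  The response's marginal R2 budget is split across the
categories in proportion to summed |composite effect|, the
conditional-minus-marginal gap is the within-location (random) share, and
1 - conditional R2 is unexplained; the shares sum to one by construction.
Aggregation across a compartment's clusters weights responses by their
relative cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_tables import ValidationError
from .sem import PathModel

CLIMATE_SOURCES = ("temperature", "precipitation")
CATEGORIES = ("temperature_only", "precipitation_only", "joint")


@dataclass
class AttributionResult:
    response_id: str
    paths: pd.DataFrame                 # path, category, composite_effect, mediator
    category_shares: dict[str, float]   # explained-variation share per category
    random_share: float
    unexplained_share: float
    marginal_r2: float
    conditional_r2: float
    cluster_relative_size: float = 1.0
    signed_category_sums: dict[str, float] = field(default_factory=dict)

    def shares(self) -> dict[str, float]:
        out = dict(self.category_shares)
        out["random"] = self.random_share
        out["unexplained"] = self.unexplained_share
        return out


def _significant_dag(model: PathModel, alpha: float = 0.05) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(model.nodes())
    if model.coefficients is None:
        raise ValidationError("model has no fitted coefficients")
    for _, row in model.coefficients.iterrows():
        if row["p_value"] < alpha:
            g.add_edge(row["parent"], row["child"], coef=row["estimate"])
    return g


def enumerate_paths(model: PathModel, target: str,
                    sources=CLIMATE_SOURCES, alpha: float = 0.05) -> list[list[str]]:
    """All simple directed source -> target paths over significant edges."""
    g = _significant_dag(model, alpha)
    if target not in g:
        raise ValidationError(f"target {target!r} not in model")
    paths = []
    for s in sources:
        if s not in g:
            continue
        paths.extend(nx.all_simple_paths(g, s, target))
    return sorted(paths)


def composite_effect(path: list[str], model: PathModel) -> float:
    """Product of standardized coefficients along a path."""
    coefs = model.coefficients.set_index(["parent", "child"])["estimate"]
    eff = 1.0
    for a, b in zip(path[:-1], path[1:]):
        if (a, b) not in coefs.index:
            raise ValidationError(f"edge {a}->{b} not retained in the model")
        eff *= float(coefs.loc[(a, b)])
    return eff


def classify_pathway(path: list[str], model: PathModel,
                     alpha: float = 0.05) -> str:
    """temperature_only / precipitation_only / joint for one path.

    A direct (length-1) path carries its source's label.  Otherwise the path
    is joint when its first mediator has both climate drivers among its
    ancestors in the retained model.
    """
    src = path[0]
    if src not in CLIMATE_SOURCES:
        raise ValidationError(f"path must start at a climate driver, got {src!r}")
    own = "temperature_only" if src == "temperature" else "precipitation_only"
    if len(path) == 2:
        return own
    g = _significant_dag(model, alpha)
    mediator = path[1]
    anc = nx.ancestors(g, mediator)
    if set(CLIMATE_SOURCES) <= anc:
        return "joint"
    return own


def explained_fractions(
    response: str,
    model: PathModel,
    cluster_relative_size: float = 1.0,
    alpha: float = 0.05,
    on_empty: str = "error",
) -> AttributionResult:
    """Allocate the response's explained variation across climate categories.

    ``on_empty`` controls the case where the response has marginal R2 > 0 but
    no significant climate pathway (a retained edge with p >= alpha):
    ``"error"`` raises; ``"unexplained"`` assigns zero to every climate
    category and folds the unattributable fixed-effect variation into the
    unexplained share (so the shares still sum to one).
    """
    if response not in model.r2:
        raise ValidationError(f"no fitted R2 for response {response!r}")
    r2m, r2c = model.r2[response]
    paths = enumerate_paths(model, response, alpha=alpha)
    if not paths and r2m > 1e-9:
        if on_empty != "unexplained":
            raise ValidationError(
                f"{response!r} has marginal R2 {r2m:.3f} but no retained "
                "significant pathway")
        empty = pd.DataFrame(columns=["path", "category", "composite_effect",
                                      "abs_effect", "mediator"])
        return AttributionResult(
            response_id=response, paths=empty,
            category_shares={c: 0.0 for c in CATEGORIES},
            random_share=r2c - r2m,
            unexplained_share=1.0 - (r2c - r2m),
            marginal_r2=r2m, conditional_r2=r2c,
            cluster_relative_size=cluster_relative_size,
            signed_category_sums={c: 0.0 for c in CATEGORIES})
    rows = []
    for p in paths:
        eff = composite_effect(p, model)
        rows.append({
            "path": " -> ".join(p),
            "category": classify_pathway(p, model, alpha),
            "composite_effect": eff,
            "abs_effect": abs(eff),
            "mediator": p[-2] if len(p) > 2 else f"direct {p[0]}",
        })
    pdf = pd.DataFrame(rows, columns=["path", "category", "composite_effect",
                                      "abs_effect", "mediator"])
    total_abs = pdf["abs_effect"].sum() if len(pdf) else 0.0
    shares = {}
    signed = {}
    for cat in CATEGORIES:
        sub = pdf[pdf["category"] == cat]
        frac = sub["abs_effect"].sum() / total_abs if total_abs > 0 else 0.0
        shares[cat] = frac * r2m
        signed[cat] = float(sub["composite_effect"].sum())
    random_share = r2c - r2m
    unexplained = 1.0 - r2c
    return AttributionResult(
        response_id=response,
        paths=pdf,
        category_shares=shares,
        random_share=random_share,
        unexplained_share=unexplained,
        marginal_r2=r2m,
        conditional_r2=r2c,
        cluster_relative_size=cluster_relative_size,
        signed_category_sums=signed,
    )


def per_variable_contributions(result: AttributionResult) -> pd.Series:
    """Summed |composite effect| keyed by each path's final mediator."""
    if result.paths.empty:
        return pd.Series(dtype=float)
    return result.paths.groupby("mediator")["abs_effect"].sum()


def aggregate_attribution(results: list[AttributionResult]) -> dict[str, float]:
    """Cluster-size-weighted mean of the share vectors; sums to one."""
    if not results:
        raise ValidationError("no attribution results to aggregate")
    w = np.array([r.cluster_relative_size for r in results], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("non-positive cluster weights")
    w = w / w.sum()
    keys = [*CATEGORIES, "random", "unexplained"]
    agg = {k: 0.0 for k in keys}
    for wi, r in zip(w, results):
        sh = r.shares()
        for k in keys:
            agg[k] += wi * sh[k]
    return agg
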