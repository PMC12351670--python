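"""Piecewise structural equation modelling with d-separation tests.

A path model is a DAG of structural equations; each equation is fitted as a
separate random-intercept linear model (location as the grouping factor) on
standardized variables, so coefficients are standardized effect sizes.
Global fit is judged by the d-separation basis set: every non-adjacent
variable pair (not declared as a correlated error) yields an independence
claim, tested by regressing the later variable (topological order) on the
earlier one plus the union of both variables' parents.  Claim p-values
combine into Fisher's C = -2 sum ln p, chi-square with 2k df under the
model; models are accepted when p_C > 0.05.

Model reduction is backward elimination: repeatedly drop the retained edge
with the highest p-value if doing so lowers the small-sample-corrected AIC

    AICc = C + 2 K n / (n - K - 1)

with K counting every estimated parameter (slopes, intercepts and the two
variance components of each equation).  Microbial responses are appended
downstream of an accepted base model; because the model is fit piecewise,
appending never perturbs upstream estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ValidationError
from .lmm import fit_lmm

logger = logging.getLogger(__name__)

TRANSFORM_LADDER = ("identity", "log", "sqrt")
SHAPIRO_ALPHA = 0.05


# ---------------------------------------------------------------------------
# model skeleton
# ---------------------------------------------------------------------------

@dataclass
class PathModel:
    """DAG of structural equations, optionally with fitted statistics."""

    equations: dict[str, list[str]]          # child -> ordered parent list
    correlated: set[frozenset] = field(default_factory=set)
    transforms: dict[str, str] = field(default_factory=dict)
    # fitted state
    coefficients: pd.DataFrame | None = None  # (child, parent) rows
    r2: dict[str, tuple[float, float]] = field(default_factory=dict)
    fisher_c: float = float("nan")
    df_c: int = 0
    p_c: float = float("nan")
    aicc: float = float("nan")
    n_obs: int = 0
    n_params: int = 0
    accepted: bool = False
    warnings: list[str] = field(default_factory=list)

    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for child, parents in self.equations.items():
            for p in parents:
                seen.setdefault(p, None)
            seen.setdefault(child, None)
        return list(seen)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in self.equations.items() for p in ps]

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes())
        g.add_edges_from(self.edges())
        return g

    def copy(self) -> "PathModel":
        return replace(
            self,
            equations={c: list(ps) for c, ps in self.equations.items()},
            correlated=set(self.correlated),
            transforms=dict(self.transforms),
            coefficients=None if self.coefficients is None
            else self.coefficients.copy(),
            r2=dict(self.r2),
            warnings=list(self.warnings),
        )

    def validate(self, known_vars=None) -> None:
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValidationError(f"model contains a cycle: {cyc}")
        if known_vars is not None:
            unknown = set(self.nodes()) - set(known_vars)
            if unknown:
                raise ValidationError(f"unknown variables: {sorted(unknown)}")

    def parents(self, node: str) -> list[str]:
        return list(self.equations.get(node, []))


def parse_model(spec_text: str, known_vars=None) -> PathModel:
    """Parse a plain-text model: ``child ~ a + b`` per line, ``x ~~ y`` for
    correlated errors, ``#`` comments."""
    equations: dict[str, list[str]] = {}
    correlated: set[frozenset] = set()
    for raw in spec_text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            a, b = (t.strip() for t in line.split("~~", 1))
            if not a or not b or a == b:
                raise ValidationError(f"bad correlated-error line: {raw!r}")
            correlated.add(frozenset((a, b)))
            continue
        if "~" not in line:
            raise ValidationError(f"bad model line: {raw!r}")
        child, rhs = (t.strip() for t in line.split("~", 1))
        parents = [t.strip() for t in rhs.split("+") if t.strip()]
        if not child or not parents:
            raise ValidationError(f"bad model line: {raw!r}")
        if child in equations:
            raise ValidationError(f"duplicate equation for {child!r}")
        if len(set(parents)) != len(parents):
            raise ValidationError(f"duplicate parent in equation for {child!r}")
        equations[child] = parents
    model = PathModel(equations=equations, correlated=correlated)
    model.validate(known_vars)
    return model


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def fishers_c(claim_ps) -> tuple[float, int, float]:
    """C = -2 sum ln p over the basis set; chi-square with 2k df."""
    ps = np.asarray(list(claim_ps), dtype=float)
    if len(ps) == 0:
        return 0.0, 0, 1.0
    if (ps <= 0).any():
        raise ValidationError("claim p-value of 0: perfect dependence, "
                              "the model must be revised")
    if (ps > 1).any():
        raise ValueError("claim p-values must lie in (0, 1]")
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def aicc(c: float, n_params: int, n_obs: int) -> float:
    """Small-sample AIC on the Fisher's C scale."""
    denom = n_obs - n_params - 1
    if denom <= 0:
        raise ValidationError(
            f"AICc undefined: n_obs={n_obs} <= n_params+1={n_params + 1}")
    return float(c + 2.0 * n_params * n_obs / denom)


def basis_set(model: PathModel) -> list[dict]:
    """Shipley-style independence claims for the model's DAG.

    One claim per non-adjacent pair not declared as a correlated error,
    conditioning on the union of both variables' parents; the variable later
    in (lexicographic) topological order is the regression response.
    """
    g = model.dag()
    order = list(nx.lexicographical_topological_sort(g))
    pos = {v: i for i, v in enumerate(order)}
    adjacent = {frozenset(e) for e in g.edges()}
    claims = []
    for i, x in enumerate(order):
        for y in order[i + 1:]:
            pair = frozenset((x, y))
            if pair in adjacent or pair in model.correlated:
                continue
            cond = sorted((set(g.predecessors(x)) | set(g.predecessors(y)))
                          - {x, y})
            claims.append({"x": x, "y": y, "conditioning": cond,
                           "response": y if pos[y] > pos[x] else x})
    return claims


def choose_transform(y_raw: np.ndarray, X: np.ndarray, groups) -> str:
    """First transform on the ladder whose LMM residuals pass Shapiro-Wilk."""
    for name in TRANSFORM_LADDER:
        y = apply_transform(y_raw, name)
        if y is None:
            continue
        ys = _standardize(y)
        fit = fit_lmm(ys, X, groups)
        resid = ys - fit.fitted_fixed
        if stats.shapiro(resid).pvalue > SHAPIRO_ALPHA:
            return name
    return "identity"


def apply_transform(y: np.ndarray, name: str) -> np.ndarray | None:
    if name == "identity":
        return np.asarray(y, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        return None
    positive = y[y > 0]
    if len(positive) == 0:
        return None
    if name == "log":
        eps = 0.5 * positive.min()
        return np.log(y + eps)
    if name == "sqrt":
        return np.sqrt(y)
    raise ValueError(f"unknown transform {name!r}")


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValidationError("zero-variance variable")
    return (v - v.mean()) / sd


# ---------------------------------------------------------------------------
# fitting engine
# ---------------------------------------------------------------------------

class SemEngine:
    """Fits structural equations and claim regressions over one dataset.

    Caches every regression by (response, predictors, transform) so that
    backward elimination — which re-evaluates largely overlapping claim sets
    — costs only the regressions that actually change.
    """

    def __init__(self, data: pd.DataFrame, group_col: str = "location_id"):
        if group_col not in data.columns:
            raise ValidationError(f"grouping column {group_col!r} missing")
        self.raw = data.reset_index(drop=True)
        self.groups = self.raw[group_col].to_numpy()
        self._std_cache: dict[tuple[str, str], np.ndarray] = {}
        self._fit_cache: dict = {}
        self._between_cache: dict[str, bool] = {}

    def column(self, name: str, transform: str = "identity") -> np.ndarray:
        key = (name, transform)
        if key not in self._std_cache:
            if name not in self.raw.columns:
                raise ValidationError(f"variable {name!r} not in data")
            y = apply_transform(self.raw[name].to_numpy(dtype=float), transform)
            if y is None:
                raise ValidationError(
                    f"transform {transform!r} inadmissible for {name!r}")
            self._std_cache[key] = _standardize(y)
        return self._std_cache[key]

    def regress(self, response: str, predictors: tuple[str, ...],
                transforms: dict[str, str]):
        r_tr = transforms.get(response, "identity")
        key = (response, r_tr, tuple(sorted(predictors)),
               tuple(sorted((p, transforms.get(p, "identity"))
                            for p in predictors)))
        if key in self._fit_cache:
            return self._fit_cache[key]
        y = self.column(response, r_tr)
        cols = [np.ones(len(y))]
        for p in predictors:
            cols.append(self.column(p, transforms.get(p, "identity")))
        fit = fit_lmm(y, np.column_stack(cols), self.groups,
                      exog_names=["Intercept", *predictors])
        self._fit_cache[key] = fit
        return fit

    # -- public operations ------------------------------------------------

    def fit_equation(self, child: str, parents, transforms=None) -> dict:
        """One structural equation: standardized coefficients, p, R2 pair."""
        transforms = transforms or {}
        fit = self.regress(child, tuple(parents), transforms)
        r2m, r2c = fit.marginal_conditional_r2()
        return {
            "child": child,
            "parents": list(parents),
            "estimates": dict(zip(parents, fit.params[1:])),
            "se": dict(zip(parents, fit.bse[1:])),
            "pvalues": dict(zip(parents, fit.pvalues[1:])),
            "marginal_r2": r2m,
            "conditional_r2": r2c,
            "singular_random_effect": fit.singular_random_effect,
            "n_obs": fit.n_obs,
        }

    def _between_location(self, name: str) -> bool:
        if name not in self._between_cache:
            vals = self.raw[name]
            ptp = vals.groupby(self.groups).agg(lambda s: s.max() - s.min())
            scale = max(1.0, float(vals.abs().max()))
            self._between_cache[name] = bool((ptp <= 1e-9 * scale).all())
        return self._between_cache[name]

    def claim_pvalue(self, claim: dict, transforms=None) -> float:
        """Independence-claim p-value.

        The regression response is the claim's later-topological-order
        variable, unless that variable is constant within every location
        while the other is not: a location random intercept would absorb a
        design-constant response completely, so the direction is swapped to
        keep the test informative (conditional independence is symmetric).
        """
        transforms = transforms or {}
        response = claim["response"]
        other = claim["y"] if response == claim["x"] else claim["x"]
        if self._between_location(response) and not self._between_location(other):
            response, other = other, response
        predictors = (other, *[c for c in claim["conditioning"]
                               if c not in (other, response)])
        fit = self.regress(response, predictors, transforms)
        return float(fit.pvalues[1])

    def evaluate(self, model: PathModel) -> PathModel:
        """Fit every equation and claim; fill in C, df, p_C, AICc."""
        model = model.copy()
        model.r2 = {}
        model.warnings = []
        rows = []
        n_params = 0
        n_obs = len(self.raw)
        for child, parents in model.equations.items():
            if not parents:
                # endogenous node whose edges were all eliminated: the
                # intercept-only equation still carries its parameters, so
                # AICc comparisons during elimination stay like-for-like
                n_params += 3
                continue
            eq = self.fit_equation(child, parents, model.transforms)
            n_params += 1 + len(parents) + 2   # intercept + slopes + 2 var comps
            model.r2[child] = (eq["marginal_r2"], eq["conditional_r2"])
            if eq["singular_random_effect"]:
                model.warnings.append(f"singular random effect for {child}")
            for p in parents:
                rows.append({"child": child, "parent": p,
                             "estimate": eq["estimates"][p],
                             "se": eq["se"][p], "p_value": eq["pvalues"][p]})
        claims = basis_set(model)
        ps = [self.claim_pvalue(cl, model.transforms) for cl in claims]
        c, df, p_c = fishers_c(ps)
        model.coefficients = pd.DataFrame(
            rows, columns=["child", "parent", "estimate", "se", "p_value"])
        model.fisher_c, model.df_c, model.p_c = c, df, p_c
        model.n_obs, model.n_params = n_obs, n_params
        model.aicc = aicc(c, n_params, n_obs)
        model.accepted = p_c > 0.05
        return model

    # -- model reduction ----------------------------------------------------

    def backward_eliminate(self, model: PathModel,
                           restrict_children=None) -> PathModel:
        """Drop edges (highest p first) while removal lowers AICc.

        ``restrict_children`` limits candidate edges to equations of the
        given responses (used when appending a downstream variable).  During
        the loop an endogenous node that loses its last parent keeps an
        intercept-only equation, so every removal changes K by exactly one
        and AICc values stay comparable; nodes left with neither parents nor
        children are dropped when the final model is assembled.
        """
        current = self.evaluate(model)
        while True:
            cand = current.coefficients
            if restrict_children is not None:
                cand = cand[cand["child"].isin(set(restrict_children))]
            if cand.empty:
                break
            # stable order: highest p first, ties by declaration order
            order = cand.reset_index().sort_values(
                ["p_value", "index"], ascending=[False, True])
            improved = False
            for _, row in order.iterrows():
                trial = current.copy()
                trial.equations[row["child"]] = [
                    p for p in trial.equations[row["child"]] if p != row["parent"]]
                trial_fit = self.evaluate(trial)
                if trial_fit.aicc < current.aicc:
                    logger.debug("dropping %s -> %s (p=%.3g, AICc %.2f -> %.2f)",
                                 row["parent"], row["child"], row["p_value"],
                                 current.aicc, trial_fit.aicc)
                    current = trial_fit
                    improved = True
                    break
            if not improved:
                break
        final = current.copy()
        _prune(final)
        if final.equations != current.equations:
            return self.evaluate(final)
        return current

    def append_response(self, base: PathModel, response: str,
                        candidate_parents, auto_transform: bool = True,
                        require_accepted: bool = True) -> PathModel:
        """Add a downstream response to an accepted base model.

        The response enters as a sink regressed on ``candidate_parents``
        (must be base nodes or the climate drivers); elimination then only
        touches the response's own edges, so the base coefficients are
        bitwise unchanged — asserted before returning.
        """
        if require_accepted and not base.accepted:
            raise ValidationError("base model not accepted (p_C <= 0.05)")
        if response in base.nodes():
            raise ValidationError(f"{response!r} already in the base model")
        candidates = list(candidate_parents)
        allowed = set(base.nodes()) | {"temperature", "precipitation"}
        bad = set(candidates) - allowed
        if bad:
            raise ValidationError(f"candidate parents outside the base: {sorted(bad)}")
        if self.raw[response].std(ddof=0) == 0:
            raise ValidationError(f"response {response!r} has zero variance")
        ext = base.copy()
        ext.equations[response] = candidates
        if auto_transform:
            X = np.column_stack(
                [np.ones(len(self.raw))] + [self.column(c) for c in candidates])
            ext.transforms[response] = choose_transform(
                self.raw[response].to_numpy(dtype=float), X, self.groups)
        reduced = self.backward_eliminate(ext, restrict_children={response})
        if base.coefficients is not None:
            before = base.coefficients.set_index(["child", "parent"])["estimate"]
            after = (reduced.coefficients.set_index(["child", "parent"])
                     ["estimate"].reindex(before.index))
            if not np.array_equal(before.to_numpy(), after.to_numpy()):
                raise AssertionError("appending changed upstream estimates")
        return reduced


def _prune(model: PathModel) -> None:
    """Remove empty equations; drop endogenous nodes that became isolated."""
    empty = [c for c, ps in model.equations.items() if not ps]
    if not empty:
        return
    has_child = {p for ps in model.equations.values() for p in ps}
    for c in empty:
        del model.equations[c]
        model.transforms.pop(c, None)
        if c not in has_child:
            # fully isolated: also forget its correlated-error declarations
            model.correlated = {pair for pair in model.correlated
                                if c not in pair}
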