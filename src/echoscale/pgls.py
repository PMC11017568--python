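"""Phylogenetic generalized least squares with Pagel's λ residual structure.

The allometric models regress a log10 call parameter (peak frequency,
bandwidth, call duration) on log10 body mass, optionally with an
emission-type or family factor and its interaction with mass.  Residuals
follow σ²·C_λ, where C is the Brownian-motion covariance implied by the
phylogeny and C_λ scales its off-diagonal by λ ∈ [0, 1].  λ is profiled by
REML for reported estimates and by ML for model comparison (AIC, likelihood
ratio tests, R²_lik), the standard practice because REML likelihoods are not
comparable across fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .errors import ModelError, NumericalError
from .trait_data import AlignedDataset, PhyloTree

__all__ = [
    "phylo_vcv",
    "lambda_transform",
    "gls_fit",
    "profile_lambda",
    "fit_pgls",
    "model_selection",
    "r2_lik",
    "anova_type3",
    "slope_ci",
    "PglsModel",
    "parse_formula",
    "build_design",
]

_LOG2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# phylogenetic covariance
# ----------------------------------------------------------------------

def phylo_vcv(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance of tip states implied by the tree.

    C[i, j] is the branch length shared by tips i and j on their paths from
    the root (the depth of their most recent common ancestor); the diagonal
    holds tip-to-root distances.  Returns (C, tip_order).
    """
    t = tree.dendropy_tree
    tips = list(t.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in tips]
    index = {id(leaf): i for i, leaf in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(t.seed_node): 0.0}
    for nd in t.preorder_node_iter():
        if nd is not t.seed_node:
            depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge.length

    # postorder: tip-index sets per node; pairs split across children share
    # the depth of this node
    tipset: dict[int, list[int]] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            i = index[id(nd)]
            tipset[id(nd)] = [i]
            C[i, i] = depth[id(nd)]
            continue
        groups = [tipset.pop(id(ch)) for ch in nd.child_nodes()]
        d = depth[id(nd)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipset[id(nd)] = [i for g in groups for i in g]
    return C, labels


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of C by λ, keeping the diagonal intact."""
    if not (0.0 <= lam <= 1.0):
        raise ModelError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


# ----------------------------------------------------------------------
# GLS core
# ----------------------------------------------------------------------

def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Closed-form GLS fit of y on X with residual covariance σ²·V.

    Returns (beta, cov_beta, sigma2_reml, loglik_ml, loglik_reml).
    cov_beta uses the REML σ²; the log-likelihoods are the full Gaussian
    ones with σ² profiled out (ML: rss/n; REML: rss/(n−p) with the
    log|XᵀV⁻¹X| adjustment).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("residual covariance V is not positive definite") from exc
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        raise NumericalError(f"design matrix is rank deficient (rank {rank} < {p})")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)

    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise NumericalError("XᵀV⁻¹X not positive definite")
    # −log|XᵀX| makes the REML likelihood invariant to the design basis
    _, logdet_XtX0 = np.linalg.slogdet(X.T @ X)

    sigma2_ml = rss / n
    sigma2_reml = rss / (n - p) if n > p else np.nan
    tiny = 1e-300
    loglik_ml = -0.5 * (n * _LOG2PI + n * np.log(max(sigma2_ml, tiny)) + logdet_V + n)
    if n > p:
        loglik_reml = -0.5 * (
            (n - p) * _LOG2PI
            + (n - p) * np.log(max(sigma2_reml, tiny))
            + logdet_V
            + logdet_XtX
            - logdet_XtX0
            + (n - p)
        )
    else:
        loglik_reml = np.nan
    cov_beta = (sigma2_reml if n > p else sigma2_ml) * np.linalg.inv(XtX)
    return beta, cov_beta, sigma2_reml, loglik_ml, loglik_reml


class LambdaProfiler:
    """Evaluate the λ-profile likelihood efficiently for a fixed (y, X, C).

    On ultrametric trees diag(C) = T·1, so C_λ = λC + (1−λ)T·I shares C's
    eigenvectors: after one rotation each profile point costs O(np²).  For
    non-ultrametric trees each point falls back to a Cholesky solve.
    """

    def __init__(self, y, X, C):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.C = np.asarray(C, dtype=float)
        d = np.diag(self.C)
        self._T = float(d[0])
        self._fast = bool(np.allclose(d, self._T, rtol=1e-10, atol=0.0))
        if self._fast:
            evals, Q = np.linalg.eigh(self.C)
            self._evals = evals
            self._yr = Q.T @ self.y
            self._Xr = Q.T @ self.X
        _, self._logdet_XtX0 = np.linalg.slogdet(self.X.T @ self.X)

    def loglik(self, lam: float, criterion: str = "REML") -> float:
        n, p = self.X.shape
        if self._fast:
            w = lam * self._evals + (1.0 - lam) * self._T
            if np.any(w <= 0):
                return -np.inf
            sw = np.sqrt(w)
            yw = self._yr / sw
            Xw = self._Xr / sw[:, None]
            XtX = Xw.T @ Xw
            try:
                beta = np.linalg.solve(XtX, Xw.T @ yw)
            except np.linalg.LinAlgError:
                return -np.inf
            resid = yw - Xw @ beta
            rss = float(resid @ resid)
            logdet_V = float(np.sum(np.log(w)))
            sign, logdet_XtX = np.linalg.slogdet(XtX)
            if sign <= 0:
                return -np.inf
            tiny = 1e-300
            if criterion == "ML":
                s2 = rss / n
                return -0.5 * (n * _LOG2PI + n * np.log(max(s2, tiny)) + logdet_V + n)
            s2 = rss / (n - p)
            return -0.5 * (
                (n - p) * _LOG2PI
                + (n - p) * np.log(max(s2, tiny))
                + logdet_V
                + logdet_XtX
                - self._logdet_XtX0
                + (n - p)
            )
        V = lambda_transform(self.C, lam)
        try:
            _, _, _, ll_ml, ll_reml = gls_fit(self.y, self.X, V)
        except NumericalError:
            return -np.inf
        return ll_ml if criterion == "ML" else ll_reml


def profile_lambda(y, X, C, criterion: str = "REML") -> float:
    """Maximize the λ-profile likelihood over [0, 1].

    Coarse grid (step 0.05) then bounded Brent refinement around the best
    point, with the endpoints always considered; tolerance 1e-6.
    """
    if criterion not in ("REML", "ML"):
        raise ModelError(f"criterion must be REML or ML, got {criterion!r}")
    prof = LambdaProfiler(y, X, C)
    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([prof.loglik(l, criterion) for l in grid])
    if not np.any(np.isfinite(vals)):
        raise NumericalError("lambda profile is degenerate (no finite likelihood)")
    best = int(np.nanargmax(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -prof.loglik(l, criterion),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(prof.loglik(float(res.x), criterion), float(res.x))]
    candidates += [(vals[0], 0.0), (vals[-1], 1.0), (vals[best], grid[best])]
    _, lam_hat = max(candidates, key=lambda t: t[0])
    return float(lam_hat)


# ----------------------------------------------------------------------
# formulas and design matrices
# ----------------------------------------------------------------------

def parse_formula(formula: str) -> tuple[str, list[tuple[str, ...]]]:
    """Parse ``response ~ a + b + a:b`` into (response, term tuples).

    ``response ~ 1`` denotes the intercept-only model.  Only main effects
    and ``:`` interactions are supported, which covers every model used in
    the allometric analyses.
    """
    if "~" not in formula:
        raise ModelError(f"formula must contain '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not response:
        raise ModelError("formula has no response")
    terms: list[tuple[str, ...]] = []
    for raw in rhs.split("+"):
        term = raw.strip()
        if term in ("", "1"):
            continue
        parts = tuple(p.strip() for p in term.split(":"))
        if any(not p for p in parts):
            raise ModelError(f"malformed term {term!r} in formula {formula!r}")
        terms.append(parts)
    return response, terms


def build_design(
    df: pd.DataFrame, terms: list[tuple[str, ...]]
) -> tuple[np.ndarray, list[str], dict[str, slice], dict[str, str]]:
    """Treatment-coded design matrix with an intercept column.

    Factors (object/category columns) get k−1 dummies against the
    alphabetically first level; interactions are elementwise products of
    their components' columns.  Returns (X, column names, term -> column
    slice, factor -> reference level).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    term_slices: dict[str, slice] = {}
    references: dict[str, str] = {}

    def expand(var: str) -> list[tuple[str, np.ndarray]]:
        if var not in df.columns:
            raise ModelError(f"formula references unknown column {var!r}")
        s = df[var]
        if s.dtype.kind in "if":
            return [(var, s.to_numpy(dtype=float))]
        levels = sorted(pd.unique(s.astype(str)))
        if len(levels) < 2:
            raise ModelError(
                f"factor {var!r} has a single observed level ({levels}); "
                "it cannot enter the model"
            )
        references[var] = levels[0]
        return [
            (f"{var}[{lev}]", (s.astype(str) == lev).to_numpy(dtype=float))
            for lev in levels[1:]
        ]

    for parts in terms:
        label = ":".join(parts)
        pieces = [expand(v) for v in parts]
        combo = pieces[0]
        for nxt in pieces[1:]:
            combo = [
                (f"{na}:{nb}", a * b) for na, a in combo for nb, b in nxt
            ]
        start = len(cols)
        for nm, arr in combo:
            cols.append(arr)
            names.append(nm)
        term_slices[label] = slice(start, len(cols))
    X = np.column_stack(cols)
    return X, names, term_slices, references


# ----------------------------------------------------------------------
# model container
# ----------------------------------------------------------------------

@dataclass
class PglsModel:
    """A fitted Pagel's-λ PGLS model."""

    formula: str
    response: str
    terms: list[tuple[str, ...]]
    coef: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    lambda_reml: float
    sigma2_reml: float
    loglik_reml: float
    lambda_ml: float
    loglik_ml: float
    n: int
    n_coef: int
    term_slices: dict[str, slice] = field(repr=False)
    references: dict[str, str] = field(repr=False)
    _data: pd.DataFrame = field(repr=False)
    _C: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        """Parameter count for AIC: coefficients plus λ and σ²."""
        return self.n_coef + 2

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_ml + 2.0 * self.k

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        return slope_ci(self, level)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.coef, "se": self.se})
        ci = self.ci(0.95)
        out["ci_low"] = ci["low"]
        out["ci_high"] = ci["high"]
        return out


def _fit_at_lambda(y, X, C, lam, criterion="REML"):
    V = lambda_transform(C, lam)
    return gls_fit(y, X, V)


def fit_pgls(
    dataset: AlignedDataset,
    formula: str,
    lambda_: float | None = None,
) -> PglsModel:
    """Fit a Pagel's-λ PGLS model to an aligned dataset.

    λ is profiled by REML unless ``lambda_`` pins it (λ=0 reproduces
    ordinary regression exactly).  The returned model also carries the
    ML-profiled λ and log-likelihood for AIC/LR comparisons.
    """
    response, terms = parse_formula(formula)
    df = dataset.data.loc[dataset.tree.tip_labels]
    if response not in df.columns:
        raise ModelError(f"response {response!r} not in dataset")
    y = df[response].to_numpy(dtype=float)
    X, names, term_slices, references = build_design(df, terms)
    C, _ = phylo_vcv(dataset.tree)

    if lambda_ is None:
        lam_reml = profile_lambda(y, X, C, "REML")
        lam_ml = profile_lambda(y, X, C, "ML")
    else:
        lam_reml = lam_ml = float(lambda_)
    beta, cov_beta, sigma2_reml, _, loglik_reml = _fit_at_lambda(y, X, C, lam_reml)
    _, _, _, loglik_ml, _ = _fit_at_lambda(y, X, C, lam_ml)

    coef = pd.Series(beta, index=names, name="estimate")
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=names, name="se")
    vcov = pd.DataFrame(cov_beta, index=names, columns=names)
    return PglsModel(
        formula=formula,
        response=response,
        terms=terms,
        coef=coef,
        se=se,
        vcov=vcov,
        lambda_reml=lam_reml,
        sigma2_reml=sigma2_reml,
        loglik_reml=loglik_reml,
        lambda_ml=lam_ml,
        loglik_ml=loglik_ml,
        n=len(y),
        n_coef=X.shape[1],
        term_slices=term_slices,
        references=references,
        _data=df,
        _C=C,
    )


# ----------------------------------------------------------------------
# model selection, fit statistics, tests
# ----------------------------------------------------------------------

def model_selection(
    dataset: AlignedDataset,
    response: str,
    candidate_rhs: list[str],
) -> tuple[pd.DataFrame, PglsModel]:
    """Rank candidate predictor sets for one response by ML AIC.

    Each candidate is refit by ML with λ re-profiled; AIC = −2·logL_ML + 2k
    with k counting coefficients + λ + σ².  Akaike weights are normalized
    over the candidates that fit.  AIC ties (Δ < 1e-8) prefer fewer
    parameters.  The winner is refit by REML for reported estimates.
    Returns (ranked table, best model).
    """
    if len(candidate_rhs) < 2:
        raise ModelError("model selection needs at least two candidates")
    rows = []
    fits: dict[str, PglsModel] = {}
    for rhs in candidate_rhs:
        formula = f"{response} ~ {rhs}"
        try:
            m = fit_pgls(dataset, formula)
        except (ModelError, NumericalError) as exc:
            rows.append(
                {"formula": formula, "k": np.nan, "logL_ML": np.nan,
                 "AIC": np.nan, "status": f"failed: {exc}"}
            )
            continue
        fits[formula] = m
        rows.append(
            {"formula": formula, "k": m.k, "logL_ML": m.loglik_ml,
             "AIC": m.aic, "status": "ok"}
        )
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    if not ok.any():
        raise ModelError("every candidate model failed to fit")
    aic = table.loc[ok, "AIC"].to_numpy()
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table.loc[ok, "dAIC"] = delta
    table.loc[ok, "weight"] = w
    table = table.sort_values(
        ["AIC", "k"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    # tie-break at numerically equal AIC: fewer parameters first
    best_aic = table.loc[0, "AIC"]
    tied = table[np.abs(table["AIC"] - best_aic) < 1e-8]
    best_formula = tied.sort_values("k", kind="stable").iloc[0]["formula"]
    return table, fits[best_formula]


def r2_lik(model: PglsModel, null_model: PglsModel | None = None) -> float:
    """Likelihood-based partial R² against the intercept-only model.

    R²_lik = 1 − exp(−2(logL_M − logL_0)/n) from the ML fits, clipped at 0.
    If no null model is supplied, the intercept-only ML fit (λ re-profiled)
    is computed internally on the same data.
    """
    if null_model is None:
        null_ll = _refit_ml(model, [])
    else:
        if null_model.n != model.n or null_model.response != model.response:
            raise ModelError("null model does not match the fitted model's data")
        if null_model.terms:
            raise ModelError("null model must be intercept-only")
        null_ll = null_model.loglik_ml
    val = 1.0 - np.exp(-2.0 * (model.loglik_ml - null_ll) / model.n)
    return float(max(val, 0.0))


def _refit_ml(model: PglsModel, terms: list[tuple[str, ...]]) -> float:
    """ML log-likelihood (λ re-profiled) of the model with the given terms."""
    df = model._data
    y = df[model.response].to_numpy(dtype=float)
    X, _, _, _ = build_design(df, terms)
    C = model._C
    lam = profile_lambda(y, X, C, "ML")
    _, _, _, ll_ml, _ = _fit_at_lambda(y, X, C, lam, "ML")
    return ll_ml


def anova_type3(model: PglsModel) -> pd.DataFrame:
    """Type-III analysis of deviance: per-term likelihood-ratio chi-square.

    Each term is removed with all others retained; the reduced model is
    refit by ML with λ re-profiled, Chisq = 2·(logL_full − logL_reduced),
    df = number of coefficients removed, p from the χ² distribution.
    """
    if not model.terms:
        raise ModelError("intercept-only model has no terms to test")
    full_ll = model.loglik_ml
    rows = []
    for parts in model.terms:
        label = ":".join(parts)
        reduced = [t for t in model.terms if ":".join(t) != label]
        sl = model.term_slices[label]
        df_term = sl.stop - sl.start
        red_ll = _refit_ml(model, reduced)
        chisq = max(2.0 * (full_ll - red_ll), 0.0)
        p = float(stats.chi2.sf(chisq, df_term))
        rows.append({"term": label, "Chisq": chisq, "df": df_term, "p": p})
    return pd.DataFrame(rows)


def full_vs_null_lr(model: PglsModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of the full model against intercept-only."""
    null_ll = _refit_ml(model, [])
    chisq = max(2.0 * (model.loglik_ml - null_ll), 0.0)
    df = model.n_coef - 1
    return chisq, df, float(stats.chi2.sf(chisq, df))


def slope_ci(model: PglsModel, level: float = 0.95) -> pd.DataFrame:
    """Wald confidence intervals β̂ ± z·SE from the REML fit."""
    if not (0.0 < level < 1.0):
        raise ModelError(f"confidence level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = model.coef - z * model.se
    hi = model.coef + z * model.se
    return pd.DataFrame({"estimate": model.coef, "low": lo, "high": hi})
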