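"""Bernoulli GLM with the recurrent-mutation link eta = log(1 - p).

The polymorphism probability of a site with scaled mutation rate muT is
p = 1 - exp(-muT): at high rates recurrent mutations saturate the observed
polymorphism signal, and this exponential transformation corrects for that
to first order.  The linear predictor is eta = -muT = log(1 - p), modeled as
context intercepts plus methylation slopes:

    muT_i = alphaT_c + betaT_c * m_i

Model specifications mirror the standard k-mer/flank factorizations: a full
4-mer (or 6-mer) context crossed with methylation, additive single-flank or
dimer-flank models, and context-only variants with every methylation term
dropped (for taxa without appreciable DNA methylation).

Fitting is exact maximum likelihood by Fisher scoring with step-halving;
the likelihood is concave in the coefficients under this link, so the
optimum is global.  Coefficient covariance is the inverse observed
information at the MLE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import solve

from .contexts import enumerate_contexts, is_valid_context

__all__ = [
    "link",
    "inverse_link",
    "d_inverse_link",
    "ModelSpec",
    "MODELS",
    "DesignMatrix",
    "FitResult",
    "ScaledRateEstimate",
    "build_design_matrix",
    "fit_glm",
    "predict_scaled_rates",
    "model_scores",
    "fit_to_json",
    "fit_from_json",
]

_PMIN = 1e-12
_PMAX = 1.0 - 1e-12


# ---------------------------------------------------------------------------
# Link function
# ---------------------------------------------------------------------------

def link(p):
    """eta = log(1 - p), valid for p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("link(p) requires p in the open interval (0, 1)")
    return np.log1p(-p)


def inverse_link(eta):
    """p = 1 - exp(eta), valid probability for eta < 0."""
    eta = np.asarray(eta, dtype=float)
    return -np.expm1(eta)


def d_inverse_link(eta):
    """dp/deta = -exp(eta)."""
    eta = np.asarray(eta, dtype=float)
    return -np.exp(eta)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

_FACTOR_K = {"4mer": 4, "U1": 4, "D1": 4, "6mer": 6, "U2": 6, "D2": 6, "U21": 6, "D12": 6}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression model.

    ``factors`` are categorical context factors; the formula is always
    intercept + dummies(factors) and, when ``with_methylation``,
    + m + dummies(factors):m — i.e. every factor carries both a baseline
    and a methylation-slope effect.  A single k-mer factor crossed with m
    is thereby the per-context intercept+slope parameterization.
    """

    name: str
    factors: tuple[str, ...]
    with_methylation: bool = True

    @property
    def k(self) -> int:
        """Context length the site table must provide (4 or 6)."""
        return max(_FACTOR_K[f] for f in self.factors)

    def n_params(self, n_levels: Mapping[str, int]) -> int:
        base = 1 + sum(n_levels[f] - 1 for f in self.factors)
        return 2 * base if self.with_methylation else base


MODELS: dict[str, ModelSpec] = {
    "4mer": ModelSpec("4mer", ("4mer",)),
    "up1_down1": ModelSpec("up1_down1", ("U1", "D1")),
    "6mer": ModelSpec("6mer", ("6mer",)),
    "up21_down12": ModelSpec("up21_down12", ("U21", "D12")),
    "additive_positions": ModelSpec("additive_positions", ("U2", "U1", "D1", "D2")),
    "context_only_4mer": ModelSpec("context_only_4mer", ("4mer",), with_methylation=False),
    "context_only_up1_down1": ModelSpec(
        "context_only_up1_down1", ("U1", "D1"), with_methylation=False
    ),
}


def _factor_from_kmer(factor: str, kmer: str) -> str:
    """Value of a context factor for a k-mer with central CG."""
    k = len(kmer)
    half = k // 2
    if factor == "4mer":
        return kmer if k == 4 else kmer[half - 2 : half + 2]
    if factor == "6mer":
        if k != 6:
            raise ValueError("6mer factor requires a 6-mer context")
        return kmer
    if factor == "U1":
        return kmer[half - 2]
    if factor == "D1":
        return kmer[half + 1]
    if factor == "U2":
        return kmer[half - 3]
    if factor == "D2":
        return kmer[half + 2]
    if factor == "U21":
        return kmer[half - 3 : half - 1]
    if factor == "D12":
        return kmer[half + 1 : half + 3]
    raise ValueError(f"unknown context factor {factor!r}")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Sparse design matrix with treatment coding.

    Reference level of every factor is its lexicographically first level
    observed in the data; predictions are coding-invariant.
    """

    X: sp.csr_matrix
    columns: list[str]
    y: np.ndarray
    m: np.ndarray
    levels: dict[str, list[str]]
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design_matrix(sites: pd.DataFrame, spec: ModelSpec | str) -> DesignMatrix:
    """Build the treatment-coded design matrix for ``spec`` over ``sites``.

    ``sites`` must carry the context column the model needs (context4 or
    context6), a methylation column ``m`` for models with methylation
    terms, and the binary outcome ``y``.
    """
    if isinstance(spec, str):
        spec = MODELS[spec]
    ctx_col = f"context{spec.k}"
    if ctx_col not in sites.columns:
        raise ValueError(f"model {spec.name!r} needs column {ctx_col!r}")
    ctx = sites[ctx_col]
    if ctx.isna().any():
        raise ValueError(f"model {spec.name!r}: {int(ctx.isna().sum())} sites lack {ctx_col}")
    ctx = ctx.astype(str)

    y = sites["y"].to_numpy(dtype=np.int8)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome y must be binary")
    if spec.with_methylation:
        m = sites["m"].to_numpy(dtype=float)
        if np.any((m < 0) | (m > 1)) or np.any(~np.isfinite(m)):
            raise ValueError("methylation m must lie in [0, 1]")
    else:
        m = np.zeros(len(sites))

    n = len(sites)
    columns = ["Intercept"]
    levels: dict[str, list[str]] = {}
    rows: list[np.ndarray] = [np.arange(n)]
    cols: list[np.ndarray] = [np.zeros(n, dtype=np.int64)]
    data: list[np.ndarray] = [np.ones(n)]

    factor_codes: dict[str, np.ndarray] = {}
    for f in spec.factors:
        values = ctx.map(lambda s, f=f: _factor_from_kmer(f, s))
        cat = pd.Categorical(values)  # categories sorted lexicographically
        levels[f] = list(cat.categories)
        factor_codes[f] = np.asarray(cat.codes)

    def add_dummies(interact_m: bool) -> None:
        for f in spec.factors:
            codes = factor_codes[f]
            offset = len(columns)
            suffix = ":m" if interact_m else ""
            for lvl in levels[f][1:]:
                columns.append(f"{f}[{lvl}]{suffix}")
            nz = np.nonzero(codes > 0)[0]
            rows.append(nz)
            cols.append(offset + codes[nz] - 1)
            data.append(m[nz] if interact_m else np.ones(len(nz)))

    add_dummies(interact_m=False)
    if spec.with_methylation:
        columns.append("m")
        rows.append(np.arange(n))
        cols.append(np.full(n, len(columns) - 1, dtype=np.int64))
        data.append(m.copy())
        add_dummies(interact_m=True)

    X = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, len(columns)),
    ).tocsr()
    return DesignMatrix(X=X, columns=columns, y=y, m=m, levels=levels, spec=spec)


def _prediction_row(columns: Sequence[str], levels: Mapping[str, list[str]], spec: ModelSpec,
                    context: str, x: float) -> np.ndarray:
    """Row vector for one context at methylation state x, matching training coding."""
    col_index = {c: i for i, c in enumerate(columns)}
    row = np.zeros(len(columns))
    row[col_index["Intercept"]] = 1.0
    if spec.with_methylation:
        row[col_index["m"]] = x
    for f in spec.factors:
        lvl = _factor_from_kmer(f, context)
        if lvl not in levels[f]:
            raise ValueError(f"factor {f} level {lvl!r} was not seen during fitting")
        if lvl == levels[f][0]:
            continue  # reference level
        row[col_index[f"{f}[{lvl}]"]] = 1.0
        if spec.with_methylation:
            row[col_index[f"{f}[{lvl}]:m"]] = x
    return row


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model."""

    spec: ModelSpec
    columns: list[str]
    levels: dict[str, list[str]]
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    null_deviance: float
    residual_deviance: float
    aic: float
    bic: float
    n_obs: int
    n_iter: int
    converged: bool
    n_clipped: int
    eta: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.theta)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return pd.DataFrame({"term": self.columns, "estimate": self.theta, "se": se})


def _loglik_and_clip(eta: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Log-likelihood with probabilities clipped into [1e-12, 1-1e-12].

    Returns (loglik, clipped p, number of clipped observations).  Clipping
    keeps the iteration inside the valid region when a trial step pushes
    eta to or above 0.
    """
    p = -np.expm1(eta)
    n_clip = int(np.count_nonzero((p < _PMIN) | (p > _PMAX)))
    p = np.clip(p, _PMIN, _PMAX)
    ll = float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))
    return ll, p, n_clip


def fit_glm(dm: DesignMatrix, max_iter: int = 100, tol: float = 1e-10,
            keep_eta: bool = True) -> FitResult:
    """Fit by Fisher scoring with step-halving on the exact likelihood.

    The per-observation log-likelihood y log(1-e^eta) + (1-y) eta is
    concave in eta (second derivative -y e^eta / p^2 <= 0), so the MLE is
    a global maximum.  Iteration uses the expected information, whose
    weights (1-p)/p are positive for every row; the reported covariance is
    the inverse *observed* information at the optimum.
    """
    X, y = dm.X, dm.y
    n, p_dim = X.shape
    if n <= p_dim:
        raise ValueError(f"need more observations ({n}) than parameters ({p_dim})")

    ybar = float(np.mean(y))
    theta = np.zeros(p_dim)
    theta[0] = np.log1p(-min(max(ybar, _PMIN), _PMAX))

    eta = X @ theta
    ll, pi, _ = _loglik_and_clip(eta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        one_m_p = 1.0 - pi  # = e^eta after clipping
        score = np.where(y == 1, -one_m_p / pi, 1.0)
        grad = X.T @ score
        w_exp = one_m_p / pi
        XtW = X.multiply(w_exp[:, None]).T if sp.issparse(X) else (X * w_exp[:, None]).T
        H = np.asarray((XtW @ X).todense() if sp.issparse(X) else XtW @ X)
        try:
            step = solve(H, grad, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]

        # step-halving; the valid region {eta < 0} is open and the start is
        # interior, so a feasible improving step always exists unless the
        # MLE sits at the current point
        t = 1.0
        accepted = False
        for _ in range(31):
            cand = theta + t * step
            eta_c = X @ cand
            ll_c, p_c, _ = _loglik_and_clip(eta_c, y)
            if float(np.max(eta_c)) < 0.0 and ll_c >= ll:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if ll_c >= ll:  # only infeasible improvement: accept clipped, flagged
                accepted = True
            else:
                break
        theta, eta, pi = cand, eta_c, p_c
        if abs(ll_c - ll) < tol * (abs(ll) + 1.0):
            ll = ll_c
            converged = True
            break
        ll = ll_c

    ll, pi, n_clipped = _loglik_and_clip(X @ theta, y)
    eta_hat = np.log1p(-pi)

    # observed information: only polymorphic rows contribute curvature
    w_obs = np.where(y == 1, (1.0 - pi) / pi**2, 0.0)
    XtWo = X.multiply(w_obs[:, None]).T if sp.issparse(X) else (X * w_obs[:, None]).T
    info = np.asarray((XtWo @ X).todense() if sp.issparse(X) else XtWo @ X)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        converged = False

    # null model: intercept only, closed form p-hat = mean(y)
    if 0.0 < ybar < 1.0:
        ll0 = float(n * (ybar * np.log(ybar) + (1.0 - ybar) * np.log1p(-ybar)))
    else:
        ll0 = 0.0  # degenerate outcome: null model is saturated

    return FitResult(
        spec=dm.spec,
        columns=list(dm.columns),
        levels={f: list(v) for f, v in dm.levels.items()},
        theta=theta,
        cov=cov,
        loglik=ll,
        null_deviance=-2.0 * ll0,
        residual_deviance=-2.0 * ll,
        aic=2.0 * p_dim - 2.0 * ll,
        bic=p_dim * np.log(n) - 2.0 * ll,
        n_obs=n,
        n_iter=it,
        converged=converged,
        n_clipped=n_clipped,
        eta=eta_hat if keep_eta else None,
    )


# ---------------------------------------------------------------------------
# Prediction and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledRateEstimate:
    """muT for one context at methylation state 0 or 1, with Wald CI."""

    context: str
    state: int
    muT: float
    se: float
    ci_low: float
    ci_high: float


def _constructible_contexts(spec: ModelSpec, levels: Mapping[str, list[str]]) -> list[str]:
    out = []
    for c in enumerate_contexts(spec.k):
        if all(_factor_from_kmer(f, c) in levels[f] for f in spec.factors):
            out.append(c)
    return out


def predict_scaled_rates(
    fit: FitResult,
    x: int,
    contexts: Iterable[str] | None = None,
) -> list[ScaledRateEstimate]:
    """Scaled mutation rate muT = -eta per context at methylation state x.

    x = 0 gives the unmethylated baseline (alphaT), x = 1 the fully
    methylated rate ((alpha+beta)T).  By default every k-mer context
    constructible from the factor levels seen in training is predicted;
    passing ``contexts`` with an unseen level raises an error naming it.
    For context-only models the methylation state must be 0 (a single
    state exists).
    """
    if x not in (0, 1):
        raise ValueError("methylation state x must be 0 or 1; extrapolation is out of contract")
    if not fit.spec.with_methylation and x != 0:
        raise ValueError(f"model {fit.spec.name!r} has no methylation terms; only x=0 is defined")
    if contexts is None:
        contexts = _constructible_contexts(fit.spec, fit.levels)
    out = []
    for c in contexts:
        if not is_valid_context(c, fit.spec.k):
            raise ValueError(f"{c!r} is not a valid {fit.spec.k}-mer CpG context")
        row = _prediction_row(fit.columns, fit.levels, fit.spec, c, float(x))
        mu = float(-(row @ fit.theta))
        se = float(np.sqrt(max(row @ fit.cov @ row, 0.0)))
        out.append(ScaledRateEstimate(c, x, mu, se, mu - 1.96 * se, mu + 1.96 * se))
    return out


def rates_to_frame(estimates: Iterable[ScaledRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.context, e.state, e.muT, e.se, e.ci_low, e.ci_high) for e in estimates],
        columns=["context", "state", "muT", "se", "ci_low", "ci_high"],
    )


def model_scores(fit: FitResult) -> dict[str, float]:
    """AIC, BIC and proportion of null deviance explained."""
    ve = (fit.null_deviance - fit.residual_deviance) / fit.null_deviance if fit.null_deviance else np.nan
    return {"AIC": fit.aic, "BIC": fit.bic, "variance_explained": ve}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def fit_to_json(fit: FitResult, path) -> None:
    payload = {
        "spec": fit.spec.name,
        "columns": fit.columns,
        "levels": fit.levels,
        "theta": fit.theta.tolist(),
        "cov": fit.cov.tolist(),
        "loglik": fit.loglik,
        "null_deviance": fit.null_deviance,
        "residual_deviance": fit.residual_deviance,
        "AIC": fit.aic,
        "BIC": fit.bic,
        "variance_explained": model_scores(fit)["variance_explained"],
        "n_obs": fit.n_obs,
        "convergence": {
            "iterations": fit.n_iter,
            "converged": fit.converged,
            "n_clipped": fit.n_clipped,
        },
        "coefficients": fit.coef_table().to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def fit_from_json(path) -> FitResult:
    with open(path) as fh:
        d = json.load(fh)
    return FitResult(
        spec=MODELS[d["spec"]],
        columns=d["columns"],
        levels=d["levels"],
        theta=np.asarray(d["theta"]),
        cov=np.asarray(d["cov"]),
        loglik=d["loglik"],
        null_deviance=d["null_deviance"],
        residual_deviance=d["residual_deviance"],
        aic=d["AIC"],
        bic=d["BIC"],
        n_obs=d["n_obs"],
        n_iter=d["convergence"]["iterations"],
        converged=d["convergence"]["converged"],
        n_clipped=d["convergence"]["n_clipped"],
    )
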