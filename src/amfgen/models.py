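"""Statistical modeling layer: all-subsets candidate enumeration with
marginality constraints, AIC-based selection, and the two model families
used by the analysis.

Selection rule: among candidates within delta-AIC < 2 (strict) of the
best AIC, the model with the fewest estimated parameters (lowest df,
i.e. most parsimonious) is selected; ties on df break by smaller AIC,
then by the deterministic enumeration order.

Gaussian linear mixed models are fit by maximum likelihood (ML, not
REML) through statsmodels' MixedLM so that AIC values are comparable
across fixed-effect structures, the prerequisite for all-subsets
selection. Crossed random intercepts (e.g. plant species crossed with
mesocosm nested in community) use the single-group variance-components
construction. The zero-inflated beta family (for proportional responses
in [0, 1)) is a two-part fixed-effects model fit by joint MLE: a
logistic zero-inflation part (intercept-only by default) and a beta
regression with logit mean link and log precision.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "Term",
    "ModelSpec",
    "ModelCandidate",
    "term_name",
    "enumerate_submodels",
    "select_best",
    "fit_lmm",
    "fit_zib",
    "dredge",
    "residual_check",
]

# a fixed-effect term is a sorted tuple of factor names; length > 1 is an
# interaction
Term = tuple[str, ...]


def term_name(term: Term) -> str:
    return ":".join(term)


def _as_term(t: Sequence[str] | str) -> Term:
    if isinstance(t, str):
        parts = t.split(":")
    else:
        parts = list(t)
    return tuple(sorted(parts))


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect structure plus random terms and family."""

    response: str
    fixed_terms: frozenset[Term]
    random_terms: tuple[tuple[str, str], ...] = ()  # (name, vc formula)
    family: str = "gaussian"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fixed_terms", frozenset(_as_term(t) for t in self.fixed_terms)
        )
        violations = marginality_violations(self.fixed_terms)
        if violations:
            raise ValueError(
                f"marginality violated: interaction(s) "
                f"{[term_name(t) for t in violations]} lack lower-order terms"
            )
        if self.family not in ("gaussian", "zero_inflated_beta"):
            raise ValueError(f"unknown family {self.family!r}")

    def formula(self) -> str:
        terms = sorted(self.fixed_terms, key=lambda t: (len(t), t))
        rhs = " + ".join(term_name(t) for t in terms) if terms else "1"
        return f"{self.response} ~ {rhs}"

    def sort_key(self) -> tuple:
        return (
            len(self.fixed_terms),
            tuple(sorted((len(t), t) for t in self.fixed_terms)),
        )


@dataclass
class ModelCandidate:
    spec: ModelSpec
    aic: float
    df: int
    fit_summary: pd.DataFrame
    converged: bool = True
    log_likelihood: float = float("nan")
    params: dict = field(default_factory=dict)


def marginality_violations(terms: frozenset[Term]) -> list[Term]:
    """Interactions whose lower-order terms are not all present."""
    bad = []
    for t in terms:
        if len(t) > 1:
            for k in range(1, len(t)):
                for sub in itertools.combinations(t, k):
                    if tuple(sorted(sub)) not in terms:
                        bad.append(t)
                        break
                else:
                    continue
                break
    return bad


def enumerate_submodels(
    maximal: ModelSpec, always_keep: Sequence[Term | str] = ()
) -> list[ModelSpec]:
    """All fixed-term subsets of the maximal model respecting marginality.

    ``always_keep`` terms appear in every candidate (design covariates
    pinned by the experiment). Candidates come in a deterministic order:
    by number of terms, then lexicographically. The null (or
    always-keep-only) and maximal models are always present.
    """
    keep = frozenset(_as_term(t) for t in always_keep)
    if not keep <= maximal.fixed_terms:
        raise ValueError("always_keep terms must be part of the maximal model")
    free = sorted(maximal.fixed_terms - keep)
    specs = []
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            terms = keep | frozenset(combo)
            if marginality_violations(terms):
                continue
            specs.append(replace(maximal, fixed_terms=terms))
    specs.sort(key=lambda s: s.sort_key())
    return specs


def select_best(candidates: Sequence[ModelCandidate]) -> ModelCandidate:
    """Most parsimonious candidate within strict delta-AIC < 2 of the best.

    Ties on df break by smaller AIC, then by deterministic spec order.
    """
    finite = [c for c in candidates if np.isfinite(c.aic)]
    if not finite:
        raise ValueError("no candidate with finite AIC")
    best_aic = min(c.aic for c in finite)
    window = [c for c in finite if c.aic - best_aic < 2.0]
    return min(window, key=lambda c: (c.df, c.aic, c.spec.sort_key()))


def fit_lmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    group_col: str | None = None,
) -> ModelCandidate:
    """Fit a Gaussian LMM by ML and return its AIC, df and coefficients.

    Random intercepts come from ``spec.random_terms`` as variance
    components. With ``group_col`` None, all observations form a single
    group so arbitrary crossed random intercepts are supported; with a
    group column, components are nested within that grouping factor.
    df = fixed parameters + variance components + residual variance.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires the gaussian family")
    data = data.reset_index(drop=True)
    vc = {name: formula for name, formula in spec.random_terms}
    groups = data[group_col] if group_col else np.ones(len(data))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            spec.formula(), data, groups=groups, vc_formula=vc or None
        )
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            return ModelCandidate(spec, float("inf"), 0, pd.DataFrame(),
                                  converged=False)
    k_fe = len(res.fe_params)
    df = k_fe + len(vc) + 1
    aic = -2.0 * res.llf + 2.0 * df
    names = list(res.fe_params.index)
    se = np.asarray(res.bse.iloc[:k_fe])
    est = np.asarray(res.fe_params)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    summary = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )
    return ModelCandidate(
        spec, float(aic), int(df), summary,
        converged=bool(res.converged), log_likelihood=float(res.llf),
        params={"vcomp": dict(zip(vc, np.asarray(res.vcomp))),
                "resid_var": float(res.scale)},
    )


def _zib_negloglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    alpha, beta, lam = theta[0], theta[1:-1], theta[-1]
    pi = special.expit(alpha)
    phi = np.exp(lam)
    nll = 0.0
    zero = y == 0
    n0 = int(zero.sum())
    if n0:
        nll -= n0 * np.log(pi + 1e-300)
    pos = ~zero
    if pos.any():
        mu = special.expit(X[pos] @ beta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        a, b = mu * phi, (1 - mu) * phi
        nll -= np.sum(np.log1p(-pi) + stats.beta.logpdf(y[pos], a, b))
    return float(nll)


def fit_zib(spec: ModelSpec, data: pd.DataFrame) -> ModelCandidate:
    """Fit a zero-inflated beta regression by joint MLE.

    Response must lie in [0, 1). A response equal to 1 raises with
    advice to apply the standard (y*(n-1)+0.5)/n shrinkage first.
    Zero-inflation is intercept-only; the positive part is a beta
    regression with logit mean link and a single log-precision
    parameter. df = 1 (zero part) + fixed parameters + 1 (precision).
    """
    if spec.family != "zero_inflated_beta":
        raise ValueError("fit_zib requires the zero_inflated_beta family")
    y = np.asarray(data[spec.response], dtype=float)
    if (y < 0).any() or (y > 1).any():
        raise ValueError("response outside [0, 1]")
    if (y == 1).any():
        raise ValueError(
            "response contains exactly 1; apply the (y*(n-1)+0.5)/n "
            "shrinkage transform before fitting"
        )
    rhs = spec.formula().split("~", 1)[1]
    X = np.asarray(patsy.dmatrix(rhs, data, return_type="dataframe"))
    x_names = patsy.dmatrix(rhs, data, return_type="dataframe").columns.tolist()
    k = X.shape[1]
    n0 = int((y == 0).sum())
    if n0 == len(y):
        # all-zero response: the beta part is degenerate
        summary = pd.DataFrame(
            {"term": ["zi_intercept"], "estimate": [np.inf], "se": [np.nan],
             "z": [np.nan], "p": [np.nan]}
        )
        return ModelCandidate(spec, float("inf"), k + 2, summary, converged=False)
    pi0 = np.clip(n0 / len(y), 0.01, 0.99)
    theta0 = np.zeros(k + 2)
    theta0[0] = special.logit(pi0)
    pos_mean = np.clip(y[y > 0].mean(), 1e-3, 1 - 1e-3)
    theta0[1] = special.logit(pos_mean)
    theta0[-1] = np.log(5.0)
    res = optimize.minimize(
        _zib_negloglik, theta0, args=(X, y), method="L-BFGS-B",
        options={"maxiter": 500},
    )
    llf = -res.fun
    df = k + 2
    aic = -2.0 * llf + 2.0 * df
    try:
        hess = approx_hess1(res.x, _zib_negloglik, args=(X, y))
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(df, np.nan)
    names = ["zi_intercept"] + x_names + ["log_precision"]
    est = res.x
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    summary = pd.DataFrame(
        {"term": names, "estimate": est, "se": se, "z": z,
         "p": 2 * stats.norm.sf(np.abs(z))}
    )
    return ModelCandidate(
        spec, float(aic), int(df), summary, converged=bool(res.success),
        log_likelihood=float(llf),
        params={"zi_prob": float(special.expit(res.x[0])),
                "precision": float(np.exp(res.x[-1]))},
    )


def dredge(
    maximal: ModelSpec,
    data: pd.DataFrame,
    fitter: Callable[[ModelSpec, pd.DataFrame], ModelCandidate] | None = None,
    always_keep: Sequence[Term | str] = (),
) -> tuple[ModelCandidate, list[ModelCandidate]]:
    """Fit every marginality-respecting submodel and apply the selection
    rule; non-converged fits are excluded with a warning."""
    if fitter is None:
        fitter = fit_lmm if maximal.family == "gaussian" else fit_zib
    candidates = [fitter(s, data) for s in enumerate_submodels(maximal, always_keep)]
    ok = [c for c in candidates if c.converged and np.isfinite(c.aic)]
    dropped = len(candidates) - len(ok)
    if dropped:
        warnings.warn(
            f"{dropped} candidate(s) excluded from selection "
            f"(non-converged or infinite AIC)",
            stacklevel=2,
        )
    return select_best(ok), candidates


def residual_check(
    candidate: ModelCandidate,
    data: pd.DataFrame,
    n_sim: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Simulation-based residual diagnostic for Gaussian candidates.

    Simulates responses from the fitted fixed-effect mean and total
    variance, compares observed against simulated residual quantiles
    (KS statistic) and a dispersion ratio. Reported, not gating.
    """
    rng = np.random.default_rng(seed)
    rhs = candidate.spec.formula().split("~", 1)[1]
    X = np.asarray(patsy.dmatrix(rhs, data, return_type="dataframe"))
    mu = X @ np.asarray(candidate.fit_summary["estimate"])
    y = np.asarray(data[candidate.spec.response], dtype=float)
    resid = y - mu
    total_var = candidate.params.get("resid_var", float(np.var(resid))) + sum(
        candidate.params.get("vcomp", {}).values()
    )
    sims = rng.normal(0.0, np.sqrt(total_var), size=(n_sim, len(y)))
    ks = stats.ks_2samp(resid, sims.ravel()).statistic
    dispersion = float(np.var(resid) / total_var)
    return {"ks_statistic": float(ks), "dispersion_ratio": dispersion}
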