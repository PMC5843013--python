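"""Bias-adjusted three-step regression of class membership on risk factors.

The three steps: (1) fit the unconditional latent class model and compute
posterior class probabilities; (2) assign each child to their modal class
and summarise the assignment error in a classification-error matrix D,
where D[t, m] = P(modal class m | true class t); (3) regress the modal
assignments on covariates by maximum likelihood under a multinomial-logit
model for the *true* class with the misclassification D treated as fixed:

    l(gamma) = sum_i log sum_t P(t | x_i; gamma) * D[t, m_i]

This removes the attenuation bias of regressing directly on modal labels.
With D = identity the estimator reduces exactly to ordinary multinomial
logistic regression on the modal labels.  Standard errors come from the
observed information of the step-3 likelihood; uncertainty in D itself is
not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibration import COMPOSITE_CLASS_NAMES
from .collapse import CompositePosterior

__all__ = [
    "ErrorMatrix",
    "ThreeStepResult",
    "modal_assign",
    "error_matrix",
    "build_design",
    "fit_threestep",
    "wald_intervals",
    "omnibus_test",
]


@dataclass
class ErrorMatrix:
    """Classification-error matrix: rows true class, columns modal class."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")
        if ((self.D < -1e-12) | (self.D > 1 + 1e-12)).any():
            raise ValueError("D entries must lie in [0, 1]")
        if not np.allclose(self.D.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("D rows must sum to 1")


def modal_assign(composite: CompositePosterior) -> np.ndarray:
    """Modal composite-class index per child (ties break to the less severe group)."""
    return composite.modal_labels


def error_matrix(composite: CompositePosterior) -> ErrorMatrix:
    """Estimate D[t, m] = sum_i p_it 1[m_i = m] / sum_i p_it from the posterior."""
    p = composite.probs
    m = composite.modal_labels
    k = p.shape[1]
    mass = p.sum(axis=0)
    empty = np.flatnonzero(mass <= 0)
    if empty.size:
        names = [composite.labels[j] for j in empty]
        raise ValueError(f"no posterior mass in class(es) {names}; D undefined")
    ind = np.zeros((p.shape[0], k))
    ind[np.arange(p.shape[0]), m] = 1.0
    return ErrorMatrix(D=(p.T @ ind) / mass[:, None])


@dataclass
class ThreeStepResult:
    """Step-3 multinomial fit with the normative class as reference."""

    coef: np.ndarray  # (p, K-1): column j = class j+1 vs reference
    cov: np.ndarray  # ((p*(K-1)), (p*(K-1))) covariance, column-major blocks
    term_names: list[str]
    class_labels: list[str]
    loglik: float
    n_used: int
    gradient_norm: float
    converged: bool
    separation: bool = False
    factor_terms: dict[str, list[int]] = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        """Standard errors, same shape as ``coef`` (p, K-1)."""
        return np.sqrt(np.diag(self.cov)).reshape(self.coef.shape, order="F")


def build_design(
    covariates: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]], np.ndarray]:
    """Design matrix with intercept and treatment-coded categorical terms.

    Categorical columns must be pandas Categorical; the first declared
    category is the reference level.  Rows with any missing value among
    the requested terms are dropped (listwise deletion).  Returns the
    design matrix, column names, a map from term to its column indices and
    the boolean row mask of retained children.
    """
    sub = covariates[terms]
    keep = sub.notna().all(axis=1).to_numpy()
    sub = sub.loc[keep]
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    factor_terms: dict[str, list[int]] = {}
    for term in terms:
        col = sub[term]
        idx: list[int] = []
        if isinstance(col.dtype, pd.CategoricalDtype):
            for lvl in col.cat.categories[1:]:
                cols.append((col == lvl).to_numpy(dtype=float))
                names.append(f"{term}[{lvl}]")
                idx.append(len(names) - 1)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            idx.append(len(names) - 1)
        factor_terms[term] = idx
    return np.column_stack(cols), names, factor_terms, keep


def _step3_negloglik_grad(
    gamma_flat: np.ndarray, x: np.ndarray, d_cols: np.ndarray, k: int
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient of the misclassified-outcome logit.

    ``d_cols[i, t]`` holds D[t, m_i].  gamma is flattened column-major:
    one length-p block per non-reference class.
    """
    n, p = x.shape
    gamma = gamma_flat.reshape(p, k - 1, order="F")
    eta = np.column_stack([np.zeros(n), x @ gamma])  # reference logit 0
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    probs = expeta / expeta.sum(axis=1, keepdims=True)  # (n, K)
    li = (probs * d_cols).sum(axis=1)
    if (li <= 0).any():
        return np.inf, np.zeros_like(gamma_flat)
    ll = np.log(li).sum()
    # d ll / d eta_{it} = p_it d_it / L_i - p_it  (t >= 1)
    w = probs * d_cols / li[:, None] - probs
    grad = (x.T @ w[:, 1:]).ravel(order="F")
    return -ll, -grad


def fit_threestep(
    labels: np.ndarray,
    D: ErrorMatrix | np.ndarray,
    covariates: pd.DataFrame,
    terms: list[str],
    class_labels: list[str] | None = None,
    gtol: float = 1e-8,
) -> ThreeStepResult:
    """Maximum-likelihood step-3 regression with fixed classification error.

    Parameters
    ----------
    labels
        Modal class assignment per child (0 = reference/normative).
    D
        Row-stochastic classification-error matrix (true x modal).
    covariates
        Per-child table; rows must align with ``labels``.
    terms
        Covariate columns to include (categoricals are treatment coded
        against their first declared level).

    Raises on a singular D; quasi-complete separation is flagged on the
    result rather than raised.
    """
    D = D if isinstance(D, ErrorMatrix) else ErrorMatrix(np.asarray(D))
    k = D.D.shape[0]
    if abs(np.linalg.det(D.D)) < 1e-12:
        raise ValueError("classification-error matrix D is singular")
    labels = np.asarray(labels)
    if labels.shape[0] != len(covariates):
        raise ValueError("labels and covariates must align")
    x, names, factor_terms, keep = build_design(covariates, terms)
    m = labels[keep]
    d_cols = D.D[:, m].T  # (n, K): column t = D[t, m_i]
    p = x.shape[1]

    x0 = np.zeros(p * (k - 1))
    res = optimize.minimize(
        _step3_negloglik_grad,
        x0,
        args=(x, d_cols, k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": gtol},
    )
    # polish with a few Newton-free BFGS steps if the gradient is not tight
    if np.max(np.abs(res.jac)) > gtol:
        res = optimize.minimize(
            _step3_negloglik_grad,
            res.x,
            args=(x, d_cols, k),
            jac=True,
            method="BFGS",
            options={"maxiter": 500, "gtol": gtol},
        )
    gamma = res.x.reshape(p, k - 1, order="F")
    grad_norm = float(np.max(np.abs(res.jac)))
    separation = bool(np.any(np.abs(gamma) > 15.0))

    hess = _numerical_hessian(res.x, x, d_cols, k)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((res.x.size, res.x.size), np.nan)
        separation = True

    return ThreeStepResult(
        coef=gamma,
        cov=cov,
        term_names=names,
        class_labels=list(class_labels or COMPOSITE_CLASS_NAMES[:k]),
        loglik=-float(res.fun),
        n_used=int(keep.sum()),
        gradient_norm=grad_norm,
        converged=grad_norm < 1e-5,
        separation=separation,
        factor_terms=factor_terms,
    )


def _numerical_hessian(theta, x, d_cols, k, eps: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    q = theta.size
    hess = np.empty((q, q))
    for j in range(q):
        step = eps * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = _step3_negloglik_grad(tp, x, d_cols, k)
        _, gm = _step3_negloglik_grad(tm, x, d_cols, k)
        hess[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


def wald_intervals(result: ThreeStepResult, level: float = 0.95) -> pd.DataFrame:
    """Odds ratios exp(gamma) with Wald confidence intervals per term and class."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = result.se
    rows = []
    for j, cls in enumerate(result.class_labels[1:]):
        for i, name in enumerate(result.term_names):
            g, s = result.coef[i, j], se[i, j]
            rows.append(
                {
                    "class": cls,
                    "term": name,
                    "coef": g,
                    "se": s,
                    "or": np.exp(g),
                    "ci_low": np.exp(g - z * s),
                    "ci_high": np.exp(g + z * s),
                }
            )
    return pd.DataFrame(rows)


def omnibus_test(result: ThreeStepResult, risk_factor: str) -> float:
    """Joint Wald test that all the factor's coefficients are zero.

    Tests the factor's coefficient block across every non-reference class;
    df = (number of design columns for the factor) x (K - 1).
    """
    if risk_factor not in result.factor_terms:
        raise KeyError(f"unknown risk factor {risk_factor!r}")
    p, km1 = result.coef.shape
    cols = result.factor_terms[risk_factor]
    flat_idx = [j * p + i for j in range(km1) for i in cols]
    c = result.coef.ravel(order="F")[flat_idx]
    v = result.cov[np.ix_(flat_idx, flat_idx)]
    try:
        stat = float(c @ np.linalg.solve(v, c))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular covariance block for {risk_factor!r}"
        ) from err
    return float(stats.chi2.sf(stat, df=len(flat_idx)))
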