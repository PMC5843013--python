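"""Longitudinal latent class analysis (LLCA) for repeated binary indicators.

The model: each child belongs to one of C latent trajectory classes with
marginal probabilities (class weights) pi_c; given the class, the binary
symptom indicators at the T waves are independent Bernoulli variables with
class- and wave-specific probabilities rho_{c,t} (local independence).
Missing indicators are handled by full-information maximum likelihood under
missingness at random: each child's likelihood is evaluated over their
observed waves only.

Estimation is by EM with multiple random starts.  Children sharing an
identical observed response pattern contribute identical terms, so the
E and M steps run on the unique patterns with multiplicity weights; this
makes fits at cohort scale (n ~ 10^4, T <= 6) essentially instantaneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .panel import ResponsePanel

__all__ = [
    "LCAParams",
    "PosteriorMatrix",
    "compute_loglik",
    "em_fit",
    "posterior_probs",
    "enumerate_classes",
    "canonical_order",
    "label_classes",
]

RHO_CLAMP = 1e-6  # keeps item probabilities off the 0/1 boundary


@dataclass
class LCAParams:
    """Fitted (or hypothesised) parameters of a C-class LLCA model."""

    class_weights: np.ndarray  # (C,)
    item_probs: np.ndarray  # (C, T)
    loglik: float = np.nan
    converged: bool = False
    n_children: int = 0

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        self.item_probs = np.atleast_2d(np.asarray(self.item_probs, dtype=float))
        if self.class_weights.ndim != 1:
            raise ValueError("class_weights must be a vector")
        if self.item_probs.shape[0] != self.n_classes:
            raise ValueError("item_probs must have one row per class")
        if not np.isclose(self.class_weights.sum(), 1.0, atol=1e-8):
            raise ValueError("class_weights must sum to 1")
        if ((self.item_probs < 0) | (self.item_probs > 1)).any():
            raise ValueError("item_probs must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.class_weights.shape[0]

    @property
    def n_waves(self) -> int:
        return self.item_probs.shape[1]

    @property
    def n_params(self) -> int:
        """Free parameters: (C-1) weights plus C*T item probabilities."""
        return (self.n_classes - 1) + self.n_classes * self.n_waves


@dataclass
class PosteriorMatrix:
    """Posterior class-membership probabilities, one row per child."""

    probs: np.ndarray  # (n, C)
    child_ids: np.ndarray
    entropy_quality: float = np.nan

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


def relative_entropy_quality(probs: np.ndarray) -> float:
    """Entropy-based classification quality in [0, 1]; 1 = perfect separation."""
    n, c = probs.shape
    if c == 1:
        return 1.0
    with np.errstate(invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(c)))


# ---------------------------------------------------------------------------
# likelihood machinery (weighted unique response patterns)


def _unique_patterns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse rows to unique {0,1,missing} patterns with multiplicities."""
    enc = np.where(np.isfinite(values), values, 2.0).astype(np.int8)
    uniq, inverse, counts = np.unique(
        enc, axis=0, return_inverse=True, return_counts=True
    )
    patterns = np.where(uniq == 2, np.nan, uniq.astype(float))
    return patterns, inverse, counts.astype(float)


def _log_components(patterns: np.ndarray, item_probs: np.ndarray) -> np.ndarray:
    """log P(pattern | class) for each unique pattern (rows) and class (cols).

    Missing waves contribute nothing; a 0/1 item probability contradicting
    an observation yields -inf, never NaN.
    """
    obs = np.isfinite(patterns)
    y = np.where(obs, patterns, 0.0)
    rho = np.clip(item_probs, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        log_rho = np.log(rho)
        log_1mrho = np.log1p(-rho)
    # (U, 1, T) against (1, C, T) -> (U, C)
    with np.errstate(invalid="ignore"):
        terms = y[:, None, :] * log_rho[None] + (1.0 - y[:, None, :]) * log_1mrho[None]
    terms = np.where(obs[:, None, :], terms, 0.0)
    # 0 * -inf would be NaN; an unobserved wave must contribute exactly 0
    terms = np.nan_to_num(terms, nan=0.0, posinf=np.inf, neginf=-np.inf)
    terms = np.where(obs[:, None, :], terms, 0.0)
    return terms.sum(axis=2)


def compute_loglik(params: LCAParams, panel: ResponsePanel) -> float:
    """Observed-data log-likelihood of the panel under ``params``.

    Each child contributes log sum_c pi_c prod_{t observed} Bernoulli(y_t;
    rho_ct); evaluation is in the log domain throughout.
    """
    if panel.n_children == 0:
        raise ValueError("empty panel")
    if params.n_waves != panel.n_waves:
        raise ValueError("params and panel disagree on the number of waves")
    patterns, _, counts = _unique_patterns(panel.values)
    logcomp = _log_components(patterns, params.item_probs)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.class_weights)
    return float(counts @ logsumexp(logcomp + logpi[None, :], axis=1))


def posterior_probs(params: LCAParams, panel: ResponsePanel) -> PosteriorMatrix:
    """Posterior class probabilities by Bayes rule over observed items."""
    if params.n_waves != panel.n_waves:
        raise ValueError("params and panel disagree on the number of waves")
    patterns, inverse, _ = _unique_patterns(panel.values)
    logcomp = _log_components(patterns, params.item_probs)
    with np.errstate(divide="ignore"):
        lw = logcomp + np.log(params.class_weights)[None, :]
    norm = logsumexp(lw, axis=1)
    dead = ~np.isfinite(norm)
    if dead.any():
        bad = panel.child_ids[np.isin(inverse, np.flatnonzero(dead))]
        raise ValueError(
            f"zero likelihood under every class for child(ren) {bad[:5].tolist()}"
        )
    probs = np.exp(lw - norm[:, None])[inverse]
    return PosteriorMatrix(
        probs=probs,
        child_ids=panel.child_ids,
        entropy_quality=relative_entropy_quality(probs),
    )


# ---------------------------------------------------------------------------
# EM


def _em_one_start(
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    rho: np.ndarray,
    tol: float,
    max_iter: int,
    history: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    obs = np.isfinite(patterns)
    y = np.where(obs, patterns, 0.0)
    n = counts.sum()
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        logcomp = _log_components(patterns, rho)
        with np.errstate(divide="ignore"):
            lw = logcomp + np.log(pi)[None, :]
        norm = logsumexp(lw, axis=1)
        new_loglik = float(counts @ norm)
        post = np.exp(lw - norm[:, None])  # (U, C)
        wpost = post * counts[:, None]
        # M-step
        pi = wpost.sum(axis=0) / n
        num = wpost.T @ (y * obs)  # (C, T)
        den = wpost.T @ obs
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(den > 0, num / np.maximum(den, 1e-300), rho)
        rho = np.clip(rho, RHO_CLAMP, 1.0 - RHO_CLAMP)
        if history is not None:
            history.append(new_loglik)
        if np.isfinite(loglik) and new_loglik - loglik < tol * abs(new_loglik):
            converged = True
            break
        loglik = new_loglik
    # report the likelihood at the returned (post M-step) parameters
    logcomp = _log_components(patterns, rho)
    with np.errstate(divide="ignore"):
        lw = logcomp + np.log(pi)[None, :]
    loglik = float(counts @ logsumexp(lw, axis=1))
    return pi, rho, loglik, converged


def em_fit(
    panel: ResponsePanel,
    n_classes: int,
    n_starts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = 0,
    init: LCAParams | None = None,
    canonicalize: bool = True,
    loglik_history: list[list[float]] | None = None,
) -> tuple[LCAParams, PosteriorMatrix]:
    """Fit a C-class LLCA model by EM over multiple random starts.

    Starts draw class weights from a flat Dirichlet and item probabilities
    from Uniform(0.05, 0.95); the best start by final log-likelihood wins.
    Pass ``init`` to add a deterministic warm start (e.g. for reproducible
    refits); item probabilities are clamped to [1e-6, 1-1e-6] to avoid
    degenerate boundary likelihoods.

    Returns the fitted parameters (canonically ordered unless
    ``canonicalize=False``) and the posterior matrix.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if panel.n_children == 0:
        raise ValueError("empty panel")
    if (panel.n_observed_waves() == 0).any():
        raise ValueError("panel contains children with no observed waves")
    patterns, inverse, counts = _unique_patterns(panel.values)
    if n_classes > patterns.shape[0]:
        warnings.warn(
            f"n_classes={n_classes} exceeds the {patterns.shape[0]} distinct "
            "response patterns; the model is not identified",
            stacklevel=2,
        )
    t = panel.n_waves

    if n_classes == 1:
        # closed form: weight 1, rho_t = observed mean
        obs = np.isfinite(panel.values)
        rho = np.where(
            obs.sum(axis=0) > 0,
            np.nansum(panel.values, axis=0) / np.maximum(obs.sum(axis=0), 1),
            0.5,
        )[None, :]
        rho = np.clip(rho, RHO_CLAMP, 1.0 - RHO_CLAMP)
        params = LCAParams(
            class_weights=np.array([1.0]),
            item_probs=rho,
            converged=True,
            n_children=panel.n_children,
        )
        params.loglik = compute_loglik(params, panel)
        return params, posterior_probs(params, panel)

    rng = np.random.default_rng(seed)
    start_inits: list[tuple[np.ndarray, np.ndarray]] = []
    if init is not None:
        start_inits.append(
            (init.class_weights.copy(), np.clip(init.item_probs, RHO_CLAMP, 1 - RHO_CLAMP))
        )
    for _ in range(n_starts):
        start_inits.append(
            (
                rng.dirichlet(np.ones(n_classes)),
                rng.uniform(0.05, 0.95, size=(n_classes, t)),
            )
        )

    best: tuple[np.ndarray, np.ndarray, float, bool] | None = None
    for pi0, rho0 in start_inits:
        hist: list[float] | None = [] if loglik_history is not None else None
        result = _em_one_start(patterns, counts, pi0, rho0, tol, max_iter, hist)
        if loglik_history is not None:
            loglik_history.append(hist)  # type: ignore[arg-type]
        if best is None or result[2] > best[2]:
            best = result
    assert best is not None
    pi, rho, loglik, converged = best
    params = LCAParams(
        class_weights=pi / pi.sum(),
        item_probs=rho,
        loglik=loglik,
        converged=converged,
        n_children=panel.n_children,
    )
    if canonicalize:
        params = canonical_order(params)
    return params, posterior_probs(params, panel)


# ---------------------------------------------------------------------------
# label switching


def _canonical_permutation(params: LCAParams) -> np.ndarray:
    """Sort key: mean item probability ascending, then onset wave, then weight.

    The class with the lowest overall symptom probability comes first and is
    the "normative" class.  Near-ties in overall level are resolved by the
    wave at which the profile first crosses 0.5 (early onset sorts before
    late onset), then by class weight descending.
    """
    mean_rho = params.item_probs.mean(axis=1)
    crossing = np.array(
        [
            int(np.argmax(row > 0.5)) if (row > 0.5).any() else params.n_waves
            for row in params.item_probs
        ]
    )
    # round the primary key so that profiles with equal overall burden but
    # different timing are ordered by onset, not by rounding noise
    key = np.round(mean_rho, 10)
    order = np.lexsort((-params.class_weights, crossing, key))
    return order


def canonical_order(params: LCAParams) -> LCAParams:
    """Return an equivalent model with classes in canonical order."""
    order = _canonical_permutation(params)
    return replace(
        params,
        class_weights=params.class_weights[order],
        item_probs=params.item_probs[order],
    )


def label_classes(params: LCAParams) -> list[str]:
    """Descriptive names for a canonically ordered 4-class fit.

    Class 0 is "normative"; the remaining classes are named by profile
    shape: "early" if the first half of the profile dominates, "late" if
    the second half dominates, "persistent" for the class with the highest
    overall probability.  For other class counts, generic names are used.
    """
    if params.n_classes != 4:
        return [f"class{i + 1}" for i in range(params.n_classes)]
    names = [""] * 4
    names[0] = "normative"
    rest = [1, 2, 3]
    means = params.item_probs.mean(axis=1)
    persistent = max(rest, key=lambda i: means[i])
    names[persistent] = "persistent"
    rest.remove(persistent)
    t = params.n_waves
    half = t // 2
    for i in rest:
        early_mean = params.item_probs[i, :half].mean()
        late_mean = params.item_probs[i, t - half :].mean()
        names[i] = "early" if early_mean >= late_mean else "late"
    if names.count("early") == 2 or names.count("late") == 2:
        # fall back to onset ordering if both middle classes lean one way
        a, b = [i for i in range(4) if names[i] in ("early", "late")]
        names[a], names[b] = "early", "late"
    return names


# ---------------------------------------------------------------------------
# class enumeration


def enumerate_classes(
    panel: ResponsePanel,
    c_min: int = 1,
    c_max: int = 6,
    n_starts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = 0,
):
    """Model-comparison table over a range of class counts.

    Returns a DataFrame with one row per C holding the log-likelihood,
    parameter count, BIC = -2 loglik + k log n, AIC, entropy-based
    classification quality and smallest class share; the BIC-minimising
    row is flagged.
    """
    import pandas as pd

    if c_min < 1:
        raise ValueError("c_min must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for c, child_seed in zip(
        range(c_min, c_max + 1), ss.spawn(c_max - c_min + 1)
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, post = em_fit(
                panel,
                c,
                n_starts=n_starts,
                tol=tol,
                max_iter=max_iter,
                seed=child_seed.generate_state(1)[0] % (2**31),
            )
        n = params.n_children
        rows.append(
            {
                "n_classes": c,
                "loglik": params.loglik,
                "n_params": params.n_params,
                "bic": -2.0 * params.loglik + params.n_params * np.log(n),
                "aic": -2.0 * params.loglik + 2.0 * params.n_params,
                "entropy": post.entropy_quality,
                "min_class_share": float(params.class_weights.min()),
                "converged": params.converged,
            }
        )
    table = pd.DataFrame(rows)
    table["best_bic"] = table["bic"] == table["bic"].min()
    return table
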