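"""Parallel-process latent class model linking soiling and constipation.

Two latent class variables — one per symptom process, each with four
classes — are measured by their own repeated binary indicators and linked
only through their 4x4 joint membership distribution pi_ab.  Given the
class pair (a, b), soiling items depend only on a and constipation items
only on b, and all items are conditionally independent.  The model is a
16-component finite mixture fitted by EM; missing items are skipped as in
the single-process model.

Initialisation includes a "warm start" built from the two single-process
fits (product-of-marginals joint weights, single-fit measurement
parameters) plus random starts.  Because the warm start reproduces the two
independent fits exactly, the fitted joint log-likelihood can never fall
below the sum of the single-process log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import lca
from .calibration import CONSTIPATION_CLASS_NAMES, SOILING_CLASS_NAMES
from .lca import LCAParams, RHO_CLAMP, _log_components, _unique_patterns
from .panel import ResponsePanel

__all__ = ["ParallelLCAParams", "JointPosterior", "fit_parallel", "joint_class_table"]


@dataclass
class ParallelLCAParams:
    """Fitted parameters of the 4x4 parallel-process model."""

    joint_weights: np.ndarray  # (A, B): soiling class x constipation class
    soiling_item_probs: np.ndarray  # (A, T_s)
    constipation_item_probs: np.ndarray  # (B, T_c)
    loglik: float = np.nan
    converged: bool = False
    n_children: int = 0

    def __post_init__(self) -> None:
        self.joint_weights = np.asarray(self.joint_weights, dtype=float)
        if (self.joint_weights < -1e-12).any():
            raise ValueError("joint weights must be non-negative")
        if not np.isclose(self.joint_weights.sum(), 1.0, atol=1e-8):
            raise ValueError("joint weights must sum to 1")

    @property
    def n_params(self) -> int:
        a, b = self.joint_weights.shape
        return (a * b - 1) + self.soiling_item_probs.size + self.constipation_item_probs.size

    @property
    def soiling_marginal(self) -> LCAParams:
        """Implied single-process soiling model (row sums of the joint)."""
        return LCAParams(
            class_weights=self.joint_weights.sum(axis=1),
            item_probs=self.soiling_item_probs,
            n_children=self.n_children,
        )

    @property
    def constipation_marginal(self) -> LCAParams:
        """Implied single-process constipation model (column sums)."""
        return LCAParams(
            class_weights=self.joint_weights.sum(axis=0),
            item_probs=self.constipation_item_probs,
            n_children=self.n_children,
        )


@dataclass
class JointPosterior:
    """Posterior over the 16 joint cells; cell index = 4*a + b."""

    probs: np.ndarray  # (n, A*B)
    child_ids: np.ndarray
    n_soiling: int = 4
    n_constipation: int = 4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("joint posterior rows must sum to 1")

    def soiling_posterior(self) -> np.ndarray:
        """Marginal posterior over soiling classes (sum over b)."""
        n = self.probs.shape[0]
        return self.probs.reshape(n, self.n_soiling, self.n_constipation).sum(axis=2)

    def constipation_posterior(self) -> np.ndarray:
        """Marginal posterior over constipation classes (sum over a)."""
        n = self.probs.shape[0]
        return self.probs.reshape(n, self.n_soiling, self.n_constipation).sum(axis=1)


def _em_parallel(
    pat_s, pat_c, counts, pi_ab, rho_s, rho_c, tol, max_iter
):
    """EM on weighted unique (soiling pattern, constipation pattern) pairs."""
    a, b = pi_ab.shape
    obs_s = np.isfinite(pat_s)
    y_s = np.where(obs_s, pat_s, 0.0)
    obs_c = np.isfinite(pat_c)
    y_c = np.where(obs_c, pat_c, 0.0)
    n = counts.sum()
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        ls = _log_components(pat_s, rho_s)  # (U, A)
        lc = _log_components(pat_c, rho_c)  # (U, B)
        with np.errstate(divide="ignore"):
            lw = ls[:, :, None] + lc[:, None, :] + np.log(pi_ab)[None, :, :]
        lw = lw.reshape(lw.shape[0], a * b)
        norm = logsumexp(lw, axis=1)
        new_loglik = float(counts @ norm)
        post = np.exp(lw - norm[:, None]).reshape(-1, a, b)
        wpost = post * counts[:, None, None]
        pi_ab = wpost.sum(axis=0) / n
        pa = wpost.sum(axis=2)  # (U, A)
        pb = wpost.sum(axis=1)  # (U, B)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_s = (pa.T @ (y_s * obs_s)) / np.maximum(pa.T @ obs_s, 1e-300)
            rho_c = (pb.T @ (y_c * obs_c)) / np.maximum(pb.T @ obs_c, 1e-300)
        rho_s = np.clip(rho_s, RHO_CLAMP, 1 - RHO_CLAMP)
        rho_c = np.clip(rho_c, RHO_CLAMP, 1 - RHO_CLAMP)
        if np.isfinite(loglik) and new_loglik - loglik < tol * abs(new_loglik):
            converged = True
            break
        loglik = new_loglik
    ls = _log_components(pat_s, rho_s)
    lc = _log_components(pat_c, rho_c)
    with np.errstate(divide="ignore"):
        lw = (ls[:, :, None] + lc[:, None, :] + np.log(pi_ab)[None, :, :]).reshape(
            -1, a * b
        )
    loglik = float(counts @ logsumexp(lw, axis=1))
    return pi_ab, rho_s, rho_c, loglik, converged


def fit_parallel(
    panel_soiling: ResponsePanel,
    panel_constipation: ResponsePanel,
    n_classes: int = 4,
    n_starts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | None = 0,
    single_starts: int = 10,
) -> tuple[ParallelLCAParams, JointPosterior]:
    """Fit the parallel-process model by EM.

    The two panels must cover the same children in the same order (apply
    the both-process inclusion filter first).  ``n_starts`` counts the
    random starts added on top of the warm start from the single-process
    fits; measurement parameters are re-estimated jointly, the warm start
    only seeds them.

    Returns canonically ordered parameters (normative class first in each
    process) and the per-child posterior over the 16 joint cells.
    """
    if not np.array_equal(panel_soiling.child_ids, panel_constipation.child_ids):
        raise ValueError("panels must cover the same children in the same order")
    if panel_soiling.n_children == 0:
        raise ValueError("empty panels")
    c = n_classes
    ss = np.random.SeedSequence(seed)
    seed_s, seed_c, seed_r = (s.generate_state(1)[0] % (2**31) for s in ss.spawn(3))

    # warm start from the two single-process fits
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params_s, _ = lca.em_fit(panel_soiling, c, n_starts=single_starts, seed=seed_s)
        params_c, _ = lca.em_fit(panel_constipation, c, n_starts=single_starts, seed=seed_c)

    joint_values = np.hstack([panel_soiling.values, panel_constipation.values])
    patterns, inverse, counts = _unique_patterns(joint_values)
    t_s = panel_soiling.n_waves
    pat_s, pat_c = patterns[:, :t_s], patterns[:, t_s:]

    starts = [
        (
            np.outer(params_s.class_weights, params_c.class_weights),
            np.clip(params_s.item_probs, RHO_CLAMP, 1 - RHO_CLAMP),
            np.clip(params_c.item_probs, RHO_CLAMP, 1 - RHO_CLAMP),
        )
    ]
    rng = np.random.default_rng(seed_r)
    for _ in range(n_starts):
        starts.append(
            (
                rng.dirichlet(np.ones(c * c)).reshape(c, c),
                rng.uniform(0.05, 0.95, size=(c, t_s)),
                rng.uniform(0.05, 0.95, size=(c, panel_constipation.n_waves)),
            )
        )

    best = None
    for pi0, rs0, rc0 in starts:
        result = _em_parallel(pat_s, pat_c, counts, pi0, rs0, rc0, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
    pi_ab, rho_s, rho_c, loglik, converged = best

    # canonicalise each process through the implied marginal models
    order_s = lca._canonical_permutation(
        LCAParams(class_weights=pi_ab.sum(axis=1), item_probs=rho_s)
    )
    order_c = lca._canonical_permutation(
        LCAParams(class_weights=pi_ab.sum(axis=0), item_probs=rho_c)
    )
    pi_ab = pi_ab[np.ix_(order_s, order_c)]
    rho_s, rho_c = rho_s[order_s], rho_c[order_c]

    params = ParallelLCAParams(
        joint_weights=pi_ab / pi_ab.sum(),
        soiling_item_probs=rho_s,
        constipation_item_probs=rho_c,
        loglik=loglik,
        converged=converged,
        n_children=panel_soiling.n_children,
    )

    ls = _log_components(pat_s, rho_s)
    lc_ = _log_components(pat_c, rho_c)
    with np.errstate(divide="ignore"):
        lw = (ls[:, :, None] + lc_[:, None, :] + np.log(pi_ab)[None, :, :]).reshape(
            -1, c * c
        )
    norm = logsumexp(lw, axis=1)
    probs = np.exp(lw - norm[:, None])[inverse]
    posterior = JointPosterior(
        probs=probs,
        child_ids=panel_soiling.child_ids,
        n_soiling=c,
        n_constipation=c,
    )
    return params, posterior


def joint_class_table(params: ParallelLCAParams) -> pd.DataFrame:
    """The joint class distribution as percentages with row/column totals.

    Rows are constipation classes, columns soiling classes (the published
    presentation); cells are pi_ab x 100 with a grand total of 100.
    Rounding to one decimal happens at display time, in the report.
    """
    pct = params.joint_weights.T * 100.0  # transpose: constipation rows
    a = pct.shape[1]
    table = pd.DataFrame(
        pct,
        index=CONSTIPATION_CLASS_NAMES[: pct.shape[0]],
        columns=SOILING_CLASS_NAMES[:a],
    )
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
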