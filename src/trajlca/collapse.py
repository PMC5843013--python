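"""Collapse of the 4x4 joint trajectory classes into 4 composite clinical groups.

With the normative class identified in each process (canonical class 0),
the 16 joint (soiling, constipation) cells collapse deterministically:

* (normative, normative)          -> normative                      (1 cell)
* (normative, non-normative)      -> constipation alone             (3 cells)
* (non-normative, normative)      -> soiling alone                  (3 cells)
* (non-normative, non-normative)  -> constipation with soiling      (9 cells)

The module also provides the descriptive statistics built on the composite
groups: posterior-weighted symptom rates, the soiler split, the overall
constipation prevalence and the nested-sample prevalence table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import COMPOSITE_CLASS_NAMES
from .panel import ResponsePanel

__all__ = [
    "CompositeMap",
    "CompositePosterior",
    "collapse_posterior",
    "composite_proportions",
    "soiler_split",
    "any_constipation_prevalence",
    "symptom_rates_by_class",
    "marginal_prevalence_table",
    "prevalence_percent",
    "format_percent_cell",
]


@dataclass
class CompositeMap:
    """Mapping from joint cell (a, b) to composite group index 0..3.

    ``a`` indexes the soiling class and ``b`` the constipation class, both
    canonically ordered so index 0 is the normative class.
    """

    n_soiling: int = 4
    n_constipation: int = 4
    labels: list[str] = field(default_factory=lambda: list(COMPOSITE_CLASS_NAMES))

    def composite_index(self, a: int, b: int) -> int:
        if not (0 <= a < self.n_soiling and 0 <= b < self.n_constipation):
            raise ValueError(f"joint cell ({a}, {b}) outside the class grid")
        if a == 0 and b == 0:
            return 0
        if a == 0:
            return 1  # constipation alone
        if b == 0:
            return 2  # soiling alone
        return 3  # constipation with soiling

    def as_matrix(self) -> np.ndarray:
        """(n_soiling, n_constipation) integer matrix of composite indices."""
        return np.array(
            [
                [self.composite_index(a, b) for b in range(self.n_constipation)]
                for a in range(self.n_soiling)
            ]
        )

    def indicator(self) -> np.ndarray:
        """(cells, 4) 0/1 matrix mapping flattened joint cells to groups."""
        m = self.as_matrix().ravel()
        out = np.zeros((m.size, 4))
        out[np.arange(m.size), m] = 1.0
        return out


@dataclass
class CompositePosterior:
    """Per-child probabilities over the four composite clinical groups."""

    probs: np.ndarray  # (n, 4)
    child_ids: np.ndarray
    labels: list[str] = field(default_factory=lambda: list(COMPOSITE_CLASS_NAMES))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("composite posterior must be children x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("composite posterior rows must sum to 1")

    @property
    def composite_weights(self) -> np.ndarray:
        """Estimated composite-group shares (column means of the posterior)."""
        return self.probs.mean(axis=0)

    @property
    def modal_labels(self) -> np.ndarray:
        """Modal group index per child; ties break toward the less severe group."""
        # argmax returns the first maximiser, and the group order
        # (normative, constipation alone, soiling alone, both) is already
        # sorted from least to most severe
        return np.argmax(self.probs, axis=1)


def collapse_posterior(joint_probs, child_ids=None, cmap: CompositeMap | None = None) -> CompositePosterior:
    """Sum joint-cell posterior probabilities into composite-group probabilities.

    ``joint_probs`` is (n_children, 16) with cells flattened soiling-major
    (cell index = 4*a + b), or an object with a ``probs`` attribute of that
    shape (a JointPosterior).
    """
    if hasattr(joint_probs, "probs"):
        if child_ids is None:
            child_ids = joint_probs.child_ids
        joint_probs = joint_probs.probs
    joint_probs = np.asarray(joint_probs, dtype=float)
    cmap = cmap or CompositeMap()
    ind = cmap.indicator()
    if joint_probs.shape[1] != ind.shape[0]:
        raise ValueError(
            f"joint posterior has {joint_probs.shape[1]} cells but the map "
            f"covers {ind.shape[0]}"
        )
    if child_ids is None:
        child_ids = np.arange(joint_probs.shape[0])
    return CompositePosterior(
        probs=joint_probs @ ind, child_ids=np.asarray(child_ids), labels=cmap.labels
    )


def composite_proportions(joint_weights, cmap: CompositeMap | None = None) -> np.ndarray:
    """Collapse a 4x4 joint table (probabilities or percentages) to 4 shares.

    The output is on the same scale as the input and ordered (normative,
    constipation alone, soiling alone, constipation with soiling); mass is
    conserved exactly.
    """
    w = np.asarray(joint_weights, dtype=float)
    if w.shape != (4, 4):
        raise ValueError("joint weights must be a 4x4 table")
    cmap = cmap or CompositeMap()
    return w.ravel() @ cmap.indicator()


def soiler_split(composite) -> tuple[int, int]:
    """Percent split of soilers into soiling-alone vs with-constipation.

    Returns integer percentages (soiling_alone_share, with_constipation_share)
    among children in either soiling group.
    """
    c = np.asarray(composite, dtype=float)
    alone, with_con = c[2], c[3]
    total = alone + with_con
    if total <= 0:
        raise ValueError("no mass in either soiling group; split undefined")
    share = int(round(100.0 * alone / total))
    return share, 100 - share


def any_constipation_prevalence(composite) -> float:
    """Overall constipation prevalence: constipation alone + with soiling."""
    c = np.asarray(composite, dtype=float)
    return float(c[1] + c[3])


def symptom_rates_by_class(
    composite: CompositePosterior, symptom: np.ndarray
) -> np.ndarray:
    """Posterior-weighted symptom rate within each composite group.

    ``symptom`` is a per-child binary indicator aligned with the posterior;
    NaN entries are dropped from both numerator and denominator.  A group
    with no posterior mass among observed children gets NaN.
    """
    y = np.asarray(symptom, dtype=float)
    if y.shape[0] != composite.probs.shape[0]:
        raise ValueError("symptom vector must align with the posterior rows")
    obs = np.isfinite(y)
    p = composite.probs[obs]
    denom = p.sum(axis=0)
    num = p.T @ y[obs]
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)


# ---------------------------------------------------------------------------
# prevalence tables


def prevalence_percent(n_with: float, n_without: float) -> float:
    """Percent with symptom among respondents, to one decimal place."""
    total = n_with + n_without
    if total <= 0:
        return np.nan
    return round(100.0 * n_with / total, 1)


def marginal_prevalence_table(
    panel_soiling: ResponsePanel, panel_constipation: ResponsePanel
) -> pd.DataFrame:
    """Per-wave symptom prevalence for the three nested analytic samples.

    The samples are: at least one non-missing wave on both processes, at
    least three non-missing waves on both, and complete data on all waves.
    Returns long-format rows (sample, process, wave_index, wave_label,
    n_observed, n_with_symptom, percent).
    """
    ns = panel_soiling.n_observed_waves()
    nc = panel_constipation.n_observed_waves()
    samples = {
        "ge1_both": (ns >= 1) & (nc >= 1),
        "ge3_both": (ns >= 3) & (nc >= 3),
        "complete": (ns == panel_soiling.n_waves) & (nc == panel_constipation.n_waves),
    }
    rows = []
    for sample, mask in samples.items():
        for panel in (panel_soiling, panel_constipation):
            vals = panel.values[mask]
            for t in range(panel.n_waves):
                col = vals[:, t]
                observed = np.isfinite(col)
                n_obs = int(observed.sum())
                n_with = int(np.nansum(col))
                rows.append(
                    {
                        "sample": sample,
                        "process": panel.process_name,
                        "wave_index": t,
                        "wave_label": panel.wave_labels[t],
                        "n_observed": n_obs,
                        "n_with_symptom": n_with,
                        "percent": prevalence_percent(n_with, n_obs - n_with),
                    }
                )
    return pd.DataFrame(rows)


def format_percent_cell(value: float) -> str:
    """Render a class percentage, masking near-zero estimates as "<0.1"."""
    if 0.0 < value < 0.05:
        return "<0.1"
    return f"{value:.1f}"
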