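"""Synthetic ALSPAC-like cohort generator with known latent structure.

Children receive a (soiling class, constipation class) pair from a 4x4
joint distribution; the binary symptom indicators at each wave are then
independent Bernoulli draws from class-specific profiles.  Covariates can
tilt class membership through a multinomial-logit model on the four
*composite* clinical groups (normative reference): given the composite
group, the joint cell is drawn with the within-group cell proportions of
the base joint weights.  Missingness is wave-wise missing-completely-at-
random with an optional monotone geometric dropout process.

Defaults reproduce the published ALSPAC study conditions: the joint class
distribution, well-separated trajectory profiles, an analytic sample of
8435 children, and covariate effects on the odds-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import calibration
from .calibration import COMPOSITE_CLASS_NAMES
from .collapse import CompositeMap
from .panel import ResponsePanel

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "TrueLabels",
    "SyntheticCohort",
    "generate_cohort",
    "apply_missingness",
]


@dataclass
class CovariateSpec:
    """One simulated covariate and its per-composite-class effects.

    Parameters
    ----------
    name
        Column name in the covariate table.
    kind
        ``"binary"`` (0/1 with given prevalence), ``"categorical"``
        (levels drawn from ``level_probs``; the first level is the
        reference) or ``"continuous"`` (standard normal, 1-SD units).
    prevalence
        P(covariate = 1) for binary covariates.
    levels, level_probs
        Level names and marginal probabilities for categorical covariates.
    effects
        Log-odds effects on composite-class membership, reference class
        (normative) fixed at 0.  Shape: (4,) for binary/continuous, or
        (n_levels - 1, 4) for categorical (one row per non-reference
        level).  All zeros means no association.
    """

    name: str
    kind: str = "binary"
    prevalence: float = 0.5
    levels: list[str] = field(default_factory=list)
    level_probs: list[float] = field(default_factory=list)
    effects: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if not np.isfinite(self.effects).all():
            raise ValueError(f"covariate {self.name!r} has non-finite effects")
        if self.effects.shape[1] != 4:
            raise ValueError("effects must have one column per composite class")
        if not np.all(self.effects[:, 0] == 0.0):
            raise ValueError("reference (normative) class effects must be 0")
        if self.kind == "categorical":
            if len(self.levels) != len(self.level_probs) or len(self.levels) < 2:
                raise ValueError("categorical covariates need matching levels/probs")
            if not np.isclose(sum(self.level_probs), 1.0, atol=1e-8):
                raise ValueError("level_probs must sum to 1")
            if self.effects.shape[0] != len(self.levels) - 1:
                raise ValueError("need one effects row per non-reference level")
        elif self.effects.shape[0] != 1:
            raise ValueError("binary/continuous covariates take a single effects row")

    def design_columns(self, x: np.ndarray) -> np.ndarray:
        """Expand the drawn covariate into its design-matrix columns."""
        if self.kind == "categorical":
            return np.column_stack(
                [(x == lvl).astype(float) for lvl in range(1, len(self.levels))]
            )
        return np.asarray(x, dtype=float)[:, None]

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "binary":
            return (rng.random(n) < self.prevalence).astype(float)
        if self.kind == "continuous":
            return rng.standard_normal(n)
        return rng.choice(len(self.levels), size=n, p=self.level_probs)


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_children: int = 8435
    joint_class_weights: np.ndarray = field(
        default_factory=calibration.default_joint_weights
    )
    soiling_profiles: np.ndarray = field(
        default_factory=calibration.well_separated_soiling_profiles
    )
    constipation_profiles: np.ndarray = field(
        default_factory=calibration.well_separated_constipation_profiles
    )
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    response_prob: float | np.ndarray = 1.0  # per-wave probability of response
    dropout_hazard: float = 0.0  # per-wave monotone dropout hazard
    seed: int = 0

    def __post_init__(self) -> None:
        self.joint_class_weights = np.asarray(self.joint_class_weights, dtype=float)
        self.soiling_profiles = np.asarray(self.soiling_profiles, dtype=float)
        self.constipation_profiles = np.asarray(self.constipation_profiles, dtype=float)
        self.validate()

    def validate(self) -> None:
        w = self.joint_class_weights
        if w.shape != (4, 4):
            raise ValueError("joint_class_weights must be 4x4")
        if (w < 0).any():
            raise ValueError("joint_class_weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("joint_class_weights must sum to 1 (within 1e-12)")
        for name, prof, ncls in (
            ("soiling_profiles", self.soiling_profiles, 4),
            ("constipation_profiles", self.constipation_profiles, 4),
        ):
            if prof.ndim != 2 or prof.shape[0] != ncls:
                raise ValueError(f"{name} must have {ncls} rows")
            if ((prof < 0) | (prof > 1)).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        rp = np.asarray(self.response_prob, dtype=float)
        if ((rp < 0) | (rp > 1)).any():
            raise ValueError("response_prob must lie in [0, 1]")
        if not 0.0 <= self.dropout_hazard <= 1.0:
            raise ValueError("dropout_hazard must lie in [0, 1]")
        if self.n_children < 1:
            raise ValueError("n_children must be positive")

    # -- plain-text round trip ---------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_children": int(self.n_children),
            "joint_class_weights": self.joint_class_weights.tolist(),
            "soiling_profiles": self.soiling_profiles.tolist(),
            "constipation_profiles": self.constipation_profiles.tolist(),
            "response_prob": np.asarray(self.response_prob).tolist(),
            "dropout_hazard": float(self.dropout_hazard),
            "seed": int(self.seed),
            "covariates": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "prevalence": float(s.prevalence),
                    "levels": list(s.levels),
                    "level_probs": [float(p) for p in s.level_probs],
                    "effects": s.effects.tolist(),
                }
                for s in self.covariate_specs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {
            "n_children",
            "joint_class_weights",
            "soiling_profiles",
            "constipation_profiles",
            "response_prob",
            "dropout_hazard",
            "seed",
            "covariates",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        specs = [
            CovariateSpec(
                name=c["name"],
                kind=c.get("kind", "binary"),
                prevalence=c.get("prevalence", 0.5),
                levels=c.get("levels", []),
                level_probs=c.get("level_probs", []),
                effects=np.asarray(c.get("effects", np.zeros(4))),
            )
            for c in doc.pop("covariates", [])
        ]
        return cls(covariate_specs=specs, **doc)


@dataclass
class TrueLabels:
    """Ground-truth class assignments for a synthetic cohort (0-based)."""

    soiling_class: np.ndarray
    constipation_class: np.ndarray
    composite_class: np.ndarray
    child_ids: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "child_id": self.child_ids,
                "soiling_class": self.soiling_class,
                "constipation_class": self.constipation_class,
                "composite_class": self.composite_class,
                "composite_label": [
                    COMPOSITE_CLASS_NAMES[k] for k in self.composite_class
                ],
            }
        )


@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`."""

    soiling: ResponsePanel
    constipation: ResponsePanel
    covariates: pd.DataFrame
    labels: TrueLabels


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a fully observed cohort from the generator model.

    With all covariate effects zero, the (soiling, constipation) pair is a
    straight draw from ``joint_class_weights``.  With non-zero effects the
    composite group is drawn from a multinomial logit whose intercepts are
    the log base shares (so effects = 0 recovers the base distribution),
    and the joint cell is then drawn conditional on the group using the
    within-group cell proportions of the base weights.  Reproducible given
    ``config.seed``; apply :func:`apply_missingness` afterwards.
    """
    config.validate()
    n = config.n_children
    rng = np.random.default_rng(config.seed)
    cmap = CompositeMap()
    cell_to_comp = cmap.as_matrix().ravel()  # (16,) flattened soiling-major
    w = config.joint_class_weights.ravel()
    base_comp = np.array([w[cell_to_comp == k].sum() for k in range(4)])

    # covariates and design
    cov_values = {s.name: s.draw(n, rng) for s in config.covariate_specs}
    design_blocks = [
        s.design_columns(cov_values[s.name]) for s in config.covariate_specs
    ]
    effect_blocks = [s.effects for s in config.covariate_specs]

    any_effects = any(np.any(e != 0.0) for e in effect_blocks)
    if any_effects:
        with np.errstate(divide="ignore"):
            eta = np.tile(np.log(base_comp), (n, 1))  # zero-mass group stays at 0
        for x_cols, eff in zip(design_blocks, effect_blocks):
            eta += x_cols @ eff
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        composite = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    else:
        composite = rng.choice(4, size=n, p=base_comp)

    # joint cell conditional on composite group
    cell = np.empty(n, dtype=int)
    for k in range(4):
        idx = np.flatnonzero(composite == k)
        if idx.size == 0:
            continue
        cells_k = np.flatnonzero(cell_to_comp == k)
        probs_k = w[cells_k] / w[cells_k].sum()
        cell[idx] = rng.choice(cells_k, size=idx.size, p=probs_k)
    a, b = cell // 4, cell % 4

    soiling_values = (
        rng.random((n, config.soiling_profiles.shape[1]))
        < config.soiling_profiles[a]
    ).astype(float)
    constipation_values = (
        rng.random((n, config.constipation_profiles.shape[1]))
        < config.constipation_profiles[b]
    ).astype(float)

    child_ids = np.arange(n)
    covariates = pd.DataFrame({"child_id": child_ids})
    for s in config.covariate_specs:
        x = cov_values[s.name]
        covariates[s.name] = (
            pd.Categorical.from_codes(x.astype(int), categories=s.levels)
            if s.kind == "categorical"
            else x
        )

    return SyntheticCohort(
        soiling=ResponsePanel(
            soiling_values,
            child_ids,
            "soiling",
            list(calibration.SOILING_WAVE_LABELS[: soiling_values.shape[1]]),
        ),
        constipation=ResponsePanel(
            constipation_values,
            child_ids,
            "constipation",
            list(calibration.CONSTIPATION_WAVE_LABELS[: constipation_values.shape[1]]),
        ),
        covariates=covariates,
        labels=TrueLabels(
            soiling_class=a,
            constipation_class=b,
            composite_class=composite,
            child_ids=child_ids,
        ),
    )


def apply_missingness(
    panel: ResponsePanel,
    response_prob: float | np.ndarray = 1.0,
    dropout_hazard: float = 0.0,
    seed: int | None = 0,
) -> ResponsePanel:
    """Impose MCAR wave-wise missingness plus monotone geometric dropout.

    Each wave is independently unobserved with probability
    ``1 - response_prob`` (scalar or per-wave).  Dropout then censors each
    child from a random wave onward: from wave 1, each successive wave is
    the dropout point with probability ``dropout_hazard``.  Missingness is
    independent of latent class and responses.
    """
    values = panel.values.copy()
    n, t = values.shape
    rp = np.broadcast_to(np.asarray(response_prob, dtype=float), (t,))
    if ((rp < 0) | (rp > 1)).any():
        raise ValueError("response_prob must lie in [0, 1]")
    if not 0.0 <= dropout_hazard <= 1.0:
        raise ValueError("dropout_hazard must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    miss = rng.random((n, t)) >= rp[None, :]
    if dropout_hazard > 0:
        # geometric first-failure over wave transitions 1..t-1
        u = rng.random((n, t - 1)) < dropout_hazard
        dropped = np.concatenate(
            [np.zeros((n, 1), dtype=bool), np.cumsum(u, axis=1) > 0], axis=1
        )
        miss |= dropped
    values[miss] = np.nan
    return replace(panel, values=values)


def apply_missingness_from_config(
    panel: ResponsePanel, config: GeneratorConfig, seed: int | None = None
) -> ResponsePanel:
    """Convenience wrapper using the config's missingness settings."""
    return apply_missingness(
        panel,
        response_prob=config.response_prob,
        dropout_hazard=config.dropout_hazard,
        seed=config.seed + 1 if seed is None else seed,
    )
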