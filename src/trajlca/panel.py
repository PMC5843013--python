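"""Repeated binary symptom panels with missing data.

A :class:`ResponsePanel` holds one symptom process (e.g. soiling or
constipation) as a children x waves matrix of {0, 1, missing} indicators.
Missing entries are NaN internally and empty fields in delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ResponsePanel",
    "apply_inclusion_filter",
    "apply_inclusion_filter_pair",
    "align_panels",
    "read_panel",
    "write_panel",
]


@dataclass
class ResponsePanel:
    """Per-child binary indicators for one process across waves.

    Parameters
    ----------
    values
        Float array of shape (n_children, n_waves) with entries 0.0, 1.0
        or NaN (missing).
    child_ids
        Integer or string identifiers, one per row.
    process_name
        Label such as ``"soiling"`` or ``"constipation"``.
    wave_labels
        Display-only age labels, one per wave.
    """

    values: np.ndarray
    child_ids: np.ndarray
    process_name: str = "process"
    wave_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D children x waves array")
        self.child_ids = np.asarray(self.child_ids)
        if self.child_ids.shape[0] != self.values.shape[0]:
            raise ValueError("child_ids length must match number of rows")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("panel values must be 0, 1 or missing")
        if not self.wave_labels:
            self.wave_labels = [f"wave{t}" for t in range(self.n_waves)]
        if len(self.wave_labels) != self.n_waves:
            raise ValueError("wave_labels length must match number of waves")

    @property
    def n_children(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return np.isfinite(self.values)

    def n_observed_waves(self) -> np.ndarray:
        """Number of non-missing waves per child."""
        return self.observed.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "ResponsePanel":
        """Return the panel restricted to children selected by ``mask``."""
        return replace(self, values=self.values[mask], child_ids=self.child_ids[mask])


def apply_inclusion_filter(panel: ResponsePanel, min_waves: int = 3) -> ResponsePanel:
    """Retain children observed at ``min_waves`` or more waves.

    This is the single-process analogue of the cohort inclusion rule; use
    :func:`apply_inclusion_filter_pair` when both processes must qualify.
    """
    if min_waves > panel.n_waves:
        raise ValueError(
            f"min_waves={min_waves} exceeds the {panel.n_waves} waves in the panel"
        )
    return panel.subset(panel.n_observed_waves() >= min_waves)


def apply_inclusion_filter_pair(
    panel_a: ResponsePanel, panel_b: ResponsePanel, min_waves: int = 3
) -> tuple[ResponsePanel, ResponsePanel]:
    """Retain children with >= ``min_waves`` observed waves on *both* processes."""
    if min_waves > panel_a.n_waves or min_waves > panel_b.n_waves:
        raise ValueError("min_waves exceeds the number of waves in a panel")
    if not np.array_equal(panel_a.child_ids, panel_b.child_ids):
        raise ValueError("panels must cover the same children in the same order")
    keep = (panel_a.n_observed_waves() >= min_waves) & (
        panel_b.n_observed_waves() >= min_waves
    )
    return panel_a.subset(keep), panel_b.subset(keep)


def align_panels(
    panel_a: ResponsePanel, panel_b: ResponsePanel
) -> tuple[ResponsePanel, ResponsePanel]:
    """Restrict two panels to their common children, ordered identically."""
    common, ia, ib = np.intersect1d(
        panel_a.child_ids, panel_b.child_ids, return_indices=True
    )
    if common.size == 0:
        raise ValueError("panels share no child ids")
    return panel_a.subset(ia), panel_b.subset(ib)


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_panel(panel: ResponsePanel, path, format: str = "long") -> None:
    """Write a panel as comma-separated text (missing values as empty fields)."""
    if format == "long":
        n, t = panel.values.shape
        df = pd.DataFrame(
            {
                "child_id": np.repeat(panel.child_ids, t),
                "process": panel.process_name,
                "wave_index": np.tile(np.arange(t), n),
                "value": panel.values.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.0f")
    elif format == "wide":
        df = pd.DataFrame(
            panel.values, columns=[f"w{t}" for t in range(panel.n_waves)]
        )
        df.insert(0, "child_id", panel.child_ids)
        df.to_csv(path, index=False, float_format="%.0f")
    else:
        raise ValueError(f"unknown panel format {format!r}")


def read_panel(
    path,
    format: str = "long",
    process_name: str | None = None,
    wave_labels: list[str] | None = None,
) -> ResponsePanel:
    """Read a panel written by :func:`write_panel`.

    Values are validated to {0, 1, missing}; duplicate (child, wave) rows
    and non-binary values are rejected with the offending row number.
    """
    df = pd.read_csv(path)
    if format == "long":
        required = {"child_id", "process", "wave_index", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long panel file must have columns {sorted(required)}")
        if process_name is not None:
            df = df[df["process"] == process_name]
        procs = df["process"].unique()
        if len(procs) != 1:
            raise ValueError(
                "panel file contains multiple processes; pass process_name"
            )
        _check_values(df["value"])
        dup = df.duplicated(subset=["child_id", "wave_index"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # header + 1-based
            raise ValueError(f"duplicate (child_id, wave_index) at file row {row}")
        wide = df.pivot(index="child_id", columns="wave_index", values="value")
        wide = wide.sort_index()
        return ResponsePanel(
            values=wide.to_numpy(dtype=float),
            child_ids=wide.index.to_numpy(),
            process_name=str(procs[0]),
            wave_labels=wave_labels or [],
        )
    if format == "wide":
        if "child_id" not in df.columns:
            raise ValueError("wide panel file must have a child_id column")
        dup = df.duplicated(subset=["child_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
            raise ValueError(f"duplicate child_id at file row {row}")
        df = df.sort_values("child_id")
        wave_cols = [c for c in df.columns if c != "child_id"]
        _check_values(df[wave_cols].to_numpy().ravel())
        return ResponsePanel(
            values=df[wave_cols].to_numpy(dtype=float),
            child_ids=df["child_id"].to_numpy(),
            process_name=process_name or "process",
            wave_labels=wave_labels or [],
        )
    raise ValueError(f"unknown panel format {format!r}")


def _check_values(values) -> None:
    arr = np.asarray(values, dtype=float)
    bad = np.isfinite(arr) & ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"non-binary panel value at file row {row}")
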