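"""Cell-level data containers, readers, intensity normalization and filtering.

The central container is :class:`CellTable`: one row per segmented cell,
one column per marker, plus a subject identifier and optional image /
cell-type / tissue-region annotations.  All co-expression statistics in
this package operate on the marker intensities of one subject at a time,
so the table offers :meth:`CellTable.subject_matrix` to pull the cells of
a single subject as an ``n_j x p`` array.

Marker intensities are modelled as random variables on the unit interval,
so raw intensities usually need to be rescaled.  Three min-max flavours
are provided (see :class:`NormalizationSpec`); the default pools the
min / max over all subjects so that subjects stay on a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateMarkerError,
    EmptyInputError,
)

logger = logging.getLogger(__name__)

#: optional metadata columns a CellTable understands, in canonical order
OPTIONAL_COLUMNS = ("image_id", "cell_type", "tissue_region")


@dataclass
class CellTable:
    """Cell x marker intensity data for one or more subjects.

    Parameters
    ----------
    frame
        One row per cell.  Must contain a ``subject_id`` column and one
        column per entry of ``marker_names``; may contain ``image_id``,
        ``cell_type`` and ``tissue_region``.
    marker_names
        Ordered marker columns; the order is shared by every subject.
    """

    frame: pd.DataFrame
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.marker_names = list(self.marker_names)
        if "subject_id" not in self.frame.columns:
            raise ConfigurationError("CellTable frame lacks a 'subject_id' column")
        if len(self.marker_names) < 2:
            raise ConfigurationError("a CellTable needs at least 2 markers")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ConfigurationError("marker names must be unique")
        missing = [m for m in self.marker_names if m not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"marker columns missing from frame: {missing}")
        if len(self.frame) == 0:
            raise EmptyInputError("CellTable has no cells")
        vals = self.frame[self.marker_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("marker intensities must be finite")
        if np.any(vals < 0):
            raise ConfigurationError("marker intensities must be non-negative")

    # -- basic introspection -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.frame)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def subjects(self) -> list:
        """Subject identifiers in order of first appearance."""
        return list(pd.unique(self.frame["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def cells_per_subject(self) -> pd.Series:
        return self.frame.groupby("subject_id", sort=False).size()

    def subject_matrix(self, subject, markers: Sequence[str] | None = None) -> np.ndarray:
        """Return the ``n_j x p`` intensity matrix of one subject."""
        markers = list(markers) if markers is not None else self.marker_names
        sub = self.frame.loc[self.frame["subject_id"] == subject, markers]
        return sub.to_numpy(dtype=float)

    def intensity_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        markers = list(markers) if markers is not None else self.marker_names
        return self.frame[markers].to_numpy(dtype=float)


@dataclass(frozen=True)
class NormalizationSpec:
    """How raw intensities are mapped onto [0, 1].

    ``method`` is one of

    - ``none``: values are assumed to already lie in [0, 1];
    - ``global_minmax``: per marker, min-max scaling with the min / max
      pooled over all subjects (default elsewhere in the package --
      subject-level statistics stay comparable on a shared scale);
    - ``per_subject_minmax``: min-max scaling within each subject;
    - ``quantile_cap_minmax``: winsorize each marker at the pooled
      ``cap_quantile`` (robust to hot pixels), then global min-max.
    """

    method: str = "global_minmax"
    cap_quantile: float = 0.99

    def __post_init__(self) -> None:
        valid = {"none", "global_minmax", "per_subject_minmax", "quantile_cap_minmax"}
        if self.method not in valid:
            raise ConfigurationError(f"unknown normalization method {self.method!r}")
        if not 0 < self.cap_quantile <= 1:
            raise ConfigurationError("cap_quantile must lie in (0, 1]")


@dataclass
class OutcomeSpec:
    """A subject-level outcome with optional covariates.

    ``outcome_type`` is ``continuous``, ``binary`` or ``survival``.
    For survival, ``y`` holds the observed time (min of event and
    censoring time) and ``event`` the 0/1 event indicator.
    ``covariates`` is an ``N x S`` matrix (``S`` may be 0).
    """

    outcome_type: str
    y: np.ndarray
    subject_order: list
    event: np.ndarray | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in {"continuous", "binary", "survival"}:
            raise ConfigurationError(f"unknown outcome type {self.outcome_type!r}")
        self.y = np.asarray(self.y, dtype=float)
        self.subject_order = list(self.subject_order)
        n = len(self.subject_order)
        if self.y.shape != (n,):
            raise ConfigurationError("outcome vector length must match subject_order")
        if not np.all(np.isfinite(self.y)):
            raise ConfigurationError("outcome values must be finite")
        if self.outcome_type == "survival":
            if self.event is None:
                raise ConfigurationError("survival outcomes need an event indicator")
            self.event = np.asarray(self.event, dtype=float)
            if self.event.shape != (n,):
                raise ConfigurationError("event vector length must match subject_order")
            if not set(np.unique(self.event)) <= {0.0, 1.0}:
                raise ConfigurationError("event indicator must be 0/1")
            if np.any(self.y < 0):
                raise ConfigurationError("survival times must be non-negative")
        if self.outcome_type == "binary":
            if not set(np.unique(self.y)) <= {0.0, 1.0}:
                raise ConfigurationError(
                    "binary outcomes must be coded 0/1; multinomial outcomes "
                    "are not supported"
                )
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ConfigurationError("covariate matrix must have N rows")
            if not np.all(np.isfinite(self.covariates)):
                raise ConfigurationError("covariates must not contain missing values")
            if self.covariate_names is None:
                self.covariate_names = [
                    f"C{k}" for k in range(self.covariates.shape[1])
                ]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_order)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_cell_table(
    path,
    marker_columns: Sequence[str],
    subject_column: str = "subject_id",
    optional_columns: Mapping[str, str] | None = None,
) -> CellTable:
    """Read a delimited cell-level table (CSV or TSV, by extension).

    Rows with a missing value in any marker column are dropped (row-wise
    deletion, never imputation); the drop count is logged.

    Parameters
    ----------
    optional_columns
        Mapping from canonical names (``image_id``, ``cell_type``,
        ``tissue_region``) to the column names in the file.
    """
    raw = _read_delimited(path)
    optional_columns = dict(optional_columns or {})
    for key in optional_columns:
        if key not in OPTIONAL_COLUMNS:
            raise ConfigurationError(f"unknown optional column role {key!r}")
    needed = [subject_column, *marker_columns, *optional_columns.values()]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"columns missing from {path}: {missing}")

    frame = pd.DataFrame({"subject_id": raw[subject_column]})
    for canon, col in optional_columns.items():
        frame[canon] = raw[col]
    for m in marker_columns:
        frame[m] = pd.to_numeric(raw[m], errors="coerce")

    keep = frame[list(marker_columns)].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d cell rows with missing marker values", n_dropped)
    frame = frame.loc[keep].reset_index(drop=True)
    if len(frame) == 0:
        raise EmptyInputError(f"no usable cell rows in {path}")
    return CellTable(frame=frame, marker_names=list(marker_columns))


def load_outcome_table(
    path,
    outcome_type: str,
    subject_column: str = "subject_id",
    value_column: str = "y",
    event_column: str | None = None,
    covariate_columns: Sequence[str] = (),
) -> OutcomeSpec:
    """Read a subject-level outcome CSV into an :class:`OutcomeSpec`."""
    raw = _read_delimited(path)
    needed = [subject_column, value_column, *covariate_columns]
    if outcome_type == "survival":
        if event_column is None:
            raise ConfigurationError("survival outcomes need an event column")
        needed.append(event_column)
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"columns missing from {path}: {missing}")
    covs = (
        raw[list(covariate_columns)].to_numpy(dtype=float)
        if covariate_columns
        else None
    )
    return OutcomeSpec(
        outcome_type=outcome_type,
        y=raw[value_column].to_numpy(dtype=float),
        event=(raw[event_column].to_numpy(dtype=float) if outcome_type == "survival" else None),
        covariates=covs,
        covariate_names=list(covariate_columns) or None,
        subject_order=list(raw[subject_column]),
    )


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def _check_span(marker: str, lo: float, hi: float, stratum: str) -> None:
    if hi <= lo:
        raise DegenerateMarkerError(
            f"marker {marker!r} is constant over its {stratum} "
            "normalization stratum (max == min)"
        )


def normalize_intensities(table: CellTable, spec: NormalizationSpec) -> CellTable:
    """Map marker intensities onto [0, 1] according to ``spec``.

    Row count and column order are preserved.  ``global_minmax`` is
    idempotent: applying it twice gives the same table as applying it once.
    """
    frame = table.frame.copy()
    if spec.method == "none":
        vals = frame[table.marker_names].to_numpy(dtype=float)
        if vals.min() < 0 or vals.max() > 1:
            raise ConfigurationError(
                "method 'none' requires intensities already in [0, 1]"
            )
        return CellTable(frame=frame, marker_names=table.marker_names)

    if spec.method in {"global_minmax", "quantile_cap_minmax"}:
        for m in table.marker_names:
            x = frame[m].to_numpy(dtype=float)
            if spec.method == "quantile_cap_minmax":
                cap = float(np.quantile(x, spec.cap_quantile))
                x = np.minimum(x, cap)
            lo, hi = float(x.min()), float(x.max())
            _check_span(m, lo, hi, "pooled")
            frame[m] = (x - lo) / (hi - lo)
    else:  # per_subject_minmax
        for m in table.marker_names:
            out = np.empty(len(frame), dtype=float)
            for subject, idx in frame.groupby("subject_id", sort=False).groups.items():
                x = frame.loc[idx, m].to_numpy(dtype=float)
                lo, hi = float(x.min()), float(x.max())
                _check_span(m, lo, hi, f"subject {subject!r}")
                out[frame.index.get_indexer(idx)] = (x - lo) / (hi - lo)
            frame[m] = out
    return CellTable(frame=frame, marker_names=table.marker_names)


def filter_cells(
    table: CellTable,
    cell_type_in: Iterable | None = None,
    tissue_region_in: Iterable | None = None,
) -> CellTable:
    """Subset cells by cell type and/or tissue region.

    Subjects left with zero cells are removed with a warning.  With no
    filters the table is returned unchanged.
    """
    if cell_type_in is None and tissue_region_in is None:
        return table
    frame = table.frame
    mask = np.ones(len(frame), dtype=bool)
    for colname, values in (
        ("cell_type", cell_type_in),
        ("tissue_region", tissue_region_in),
    ):
        if values is None:
            continue
        if colname not in frame.columns:
            raise ConfigurationError(
                f"filter on {colname!r} requested but column is absent"
            )
        mask &= frame[colname].isin(set(values)).to_numpy()
    kept = frame.loc[mask].reset_index(drop=True)
    lost = set(table.subjects) - set(pd.unique(kept["subject_id"]))
    if lost:
        warnings.warn(
            f"filter removed all cells of {len(lost)} subject(s): {sorted(map(str, lost))}",
            stacklevel=2,
        )
    if len(kept) == 0:
        warnings.warn("filter matched no cells", stacklevel=2)
        # Downstream construction will raise EmptyInputError; surface it here.
        raise EmptyInputError("filter matched no cells")
    return CellTable(frame=kept, marker_names=table.marker_names)


def align_subject_statistic(
    subject_ids: Sequence, values: np.ndarray, outcome: OutcomeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Align a per-subject statistic with an outcome's subject order.

    Returns ``(E, keep_mask)`` where ``E`` has one entry per outcome
    subject that also carries a statistic, and ``keep_mask`` marks those
    outcome rows.  Outcome subjects without a statistic (e.g. excluded as
    degenerate) are dropped with a warning.
    """
    lookup = {s: float(v) for s, v in zip(subject_ids, values)}
    keep = np.array([s in lookup for s in outcome.subject_order], dtype=bool)
    if not keep.any():
        raise EmptyInputError("no overlap between statistic subjects and outcome subjects")
    if not keep.all():
        miss = [s for s in outcome.subject_order if s not in lookup]
        warnings.warn(
            f"{len(miss)} outcome subject(s) have no co-expression statistic "
            f"and are dropped: {miss[:5]}",
            stacklevel=2,
        )
    e = np.array([lookup[s] for s, k in zip(outcome.subject_order, keep) if k])
    return e, keep


def subset_outcome(outcome: OutcomeSpec, keep: np.ndarray) -> OutcomeSpec:
    """Row-subset an OutcomeSpec by a boolean mask."""
    return OutcomeSpec(
        outcome_type=outcome.outcome_type,
        y=outcome.y[keep],
        event=None if outcome.event is None else outcome.event[keep],
        covariates=None if outcome.covariates is None else outcome.covariates[keep],
        covariate_names=outcome.covariate_names,
        subject_order=[s for s, k in zip(outcome.subject_order, keep) if k],
    )
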