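"""Traditional thresholding and correlation baselines.

The thresholding pipeline declares cell *i* positive for marker *k* when
its intensity strictly exceeds a cutoff ``t_k``; ties at the threshold
count as negative.  Per subject and per marker pair the proportions of
double-positive, first-only-positive and second-only-positive cells form
a feature vector; subjects are grouped by hierarchical clustering of
these vectors and the cluster label is tested against the outcome.
Three named comparators draw their cutoffs from pooled intensity
quantiles: Median-Thresholding (q = 0.5), Threshold 1 (q = 0.95) and
Threshold 2 (q = 0.99).

The correlation baseline uses the absolute per-subject Pearson
correlation of a marker pair as the co-expression statistic -- a linear
measure that two-marker EQMI* is compared against.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .association import AssociationResult, CoexpressionVector, indicator_association
from .data import CellTable, OutcomeSpec
from .errors import (
    ClusterCountError,
    ConfigurationError,
    DegenerateInputError,
    EmptyInputError,
)

#: the named quantile comparators
NAMED_THRESHOLDS = {"median_threshold": 0.5, "threshold1": 0.95, "threshold2": 0.99}


@dataclass(frozen=True)
class ThresholdSet:
    """Per-marker positivity cutoffs."""

    t: np.ndarray
    marker_names: tuple
    source_tag: str = "user"

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.atleast_1d(np.asarray(self.t, dtype=float)))
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        if self.t.shape != (len(self.marker_names),):
            raise ConfigurationError("one threshold per marker required")
        if self.source_tag not in {"median", "q95", "q99", "user"}:
            raise ConfigurationError(f"unknown threshold source {self.source_tag!r}")


@dataclass
class PositivityProfile:
    """Per-subject positivity-pattern proportions.

    ``table`` has one row per subject (indexed by subject_id) and one
    column per pattern label.  In ``pairwise`` mode the labels are, for
    each unordered marker pair, ``A+B+``, ``A+B-`` and ``A-B+``; in
    ``full_pattern`` mode they are the 2^p - 1 non-all-negative
    sign patterns over all p markers.
    """

    table: pd.DataFrame
    mode: str = "pairwise"

    def __post_init__(self) -> None:
        if self.mode not in {"pairwise", "full_pattern"}:
            raise ConfigurationError(f"unknown positivity mode {self.mode!r}")

    @property
    def subjects(self) -> list:
        return list(self.table.index)

    def matrix(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    """Hierarchical-clustering labels over subjects."""

    subjects: list
    labels: np.ndarray
    M: int
    linkage_tag: str = "ward"
    distance_tag: str = "euclidean"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.subjects),):
            raise ConfigurationError("one label per subject required")
        present = set(self.labels.tolist())
        if present != set(range(self.M)):
            raise ClusterCountError(
                f"expected {self.M} non-empty clusters, found labels {sorted(present)}"
            )


# ---------------------------------------------------------------------------
# thresholds and positivity
# ---------------------------------------------------------------------------

def global_quantile_thresholds(table: CellTable, q: float) -> ThresholdSet:
    """Per-marker q-quantile of intensities pooled over all subjects.

    Uses the linear-interpolation quantile convention.
    """
    if not 0 < q < 1:
        raise ConfigurationError("quantile must lie in (0, 1)")
    vals = table.intensity_matrix()
    t = np.quantile(vals, q, axis=0)  # linear interpolation is numpy's default
    tag = {0.5: "median", 0.95: "q95", 0.99: "q99"}.get(q, "user")
    return ThresholdSet(t=t, marker_names=tuple(table.marker_names), source_tag=tag)


def positivity_proportions(
    table: CellTable, thresholds: ThresholdSet, mode: str = "pairwise"
) -> PositivityProfile:
    """Per-subject proportions of marker-positivity patterns.

    Positivity is strict: cell i is positive for marker k iff
    ``X_ki > t_k``.  Pairwise mode reports, per unordered pair (A, B),
    the proportions of A+B+, A+B- and A-B+ cells; full_pattern mode
    reports every non-all-negative sign pattern over all markers.
    """
    if tuple(thresholds.marker_names) != tuple(table.marker_names):
        raise ConfigurationError("thresholds not aligned with table markers")
    markers = table.marker_names
    p = len(markers)
    pos = table.intensity_matrix() > thresholds.t  # strict inequality
    subj = table.frame["subject_id"].to_numpy()
    subjects = table.subjects

    rows = {}
    for s in subjects:
        mask = subj == s
        P = pos[mask]
        n = P.shape[0]
        row = {}
        if mode == "pairwise":
            for a, b in itertools.combinations(range(p), 2):
                A, B = markers[a], markers[b]
                row[f"{A}+{B}+"] = float(np.mean(P[:, a] & P[:, b]))
                row[f"{A}+{B}-"] = float(np.mean(P[:, a] & ~P[:, b]))
                row[f"{A}-{B}+"] = float(np.mean(~P[:, a] & P[:, b]))
        else:
            for signs in itertools.product((True, False), repeat=p):
                if not any(signs):
                    continue  # the all-negative pattern is implicit
                label = "".join(
                    f"{m}{'+' if s_ else '-'}" for m, s_ in zip(markers, signs)
                )
                match = np.ones(n, dtype=bool)
                for k, s_ in enumerate(signs):
                    match &= P[:, k] if s_ else ~P[:, k]
                row[label] = float(match.mean())
        rows[s] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.loc[subjects]
    frame.index.name = "subject_id"
    return PositivityProfile(table=frame, mode=mode)


# ---------------------------------------------------------------------------
# clustering and association
# ---------------------------------------------------------------------------

def cluster_subjects(
    profiles: PositivityProfile,
    M: int = 2,
    linkage_tag: str = "ward",
    distance_tag: str = "euclidean",
) -> ClusterAssignment:
    """Agglomerative clustering of subjects on their proportion vectors.

    Ward linkage on Euclidean distances by default; the dendrogram is cut
    at M clusters.  Deterministic given the input.  Labels are renumbered
    by order of first appearance so identical inputs give identical labels.
    """
    X = profiles.matrix()
    N = X.shape[0]
    if not 2 <= M <= N:
        raise ConfigurationError("need N >= M >= 2")
    if np.unique(X, axis=0).shape[0] < M:
        raise ClusterCountError(
            f"only {np.unique(X, axis=0).shape[0]} distinct profile vectors; "
            f"cannot form M = {M} clusters -- reduce M"
        )
    Z = linkage(X, method=linkage_tag, metric=distance_tag)
    raw = fcluster(Z, t=M, criterion="maxclust")
    # renumber by first appearance (lowest subject index first)
    remap, labels = {}, np.empty(N, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = remap.setdefault(r, len(remap))
    if len(remap) != M:
        raise ClusterCountError(
            f"linkage cut produced {len(remap)} clusters instead of {M} -- reduce M"
        )
    return ClusterAssignment(
        subjects=profiles.subjects, labels=labels, M=M,
        linkage_tag=linkage_tag, distance_tag=distance_tag,
    )


def threshold_association(
    assignment: ClusterAssignment, outcome: OutcomeSpec
) -> AssociationResult:
    """Test the cluster label against the outcome.

    M = 2 yields a single-indicator test; M > 2 an (M-1)-df joint test.
    """
    M = assignment.M
    Z = np.zeros((len(assignment.subjects), M - 1))
    for m in range(1, M):
        Z[:, m - 1] = (assignment.labels == m).astype(float)
    return indicator_association(Z, assignment.subjects, outcome)


def run_threshold_pipeline(
    table: CellTable,
    outcome: OutcomeSpec,
    q: float,
    M: int = 2,
    mode: str = "pairwise",
) -> AssociationResult:
    """Quantile thresholds -> positivity profiles -> clustering -> test."""
    thr = global_quantile_thresholds(table, q)
    prof = positivity_proportions(table, thr, mode=mode)
    assign = cluster_subjects(prof, M=M)
    return threshold_association(assign, outcome)


# ---------------------------------------------------------------------------
# correlation baseline
# ---------------------------------------------------------------------------

def abs_pearson_coexpression(
    table: CellTable, marker_pair: tuple[str, str]
) -> CoexpressionVector:
    """|Pearson correlation| of a marker pair, per subject.

    Requires at least 3 cells per subject; subjects with a constant
    marker are excluded with a warning.
    """
    if len(marker_pair) != 2:
        raise ConfigurationError("the correlation baseline needs exactly 2 markers")
    for m in marker_pair:
        if m not in table.marker_names:
            raise ConfigurationError(f"unknown marker {m!r}")
    ids, vals = [], []
    for subject in table.subjects:
        X = table.subject_matrix(subject, list(marker_pair))
        if X.shape[0] < 3:
            raise DegenerateInputError(
                f"subject {subject!r} has fewer than 3 cells; "
                "the Pearson baseline needs n_j >= 3"
            )
        sd = X.std(axis=0)
        if np.any(sd == 0):
            warnings.warn(
                f"subject {subject!r} excluded from correlation baseline: "
                "constant marker",
                stacklevel=2,
            )
            continue
        r = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
        ids.append(subject)
        vals.append(abs(r))
    if not ids:
        raise EmptyInputError("no subject supported the correlation baseline")
    return CoexpressionVector(
        subject_order=ids, E=np.asarray(vals), statistic_tag="abs_pearson"
    )
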