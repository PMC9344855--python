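"""Model / Results façade over the co-expression pipeline.

:class:`CoexpressionModel` bundles a cell table, an outcome and an
analysis configuration; :meth:`CoexpressionModel.fit` computes the
per-subject co-expression statistic and the association test in one
step, returning a :class:`CoexpressionResults` that carries the
estimates, the per-subject statistic table and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    CoexpressionVector,
    run_association,
)
from .baselines import abs_pearson_coexpression, run_threshold_pipeline
from .data import CellTable, NormalizationSpec, OutcomeSpec, normalize_intensities
from .errors import ConfigurationError
from .qmi import compute_eqmi_all_subjects

_STATISTICS = {"eqmi_star", "abs_pearson"}


class CoexpressionModel:
    """Subject-level marker co-expression association model.

    Parameters
    ----------
    cells
        Cell-level intensities, one row per cell.
    outcome
        Subject-level outcome (continuous, binary or survival) with
        optional covariates.
    markers
        Marker subset to analyse (default: all markers in the table).
    statistic
        ``eqmi_star`` (default) or ``abs_pearson`` (2 markers only).
    bandwidth
        ``plugin`` (default), ``silverman`` or ``fixed``.
    normalization
        Optional :class:`NormalizationSpec` applied before estimation.
    """

    def __init__(
        self,
        cells: CellTable,
        outcome: OutcomeSpec,
        markers: list[str] | None = None,
        statistic: str = "eqmi_star",
        bandwidth: str = "plugin",
        fixed_h=None,
        poly_degree: int = 1,
        normalization: NormalizationSpec | None = None,
    ) -> None:
        if statistic not in _STATISTICS:
            raise ConfigurationError(
                f"statistic must be one of {sorted(_STATISTICS)}"
            )
        self.cells = (
            normalize_intensities(cells, normalization) if normalization else cells
        )
        self.outcome = outcome
        self.markers = list(markers) if markers else list(cells.marker_names)
        if statistic == "abs_pearson" and len(self.markers) != 2:
            raise ConfigurationError("abs_pearson requires exactly 2 markers")
        self.statistic = statistic
        self.bandwidth = bandwidth
        self.fixed_h = fixed_h
        self.poly_degree = poly_degree

    @classmethod
    def from_dataframes(
        cls,
        cell_frame: pd.DataFrame,
        outcome_frame: pd.DataFrame,
        marker_columns: list[str],
        outcome_type: str,
        subject_column: str = "subject_id",
        value_column: str = "y",
        event_column: str | None = None,
        covariate_columns: list[str] = (),
        **kwargs,
    ) -> "CoexpressionModel":
        """Build the model from in-memory cell and outcome DataFrames."""
        frame = cell_frame.rename(columns={subject_column: "subject_id"})
        cells = CellTable(
            frame=frame[["subject_id", *marker_columns]].copy(),
            marker_names=list(marker_columns),
        )
        outcome = OutcomeSpec(
            outcome_type=outcome_type,
            y=outcome_frame[value_column].to_numpy(dtype=float),
            event=(
                outcome_frame[event_column].to_numpy(dtype=float)
                if outcome_type == "survival"
                else None
            ),
            covariates=(
                outcome_frame[list(covariate_columns)].to_numpy(dtype=float)
                if covariate_columns
                else None
            ),
            covariate_names=list(covariate_columns) or None,
            subject_order=list(outcome_frame[subject_column]),
        )
        return cls(cells, outcome, markers=marker_columns, **kwargs)

    def fit(self) -> "CoexpressionResults":
        """Compute the per-subject statistic and run the association test."""
        if self.statistic == "eqmi_star":
            per_subject = compute_eqmi_all_subjects(
                self.cells,
                markers=self.markers,
                bw_method=self.bandwidth,
                fixed_h=self.fixed_h,
            )
            E = CoexpressionVector(
                subject_order=list(per_subject["subject_id"]),
                E=per_subject["eqmi_star"].to_numpy(),
                statistic_tag="eqmi_star",
            )
        else:
            E = abs_pearson_coexpression(self.cells, tuple(self.markers))
            per_subject = E.to_frame()
        assoc = run_association(E, self.outcome, poly_degree=self.poly_degree)
        assoc.marker_set = list(self.markers)
        return CoexpressionResults(
            model=self, statistic=E, per_subject=per_subject, association=assoc
        )


@dataclass
class CoexpressionResults:
    """Fitted co-expression association: estimates plus diagnostics."""

    model: CoexpressionModel
    statistic: CoexpressionVector
    per_subject: pd.DataFrame
    association: AssociationResult

    @property
    def coefficient(self) -> float:
        return self.association.coefficient

    @property
    def p_value(self) -> float:
        return self.association.p_value

    @property
    def hazard_ratio(self) -> float | None:
        return self.association.hazard_ratio

    def summary(self) -> str:
        a = self.association
        e = self.statistic.E
        lines = [
            "Marker co-expression association",
            "=" * 48,
            f"statistic:      {self.statistic.statistic_tag}",
            f"markers:        {';'.join(self.model.markers)}",
            f"outcome type:   {self.model.outcome.outcome_type}",
            f"subjects used:  {a.n_used}",
            f"E mean (sd):    {e.mean():.4f} ({e.std(ddof=1):.4f})"
            if len(e) > 1
            else f"E mean:         {e.mean():.4f}",
            "-" * 48,
            f"coefficient:    {a.coefficient:.4f}",
        ]
        if a.hazard_ratio is not None:
            lines.append(f"hazard ratio:   {a.hazard_ratio:.4f}")
        lines.append(f"{a.test_tag.upper()} p-value:    {a.p_value:.4g}")
        if a.flag:
            lines.append(f"flag:           {a.flag}")
        lines.append("=" * 48)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CoexpressionResults coef={self.coefficient:.4g} "
            f"p={self.p_value:.4g} n={self.association.n_used}>"
        )


def threshold_baseline_fit(
    cells: CellTable, outcome: OutcomeSpec, comparator: str, M: int = 2
) -> AssociationResult:
    """Convenience wrapper for the named thresholding comparators
    (``median_threshold``, ``threshold1``, ``threshold2``)."""
    from .baselines import NAMED_THRESHOLDS

    if comparator not in NAMED_THRESHOLDS:
        raise ConfigurationError(
            f"comparator must be one of {sorted(NAMED_THRESHOLDS)}"
        )
    return run_threshold_pipeline(cells, outcome, q=NAMED_THRESHOLDS[comparator], M=M)
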