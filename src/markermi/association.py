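"""Subject-level association tests between a co-expression statistic and
clinical outcomes.

The per-subject statistic E (EQMI*, |Pearson r|, or a cluster-label
indicator) enters an outcome-appropriate regression:

- continuous Y:  ordinary least squares  Y = Cβ + Eγ + ε, Wald test of γ;
- binary Y:      logistic regression, Wald test of the E coefficient;
- survival Y:    Cox proportional-hazards λ(t|C,E) = λ0(t) exp(Cᵀβ + Eγ),
                 likelihood-ratio test (1 df) of γ, hazard ratio exp(γ̂).

Multi-marker scans enumerate every marker subset of a chosen minimum
size, compute EQMI* per subject and subset, run the test, and apply a
Bonferroni correction *within each subset size* (pairs compared against
α / #pairs, triplets against α / #triplets, and so on).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .data import CellTable, OutcomeSpec, align_subject_statistic, subset_outcome
from .errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
)
from .qmi import compute_eqmi_all_subjects

VALID_STATISTIC_TAGS = {"eqmi_star", "abs_pearson", "cluster_label"}


@dataclass
class CoexpressionVector:
    """A length-N per-subject co-expression statistic."""

    subject_order: list
    E: np.ndarray
    statistic_tag: str = "eqmi_star"

    def __post_init__(self) -> None:
        self.subject_order = list(self.subject_order)
        self.E = np.asarray(self.E, dtype=float)
        if self.statistic_tag not in VALID_STATISTIC_TAGS:
            raise ConfigurationError(f"unknown statistic tag {self.statistic_tag!r}")
        if self.E.shape != (len(self.subject_order),):
            raise ConfigurationError("statistic length must match subject_order")
        if not np.all(np.isfinite(self.E)):
            raise ConfigurationError("statistic contains missing values")
        if self.statistic_tag == "cluster_label":
            if not np.allclose(self.E, np.round(self.E)) or self.E.min() < 0:
                raise ConfigurationError("cluster labels must be integers >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_order, "statistic": self.E,
             "statistic_tag": self.statistic_tag}
        )


@dataclass
class AssociationResult:
    """Outcome-association summary for one statistic / marker set."""

    coefficient: float
    p_value: float
    test_tag: str
    n_used: int
    marker_set: list[str] = field(default_factory=list)
    hazard_ratio: float | None = None
    flag: str | None = None  # 'separation', 'non_convergence', 'degenerate'

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _aligned(E: CoexpressionVector, outcome: OutcomeSpec):
    """Reduce outcome rows to the subjects carrying a statistic."""
    e, keep = align_subject_statistic(E.subject_order, E.E, outcome)
    return e, subset_outcome(outcome, keep)


def _design(outcome: OutcomeSpec, e: np.ndarray, poly_degree: int):
    """[const | covariates | E, E², ...] design with column names."""
    n = len(e)
    cols = [np.ones(n)]
    names = ["const"]
    if outcome.covariates is not None and outcome.covariates.shape[1]:
        for k in range(outcome.covariates.shape[1]):
            cols.append(outcome.covariates[:, k])
            names.append(outcome.covariate_names[k])
    e_names = []
    for d in range(1, poly_degree + 1):
        cols.append(e**d)
        name = "E" if d == 1 else f"E^{d}"
        names.append(name)
        e_names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {names}"
        )
    return X, names, e_names


def linear_association(
    E: CoexpressionVector, outcome: OutcomeSpec, poly_degree: int = 1
) -> AssociationResult:
    """OLS of a continuous outcome on [covariates, E, ..., E^degree].

    Wald (F) test of H0: all E terms are zero; the reported coefficient
    is the linear-term estimate.
    """
    if outcome.outcome_type != "continuous":
        raise ConfigurationError("linear_association needs a continuous outcome")
    if poly_degree < 1:
        raise ConfigurationError("poly_degree must be >= 1")
    e, out = _aligned(E, outcome)
    n = len(e)
    if n <= out.n_covariates + poly_degree + 1:
        raise DegenerateInputError("too few subjects for the requested model")
    X, names, e_names = _design(out, e, poly_degree)
    res = sm.OLS(out.y, X).fit()
    R = np.zeros((len(e_names), X.shape[1]))
    for r, name in enumerate(e_names):
        R[r, names.index(name)] = 1.0
    wald = res.f_test(R)
    return AssociationResult(
        coefficient=float(res.params[names.index("E")]),
        p_value=float(wald.pvalue),
        test_tag="wald",
        n_used=n,
    )


def logistic_association(
    E: CoexpressionVector, outcome: OutcomeSpec
) -> AssociationResult:
    """Logistic regression of a binary outcome on [covariates, E].

    Complete separation is flagged (p_value NaN) rather than raised.
    """
    if outcome.outcome_type != "binary":
        raise ConfigurationError("logistic_association needs a binary outcome")
    e, out = _aligned(E, outcome)
    if len(np.unique(out.y)) < 2:
        raise DegenerateInputError("binary outcome has a single class")
    X, names, _ = _design(out, e, poly_degree=1)
    j = names.index("E")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(out.y, X).fit(disp=0, maxiter=200)
        except Exception:
            res = None
    if res is None or not res.mle_retvals.get("converged", False) or abs(res.params[j]) > 50:
        warnings.warn(
            "logistic fit did not converge (possible complete separation); "
            "result flagged",
            stacklevel=2,
        )
        coef = float(res.params[j]) if res is not None else float("nan")
        return AssociationResult(
            coefficient=coef, p_value=float("nan"), test_tag="wald",
            n_used=len(e), flag="separation",
        )
    return AssociationResult(
        coefficient=float(res.params[j]),
        p_value=float(res.pvalues[j]),
        test_tag="wald",
        n_used=len(e),
    )


def _cox_frame(out: OutcomeSpec, columns: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame({"time": out.y, "event": out.event})
    if out.covariates is not None and out.covariates.shape[1]:
        for k in range(out.covariates.shape[1]):
            df[out.covariate_names[k]] = out.covariates[:, k]
    for name, col in columns.items():
        df[name] = col
    return df


def _cox_loglik(df: pd.DataFrame, ties: str) -> float:
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.log_likelihood_)


def breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow-tie Cox log partial likelihood at coefficient vector beta."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = time >= t
        ll += float(eta[dead].sum()) - dead.sum() * float(
            np.log(np.sum(np.exp(eta[risk])))
        )
    return ll


def _breslow_fit(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Maximize the Breslow partial likelihood; returns (beta_hat, loglik)."""
    from scipy.optimize import minimize

    res = minimize(
        lambda b: -breslow_partial_loglik(b, X, time, event),
        x0=np.zeros(X.shape[1]),
        method="BFGS",
    )
    return res.x, -float(res.fun)


def cox_lrt_association(
    E: CoexpressionVector, outcome: OutcomeSpec, ties: str = "efron"
) -> AssociationResult:
    """Cox proportional-hazards fit with a 1-df likelihood-ratio test of E.

    The LRT compares the partial likelihood of the model with covariates
    plus E against the model with covariates alone (the null partial
    likelihood when there are no covariates).  Ties are handled by the
    Efron approximation.  Degenerate statistics and non-convergent fits
    are flagged, not fatal.
    """
    if outcome.outcome_type != "survival":
        raise ConfigurationError("cox_lrt_association needs a survival outcome")
    if ties not in {"efron", "breslow"}:
        raise ConfigurationError("ties must be 'efron' or 'breslow'")
    e, out = _aligned(E, outcome)
    if out.event.sum() < 2:
        raise DegenerateInputError("Cox model needs at least 2 events")
    if np.ptp(e) == 0:
        warnings.warn("co-expression statistic is constant; Cox fit flagged",
                      stacklevel=2)
        return AssociationResult(
            coefficient=float("nan"), p_value=float("nan"), test_tag="lrt",
            n_used=len(e), flag="degenerate",
        )
    df = _cox_frame(out, {"E": e})
    if ties == "breslow":
        covs = [c for c in df.columns if c not in {"time", "event"}]
        Xfull = df[covs].to_numpy(dtype=float)
        beta_hat, ll_full = _breslow_fit(Xfull, out.y, out.event)
        gamma = float(beta_hat[covs.index("E")])
        if out.n_covariates:
            _, ll_reduced = _breslow_fit(
                df[[c for c in covs if c != "E"]].to_numpy(dtype=float),
                out.y, out.event,
            )
        else:
            ll_reduced = breslow_partial_loglik(
                np.zeros(1), Xfull[:, [covs.index("E")]], out.y, out.event
            )
        lrt_stat = max(2.0 * (ll_full - ll_reduced), 0.0)
        p = float(stats.chi2.sf(lrt_stat, df=1))
        return AssociationResult(
            coefficient=gamma, hazard_ratio=float(np.exp(gamma)),
            p_value=p, test_tag="lrt", n_used=len(e),
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        warnings.warn("Cox fit failed to converge; result flagged", stacklevel=2)
        return AssociationResult(
            coefficient=float("nan"), p_value=float("nan"), test_tag="lrt",
            n_used=len(e), flag="non_convergence",
        )
    gamma = float(cph.params_["E"])
    if out.n_covariates:
        ll_full = float(cph.log_likelihood_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll_reduced = _cox_loglik(df.drop(columns=["E"]), ties)
        lrt_stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    else:
        # with no covariates the reduced model is the null partial likelihood
        lrt_stat = max(float(cph.log_likelihood_ratio_test().test_statistic), 0.0)
    p = float(stats.chi2.sf(lrt_stat, df=1))
    return AssociationResult(
        coefficient=gamma,
        hazard_ratio=float(np.exp(gamma)),
        p_value=p,
        test_tag="lrt",
        n_used=len(e),
    )


def run_association(
    E: CoexpressionVector, outcome: OutcomeSpec, poly_degree: int = 1
) -> AssociationResult:
    """Dispatch to the outcome-appropriate test."""
    if outcome.outcome_type == "continuous":
        return linear_association(E, outcome, poly_degree=poly_degree)
    if outcome.outcome_type == "binary":
        return logistic_association(E, outcome)
    return cox_lrt_association(E, outcome)


def indicator_association(
    Z: np.ndarray, subject_order: list, outcome: OutcomeSpec
) -> AssociationResult:
    """Association test of an N x (M-1) cluster-indicator matrix.

    For a single indicator column this reduces to the scalar tests above
    (with ``statistic_tag='cluster_label'``).  For M > 2 clusters the
    test is an (M-1)-df joint test: an F test for continuous outcomes, a
    likelihood-ratio test for binary and survival outcomes.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(subject_order):
        Z = Z.T
    if Z.shape[1] == 1:
        E = CoexpressionVector(
            subject_order=subject_order, E=Z[:, 0], statistic_tag="cluster_label"
        )
        return run_association(E, outcome)

    # multi-df path: align on subjects present in the outcome
    lookup = {s: Z[i] for i, s in enumerate(subject_order)}
    keep = np.array([s in lookup for s in outcome.subject_order], dtype=bool)
    out = subset_outcome(outcome, keep)
    Zal = np.vstack([lookup[s] for s in out.subject_order])
    m1 = Zal.shape[1]
    n = len(out.y)
    base_cols = [np.ones(n)]
    if out.covariates is not None and out.covariates.shape[1]:
        base_cols.extend(out.covariates[:, k] for k in range(out.covariates.shape[1]))
    Xr = np.column_stack(base_cols)
    Xf = np.column_stack([Xr, Zal])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise CollinearityError("cluster indicators are collinear with covariates")

    if outcome.outcome_type == "continuous":
        res = sm.OLS(out.y, Xf).fit()
        R = np.zeros((m1, Xf.shape[1]))
        R[:, -m1:] = np.eye(m1)
        wald = res.f_test(R)
        return AssociationResult(
            coefficient=float(res.params[-m1]), p_value=float(wald.pvalue),
            test_tag="wald", n_used=n,
        )
    if outcome.outcome_type == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(out.y, Xf).fit(disp=0, maxiter=200)
            red = sm.Logit(out.y, Xr).fit(disp=0, maxiter=200)
        lrt = max(2.0 * (full.llf - red.llf), 0.0)
        return AssociationResult(
            coefficient=float(full.params[-m1]),
            p_value=float(stats.chi2.sf(lrt, df=m1)),
            test_tag="lrt", n_used=n,
        )
    # survival
    df = _cox_frame(out, {f"Z{m}": Zal[:, m] for m in range(m1)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ll_full = _cox_loglik(df, "efron")
        red = df.drop(columns=[f"Z{m}" for m in range(m1)])
        if red.shape[1] > 2:
            ll_red = _cox_loglik(red, "efron")
        else:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            ll_red = ll_full - 0.5 * float(
                cph.log_likelihood_ratio_test().test_statistic
            )
    lrt = max(2.0 * (ll_full - ll_red), 0.0)
    cph_full = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph_full.fit(df, duration_col="time", event_col="event")
    gamma0 = float(cph_full.params_["Z0"])
    return AssociationResult(
        coefficient=gamma0, hazard_ratio=float(np.exp(gamma0)),
        p_value=float(stats.chi2.sf(lrt, df=m1)), test_tag="lrt", n_used=n,
    )


# ---------------------------------------------------------------------------
# marker-combination scan
# ---------------------------------------------------------------------------

def combination_scan(
    table: CellTable,
    markers: list[str],
    outcome: OutcomeSpec,
    min_size: int = 2,
    alpha: float = 0.05,
    bw_method: str = "plugin",
    fixed_h=None,
) -> pd.DataFrame:
    """Test every marker subset of size >= ``min_size`` for association.

    For p markers and min_size 2 there are 2^p - p - 1 subsets.  P-values
    are Bonferroni-corrected within each subset size: a subset of size m
    is significant when its raw p-value is below α / (number of size-m
    subsets scanned).

    Returns a DataFrame with columns ``marker_set, size, coefficient,
    hazard_ratio, p_value, bonferroni_alpha, significant``.
    """
    p = len(markers)
    if not 2 <= p <= 10:
        raise ConfigurationError(
            f"combination scan supports 2 <= p <= 10 markers (got {p}); the "
            "subset count grows as 2^p -- pre-select a smaller marker panel"
        )
    if min_size < 2:
        raise ConfigurationError("min_size must be >= 2")

    rows = []
    for size in range(min_size, p + 1):
        for subset in itertools.combinations(markers, size):
            per_subject = compute_eqmi_all_subjects(
                table, markers=list(subset), bw_method=bw_method, fixed_h=fixed_h
            )
            E = CoexpressionVector(
                subject_order=list(per_subject["subject_id"]),
                E=per_subject["eqmi_star"].to_numpy(),
                statistic_tag="eqmi_star",
            )
            res = run_association(E, outcome)
            rows.append(
                {
                    "marker_set": ";".join(subset),
                    "size": size,
                    "coefficient": res.coefficient,
                    "hazard_ratio": res.hazard_ratio,
                    "p_value": res.p_value,
                }
            )
    scan = pd.DataFrame(rows)
    counts = scan.groupby("size")["marker_set"].transform("count")
    scan["bonferroni_alpha"] = alpha / counts
    scan["significant"] = scan["p_value"] < scan["bonferroni_alpha"]
    return scan
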