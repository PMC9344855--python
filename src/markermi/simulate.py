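"""Synthetic multiplex-imaging data and the empirical-power engine.

Every scenario emulates a cohort split into two latent groups: subjects
with high marker co-expression (group indicator I_j = 0) and subjects
with little or none (I_j = 1).  Marker marginals mimic real mIHC
intensity profiles via Beta distributions -- the defaults, Beta(1.5, 170)
and Beta(1.6, 35), reproduce the heavily right-skewed intensities of a
functional and a phenotypic marker.

Scenarios
---------
- ``copula2``: a Gaussian copula couples the two Beta marginals; the
  copula correlation is drawn per subject from U(0.75, 0.9) in the
  dependent group and U(0, 0.15) otherwise -- a linear dependence
  pattern, where correlation and EQMI* carry the same information.
- ``squared``: in the dependent group X2 = (X1 - 0.05)^2 + e with
  X1 ~ U(0, 0.1) and e ~ U(0, 0.0005) -- strong dependence, yet the
  population Pearson correlation is exactly zero by symmetry.
- ``circular``: X2 = 0.05 + s·sqrt(0.05^2 - (X1 - 0.05)^2) + e with
  s ~ U(-1, 1) (or Rademacher ±1) -- a ring; correlation is zero, and
  median-based positivity proportions are identical across the groups.
- ``copula3_caseA/B/C``: three Beta marginals coupled by a Gaussian
  copula whose pairwise correlations are U(0.4, 0.6) vs U(0.2, 0.4)
  across groups; case B pins rho_13 = 0, case C pins rho_13 = rho_23 = 0,
  shrinking the between-group contrast from A to C.

Outcomes are continuous, Y_j = I_j·beta + eps_j with eps ~ N(0, sigma²),
redrawn ``outcome_reps`` times over fixed intensities; empirical power
is the rejection fraction at level alpha, averaged over
``dataset_repeats`` independently regenerated cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .association import CoexpressionVector, linear_association
from .baselines import (
    NAMED_THRESHOLDS,
    abs_pearson_coexpression,
    cluster_subjects,
    global_quantile_thresholds,
    positivity_proportions,
)
from .data import CellTable, OutcomeSpec
from .errors import ClusterCountError, ConfigurationError, ScenarioError
from .qmi import compute_eqmi_all_subjects

SCENARIOS = {
    "copula2", "squared", "circular",
    "copula3_caseA", "copula3_caseB", "copula3_caseC",
}
POWER_METHODS = ("eqmi", "corr", "median_threshold", "threshold1", "threshold2")

#: Beta marginal parameters fitted to skewed mIHC marker intensity profiles
DEFAULT_MARGINALS_2 = ((1.5, 170.0), (1.6, 35.0))
DEFAULT_MARGINALS_3 = ((1.5, 170.0), (1.6, 35.0), (1.6, 35.0))


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one simulation scenario."""

    scenario_tag: str = "copula2"
    N: int = 40
    ncells: int = 1000
    beta: float = 1.0
    sigma: float = 1.0
    outcome_reps: int = 100
    dataset_repeats: int = 20
    alpha: float = 0.05
    seed: int = 0
    group_prob: float = 0.5
    marginal_params: tuple = None
    circular_s: str = "uniform"  # 'uniform' U(-1,1) or 'rademacher' ±1

    def __post_init__(self) -> None:
        if self.scenario_tag not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario_tag!r}")
        if self.N < 4 or self.ncells < 10:
            raise ConfigurationError("need N >= 4 subjects and ncells >= 10")
        if not 0 < self.group_prob < 1:
            raise ConfigurationError("group_prob must lie in (0, 1)")
        if self.outcome_reps < 1 or self.dataset_repeats < 1:
            raise ConfigurationError("repeat counts must be >= 1")
        if self.circular_s not in {"uniform", "rademacher"}:
            raise ConfigurationError("circular_s must be 'uniform' or 'rademacher'")
        if self.marginal_params is None:
            default = (
                DEFAULT_MARGINALS_3
                if self.scenario_tag.startswith("copula3")
                else DEFAULT_MARGINALS_2
            )
            object.__setattr__(self, "marginal_params", default)
        object.__setattr__(
            self,
            "marginal_params",
            tuple((float(a), float(b)) for a, b in self.marginal_params),
        )

    @property
    def n_markers(self) -> int:
        return 3 if self.scenario_tag.startswith("copula3") else 2


def _subject_ids(N: int) -> list[str]:
    return [f"S{j:03d}" for j in range(N)]


def _as_cell_table(X_by_subject: list[np.ndarray], N: int, p: int) -> CellTable:
    ids = _subject_ids(N)
    markers = [f"M{k + 1}" for k in range(p)]
    frames = []
    for j, X in enumerate(X_by_subject):
        df = pd.DataFrame(X, columns=markers)
        df.insert(0, "subject_id", ids[j])
        frames.append(df)
    frame = pd.concat(frames, ignore_index=True)
    return CellTable(frame=frame, marker_names=markers)


def _copula_draw(rng, R: np.ndarray, n: int, marginals) -> np.ndarray:
    """Gaussian copula: N(0, R) -> Phi -> Beta inverse CDFs, columnwise."""
    U = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=n, method="cholesky")
    V = stats.norm.cdf(U)
    X = np.column_stack(
        [stats.beta.ppf(V[:, k], a, b) for k, (a, b) in enumerate(marginals)]
    )
    return X


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_copula2(scn: SimScenario) -> tuple[CellTable, np.ndarray]:
    """Two markers, linear (copula) dependence vs near-independence."""
    if scn.scenario_tag != "copula2":
        raise ConfigurationError("scenario_tag must be 'copula2'")
    rng = np.random.default_rng(scn.seed)
    groups = (rng.random(scn.N) >= scn.group_prob).astype(int)
    data = []
    for j in range(scn.N):
        rho = rng.uniform(0.75, 0.9) if groups[j] == 0 else rng.uniform(0.0, 0.15)
        R = np.array([[1.0, rho], [rho, 1.0]])
        data.append(_copula_draw(rng, R, scn.ncells, scn.marginal_params))
    return _as_cell_table(data, scn.N, 2), groups


def simulate_squared(scn: SimScenario) -> tuple[CellTable, np.ndarray]:
    """Two markers, parabolic dependence (zero linear correlation)."""
    if scn.scenario_tag != "squared":
        raise ConfigurationError("scenario_tag must be 'squared'")
    rng = np.random.default_rng(scn.seed)
    groups = (rng.random(scn.N) >= scn.group_prob).astype(int)
    data = []
    for j in range(scn.N):
        x1 = rng.uniform(0.0, 0.1, size=scn.ncells)
        if groups[j] == 0:
            e = rng.uniform(0.0, 0.0005, size=scn.ncells)
            x2 = (x1 - 0.05) ** 2 + e
        else:
            x2 = rng.uniform(0.0, 0.1, size=scn.ncells)
        data.append(np.column_stack([x1, x2]))
    return _as_cell_table(data, scn.N, 2), groups


def simulate_circular(scn: SimScenario) -> tuple[CellTable, np.ndarray]:
    """Two markers, circular dependence (zero linear correlation)."""
    if scn.scenario_tag != "circular":
        raise ConfigurationError("scenario_tag must be 'circular'")
    rng = np.random.default_rng(scn.seed)
    groups = (rng.random(scn.N) >= scn.group_prob).astype(int)
    data = []
    for j in range(scn.N):
        x1 = rng.uniform(0.0, 0.1, size=scn.ncells)
        if groups[j] == 0:
            e = rng.uniform(0.0, 0.0005, size=scn.ncells)
            if scn.circular_s == "uniform":
                s = rng.uniform(-1.0, 1.0, size=scn.ncells)
            else:
                s = rng.choice([-1.0, 1.0], size=scn.ncells)
            x2 = 0.05 + s * np.sqrt(np.maximum(0.05**2 - (x1 - 0.05) ** 2, 0.0)) + e
        else:
            x2 = rng.uniform(0.0, 0.1, size=scn.ncells)
        data.append(np.column_stack([x1, x2]))
    return _as_cell_table(data, scn.N, 2), groups


def _copula3_correlations(rng, case: str, group: int) -> np.ndarray:
    lo, hi = (0.4, 0.6) if group == 0 else (0.2, 0.4)
    r12 = rng.uniform(lo, hi)
    r23 = rng.uniform(lo, hi) if case in {"A", "B"} else 0.0
    r13 = rng.uniform(lo, hi) if case == "A" else 0.0
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    return R


def simulate_copula3(scn: SimScenario) -> tuple[CellTable, np.ndarray]:
    """Three markers with case-dependent linear dependence structure.

    Per subject the 3 x 3 copula correlation matrix is drawn by case
    (A: all three pairs differ across groups; B: rho_13 pinned to 0;
    C: rho_13 and rho_23 pinned to 0).  Non-positive-definite draws are
    redrawn, up to 100 times.
    """
    if not scn.scenario_tag.startswith("copula3"):
        raise ConfigurationError("scenario_tag must be copula3_caseA/B/C")
    case = scn.scenario_tag[-1]
    rng = np.random.default_rng(scn.seed)
    groups = (rng.random(scn.N) >= scn.group_prob).astype(int)
    data = []
    for j in range(scn.N):
        for attempt in range(100):
            R = _copula3_correlations(rng, case, groups[j])
            if np.linalg.eigvalsh(R).min() > 1e-10:
                break
        else:
            raise ScenarioError("correlation matrix not positive definite "
                                "after 100 redraws")
        data.append(_copula_draw(rng, R, scn.ncells, scn.marginal_params))
    return _as_cell_table(data, scn.N, 3), groups


_GENERATORS = {
    "copula2": simulate_copula2,
    "squared": simulate_squared,
    "circular": simulate_circular,
    "copula3_caseA": simulate_copula3,
    "copula3_caseB": simulate_copula3,
    "copula3_caseC": simulate_copula3,
}


def generate(scn: SimScenario) -> tuple[CellTable, np.ndarray]:
    """Dispatch on ``scn.scenario_tag``; returns (cells, group indicators)."""
    return _GENERATORS[scn.scenario_tag](scn)


def simulate_outcomes(
    group_labels: np.ndarray,
    beta: float,
    sigma: float,
    outcome_reps: int,
    seed: int,
) -> list[OutcomeSpec]:
    """Continuous outcomes Y = I·beta + eps over fixed group labels.

    The dependent group carries I = 0 and the independent group I = 1,
    so a positive beta raises the outcome of low-co-expression subjects.
    Each repetition redraws only the noise.
    """
    groups = np.asarray(group_labels)
    ids = _subject_ids(len(groups))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(outcome_reps):
        y = groups * beta + rng.normal(0.0, sigma, size=len(groups))
        out.append(
            OutcomeSpec(outcome_type="continuous", y=y, subject_order=ids)
        )
    return out


# ---------------------------------------------------------------------------
# power engine
# ---------------------------------------------------------------------------

def _method_statistics(
    table: CellTable, methods: list[str], bw_method: str
) -> dict[str, CoexpressionVector | None]:
    """Per-subject statistic of each method on one generated cohort.

    For thresholding methods the 'statistic' is the M = 2 cluster label
    from the pairwise positivity profiles.  A method that cannot be
    computed on this cohort (correlation with p > 2, or a degenerate
    clustering) maps to None.
    """
    stats_by_method: dict[str, CoexpressionVector | None] = {}
    for method in methods:
        if method == "eqmi":
            per_subject = compute_eqmi_all_subjects(table, bw_method=bw_method)
            stats_by_method[method] = CoexpressionVector(
                subject_order=list(per_subject["subject_id"]),
                E=per_subject["eqmi_star"].to_numpy(),
                statistic_tag="eqmi_star",
            )
        elif method == "corr":
            if table.n_markers != 2:
                warnings.warn(
                    "correlation baseline skipped: needs exactly 2 markers",
                    stacklevel=3,
                )
                stats_by_method[method] = None
                continue
            stats_by_method[method] = abs_pearson_coexpression(
                table, tuple(table.marker_names)
            )
        elif method in NAMED_THRESHOLDS:
            thr = global_quantile_thresholds(table, NAMED_THRESHOLDS[method])
            prof = positivity_proportions(table, thr, mode="pairwise")
            try:
                assign = cluster_subjects(prof, M=2)
            except ClusterCountError:
                warnings.warn(
                    f"{method}: clustering degenerate on this cohort; "
                    "method contributes no rejections",
                    stacklevel=3,
                )
                stats_by_method[method] = None
                continue
            stats_by_method[method] = CoexpressionVector(
                subject_order=assign.subjects,
                E=assign.labels.astype(float),
                statistic_tag="cluster_label",
            )
        else:
            raise ConfigurationError(f"unknown power-study method {method!r}")
    return stats_by_method


def run_power_study(
    scn: SimScenario,
    methods: list[str] = ("eqmi", "corr"),
    beta_grid: list[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
    bw_method: str = "plugin",
) -> pd.DataFrame:
    """Empirical power of each method over a beta grid.

    Per dataset repeat: one cohort of intensities is generated and every
    method's per-subject statistic computed once; per beta, fresh outcome
    noise is drawn ``scn.outcome_reps`` times and the linear Wald test of
    the statistic is run at level ``scn.alpha``.  Power is the rejection
    fraction over all ``outcome_reps * dataset_repeats`` tests, with its
    Monte-Carlo standard error.

    Returns a tidy DataFrame (PowerTable): one row per
    (scenario_tag, method_tag, N, ncells, beta).
    """
    methods = list(methods)
    for m in methods:
        if m not in POWER_METHODS:
            raise ConfigurationError(f"unknown method tag {m!r}")
    beta_grid = [float(b) for b in beta_grid]
    root = np.random.SeedSequence(scn.seed)
    data_seeds, outcome_seeds = root.spawn(2)
    data_children = data_seeds.spawn(scn.dataset_repeats)
    outcome_children = outcome_seeds.spawn(scn.dataset_repeats)

    rejects = {(m, b): [] for m in methods for b in beta_grid}
    for r in range(scn.dataset_repeats):
        rep_scn = replace(
            scn, seed=int(data_children[r].generate_state(1)[0] % (2**31))
        )
        table, groups = generate(rep_scn)
        stats_by_method = _method_statistics(table, methods, bw_method)
        out_seed_base = outcome_children[r].generate_state(len(beta_grid)) % (2**31)
        for bi, beta in enumerate(beta_grid):
            outcomes = simulate_outcomes(
                groups, beta, scn.sigma, scn.outcome_reps, int(out_seed_base[bi])
            )
            for m in methods:
                E = stats_by_method[m]
                for outcome in outcomes:
                    if E is None or np.ptp(E.E) == 0:
                        rejects[(m, beta)].append(False)
                        continue
                    res = linear_association(E, outcome)
                    rejects[(m, beta)].append(bool(res.p_value < scn.alpha))

    rows = []
    for m in methods:
        for b in beta_grid:
            r = np.asarray(rejects[(m, b)], dtype=float)
            power = float(r.mean())
            rows.append(
                {
                    "scenario_tag": scn.scenario_tag,
                    "method_tag": m,
                    "N": scn.N,
                    "ncells": scn.ncells,
                    "beta": b,
                    "power": power,
                    "mc_se": float(np.sqrt(power * (1.0 - power) / r.size)),
                }
            )
    return pd.DataFrame(rows)


def plot_power(power_table: pd.DataFrame, path) -> None:
    """Power vs beta, one line per method, one panel per (scenario, N, ncells)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = list(power_table.groupby(["scenario_tag", "N", "ncells"]))
    fig, axes = plt.subplots(
        1, len(panels), figsize=(4 * len(panels), 3.2), squeeze=False
    )
    for ax, ((tag, N, ncells), sub) in zip(axes[0], panels):
        for method, grp in sub.groupby("method_tag"):
            grp = grp.sort_values("beta")
            ax.plot(grp["beta"], grp["power"], marker="o", label=method)
        ax.set_title(f"{tag}  N={N}, ncells={ncells}")
        ax.set_xlabel(r"effect size $\beta$")
        ax.set_ylabel("empirical power")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
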