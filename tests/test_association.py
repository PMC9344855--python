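"""Outcome association tests and the marker-combination scan."""

import numpy as np
import pytest

from markermi import (
    CoexpressionVector,
    OutcomeSpec,
    combination_scan,
    cox_lrt_association,
    linear_association,
    logistic_association,
)
from markermi.errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
)

from conftest import make_table
from helpers import grid_search_cox_gamma

IDS = [f"S{j}" for j in range(20)]


def _vector(values, ids=None, tag="eqmi_star"):
    ids = ids if ids is not None else [f"S{j}" for j in range(len(values))]
    return CoexpressionVector(subject_order=ids, E=np.asarray(values, float),
                              statistic_tag=tag)


class TestLinearAssociation:
    def test_exact_linear_relation_recovers_coefficient(self, rng):
        e = rng.random(20)
        E = _vector(e)
        outcome = OutcomeSpec("continuous", y=2.0 * e, subject_order=E.subject_order)
        res = linear_association(E, outcome)
        assert res.coefficient == pytest.approx(2.0, abs=1e-8)
        assert res.p_value < 1e-12

    def test_constant_statistic_is_collinear(self):
        E = _vector(np.full(10, 0.4))
        outcome = OutcomeSpec("continuous", y=np.arange(10.0),
                              subject_order=E.subject_order)
        with pytest.raises(CollinearityError):
            linear_association(E, outcome)

    def test_polynomial_terms_are_jointly_tested(self, rng):
        e = rng.random(40)
        y = (e - 0.5) ** 2 + rng.normal(0, 0.01, 40)  # purely quadratic signal
        E = _vector(e)
        outcome = OutcomeSpec("continuous", y=y, subject_order=E.subject_order)
        res2 = linear_association(E, outcome, poly_degree=2)
        assert res2.p_value < 1e-6

    def test_null_rejection_rate_is_calibrated(self):
        # gamma = 0: Y independent of E; exact t-based Wald under normality
        rng = np.random.default_rng(77)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            e = rng.random(30)
            y = rng.normal(size=30)
            res = linear_association(_vector(e, ids=[str(i) for i in range(30)]),
                                     OutcomeSpec("continuous", y=y,
                                                 subject_order=[str(i) for i in range(30)]))
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_covariates_are_adjusted_for(self, rng):
        e = rng.random(50)
        c = rng.random(50)
        y = 3.0 * c + rng.normal(0, 0.1, 50)
        E = _vector(e, ids=[str(i) for i in range(50)])
        outcome = OutcomeSpec("continuous", y=y, covariates=c[:, None],
                              subject_order=E.subject_order)
        res = linear_association(E, outcome)
        assert res.p_value > 0.01  # E carries no signal once C is adjusted


class TestLogisticAssociation:
    def test_null_has_small_coefficient_most_of_the_time(self):
        rng = np.random.default_rng(5)
        calm = 0
        for _ in range(100):
            e = rng.random(60)
            y = (rng.random(60) < 0.5).astype(float)
            ids = [str(i) for i in range(60)]
            res = logistic_association(
                _vector(e, ids=ids), OutcomeSpec("binary", y=y, subject_order=ids)
            )
            calm += res.p_value > 0.05
        assert calm >= 90

    def test_perfect_separation_is_flagged(self):
        e = np.linspace(0, 1, 20)
        y = (e > 0.5).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            res = logistic_association(
                _vector(e), OutcomeSpec("binary", y=y, subject_order=_vector(e).subject_order)
            )
        assert res.flag == "separation"
        assert np.isnan(res.p_value)

    def test_single_class_outcome_rejected(self):
        E = _vector(np.linspace(0, 1, 10))
        outcome = OutcomeSpec("binary", y=np.ones(10), subject_order=E.subject_order)
        with pytest.raises(DegenerateInputError):
            logistic_association(E, outcome)


class TestCoxAssociation:
    def test_gamma_matches_partial_likelihood_grid_search(self):
        # tie-free worked dataset; E deliberately not concordant with the
        # event order, so the partial-likelihood maximum is finite
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1], dtype=float)
        e = np.array([0.9, 0.1, 0.5, 0.8, 0.3])
        E = _vector(e, ids=list("abcde"))
        outcome = OutcomeSpec("survival", y=time, event=event,
                              subject_order=list("abcde"))
        res = cox_lrt_association(E, outcome)
        oracle = grid_search_cox_gamma(e, time, event)
        assert res.coefficient == pytest.approx(oracle, abs=1e-4)
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient), rel=1e-12)

    def test_breslow_and_efron_agree_without_ties(self, rng):
        n = 30
        e = rng.random(n)
        time = rng.exponential(1.0, n) + np.linspace(0, 1e-3, n)  # tie-free
        event = (rng.random(n) < 0.7).astype(float)
        ids = [str(i) for i in range(n)]
        outcome = OutcomeSpec("survival", y=time, event=event, subject_order=ids)
        r_e = cox_lrt_association(_vector(e, ids=ids), outcome, ties="efron")
        r_b = cox_lrt_association(_vector(e, ids=ids), outcome, ties="breslow")
        assert r_e.coefficient == pytest.approx(r_b.coefficient, abs=1e-3)
        assert r_e.p_value == pytest.approx(r_b.p_value, abs=1e-4)

    def test_constant_statistic_is_flagged(self):
        ids = list("abcdef")
        outcome = OutcomeSpec("survival", y=np.arange(1.0, 7.0),
                              event=np.ones(6), subject_order=ids)
        with pytest.warns(UserWarning, match="constant"):
            res = cox_lrt_association(_vector(np.full(6, 0.3), ids=ids), outcome)
        assert res.flag == "degenerate"

    def test_fewer_than_two_events_rejected(self):
        ids = list("abcd")
        outcome = OutcomeSpec("survival", y=np.arange(1.0, 5.0),
                              event=np.array([1.0, 0, 0, 0]), subject_order=ids)
        with pytest.raises(DegenerateInputError):
            cox_lrt_association(_vector([0.1, 0.4, 0.6, 0.9], ids=ids), outcome)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (3.5, 1.2), (0.25, -0.4)])
    def test_lrt_p_invariant_to_affine_rescaling(self, rng, a, b):
        n = 40
        e = rng.random(n)
        time = rng.exponential(np.exp(-e), n)
        event = (rng.random(n) < 0.75).astype(float)
        ids = [str(i) for i in range(n)]
        outcome = OutcomeSpec("survival", y=time, event=event, subject_order=ids)
        p0 = cox_lrt_association(_vector(e, ids=ids), outcome).p_value
        p1 = cox_lrt_association(_vector(a * e + b, ids=ids), outcome).p_value
        assert p1 == pytest.approx(p0, abs=1e-8)


@pytest.fixture(scope="module")
def scan_inputs():
    rng = np.random.default_rng(11)
    table = make_table(rng, n_subjects=8, ncells=40, p=5)
    ids = [f"S{j}" for j in range(8)]
    outcome = OutcomeSpec("continuous", y=rng.normal(size=8),
                          subject_order=ids)
    return table, outcome


class TestCombinationScan:
    def test_five_markers_give_26_combinations(self, scan_inputs):
        table, outcome = scan_inputs
        scan = combination_scan(table, table.marker_names, outcome,
                                bw_method="silverman")
        assert len(scan) == 26
        assert scan.groupby("size").size().to_dict() == {2: 10, 3: 10, 4: 5, 5: 1}

    def test_four_markers_give_11_combinations(self, scan_inputs):
        table, outcome = scan_inputs
        scan = combination_scan(table, table.marker_names[:4], outcome,
                                bw_method="silverman")
        assert len(scan) == 11
        assert scan.groupby("size").size().to_dict() == {2: 6, 3: 4, 4: 1}

    @pytest.mark.parametrize("p", [2, 3, 6, 8])
    def test_row_count_matches_closed_form(self, rng, p):
        table = make_table(rng, n_subjects=5, ncells=15, p=p)
        ids = [f"S{j}" for j in range(5)]
        outcome = OutcomeSpec("continuous", y=rng.normal(size=5),
                              subject_order=ids)
        scan = combination_scan(table, table.marker_names, outcome,
                                bw_method="silverman")
        assert len(scan) == 2**p - p - 1

    def test_bonferroni_alpha_partitions_level_within_size(self, scan_inputs):
        table, outcome = scan_inputs
        alpha = 0.05
        scan = combination_scan(table, table.marker_names, outcome,
                                alpha=alpha, bw_method="silverman")
        for _, grp in scan.groupby("size"):
            np.testing.assert_allclose(grp["bonferroni_alpha"] * len(grp), alpha)

    def test_two_markers_single_test_keeps_full_alpha(self, rng):
        table = make_table(rng, n_subjects=6, ncells=20, p=2)
        ids = [f"S{j}" for j in range(6)]
        outcome = OutcomeSpec("continuous", y=rng.normal(size=6),
                              subject_order=ids)
        scan = combination_scan(table, table.marker_names, outcome,
                                alpha=0.05, bw_method="silverman")
        assert len(scan) == 1
        assert scan["bonferroni_alpha"].iloc[0] == 0.05

    def test_more_than_ten_markers_refused(self, rng):
        table = make_table(rng, n_subjects=4, ncells=12, p=11)
        ids = [f"S{j}" for j in range(4)]
        outcome = OutcomeSpec("continuous", y=rng.normal(size=4),
                              subject_order=ids)
        with pytest.raises(ConfigurationError, match="2 <= p <= 10"):
            combination_scan(table, table.marker_names, outcome)
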