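"""Kernel machinery, V-term estimators, QMI statistics and bandwidths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markermi import (
    BandwidthSet,
    VTerms,
    compute_eqmi_all_subjects,
    csqmi,
    eqmi_raw,
    eqmi_star,
    estimate_v_terms,
    gaussian_kernel,
    pairwise_kernel_matrix,
    plugin_bandwidths,
    quadrature_oracle,
    silverman_bandwidths,
)
from markermi.errors import (
    ConfigurationError,
    DegenerateInputError,
    DegenerateMarkerError,
)
from markermi.qmi import select_bandwidths

from conftest import make_table
from helpers import naive_v_terms


class TestGaussianKernel:
    @pytest.mark.parametrize(
        "d,h,expected",
        [
            (0.0, 1.0, 1.0 / math.sqrt(2 * math.pi)),
            (0.0, math.sqrt(2.0), 1.0 / (math.sqrt(2 * math.pi) * math.sqrt(2))),
            (2.0, 1.0, math.exp(-2.0) / math.sqrt(2 * math.pi)),
        ],
    )
    def test_closed_form_values(self, d, h, expected):
        assert gaussian_kernel(d, h) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ConfigurationError):
            gaussian_kernel(0.5, 0.0)


class TestPairwiseKernelMatrix:
    def test_single_point_gives_sqrt2_kernel_at_zero(self):
        K = pairwise_kernel_matrix(np.array([0.5]), 1.0)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(1.0 / (2.0 * math.sqrt(math.pi)), rel=1e-12)

    def test_identical_points_give_constant_matrix(self):
        K = pairwise_kernel_matrix(np.zeros(4), 0.3)
        assert np.allclose(K, K[0, 0])
        assert K[0, 0] == pytest.approx(1.0 / (2.0 * 0.3 * math.sqrt(math.pi)))

    def test_entries_match_elementwise_closed_form(self):
        x = np.array([0.0, 0.1, 0.3])
        h = 0.1
        K = pairwise_kernel_matrix(x, h)
        for i in range(3):
            for s in range(3):
                expected = gaussian_kernel(x[i] - x[s], math.sqrt(2.0) * h)
                assert K[i, s] == pytest.approx(expected, rel=1e-14)
        assert np.allclose(K, K.T)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ConfigurationError):
            pairwise_kernel_matrix(np.array([0.1, np.nan]), 0.1)


class TestVTermEstimation:
    def test_matches_triple_loop_on_fixed_dataset(self, fixed_pairs):
        bw = BandwidthSet(h=[0.1, 0.1])
        v = estimate_v_terms(fixed_pairs, bw)
        vj, vc, vm = naive_v_terms(fixed_pairs, [0.1, 0.1])
        assert v.v_j == pytest.approx(vj, rel=1e-12)
        assert v.v_c == pytest.approx(vc, rel=1e-12)
        assert v.v_m == pytest.approx(vm, rel=1e-12)

    @pytest.mark.parametrize("p", [2, 3])
    def test_matches_triple_loop_with_unequal_bandwidths(self, rng, p):
        X = rng.random((12, p))
        h = rng.uniform(0.03, 0.3, size=p)
        v = estimate_v_terms(X, BandwidthSet(h=h))
        vj, vc, vm = naive_v_terms(X, h)
        np.testing.assert_allclose([v.v_j, v.v_c, v.v_m], [vj, vc, vm], rtol=1e-12)

    def test_single_cell_degenerate_case(self):
        X = np.array([[0.3, 0.7]])
        v = estimate_v_terms(X, BandwidthSet(h=[0.1, 0.2]))
        g0 = gaussian_kernel(0.0, math.sqrt(2) * 0.1) * gaussian_kernel(
            0.0, math.sqrt(2) * 0.2
        )
        assert v.v_j == pytest.approx(g0, rel=1e-12)
        assert v.v_c == pytest.approx(g0, rel=1e-12)
        assert v.v_m == pytest.approx(g0, rel=1e-12)
        assert eqmi_star(v) == 0.0

    def test_equal_bandwidth_vector_matches_scalar(self, rng):
        X = rng.random((20, 3))
        v1 = estimate_v_terms(X, BandwidthSet(h=[0.1]))
        v2 = estimate_v_terms(X, BandwidthSet(h=[0.1, 0.1, 0.1]))
        assert (v1.v_j, v1.v_c, v1.v_m) == (v2.v_j, v2.v_c, v2.v_m)


class TestQmiStatistics:
    def test_eqmi_star_is_one_when_cross_term_vanishes(self):
        assert eqmi_star(VTerms(2.0, 0.0, 3.0)) == 1.0

    def test_eqmi_star_is_zero_at_independence_identity(self):
        assert eqmi_star(VTerms(1.7, 1.7, 1.7)) == 0.0

    def test_eqmi_raw_arithmetic(self):
        assert eqmi_raw(VTerms(2.0, 0.0, 3.0)) == 5.0
        assert eqmi_raw(VTerms(1.0, 1.0, 1.0)) == 0.0

    def test_csqmi_arithmetic(self):
        assert csqmi(VTerms(1.0, 1.0, 1.0)) == pytest.approx(0.0)
        assert csqmi(VTerms(4.0, 2.0, 4.0)) == pytest.approx(math.log(4.0))
        assert csqmi(VTerms(1.0, 0.0, 1.0)) == math.inf

    def test_fixed_dataset_value_matches_oracle(self, fixed_pairs):
        from helpers import naive_eqmi_star

        v = estimate_v_terms(fixed_pairs, BandwidthSet(h=[0.1, 0.1]))
        assert eqmi_star(v) == pytest.approx(
            naive_eqmi_star(fixed_pairs, [0.1, 0.1]), rel=1e-12
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        data=st.integers(0, 2**31 - 1),
        n=st.integers(2, 30),
        p=st.integers(2, 3),
    )
    def test_eqmi_star_bounded_on_random_data(self, data, n, p):
        rng = np.random.default_rng(data)
        X = rng.random((n, p))
        h = rng.uniform(0.02, 0.5, size=p)
        v = estimate_v_terms(X, BandwidthSet(h=h))
        val = eqmi_star(v)
        assert 0.0 <= val <= 1.0
        assert eqmi_raw(v) >= -1e-10


class TestBandwidthSelection:
    def test_silverman_matches_hand_computation(self):
        x = np.array([0.05, 0.1, 0.12, 0.2, 0.33, 0.4, 0.41, 0.52, 0.6, 0.9])
        sd = x.std(ddof=1)
        iqr = np.quantile(x, 0.75) - np.quantile(x, 0.25)
        expected = 0.9 * min(sd, iqr / 1.34) * 10 ** (-0.2)
        bw = silverman_bandwidths(np.column_stack([x, x[::-1]]))
        assert bw.h[0] == pytest.approx(expected, rel=1e-12)

    def test_silverman_approaches_analytic_normal_limit(self, rng):
        X = rng.standard_normal((1024, 2))
        bw = silverman_bandwidths(X)
        assert bw.h[0] == pytest.approx(0.9 * 1024 ** (-0.2), abs=0.02)

    def test_constant_marker_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(DegenerateMarkerError):
            silverman_bandwidths(X)
        with pytest.raises(DegenerateMarkerError):
            plugin_bandwidths(X)

    def test_plugin_near_amise_optimum_for_normal(self, rng):
        X = rng.standard_normal((1000, 2))
        bw = plugin_bandwidths(X)
        target = (4.0 / (3.0 * 1000)) ** 0.2  # AMISE-optimal, sigma = 1
        for h in bw.h:
            assert abs(h - target) / target < 0.25

    def test_plugin_switches_to_silverman_above_six_markers(self, rng):
        X = rng.random((200, 7))
        with pytest.warns(UserWarning, match="Silverman"):
            bw = plugin_bandwidths(X)
        assert bw.method_tag == "silverman"

    def test_plugin_needs_at_least_four_cells(self, rng):
        with pytest.raises(DegenerateInputError):
            plugin_bandwidths(rng.random((3, 2)))

    def test_fixed_dispatch_broadcasts_scalar(self, rng):
        bw = select_bandwidths(rng.random((10, 3)), "fixed", fixed_h=0.07)
        np.testing.assert_allclose(bw.h, [0.07, 0.07, 0.07])


class TestQuadratureOracle:
    def test_v_terms_form_a_square_integral(self, rng):
        X = rng.random((40, 2))
        v = quadrature_oracle(X, BandwidthSet(h=[0.1, 0.15]))
        assert v.v_j - 2 * v.v_c + v.v_m >= -1e-10

    def test_agrees_with_pairwise_estimator(self, rng):
        X = rng.random((200, 2))
        bw = plugin_bandwidths(X)
        v_fast = estimate_v_terms(X, bw)
        v_quad = quadrature_oracle(X, bw)
        for a, b in [(v_fast.v_j, v_quad.v_j), (v_fast.v_c, v_quad.v_c),
                     (v_fast.v_m, v_quad.v_m)]:
            assert abs(a - b) / abs(b) < 1e-4

    def test_agrees_with_triple_loop_on_fixed_dataset(self, fixed_pairs):
        v = quadrature_oracle(fixed_pairs, BandwidthSet(h=[0.1, 0.1]),
                              grid_size=801)
        vj, vc, vm = naive_v_terms(fixed_pairs, [0.1, 0.1])
        np.testing.assert_allclose([v.v_j, v.v_c, v.v_m], [vj, vc, vm], rtol=1e-6)

    def test_rejects_more_than_two_markers(self, rng):
        with pytest.raises(ConfigurationError):
            quadrature_oracle(rng.random((10, 3)), BandwidthSet(h=[0.1] * 3))


class TestAllSubjects:
    def test_identical_subjects_get_identical_values(self, rng):
        X = rng.random((60, 2))
        import pandas as pd

        frame = pd.concat(
            [
                pd.DataFrame({"subject_id": "a", "M1": X[:, 0], "M2": X[:, 1]}),
                pd.DataFrame({"subject_id": "b", "M1": X[:, 0], "M2": X[:, 1]}),
            ],
            ignore_index=True,
        )
        from markermi import CellTable

        table = CellTable(frame=frame, marker_names=["M1", "M2"])
        res = compute_eqmi_all_subjects(table, bw_method="silverman")
        assert res["eqmi_star"].iloc[0] == res["eqmi_star"].iloc[1]

    def test_cell_order_permutation_invariance(self, rng):
        table = make_table(rng, n_subjects=1, ncells=80)
        res1 = compute_eqmi_all_subjects(table, bw_method="silverman")
        perm = table.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        from markermi import CellTable

        res2 = compute_eqmi_all_subjects(
            CellTable(frame=perm, marker_names=table.marker_names),
            bw_method="silverman",
        )
        assert res1["eqmi_star"].iloc[0] == pytest.approx(
            res2["eqmi_star"].iloc[0], abs=1e-12
        )

    def test_perfect_dependence_beats_independence(self, rng):
        dep = make_table(rng, n_subjects=1, ncells=500, dependent=True)
        ind = make_table(rng, n_subjects=1, ncells=500, dependent=False)
        e_dep = compute_eqmi_all_subjects(dep, bw_method="fixed", fixed_h=0.05)
        e_ind = compute_eqmi_all_subjects(ind, bw_method="fixed", fixed_h=0.05)
        assert e_dep["eqmi_star"].iloc[0] > e_ind["eqmi_star"].iloc[0]

    def test_degenerate_subject_excluded_with_warning(self, rng):
        import pandas as pd

        from markermi import CellTable

        frame = pd.concat(
            [
                pd.DataFrame({"subject_id": "ok", "M1": rng.random(30),
                              "M2": rng.random(30)}),
                pd.DataFrame({"subject_id": "flat", "M1": np.ones(30),
                              "M2": rng.random(30)}),
            ],
            ignore_index=True,
        )
        table = CellTable(frame=frame, marker_names=["M1", "M2"])
        with pytest.warns(UserWarning, match="flat"):
            res = compute_eqmi_all_subjects(table, bw_method="silverman")
        assert res["subject_id"].tolist() == ["ok"]

    def test_output_schema(self, rng):
        table = make_table(rng, n_subjects=3, ncells=40)
        res = compute_eqmi_all_subjects(table, bw_method="silverman")
        assert list(res.columns) == [
            "subject_id", "marker_set", "eqmi_star", "eqmi_raw", "csqmi",
            "n_cells", "h_1", "h_2", "bw_method",
        ]
        assert res["eqmi_star"].between(0, 1).all()
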