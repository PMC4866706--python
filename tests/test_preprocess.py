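"""Background correction, quantile normalization and floor filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from myolab.preprocess import (
    EPSILON,
    NormexpParams,
    compute_detection_floor,
    estimate_normexp_params,
    floor_filter,
    normexp_correct,
    preprocess,
    quantile_normalize,
)
from myolab.simulate import MixtureParams, StudyDesign, default_catalog, generate_study

from conftest import make_matrix, two_group_metadata


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

class TestEstimateParams:
    def test_degenerate_controls(self):
        vals = np.vstack([np.full((5, 2), 1100.0), np.full((10, 2), 100.0)])
        m = make_matrix(vals, n_controls=10)
        p = estimate_normexp_params(m, "s0")
        assert p.mu == 100.0
        assert p.sigma == EPSILON
        assert p.theta == pytest.approx(1000.0)

    def test_moments_match_numpy(self):
        rng = np.random.default_rng(0)
        controls = rng.normal(100, 10, size=(20, 1))
        regular = rng.normal(600, 50, size=(30, 1))
        m = make_matrix(np.vstack([regular, controls]), n_controls=20)
        p = estimate_normexp_params(m, "s0")
        assert p.mu == pytest.approx(controls.mean())
        assert p.sigma == pytest.approx(controls.std(ddof=1))
        assert p.theta == pytest.approx(regular.mean() - controls.mean())

    def test_too_few_controls_raises(self):
        m = make_matrix(np.ones((10, 2)) * 50, n_controls=5)
        with pytest.raises(ValueError, match="10"):
            estimate_normexp_params(m, "s0")

    def test_monte_carlo_recovery_of_background_location(self):
        """Background Normal(100, 15): mu recovered within 2 units over 1000
        control probes."""
        catalog = default_catalog(class_sizes={"negative_control": 1000}, seed=9)
        study = generate_study(catalog, MixtureParams(), StudyDesign(seed=9))
        p = estimate_normexp_params(study.expression, study.expression.sample_ids[0])
        assert abs(p.mu - 100.0) < 2.0


# ---------------------------------------------------------------------------
# normexp correction
# ---------------------------------------------------------------------------

def _posterior_mean_quadrature(o, mu, sigma, theta):
    """Independent oracle: numerical integration of E[S | O = o] under the
    normal-background + exponential-signal convolution with 0 < S < o."""
    w = lambda s: np.exp(-s / theta) * stats.norm.pdf(o - s, loc=mu, scale=sigma)
    num, _ = integrate.quad(lambda s: s * w(s), 0, o, limit=200)
    den, _ = integrate.quad(w, 0, o, limit=200)
    return num / den


class TestNormexpCorrect:
    def test_zero_noise_limit_subtracts_background(self):
        vals = np.full((3, 2), 1100.0)
        m = make_matrix(vals)
        p = {s: NormexpParams(mu=100.0, sigma=EPSILON, theta=1000.0) for s in m.sample_ids}
        out = normexp_correct(m, p)
        np.testing.assert_allclose(out.values.to_numpy(), 1000.0, rtol=1e-6)

    @pytest.mark.parametrize("o", [120.0, 150.0, 300.0, 1500.0])
    def test_matches_quadrature_oracle(self, o):
        mu, sigma, theta = 100.0, 20.0, 800.0
        m = make_matrix(np.array([[o]]))
        p = {"s0": NormexpParams(mu=mu, sigma=sigma, theta=theta)}
        got = normexp_correct(m, p).values.iloc[0, 0]
        want = _posterior_mean_quadrature(o, mu, sigma, theta)
        assert got == pytest.approx(want, rel=1e-4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        o1=st.floats(1.0, 5e4),
        delta=st.floats(0.01, 5e4),
        mu=st.floats(20.0, 300.0),
        sigma=st.floats(1.0, 60.0),
        theta=st.floats(50.0, 5e3),
    )
    def test_positive_and_monotone(self, o1, delta, mu, sigma, theta):
        """Corrected intensities are strictly positive and monotone
        increasing in the observed intensity for fixed parameters."""
        o2 = o1 + delta
        m = make_matrix(np.array([[o1], [o2]]))
        p = {"s0": NormexpParams(mu=mu, sigma=sigma, theta=theta)}
        out = normexp_correct(m, p).values["s0"].to_numpy()
        assert (out > 0).all()
        assert out[0] < out[1] + 1e-12


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_two_point_rank_means(self):
        m = make_matrix(np.array([[1.0, 3.0], [2.0, 4.0]]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, [[2.0, 2.0], [3.0, 3.0]])

    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col, col, col]))

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.lognormal(5, 1, size=(40, 6)))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_idempotent_and_mean_conserving(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(4, 1, size=(30, 4))
        m = make_matrix(x)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), rtol=1e-12
        )
        assert once.values.to_numpy().mean() == pytest.approx(x.mean(), rel=1e-9)

    def test_ties_get_span_mean(self):
        # column 0 has a two-way tie spanning reference ranks 1 and 2
        m = make_matrix(np.array([[1.0, 10.0], [5.0, 20.0], [5.0, 30.0]]))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(np.array([[1.0, 10.0], [5.0, 20.0], [5.0, 30.0]]), axis=0).mean(axis=1)
        assert out[0, 0] == pytest.approx(ref[0])
        assert out[1, 0] == pytest.approx((ref[1] + ref[2]) / 2)
        assert out[2, 0] == pytest.approx((ref[1] + ref[2]) / 2)

    def test_single_sample_warns_and_passes_through(self):
        m = make_matrix(np.array([[1.0], [2.0]]))
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())


# ---------------------------------------------------------------------------
# detection floor
# ---------------------------------------------------------------------------

class TestDetectionFloor:
    def test_rounds_median_to_nearest_integer(self):
        vals = np.vstack([np.full((1, 3), 500.0), np.array([[99.6, 100.1, 100.4]])])
        m = make_matrix(vals, n_controls=1)
        assert compute_detection_floor(m) == 100

    def test_single_control_value(self):
        vals = np.vstack([np.full((1, 3), 500.0), np.full((1, 3), 87.2)])
        m = make_matrix(vals, n_controls=1)
        assert compute_detection_floor(m) == 87

    def test_half_rounds_away_from_zero(self):
        vals = np.vstack([np.full((1, 2), 500.0), np.full((1, 2), 100.5)])
        m = make_matrix(vals, n_controls=1)
        assert compute_detection_floor(m) == 101

    def test_no_controls_raises(self):
        m = make_matrix(np.ones((3, 2)) * 50)
        with pytest.raises(ValueError, match="floor"):
            compute_detection_floor(m)

    def test_synthetic_defaults_floor_in_expected_band(self, default_study):
        assert 90 <= compute_detection_floor(default_study.expression) <= 110


# ---------------------------------------------------------------------------
# floor filter
# ---------------------------------------------------------------------------

class TestFloorFilter:
    @pytest.fixture()
    def matrix_and_groups(self):
        # probe0: both group means below 100; probe1: one group above
        vals = np.array(
            [[50.0, 50.0, 80.0, 80.0],
             [150.0, 150.0, 50.0, 50.0],
             [500.0, 500.0, 500.0, 500.0],
             [100.0, 100.0, 100.0, 100.0]]  # control
        )
        m = make_matrix(vals, n_controls=1)
        md = two_group_metadata(2, 2)
        return m, md

    def test_both_groups_below_removed(self, matrix_and_groups):
        m, md = matrix_and_groups
        out = floor_filter(m, md, 100)
        assert "p0" not in out.probe_ids

    def test_one_group_above_retained(self, matrix_and_groups):
        m, md = matrix_and_groups
        out = floor_filter(m, md, 100)
        assert "p1" in out.probe_ids

    def test_controls_always_removed(self, matrix_and_groups):
        m, md = matrix_and_groups
        out = floor_filter(m, md, 0)
        assert "p3" not in out.probe_ids
        assert set(out.probe_ids) == {"p0", "p1", "p2"}

    def test_monotone_in_floor(self, matrix_and_groups):
        m, md = matrix_and_groups
        low = set(floor_filter(m, md, 60).probe_ids)
        high = set(floor_filter(m, md, 200).probe_ids)
        assert high <= low

    def test_all_removed_raises(self, matrix_and_groups):
        m, md = matrix_and_groups
        with pytest.raises(ValueError):
            floor_filter(m, md, 1e9)


def test_full_chain_deterministic(dilution_study):
    a, rep_a = preprocess(dilution_study.expression, dilution_study.metadata)
    b, rep_b = preprocess(dilution_study.expression, dilution_study.metadata)
    pd.testing.assert_frame_equal(a.values, b.values)
    assert rep_a["floor"] == rep_b["floor"]
    assert (
        rep_a["n_probes_retained"] + rep_a["n_probes_removed"] + rep_a["n_control_probes"]
        == rep_a["n_probes_input"]
    )
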