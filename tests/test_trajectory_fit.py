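import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from devodiverge import (
    AgeGrid,
    AgeTransform,
    SampleRecord,
    common_age_grid,
    fit_trajectory,
    interpolate,
    transform_age,
)
from devodiverge.trajectory_fit import AgeTransformError


class TestTransformAge:
    def test_newborn_is_log2_of_gestation_offset(self):
        t = AgeTransform(offsets={"human": 280.0})
        assert transform_age(0.0, "human", t) == pytest.approx(np.log2(280.0))

    @pytest.mark.parametrize("k", [9, 10, 12.5, 15])
    def test_inverse_identity(self, k):
        o = 280.0
        t = AgeTransform(offsets={"human": o})
        assert transform_age(2.0**k - o, "human", t) == pytest.approx(k, abs=1e-12)

    def test_unknown_species_errors(self):
        with pytest.raises(AgeTransformError):
            transform_age(10.0, "bonobo", AgeTransform())

    def test_negative_age_errors(self):
        with pytest.raises(AgeTransformError):
            transform_age(-1.0, "human", AgeTransform())

    def test_non_monotone_landmarks_rejected_at_construction(self):
        with pytest.raises(AgeTransformError):
            AgeTransform(
                mode="life_history",
                landmark_map={"chimpanzee": [(0.0, 0.0), (100.0, 50.0), (90.0, 80.0)]},
            )

    def test_life_history_halftime_landmark_oracle(self):
        # landmarks: own 0 -> ref 0, own 8y -> ref 16y (a 2x slower species);
        # 4y must map where the identity transform sends 8y on the reference
        y8, y16, y4 = 8 * 365.0, 16 * 365.0, 4 * 365.0
        t = AgeTransform(
            mode="life_history",
            landmark_map={"chimpanzee": [(0.0, 0.0), (y8, y16)]},
            reference="human",
        )
        expected = transform_age(y8, "human", AgeTransform())
        assert transform_age(y4, "chimpanzee", t) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(0.0, 3e4),
        delta=st.floats(1e-3, 1e4),
        mode=st.sampled_from(["log2_offset", "life_history"]),
    )
    def test_strictly_increasing_in_age(self, a, delta, mode):
        if mode == "log2_offset":
            t = AgeTransform()
        else:
            t = AgeTransform(
                mode="life_history",
                landmark_map={"human": [(0.0, 0.0), (1000.0, 700.0), (3e4, 4e4)]},
            )
        assert transform_age(a + delta, "human", t) > transform_age(a, "human", t)


class TestFitTrajectory:
    def test_exact_line_selected_and_recovered(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 1.0 + 2.0 * x
        m = fit_trajectory(x, y, max_degree=3)
        assert m.degree == 1
        np.testing.assert_allclose(m.coefficients, [1.0, 2.0], atol=1e-9)

    def test_constant_y_gives_degree_zero(self, rng):
        x = rng.uniform(0, 10, 12)
        y = np.full(12, 3.5)
        m = fit_trajectory(x, y)
        assert m.degree == 0
        assert m.coefficients[0] == pytest.approx(3.5)
        assert m.rss == pytest.approx(0.0, abs=1e-20)

    def test_noisy_cubic_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(-2, 2, 30)
        beta = np.array([0.5, -1.0, 0.8, 0.6])
        y = np.vander(x, 4, increasing=True) @ beta + rng.normal(0, 0.1, 30)
        m = fit_trajectory(x, y, max_degree=3)
        assert m.degree == 3
        X = np.vander(x, 4, increasing=True)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(m.coefficients, oracle, atol=1e-8)

    @pytest.mark.parametrize("d", [0, 1, 2, 3])
    @pytest.mark.parametrize("selection", ["adjR2", "ftest"])
    def test_noiseless_polynomial_recovers_exact_degree(self, d, selection, rng):
        x = rng.uniform(0, 5, 25)
        beta = np.r_[rng.uniform(0.5, 2.0, d + 1)]
        y = np.vander(x, d + 1, increasing=True) @ beta
        m = fit_trajectory(x, y, max_degree=3, selection=selection)
        assert m.degree == d

    def test_chosen_rss_never_worse_than_constant(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 5, 15)
            y = rng.normal(size=15)
            m = fit_trajectory(x, y)
            rss0 = float(np.sum((y - y.mean()) ** 2))
            assert m.rss <= rss0 + 1e-12

    def test_duplicated_x_caps_degree(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        y = np.array([1.0, 1.2, 2.0, 2.2, 3.0, 3.2])
        m = fit_trajectory(x, y, max_degree=3)
        assert m.degree <= 2  # only 3 distinct x values

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            fit_trajectory([1.0, 2.0], [1.0, 2.0], max_degree=3)


def _samples(ranges):
    out = []
    for sp, ages in ranges.items():
        out += [
            SampleRecord(f"{sp}{i}", sp, "PFC", float(a)) for i, a in enumerate(ages)
        ]
    return out


class TestCommonAgeGrid:
    def test_span_is_interval_intersection(self, transform):
        # transformed spans intersect at [max of mins, min of maxes]
        samples = _samples(
            {"human": [0.0, 30000.0], "chimpanzee": [100.0, 9000.0], "macaque": [0.0, 8000.0]}
        )
        grid = common_age_grid(samples, transform, G=20)
        mins = {
            sp: transform_age(min(a), sp, transform)
            for sp, a in {
                "human": [0.0, 30000.0],
                "chimpanzee": [100.0, 9000.0],
                "macaque": [0.0, 8000.0],
            }.items()
        }
        maxs = {
            sp: transform_age(max(a), sp, transform)
            for sp, a in {
                "human": [0.0, 30000.0],
                "chimpanzee": [100.0, 9000.0],
                "macaque": [0.0, 8000.0],
            }.items()
        }
        assert grid.span[0] == pytest.approx(max(mins.values()))
        assert grid.span[1] == pytest.approx(min(maxs.values()))

    def test_two_point_grid_is_endpoints(self, transform):
        samples = _samples({"human": [0.0, 1000.0], "chimpanzee": [0.0, 1000.0]})
        grid = common_age_grid(samples, transform, G=2)
        np.testing.assert_allclose(grid.points, grid.span)

    def test_span_matches_brute_force_scan(self, transform, rng):
        ranges = {
            sp: rng.uniform(0, 20000, 8)
            for sp in ("human", "chimpanzee", "macaque")
        }
        samples = _samples(ranges)
        grid = common_age_grid(samples, transform, G=10)
        xs = {
            sp: [transform_age(a, sp, transform) for a in ages]
            for sp, ages in ranges.items()
        }
        assert grid.span[0] == pytest.approx(max(min(v) for v in xs.values()))
        assert grid.span[1] == pytest.approx(min(max(v) for v in xs.values()))
        assert np.all(grid.points >= grid.span[0] - 1e-12)
        assert np.all(grid.points <= grid.span[1] + 1e-12)

    def test_empty_overlap_advises_life_history(self):
        t = AgeTransform(offsets={"human": 1.0, "chimpanzee": 1.0, "macaque": 1.0})
        samples = _samples({"human": [0.0, 1.0], "chimpanzee": [1000.0, 2000.0]})
        with pytest.raises(ValueError, match="life_history"):
            common_age_grid(samples, t)


class TestInterpolate:
    def _model(self, coeffs):
        from devodiverge.trajectory_fit import TrajectoryModel

        return TrajectoryModel("g", "human", len(coeffs) - 1, np.array(coeffs), 10, 0.0, 5)

    def test_degree0_constant_vector(self):
        grid = AgeGrid(points=np.linspace(0, 1, 7), span=(0.0, 1.0))
        np.testing.assert_allclose(interpolate(self._model([2.5]), grid), 2.5)

    def test_identity_line(self):
        grid = AgeGrid(points=np.array([1.0, 2.0, 3.0]), span=(1.0, 3.0))
        np.testing.assert_allclose(interpolate(self._model([0.0, 1.0]), grid), [1, 2, 3])

    def test_matches_horner_reference(self, rng):
        for _ in range(25):
            coeffs = rng.normal(size=4)
            pts = np.sort(rng.uniform(-2, 2, 9))
            pts += np.arange(9) * 1e-9  # ensure strictly increasing
            grid = AgeGrid(points=pts, span=(pts[0], pts[-1]))
            horner = np.array(
                [((coeffs[3] * p + coeffs[2]) * p + coeffs[1]) * p + coeffs[0] for p in pts]
            )
            np.testing.assert_allclose(
                interpolate(self._model(list(coeffs)), grid), horner, atol=1e-12
            )
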