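"""Pearson screen: coefficient, p-value and the min-of-n selection rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cholscreen as cs
from cholscreen.errors import DegenerateVarianceError, InsufficientStrainsError
from cholscreen.simulate import SimulationParams, simulate_celldeath, simulate_panel


def _pearson_oracle(x, y):
    """Explicit-sums product-moment formula, independent of the array path."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


class TestPearsonR:
    @pytest.mark.parametrize("x, y, expected", [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 4), (2, 3, 7), 0.9897433186107870),  # hand-evaluated sums
    ])
    def test_examples(self, x, y, expected):
        assert cs.pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported(self):
        with pytest.raises(DegenerateVarianceError, match="x"):
            cs.pearson_r((5, 5, 5), (1, 2, 3))

    def test_duplicated_values_with_spread_are_legal(self):
        # mirrors the published panel: two strains share an abundance value
        r = cs.pearson_r((16.4, 16.4, 16.2), (10.0, 30.0, 50.0))
        assert -1.0 <= r <= 1.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientStrainsError):
            cs.pearson_r((1, 2), (3, 4))

    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_explicit_sums_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 10))
        y = rng.normal(size=x.size)
        assert cs.pearson_r(x, y) == pytest.approx(
            _pearson_oracle(list(x), list(y)), abs=1e-12
        )

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_invariant_under_positive_affine_maps(self, a, b):
        x, y = [1.0, 2.0, 4.0, 8.0], [3.0, 1.0, 4.0, 9.0]
        base = cs.pearson_r(x, y)
        assert cs.pearson_r([a * v + b for v in x], y) == pytest.approx(base)
        assert cs.pearson_r([-a * v + b for v in x], y) == pytest.approx(-base)


class TestCorrelationPvalue:
    def test_r_zero_gives_p_one(self):
        assert cs.correlation_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_perfect_correlation_reports_zero(self):
        assert cs.correlation_pvalue(1.0, 3) == 0.0

    def test_three_point_case_matches_cauchy_form(self):
        # with 1 degree of freedom the t distribution is standard Cauchy:
        # p = (2 /pi) * arctan(1 / t)
        r, n = 0.963, 3
        t = r * math.sqrt((n - 2) / (1 - r * r))
        expected = (2 / math.pi) * math.atan(1 / t)
        assert cs.correlation_pvalue(r, n) == pytest.approx(expected, rel=1e-12)
        assert cs.correlation_pvalue(r, n) == pytest.approx(0.174, abs=5e-4)

    def test_p_shrinks_as_r_approaches_one(self):
        ps = [cs.correlation_pvalue(r, 3) for r in (0.9, 0.99, 0.9999)]
        assert ps[0] > ps[1] > ps[2] > 0.0


class TestSelectionRule:
    def test_published_grid_selection(self, study):
        cfg = cs.ScreenConfig()
        selected = cs.select_from_grid(study.correlations, cfg)
        assert selected == ["Cept1", "Slc44a1"]

    def test_three_of_four_is_enough(self, study):
        # Slc44a1 passes exactly 3 conditions (0.521 fails)
        row = study.correlations.loc[["Slc44a1"]]
        assert cs.select_from_grid(row, cs.ScreenConfig()) == ["Slc44a1"]
        assert cs.select_from_grid(row, cs.ScreenConfig(min_conditions=4)) == []

    def test_threshold_is_strict(self):
        # two cells exactly at 0.7 do not count ("over 0.7"), leaving 2 < 3
        grid = pd.DataFrame({"c1": [0.7], "c2": [0.7], "c3": [0.72],
                             "c4": [0.73]}, index=["g1"])
        assert cs.select_from_grid(grid, cs.ScreenConfig()) == []
        nudged = grid + 1e-9
        assert cs.select_from_grid(nudged, cs.ScreenConfig()) == ["g1"]

    @given(st.integers(0, 2 ** 32 - 1))
    def test_signed_mode_never_more_permissive_than_absolute(self, seed):
        rng = np.random.default_rng(seed)
        grid = pd.DataFrame(rng.uniform(-1, 1, size=(6, 4)),
                            index=[f"g{i}" for i in range(6)])
        signed = cs.select_from_grid(grid, cs.ScreenConfig())
        absolute = cs.select_from_grid(
            grid, cs.ScreenConfig(use_absolute_r=True)
        )
        assert set(signed) <= set(absolute)


class TestScreenCorrelations:
    def test_noiseless_planted_gene_hits_unity_everywhere(self):
        params = SimulationParams(seed=5, noise_sd=0.0, n_strains=5,
                                  n_missing_strains=0, p_gene_missing=0.0)
        _, proteome, truth = simulate_panel(params)
        matrix = cs.build_reduction_matrix(
            simulate_celldeath(params, proteome), cs.Convention.REDUCTION
        )
        grid, cells, selected = cs.screen_correlations(
            proteome, matrix, ["planted1"], cs.ScreenConfig()
        )
        assert np.allclose(np.abs(grid.to_numpy()), 1.0, atol=1e-9)
        assert selected == ["planted1"]
        assert all(c.n == 5 for c in cells)

    def test_strains_without_proteome_data_are_dropped(self):
        params = SimulationParams(seed=5, noise_sd=0.0, n_strains=4,
                                  n_missing_strains=1, p_gene_missing=0.0)
        _, proteome, truth = simulate_panel(params)
        matrix = cs.build_reduction_matrix(
            simulate_celldeath(params, proteome), cs.Convention.REDUCTION
        )
        _, cells, _ = cs.screen_correlations(
            proteome, matrix, ["planted1"], cs.ScreenConfig()
        )
        assert all(c.n == 3 for c in cells)  # 4 strains minus the missing one

    def test_fewer_than_three_common_strains_raises(self):
        frame = pd.DataFrame(
            {"S1": [10.0], "S2": [11.0], "S3": [np.nan], "S4": [np.nan]},
            index=["g1"],
        )
        proteome = cs.ProteomeTable(frame)
        values = pd.DataFrame(
            50.0,
            index=["S1", "S2", "S3", "S4"],
            columns=pd.MultiIndex.from_tuples(
                [(r, d) for r in ("forebrain", "brainstem")
                 for d in (100.0, 250.0)]
            ),
        )
        matrix = cs.ReductionMatrix(values, cs.Convention.REDUCTION)
        with pytest.raises(InsufficientStrainsError):
            cs.screen_correlations(proteome, matrix, ["g1"], cs.ScreenConfig())
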