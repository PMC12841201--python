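"""Aggregation and the percent-reduction statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cholscreen as cs
from cholscreen.errors import DegenerateDenominatorError, MissingGroupError
from cholscreen.reduction import Convention
from cholscreen.simulate import SimulationParams, simulate_celldeath, simulate_panel


def _obs(strain, region, treatment, dose, values):
    return [
        cs.CellDeathObservation(strain, region, treatment, dose, f"L{i}", v)
        for i, v in enumerate(values)
    ]


class TestLitterAggregation:
    def test_group_mean_and_count(self):
        means = cs.litter_to_strain_means(
            _obs("B6", "brainstem", "ETOH", 0.0, [10, 20, 30])
        )
        (m,) = means
        assert m.mean_cell_death == 20.0 and m.n_litters == 3

    def test_single_litter(self):
        (m,) = cs.litter_to_strain_means(
            _obs("B6", "forebrain", "MD", 100.0, [12.5])
        )
        assert m.mean_cell_death == 12.5 and m.n_litters == 1

    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, order):
        values = [3.0, 7.5, 11.0, 2.25, 9.0, 5.5]
        base = _obs("B6", "brainstem", "ETOH", 100.0, values)
        shuffled = [base[i] for i in order]
        (a,) = cs.litter_to_strain_means(base)
        (b,) = cs.litter_to_strain_means(shuffled)
        assert a.mean_cell_death == b.mean_cell_death and a.n_litters == b.n_litters


class TestControlPooling:
    def test_litter_weighted_pooling_across_doses(self):
        obs = (_obs("B6", "brainstem", "MD", 0.0, [20, 20])
               + _obs("B6", "brainstem", "MD", 100.0, [24]))
        means = cs.litter_to_strain_means(obs)
        pooled = cs.pool_controls(means, "B6", "brainstem")
        assert pooled == pytest.approx((20 + 20 + 24) / 3)

    def test_single_dose_pooled_is_group_mean(self):
        means = cs.litter_to_strain_means(
            _obs("B6", "forebrain", "MD", 0.0, [18, 22])
        )
        assert cs.pool_controls(means, "B6", "forebrain") == 20.0

    def test_no_control_data_raises(self):
        means = cs.litter_to_strain_means(
            _obs("B6", "forebrain", "ETOH", 0.0, [40])
        )
        with pytest.raises(MissingGroupError):
            cs.pool_controls(means, "B6", "forebrain")


class TestPercentReduction:
    @pytest.mark.parametrize("ce, e0, md, convention, expected", [
        (20.0, 40.0, 20.0, Convention.REDUCTION, 100.0),  # full rescue
        (40.0, 40.0, 20.0, Convention.REDUCTION, 0.0),    # no rescue
        (25.0, 40.0, 20.0, Convention.REMAINING, 25.0),
        (25.0, 40.0, 20.0, Convention.REDUCTION, 75.0),
        (15.0, 40.0, 20.0, Convention.REMAINING, -25.0),  # below control: no clamping
        (45.0, 40.0, 20.0, Convention.REDUCTION, -25.0),  # worse than ethanol alone
    ])
    def test_examples(self, ce, e0, md, convention, expected):
        assert cs.percent_reduction(ce, e0, md, convention) == pytest.approx(expected)

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateDenominatorError):
            cs.percent_reduction(25.0, 20.0, 20.0)

    @given(st.tuples(*[st.floats(-100, 100) for _ in range(3)]).filter(
        lambda t: abs(t[1] - t[2]) > 1e-6))
    def test_conventions_sum_to_100(self, cem):
        ce, e0, md = cem
        total = (cs.percent_reduction(ce, e0, md, Convention.REMAINING)
                 + cs.percent_reduction(ce, e0, md, Convention.REDUCTION))
        assert total == pytest.approx(100.0, abs=1e-9)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_invariant_under_positive_affine_rescaling(self, scale, shift):
        ce, e0, md = 25.0, 40.0, 20.0
        base = cs.percent_reduction(ce, e0, md)
        mapped = cs.percent_reduction(scale * ce + shift, scale * e0 + shift,
                                      scale * md + shift)
        assert mapped == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestReductionMatrix:
    def _full_design(self):
        obs = []
        for strain, rescue in [("B6", 30.0), ("BXD51", 25.0)]:
            for region in ("forebrain", "brainstem"):
                obs += _obs(strain, region, "MD", 0.0, [20, 20])
                obs += _obs(strain, region, "ETOH", 0.0, [40, 40])
                obs += _obs(strain, region, "ETOH", 100.0, [rescue] * 2)
                obs += _obs(strain, region, "ETOH", 250.0, [rescue - 2] * 2)
        return obs

    def test_shape_covers_strains_and_conditions(self):
        m = cs.build_reduction_matrix(self._full_design())
        assert m.values.shape == (2, 4)
        assert not m.values.isna().any().any()
        assert m.value("B6", "forebrain", 100.0) == pytest.approx(50.0)

    def test_missing_group_leaves_nan_and_reason(self):
        obs = [o for o in self._full_design()
               if not (o.strain == "B6" and o.choline_dose == 250.0
                       and o.treatment == "ETOH")]
        m = cs.build_reduction_matrix(obs)
        assert np.isnan(m.value("B6", "forebrain", 250.0))
        assert not np.isnan(m.value("B6", "forebrain", 100.0))
        assert any(d[0] == "B6" and d[2] == 250.0 for d in m.dropped)

    def test_noiseless_generator_gives_constant_reduction(self):
        # no planted link, sigma = 0: every cell is the baseline 60% reduction
        params = SimulationParams(seed=11, noise_sd=0.0, planted_genes=(),
                                  base_remaining=0.4)
        _, proteome, _ = simulate_panel(params)
        obs = simulate_celldeath(params, proteome)
        m = cs.build_reduction_matrix(obs, Convention.REDUCTION)
        assert np.allclose(m.values.to_numpy(), 60.0)

    def test_degenerate_denominator_names_strain_and_region(self):
        obs = (_obs("B6", "brainstem", "MD", 0.0, [20, 20])
               + _obs("B6", "brainstem", "ETOH", 0.0, [20, 20])
               + _obs("B6", "brainstem", "ETOH", 100.0, [15, 15]))
        with pytest.raises(DegenerateDenominatorError, match="B6.*brainstem"):
            cs.build_reduction_matrix(obs, regions=("brainstem",))
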