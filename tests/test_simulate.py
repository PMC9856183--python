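"""Synthetic blood-panel generator: contracts, determinism, noise calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hctkit import (
    BloodSample,
    NoiseSpec,
    PanelSpec,
    correct_two_stage,
    make_hct_panel,
    make_interference_series,
    make_paired_cohort,
    plasma_equivalent,
    simulate_repeatability_draws,
    simulate_rlu,
    simulate_wb_measurement,
)
from hctkit.errors import DomainError, InvalidSpecificationError
from hctkit.simulate import panel_frame


class TestPanel:
    @pytest.mark.parametrize(
        "hct_levels, n_conc, expected",
        [
            ([0, 25, 30, 35, 40, 45, 50, 55, 60], 5, 45),
            ([40], 1, 1),
            ([25, 60], 3, 6),
        ],
    )
    def test_factorial_count_and_unique_ids(self, hct_levels, n_conc, expected):
        spec = PanelSpec(
            hct_levels=hct_levels,
            analyte_levels={"cTnI": list(np.geomspace(0.1, 50, n_conc))},
        )
        panel = make_hct_panel(spec)
        assert len(panel) == expected
        assert len({s.sample_id for s in panel}) == expected

    def test_deterministic_ordering_by_hct_then_conc(self):
        spec = PanelSpec(hct_levels=[60, 25], analyte_levels={"a": [5.0, 1.0]})
        panel = make_hct_panel(spec)
        assert [s.true_hct for s in panel] == [25, 25, 60, 60]
        assert [s.analytes["a"] for s in panel] == [1.0, 5.0, 1.0, 5.0]

    def test_empty_spec_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            PanelSpec(hct_levels=[], analyte_levels={"a": [1.0]})
        with pytest.raises(InvalidSpecificationError):
            PanelSpec(hct_levels=[40], analyte_levels={"a": []})
        with pytest.raises(InvalidSpecificationError):
            PanelSpec(hct_levels=[40], analyte_levels={"a": [1.0]}, replicates=0)

    def test_sample_invariants_enforced(self):
        with pytest.raises(InvalidSpecificationError):
            BloodSample("bad", 101.0, {})
        with pytest.raises(InvalidSpecificationError):
            BloodSample("bad", 40.0, {"a": -1.0})

    def test_panel_frame_layout(self):
        spec = PanelSpec(hct_levels=[25, 40], analyte_levels={"cTnI": [1.0]})
        frame = panel_frame(make_hct_panel(spec))
        assert list(frame.columns) == [
            "sample_id", "true_hct", "analyte", "true_conc", "measured_conc",
            "rlu", "replicate", "interferent", "interferent_conc",
        ]
        assert len(frame) == 2


class TestRlu:
    @pytest.mark.parametrize(
        "slope, intercept, hct, expected",
        [(1000, 0, 50, 50000), (1000, 500, 0, 500)],
    )
    def test_noiseless_line(self, slope, intercept, hct, expected, noiseless):
        s = BloodSample("s", hct, {})
        assert simulate_rlu(s, slope, intercept, noiseless) == pytest.approx(expected)

    def test_noise_contract_monte_carlo(self):
        """With 2% CV the reading stays within +-10% and the sample CV is ~2%."""
        s = BloodSample("s", 40.0, {})
        noise = NoiseSpec(rlu_cv=0.02, seed=42)
        rng = np.random.default_rng(42)
        vals = np.array(
            [simulate_rlu(s, 1000, 0, noise, rng=rng) for _ in range(10_000)]
        )
        assert np.all(np.abs(vals - 40000) < 4000)
        assert np.std(vals) / np.mean(vals) == pytest.approx(0.02, rel=0.1)

    def test_seed_reproducibility(self):
        s = BloodSample("s", 40.0, {})
        noise = NoiseSpec(rlu_cv=0.05, seed=7)
        assert simulate_rlu(s, 1000, 0, noise) == simulate_rlu(s, 1000, 0, noise)

    def test_nonpositive_slope_rejected(self, noiseless):
        with pytest.raises(InvalidSpecificationError):
            simulate_rlu(BloodSample("s", 40.0, {}), 0.0, 0.0, noiseless)


class TestWbMeasurement:
    def test_plasma_sample_keeps_residual_bias(self, ctni_bias, noiseless):
        s = BloodSample("s", 0.0, {"cTnI": 1.0})
        m = simulate_wb_measurement(s, "cTnI", ctni_bias, noiseless)
        assert m == pytest.approx(1 - 0.02329, abs=1e-5)

    def test_suppression_at_hct_50(self, ctni_bias, noiseless):
        s = BloodSample("s", 50.0, {"cTnI": 1.0})
        m = simulate_wb_measurement(s, "cTnI", ctni_bias, noiseless)
        assert m == pytest.approx(0.5 * (1 - 0.15195443), abs=1e-6)

    def test_zero_concentration_stays_zero(self, ctni_bias, noiseless):
        s = BloodSample("s", 45.0, {"cTnI": 0.0})
        assert simulate_wb_measurement(s, "cTnI", ctni_bias, noiseless) == 0.0

    def test_missing_analyte_and_domain_errors(self, ctni_bias, noiseless):
        s = BloodSample("s", 45.0, {"cTnI": 1.0})
        with pytest.raises(InvalidSpecificationError):
            simulate_wb_measurement(s, "MYO", ctni_bias, noiseless)
        with pytest.raises(DomainError):
            simulate_wb_measurement(s, "cTnI", ctni_bias, noiseless, hct=100.0)

    @pytest.mark.parametrize("hct", np.linspace(0, 65, 14))
    def test_noiseless_closure_with_two_stage_correction(
        self, hct, ctni_bias, noiseless
    ):
        s = BloodSample("s", float(hct), {"cTnI": 2.5})
        m = simulate_wb_measurement(s, "cTnI", ctni_bias, noiseless)
        assert correct_two_stage(m, float(hct), ctni_bias).final_value == pytest.approx(
            2.5, abs=1e-9
        )

    def test_monotone_suppression_in_hct(self, ctni_bias, noiseless):
        h = np.linspace(0, 65, 131)
        m = [
            simulate_wb_measurement(
                BloodSample("s", float(x), {"a": 1.0}), "a", ctni_bias, noiseless
            )
            for x in h
        ]
        assert np.all(np.diff(m) < 0)


class TestRepeatabilityDraws:
    def test_no_noise_sources_gives_identical_draws(self, ctni_bias, noiseless):
        s = BloodSample("s", 45.0, {"cTnI": 1.0})
        draws = simulate_repeatability_draws(s, "cTnI", 5, ctni_bias, noiseless)
        assert len(set(draws)) == 1

    def test_jitter_sd_calibration(self, ctni_bias):
        s = BloodSample("s", 45.0, {"cTnI": 1.0})
        noise = NoiseSpec(conc_cv=0.0, sedimentation_sd=3.0, seed=9)
        draws = simulate_repeatability_draws(s, "cTnI", 10_000, ctni_bias, noise)
        hcts = np.array([h for h, _ in draws])
        assert np.std(hcts) == pytest.approx(3.0, rel=0.05)
        assert hcts.min() >= 0 and hcts.max() <= 99

    def test_reproducible_under_fixed_seed(self, ctni_bias):
        s = BloodSample("s", 45.0, {"cTnI": 1.0})
        noise = NoiseSpec(sedimentation_sd=2.0, seed=11)
        a = simulate_repeatability_draws(s, "cTnI", 10, ctni_bias, noise)
        b = simulate_repeatability_draws(s, "cTnI", 10, ctni_bias, noise)
        assert a == b

    def test_too_few_draws_rejected(self, ctni_bias, noiseless):
        s = BloodSample("s", 45.0, {"cTnI": 1.0})
        with pytest.raises(InvalidSpecificationError):
            simulate_repeatability_draws(s, "cTnI", 1, ctni_bias, noiseless)


class TestInterferenceSeries:
    def test_identity_and_midpoint_mixes(self):
        base = BloodSample("b", 40.0, {"cTnI": 1.0})
        series = make_interference_series(base, "bilirubin", 1000.0, [(10, 0), (5, 5)])
        assert series[0].true_hct == 40.0
        assert series[0].interferents["bilirubin"] == 0.0
        assert series[0].analytes == base.analytes
        assert series[1].true_hct == pytest.approx(20.0)
        assert series[1].interferents["bilirubin"] == pytest.approx(500.0)

    def test_full_series_hct_strictly_decreasing_and_linear(self):
        base = BloodSample("b", 40.0, {})
        ratios = [(10 - k, k) for k in range(11)]
        series = make_interference_series(base, "x", 100.0, ratios)
        hcts = [s.true_hct for s in series]
        assert len(series) == 11
        assert np.all(np.diff(hcts) < 0)
        # mixing conservation: HCT exactly linear in parts_sample
        assert hcts == [pytest.approx(40.0 * (10 - k) / 10) for k in range(11)]

    def test_negative_parts_rejected(self):
        base = BloodSample("b", 40.0, {})
        with pytest.raises(InvalidSpecificationError):
            make_interference_series(base, "x", 100.0, [(-1, 11)])
        with pytest.raises(InvalidSpecificationError):
            make_interference_series(base, "x", 100.0, [(0, 0)])


class TestPairedCohort:
    def test_noiseless_ratio_matches_suppression_model(self, ctni_bias, noiseless):
        pairs = make_paired_cohort(
            86, (0.1, 50.0), (25.0, 55.0), noiseless, ctni_bias
        )
        for plasma, wb, hct in pairs:
            expected = plasma_equivalent(wb, hct)  # undo volume factor
            # remaining factor is the residual bias, so wb/plasma is exact
            ratio = wb / plasma
            from hctkit import fourpl_eval

            model = (1 - hct / 100) * (1 - fourpl_eval(ctni_bias, hct) / 100)
            assert ratio == pytest.approx(model, abs=1e-12)
            assert expected < plasma  # residual bias still suppresses

    def test_fixed_seed_stable(self, ctni_bias):
        noise = NoiseSpec(seed=21)
        a = make_paired_cohort(2, (0.1, 50.0), (25.0, 55.0), noise, ctni_bias)
        b = make_paired_cohort(2, (0.1, 50.0), (25.0, 55.0), noise, ctni_bias)
        assert a == b

    def test_corrected_whole_blood_tracks_plasma(self, ctni_bias):
        """With 3% CV noise the corrected whole-blood values correlate > 0.99."""
        from hctkit import correlation

        rs = []
        for seed in range(5):
            noise = NoiseSpec(conc_cv=0.03, seed=seed)
            pairs = make_paired_cohort(
                86, (0.1, 50.0), (25.0, 55.0), noise, ctni_bias
            )
            corrected = [
                correct_two_stage(wb, h, ctni_bias).final_value
                for _, wb, h in pairs
            ]
            rs.append(correlation([p for p, _, _ in pairs], corrected)[0])
        assert min(rs) > 0.99

    def test_invalid_ranges_rejected(self, ctni_bias, noiseless):
        with pytest.raises(InvalidSpecificationError):
            make_paired_cohort(86, (50.0, 0.1), (25.0, 55.0), noiseless, ctni_bias)
        with pytest.raises(InvalidSpecificationError):
            make_paired_cohort(1, (0.1, 50.0), (25.0, 55.0), noiseless, ctni_bias)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    hct=st.floats(min_value=0.0, max_value=65.0),
    conc=st.floats(min_value=1e-3, max_value=1e4),
)
def test_round_trip_closure_property(hct, conc):
    """Noiseless measurement followed by two-stage correction returns truth."""
    from hctkit import REFERENCE_CTNI_BIAS

    noiseless = NoiseSpec(rlu_cv=0, conc_cv=0, sedimentation_sd=0, seed=0)
    s = BloodSample("s", hct, {"a": conc})
    m = simulate_wb_measurement(s, "a", REFERENCE_CTNI_BIAS, noiseless)
    out = correct_two_stage(m, hct, REFERENCE_CTNI_BIAS).final_value
    assert out == pytest.approx(conc, rel=1e-9)
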