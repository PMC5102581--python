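"""Cost engine: batch sizing, CoG/g computation and calibration round-trips."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocogs import (
    CalibrationError,
    ConfigurationError,
    batches_required,
    breakdown_shares,
    calibrate_fixture,
    cog_per_gram,
    ufdf_filter_count,
)
from biocogs.cost_engine import COST_CATEGORIES


class TestBatchesRequired:
    def test_unit_case(self):
        assert batches_required(10.0, 1.0, 1.0, 1.0) == pytest.approx(10.0)

    def test_base_chromatography_batch_output(self):
        # One batch yields 25 x 0.484 x 0.432 = 5.2272 g.
        per_batch = 25 * 0.484 * 0.432
        assert batches_required(100.0, 25.0, 0.484, 0.432) == pytest.approx(
            100.0 / per_batch
        )

    def test_doubling_titer_halves_batches(self):
        n1 = batches_required(100.0, 25.0, 0.484, 0.66)
        n2 = batches_required(100.0, 25.0, 0.968, 0.66)
        assert n2 == pytest.approx(n1 / 2.0)

    def test_integer_mode_rounds_up(self):
        assert batches_required(10.0, 1.0, 1.0, 0.7, continuous=False) == 15

    @pytest.mark.parametrize("args", [(0, 1, 1, 1), (1, -1, 1, 1), (1, 1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ConfigurationError):
            batches_required(*args)


class TestFilterCount:
    @pytest.mark.parametrize(
        "volume,capacity,expected", [(0, 100, 0), (100, 100, 1), (101, 100, 2), (250, 50, 5)]
    )
    def test_ceiling_rule(self, volume, capacity, expected):
        assert ufdf_filter_count(volume, capacity) == expected

    @given(v1=st.floats(0, 1e4), v2=st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_volume(self, v1, v2):
        lo, hi = sorted([v1, v2])
        assert ufdf_filter_count(lo, 50.0) <= ufdf_filter_count(hi, 50.0)


class TestCogPerGram:
    def test_base_chromatography_matches_calibration_target(self, bundle):
        r = cog_per_gram(
            bundle.flowsheets["chromatography"], bundle.cost_configs["chromatography"]
        )
        assert r.cog_per_gram == pytest.approx(9396.97, rel=1e-6)

    def test_base_atps_matches_calibration_target(self, bundle):
        r = cog_per_gram(bundle.flowsheets["atps"], bundle.cost_configs["atps"])
        assert r.cog_per_gram == pytest.approx(5452.00, rel=1e-6)

    def test_scaling_all_costs_doubles_cog(self, bundle):
        fs = bundle.flowsheets["atps"]
        config = bundle.cost_configs["atps"]
        doubled = replace(
            config,
            annual_fixed={k: 2 * v for k, v in config.annual_fixed.items()},
            labor_headcount_equivalent=2 * config.labor_headcount_equivalent,
            material_lines={k: 2 * v for k, v in config.material_lines.items()},
            consumable_lines={k: 2 * v for k, v in config.consumable_lines.items()},
            ufdf_filter_cost=2 * config.ufdf_filter_cost,
        )
        base = cog_per_gram(fs, config).cog_per_gram
        assert cog_per_gram(fs, doubled).cog_per_gram == pytest.approx(2 * base)

    def test_invalid_yield_delta_rejected(self, bundle):
        with pytest.raises(ConfigurationError, match="dsp_yield_delta"):
            cog_per_gram(
                bundle.flowsheets["atps"],
                bundle.cost_configs["atps"],
                dsp_yield_delta=-70.0,
            )

    @given(
        titer=st.floats(0.3, 0.7),
        delta=st.floats(-9.0, 9.0),
        eps=st.floats(0.001, 0.05),
    )
    @settings(max_examples=40, deadline=None)
    def test_cog_strictly_decreasing_in_titer_and_yield(self, bundle, titer, delta, eps):
        fs = bundle.flowsheets["chromatography"]
        config = bundle.cost_configs["chromatography"]
        c0 = cog_per_gram(fs, config, titer=titer, dsp_yield_delta=delta).cog_per_gram
        c_titer = cog_per_gram(
            fs, config, titer=titer + eps, dsp_yield_delta=delta
        ).cog_per_gram
        c_yield = cog_per_gram(
            fs, config, titer=titer, dsp_yield_delta=delta + 100 * eps
        ).cog_per_gram
        assert c_titer < c0
        assert c_yield < c0

    def test_closed_form_with_zero_fixed_costs(self, bundle):
        """With no fixed costs and no filter-ceiling effects the engine reduces
        to CoG/g = per-batch variable total / (V x titer x yield)."""
        fs = bundle.flowsheets["atps"]
        config = replace(
            bundle.cost_configs["atps"],
            annual_fixed={"capital": 0.0, "other": 0.0},
            labor_headcount_equivalent=1e-12,
        )
        from biocogs.cost_engine import consumables_per_batch, materials_per_batch
        from biocogs.flowsheet import chain_yield

        var = materials_per_batch(config, fs) + consumables_per_batch(config, fs)
        expected = var / (25.0 * 0.484 * chain_yield(fs))
        got = cog_per_gram(fs, config).cog_per_gram
        assert got == pytest.approx(expected, rel=1e-6)

    def test_result_invariant_total_consistency(self, bundle):
        r = cog_per_gram(bundle.flowsheets["atps"], bundle.cost_configs["atps"])
        assert r.cog_per_gram * r.annual_mass == pytest.approx(
            sum(r.category_costs.values()), rel=1e-12
        )


class TestBreakdownShares:
    def test_shares_sum_to_one_and_labor_is_13_percent(self, bundle):
        for pid in ("chromatography", "atps"):
            r = cog_per_gram(bundle.flowsheets[pid], bundle.cost_configs[pid])
            shares = breakdown_shares(r)
            assert sum(shares.values()) == pytest.approx(1.0)
            assert shares["labor"] == pytest.approx(0.13, abs=1e-9)

    def test_shares_invariant_under_uniform_scaling(self, bundle):
        fs = bundle.flowsheets["chromatography"]
        config = bundle.cost_configs["chromatography"]
        r = cog_per_gram(fs, config)
        scaled = replace(
            config,
            annual_fixed={k: 3 * v for k, v in config.annual_fixed.items()},
            labor_headcount_equivalent=3 * config.labor_headcount_equivalent,
            material_lines={k: 3 * v for k, v in config.material_lines.items()},
            consumable_lines={k: 3 * v for k, v in config.consumable_lines.items()},
            ufdf_filter_cost=3 * config.ufdf_filter_cost,
        )
        r3 = cog_per_gram(fs, scaled)
        for cat in COST_CATEGORIES:
            assert breakdown_shares(r3)[cat] == pytest.approx(
                breakdown_shares(r)[cat], rel=1e-12
            )

    def test_category_ordering_matches_process_character(self, bundle):
        """ATPS spends more on materials in absolute terms; chromatography
        more on capital, consumables, labor and other."""
        costs = {
            pid: cog_per_gram(
                bundle.flowsheets[pid], bundle.cost_configs[pid]
            ).category_costs
            for pid in ("chromatography", "atps")
        }
        assert costs["atps"]["materials"] > costs["chromatography"]["materials"]
        for cat in ("capital", "consumables", "labor", "other"):
            assert costs["atps"][cat] < costs["chromatography"][cat]


class TestCalibration:
    def test_round_trip_reproduces_targets(self, bundle, flowsheets):
        """Calibrating to an arbitrary feasible target round-trips exactly."""
        template = bundle.cost_configs["chromatography"]
        shares = {
            "capital": 0.30,
            "materials": 0.15,
            "consumables": 0.22,
            "labor": 0.13,
            "other": 0.20,
        }
        config = calibrate_fixture(
            flowsheets["chromatography"], 8000.0, shares, template
        )
        r = cog_per_gram(flowsheets["chromatography"], config)
        assert r.cog_per_gram == pytest.approx(8000.0, rel=1e-9)
        got = breakdown_shares(r)
        for cat, s in shares.items():
            assert got[cat] == pytest.approx(s, abs=1e-9)

    def test_zero_perturbation_is_a_fixed_point(self, bundle):
        fs = bundle.flowsheets["atps"]
        config = bundle.cost_configs["atps"]
        base = cog_per_gram(fs, config).cog_per_gram
        again = cog_per_gram(
            fs, config, titer=0.484, dsp_yield_delta=0.0, material_multiplier=1.0
        ).cog_per_gram
        assert again == base

    def test_infeasible_share_vector_raises_with_diagnostic(self, bundle, flowsheets):
        template = bundle.cost_configs["atps"]
        shares = {
            "capital": 0.40,
            "materials": 0.005,  # below the named ATPS chemical lines
            "consumables": 0.25,
            "labor": 0.13,
            "other": 0.215,
        }
        with pytest.raises(CalibrationError, match="materials"):
            calibrate_fixture(flowsheets["atps"], 5452.0, shares, template)

    def test_shares_not_summing_to_one_rejected(self, bundle, flowsheets):
        template = bundle.cost_configs["atps"]
        with pytest.raises(CalibrationError, match="sum to 1"):
            calibrate_fixture(
                flowsheets["atps"],
                5452.0,
                {c: 0.3 for c in COST_CATEGORIES},
                template,
            )
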