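"""ATPS split, back-extraction mass balance and steady-state recycle demand."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocogs import (
    ATPSSpec,
    ConfigurationError,
    RecycleSpec,
    back_extract,
    packaged_back_extraction,
    split_system,
    steady_state_fresh_demand,
)
from biocogs.atps_model import COMPONENTS, batch_inventory_kg, build_uricase_atps


class TestSplitSystem:
    def test_volume_arithmetic(self):
        spec = ATPSSpec(system_volume_multiplier=12.0, top_fraction=0.4)
        top, bottom = split_system(1.0, spec, recovery=1.0)
        assert top.volume == pytest.approx(4.8)
        assert bottom.volume == pytest.approx(7.2)

    @given(sample=st.floats(0.5, 100.0), recovery=st.floats(0.1, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_volumes_and_product_conserve(self, sample, recovery):
        spec = ATPSSpec()
        top, bottom = split_system(sample, spec, recovery)
        assert top.volume + bottom.volume == pytest.approx(
            spec.system_volume_multiplier * sample
        )
        assert top.product_mass == pytest.approx(recovery)  # destination = top
        assert bottom.product_mass == 0.0

    def test_full_recovery_puts_all_product_in_destination(self):
        top, bottom = split_system(25.0, ATPSSpec(), recovery=1.0)
        assert top.product_mass == 1.0

    def test_multiplier_outside_printed_range_rejected(self):
        with pytest.raises(ConfigurationError, match="system_volume_multiplier"):
            ATPSSpec(system_volume_multiplier=25.0)


class TestBackExtraction:
    def test_packaged_dilution_and_bottom_fraction(self):
        result = packaged_back_extraction(25.0)
        assert result.dilution_factor == pytest.approx(10.0)
        assert result.bottom_volume / result.second_system_volume == pytest.approx(0.56)

    @given(sample=st.floats(1.0, 200.0))
    @settings(max_examples=30, deadline=None)
    def test_dilution_invariant_under_sample_scaling(self, sample):
        assert packaged_back_extraction(sample).dilution_factor == pytest.approx(10.0)

    def test_component_mass_conservation(self):
        """fresh + recycled in = discarded bottom 1 + collected bottom 2 +
        recycled top 2, exactly, for every component."""
        spec, recycle = build_uricase_atps()
        sample = 25.0
        top1, bottom1 = split_system(sample, spec, recovery=1.0)
        inventory = batch_inventory_kg(spec, recycle, sample)
        result = packaged_back_extraction(sample)
        for c in COMPONENTS:
            out = (
                bottom1.component_mass_kg[c]
                + result.bottom_phase.component_mass_kg[c]
                + result.recycled_stream.component_mass_kg[c]
            )
            assert out == pytest.approx(inventory[c], rel=1e-12)

    def test_recycled_stream_carries_target_fractions(self):
        spec, recycle = build_uricase_atps()
        inventory = batch_inventory_kg(spec, recycle, 25.0)
        result = packaged_back_extraction(25.0)
        assert result.recycled_stream.component_mass_kg["peg2000"] == pytest.approx(
            0.6 * inventory["peg2000"]
        )
        assert result.recycled_stream.component_mass_kg[
            "ammonium_sulfate"
        ] == pytest.approx(0.2 * inventory["ammonium_sulfate"])
        assert result.recycled_stream.component_mass_kg["nacl"] == pytest.approx(
            0.2 * inventory["nacl"]
        )

    def test_second_system_salt_exceeds_polymer(self):
        result = packaged_back_extraction(25.0)
        # charge composition check happened inside back_extract; verify the
        # collected bottom is salt-rich relative to polymer too
        comp = result.bottom_phase.composition
        assert comp.ammonium_sulfate > comp.peg

    def test_salt_below_polymer_raises_named_error(self):
        spec, recycle = build_uricase_atps()
        top1, _ = split_system(25.0, spec, recovery=1.0)
        inventory = batch_inventory_kg(spec, recycle, 25.0)
        with pytest.raises(ConfigurationError, match="salt"):
            back_extract(
                top1,
                recycle,
                second_system_volume=450.0,
                sample_volume=25.0,
                fresh_ammonium_sulfate_kg=0.0,  # not enough salt
                batch_inventory_kg=inventory,
            )

    def test_bottom_fraction_below_half_raises(self):
        spec, _ = build_uricase_atps()
        recycle = RecycleSpec(bottom_fraction_second_system=0.4)
        top1, _ = split_system(25.0, spec, recovery=1.0)
        inventory = batch_inventory_kg(spec, recycle, 25.0)
        with pytest.raises(ConfigurationError, match="bottom"):
            back_extract(
                top1,
                recycle,
                second_system_volume=450.0,
                sample_volume=25.0,
                fresh_ammonium_sulfate_kg=recycle.fresh_as_per_sample_l * 25.0,
                batch_inventory_kg=inventory,
            )

    def test_zero_recycle_fractions_return_nothing(self):
        spec, _ = build_uricase_atps()
        recycle = RecycleSpec(r_peg=0.0, r_as=0.0, r_nacl=0.0)
        top1, _ = split_system(25.0, spec, recovery=1.0)
        inventory = batch_inventory_kg(spec, recycle, 25.0)
        result = back_extract(
            top1,
            recycle,
            second_system_volume=10.0 * 25.0 / 0.56,
            sample_volume=25.0,
            fresh_ammonium_sulfate_kg=recycle.fresh_as_per_sample_l * 25.0,
            batch_inventory_kg=inventory,
        )
        assert all(
            m == 0.0 for m in result.recycled_stream.component_mass_kg.values()
        )


class TestSteadyStateFreshDemand:
    def test_sixty_percent_peg_reuse_means_forty_percent_fresh(self):
        fresh = steady_state_fresh_demand(RecycleSpec(), {"peg2000": 100.0})
        assert fresh["peg2000"] == pytest.approx(40.0)

    def test_full_recycle_needs_no_fresh_material(self):
        recycle = RecycleSpec(r_peg=1.0, r_as=1.0, r_nacl=1.0)
        fresh = steady_state_fresh_demand(
            recycle, {c: 50.0 for c in COMPONENTS}
        )
        assert all(v == 0.0 for v in fresh.values())

    @given(r=st.floats(0.0, 1.0), inventory=st.floats(1.0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_closed_form_equals_batch_iteration_fixed_point(self, r, inventory):
        """Iterating fresh_n = inventory - r x inventory for 20 batches lands
        on the closed form after the first recycled batch."""
        recycle = RecycleSpec(r_peg=r)
        fresh = inventory  # batch 1: everything fresh
        for _ in range(20):
            fresh = inventory - r * inventory
        closed = steady_state_fresh_demand(recycle, {"peg2000": inventory})["peg2000"]
        assert fresh == pytest.approx(closed, rel=1e-12)
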