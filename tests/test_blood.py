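"""Blood partitioning, well-counter inversion and the stability verdict."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphapk import simulate
from alphapk.blood import (
    BloodSample,
    mass_to_volume,
    activity_concentration,
    partition_samples,
    plasma_wb_ratio_stats,
    rbc_activity,
    stability_verdict,
)
from alphapk.decay import PB212_HALF_LIFE_H, counting_window_correction


def make_sample(conc_kBq_mL, sample_type="whole_blood", mass_g=1.06, **kw):
    """Forward-simulate a noiseless well-counter record at a known concentration."""
    density = 1.06 if sample_type == "whole_blood" else 1.03
    delay, duration, calib = 12.0, 2.0 / 3.0, 50.0
    volume = mass_g / density
    window = counting_window_correction(delay, duration, PB212_HALF_LIFE_H)
    counts = conc_kBq_mL * volume / window * calib * duration * 3600.0
    defaults = dict(
        patient_id="P1", time_h=1.5, sample_type=sample_type, mass_g=mass_g,
        counting_delay_h=delay, counting_duration_h=duration,
        net_counts=counts, calibration=calib, hematocrit=0.41,
    )
    defaults.update(kw)
    return BloodSample(**defaults)


class TestMassToVolume:
    @pytest.mark.parametrize(
        "mass, stype, expected",
        [(1.06, "whole_blood", 1.0), (1.03, "plasma", 1.0), (0.0, "plasma", 0.0)],
    )
    def test_density_conversion(self, mass, stype, expected):
        assert mass_to_volume(mass, stype) == pytest.approx(expected)

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            mass_to_volume(1.0, "serum")


class TestActivityConcentration:
    def test_zero_counts(self):
        assert activity_concentration(make_sample(0.0)) == 0.0

    @pytest.mark.parametrize("true_conc", [0.1, 1.7, 12.0])
    def test_inverts_forward_model(self, true_conc):
        """Noiseless forward simulation is recovered to <0.5%."""
        got = activity_concentration(make_sample(true_conc))
        assert got == pytest.approx(true_conc, rel=5e-3)

    def test_halving_mass_doubles_concentration(self):
        s1 = make_sample(1.0, mass_g=1.06)
        s2 = BloodSample(**{**s1.__dict__, "mass_g": 0.53})
        assert activity_concentration(s2) == pytest.approx(
            2 * activity_concentration(s1), rel=1e-9
        )

    def test_short_delay_warns(self):
        with pytest.warns(UserWarning, match="equilibrium"):
            make_sample(1.0, counting_delay_h=2.0)


class TestPartitioning:
    def test_forced_zero(self):
        hct = 0.45
        assert rbc_activity((1 - hct) * 12.0, 12.0, hct) == pytest.approx(0.0)

    def test_direct_substitution(self):
        assert rbc_activity(10.0, 12.0, 0.45) == pytest.approx(7.556, abs=0.001)

    def test_signed_result_preserved(self):
        """Whole blood slightly below the plasma-only expectation → small
        negative red-cell concentration, reported as such."""
        got = rbc_activity(1.0, 1.7, 0.41)
        assert got == pytest.approx(-0.007, abs=0.002)
        assert got < 0

    def test_hct_bounds(self):
        for hct in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                rbc_activity(1.0, 1.0, hct)

    @given(
        st.floats(0.01, 50), st.floats(0, 50), st.floats(0.2, 0.6)
    )
    @settings(max_examples=100, deadline=None)
    def test_algebraic_round_trip(self, a_plasma, a_rbc, hct):
        """Reconstructing whole blood from (rbc, plasma, hct) inverts exactly."""
        a_wb = (1 - hct) * a_plasma + hct * a_rbc
        assert rbc_activity(a_wb, a_plasma, hct) == pytest.approx(
            a_rbc, rel=1e-9, abs=1e-9
        )


class TestPanelStatistics:
    def test_identical_ratio_pairs(self):
        samples = []
        for t in (0.5, 2.0, 5.0):
            samples.append(make_sample(1.0, "whole_blood", time_h=t))
            samples.append(make_sample(1.7, "plasma", mass_g=1.03, time_h=t))
        mean, sd = plasma_wb_ratio_stats(partition_samples(samples))
        assert mean == pytest.approx(1.7, rel=1e-3)
        assert sd == pytest.approx(0.0, abs=1e-3)

    def test_zero_binding_ratio_is_hct_identity(self):
        """With no red-cell uptake the plasma:WB ratio is 1/(1−HCT) ≈ 1.70."""
        spec = simulate.CohortSpec(seed=5, hematocrit_sd=0.0)
        parts = partition_samples(simulate.gen_blood_panel(spec))
        mean, sd = plasma_wb_ratio_stats(parts)
        assert mean == pytest.approx(1.0 / (1.0 - 0.41), abs=0.03)
        assert 0.0 <= sd < 0.1

    @pytest.mark.parametrize("hct", [0.25, 0.41, 0.55])
    def test_identity_holds_across_hct(self, hct):
        spec = simulate.CohortSpec(seed=9, hematocrit_mean=hct, hematocrit_sd=0.0)
        mean, _ = plasma_wb_ratio_stats(partition_samples(simulate.gen_blood_panel(spec)))
        assert mean == pytest.approx(1.0 / (1.0 - hct), rel=0.02)

    def test_full_binding_ratio_is_one(self):
        spec = simulate.CohortSpec(seed=5, rbc_binding_fraction=1.0)
        mean, _ = plasma_wb_ratio_stats(partition_samples(simulate.gen_blood_panel(spec)))
        assert mean == pytest.approx(1.0, abs=0.02)

    def test_unpaired_samples_are_listed(self):
        samples = [make_sample(1.0, "whole_blood", time_h=0.5)]
        with pytest.raises(ValueError, match="unpaired"):
            partition_samples(samples)


class TestStabilityVerdict:
    def test_all_rbc_nonpositive_is_stable(self):
        spec = simulate.CohortSpec(seed=2)
        parts = partition_samples(simulate.gen_blood_panel(spec))
        verdict = stability_verdict(parts)
        assert verdict["verdict"] == "stable"
        assert verdict["n_samples"] == len(parts)

    def test_full_binding_flags_free_lead(self):
        spec = simulate.CohortSpec(seed=2, rbc_binding_fraction=1.0)
        parts = partition_samples(simulate.gen_blood_panel(spec))
        assert stability_verdict(parts)["verdict"] == "free_pb_suspected"

    def test_monotone_in_binding_fraction(self):
        """The red-cell fraction of whole blood rises with injected binding."""
        fractions = []
        for binding in (0.0, 0.2, 0.5, 1.0):
            spec = simulate.CohortSpec(seed=4, rbc_binding_fraction=binding)
            parts = partition_samples(simulate.gen_blood_panel(spec))
            fractions.append(stability_verdict(parts)["rbc_fraction_of_wb"])
        assert all(np.diff(fractions) > 0)
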