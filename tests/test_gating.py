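"""Gating: transforms, automatic thresholds, classification rules and the truth oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bh3kit import (
    AcquisitionError,
    ConfigurationError,
    GateConfig,
    ValidationError,
    apply_transform,
    classify_events,
    fit_thresholds,
)
from bh3kit.events import EventTable, LOGICAL_CHANNELS
from bh3kit.gating import classification_labels, inverse_transform

from conftest import constant_event_table


def _cells(annexin, viability, fsc=50_000.0, bead=0.0):
    n = len(np.atleast_1d(annexin))
    data = pd.DataFrame({
        "fsc": np.full(n, fsc), "ssc": np.full(n, 30_000.0),
        "annexin": np.atleast_1d(annexin).astype(float),
        "viability_dye": np.broadcast_to(np.atleast_1d(viability).astype(float), (n,)).copy(),
        "bead": np.full(n, bead),
    })
    return EventTable(data=data[list(LOGICAL_CHANNELS)], transformed=True, cofactor=150.0)


class TestTransform:
    def test_arcsinh_zero_maps_to_zero(self, vehicle_well):
        t = apply_transform(vehicle_well, "arcsinh", 150.0)
        idx = np.argmin(np.abs(vehicle_well.channel("annexin")))
        assert np.arcsinh(0.0) == 0.0
        assert t.channel("annexin")[idx] == pytest.approx(
            np.arcsinh(vehicle_well.channel("annexin")[idx] / 150.0)
        )

    def test_arcsinh_round_trip(self, vehicle_well):
        t = apply_transform(vehicle_well, "arcsinh", 150.0)
        back = inverse_transform(t, "arcsinh", 150.0)
        np.testing.assert_allclose(
            back.data["annexin"], vehicle_well.data["annexin"], rtol=1e-9, atol=1e-9
        )

    def test_log10_round_trip_on_nonnegative(self, vehicle_well):
        # log10(1 + x/c) is only invertible for x >= 0 (negative raw values are clipped)
        nonneg = vehicle_well.copy()
        nonneg.data["annexin"] = nonneg.data["annexin"].abs()
        t = apply_transform(nonneg, "log10", 150.0)
        back = inverse_transform(t, "log10", 150.0)
        np.testing.assert_allclose(back.data["annexin"], nonneg.data["annexin"],
                                   rtol=1e-9, atol=1e-6)

    def test_none_is_identity_and_scatter_untouched(self, vehicle_well):
        t = apply_transform(vehicle_well, "none", 150.0)
        pd.testing.assert_frame_equal(t.data, vehicle_well.data)
        t2 = apply_transform(vehicle_well, "arcsinh", 150.0)
        np.testing.assert_array_equal(t2.channel("fsc"), vehicle_well.channel("fsc"))

    def test_nonpositive_cofactor_rejected(self, vehicle_well):
        with pytest.raises(ValidationError):
            apply_transform(vehicle_well, "arcsinh", 0.0)


class TestFitThresholds:
    def test_constant_input_threshold_equals_constant(self):
        gate = fit_thresholds([constant_event_table(value=1.0)], GateConfig(fsc_bounds=(0, None)))
        assert gate.annexin_threshold == pytest.approx(1.0)
        assert gate.viability_threshold == pytest.approx(1.0)

    def test_median_at_q_half_on_symmetric_negatives(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1.0, 0.3, 20_000)
        table = _cells(values, values)
        gate = fit_thresholds([table], GateConfig(quantile_q=0.5, fsc_bounds=(0, None)))
        assert gate.annexin_threshold == pytest.approx(np.median(values), abs=0.01)

    def test_threshold_between_separable_supports(self):
        # Oracle: exhaustive scan for the misclassification-minimizing cutoff.
        # Small-n populations so the sample supports have a genuine gap around
        # the fitted 99.5% point of the negative mode.
        rng = np.random.default_rng(1)
        neg = rng.normal(0.8, 0.2, 100)
        pos = rng.normal(6.0, 0.2, 30)  # baseline apoptotic contamination
        values = np.concatenate([neg, pos])
        table = _cells(values, values)
        with pytest.warns(UserWarning, match="usable vehicle events"):
            gate = fit_thresholds([table], GateConfig(fsc_bounds=(0, None)))
        lo, hi = neg.max(), pos.min()
        candidates = np.linspace(values.min(), values.max(), 4000)
        errs = [(neg > c).sum() + (pos <= c).sum() for c in candidates]
        best = candidates[int(np.argmin(errs))]
        assert lo < gate.annexin_threshold < hi
        assert lo <= best <= hi  # the scan oracle agrees the optimal cutoff lies in the gap

    def test_empirical_quantile_mode_matches_numpy(self):
        rng = np.random.default_rng(2)
        values = rng.normal(1.0, 0.4, 10_000)
        table = _cells(values, values)
        gate = fit_thresholds([table], GateConfig(robust=False, fsc_bounds=(0, None)))
        assert gate.annexin_threshold == pytest.approx(np.quantile(values, 0.995))

    def test_no_vehicle_wells_is_error(self):
        with pytest.raises(ConfigurationError):
            fit_thresholds([], GateConfig())

    def test_few_events_warns_but_proceeds(self):
        table = constant_event_table(n=100, value=1.0)
        with pytest.warns(UserWarning, match="usable vehicle events"):
            gate = fit_thresholds([table], GateConfig(fsc_bounds=(0, None)))
        assert gate.complete

    def test_debris_bound_from_fsc_quantile_when_unset(self, vehicle_well):
        gate = fit_thresholds([vehicle_well], GateConfig(fsc_bounds=(None, None)))
        non_bead_fsc = vehicle_well.channel("fsc")[vehicle_well.truth != "bead"]
        assert gate.fsc_bounds[0] == pytest.approx(np.quantile(non_bead_fsc, 0.02), rel=0.05)


class TestClassify:
    GATE = GateConfig(annexin_threshold=2.0, viability_threshold=2.0,
                      fsc_bounds=(20_000.0, None), threshold_source="manual")

    def test_exactly_at_threshold_is_negative(self):
        table = _cells(annexin=[2.0, 2.0 + 1e-9], viability=[2.0, 2.0])
        q = classify_events(table, self.GATE)
        # both events have viability == threshold (negative); annexin decides
        assert q.counts["alive"] == 1 and q.counts["early_apoptotic"] == 1
        assert q.counts["dead"] == 0

    def test_all_double_negative_means_all_alive(self):
        table = _cells(annexin=np.full(500, 0.5), viability=0.5)
        q = classify_events(table, self.GATE)
        assert q.frac_alive == 1.0 and q.counts["alive"] == 500

    def test_dead_wins_over_annexin(self):
        table = _cells(annexin=np.full(10, 5.0), viability=5.0)
        q = classify_events(table, self.GATE)
        assert q.counts["dead"] == 10 and q.counts["early_apoptotic"] == 0

    def test_partition_counts_sum_to_total(self, treated_well):
        gate = GateConfig(annexin_threshold=2.0, viability_threshold=2.0)
        q = classify_events(treated_well, gate)
        assert sum(q.counts.values()) == q.total_events == treated_well.n_events

    def test_empty_table_rejected(self):
        table = EventTable(data=pd.DataFrame({ch: [] for ch in LOGICAL_CHANNELS}))
        with pytest.raises(AcquisitionError):
            classify_events(table, self.GATE)

    def test_all_beads_sets_flag_and_warns(self):
        table = _cells(annexin=np.full(50, 7.5), viability=7.5, bead=7.5)
        with pytest.warns(UserWarning, match="beads"):
            q = classify_events(table, self.GATE)
        assert q.all_beads and q.counts["bead"] == 50

    def test_incomplete_gate_rejected(self, vehicle_well):
        with pytest.raises(ConfigurationError, match="incomplete"):
            classify_events(vehicle_well, GateConfig())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=8.0), st.floats(min_value=0.0, max_value=4.0))
    def test_raising_annexin_threshold_never_increases_early(self, thr, bump):
        rng = np.random.default_rng(11)
        table = _cells(rng.normal(2.5, 1.5, 2000), rng.normal(1.0, 0.5, 2000))
        low = GateConfig(annexin_threshold=thr, viability_threshold=2.0,
                         threshold_source="manual", fsc_bounds=(0, None))
        high = GateConfig(annexin_threshold=thr + bump, viability_threshold=2.0,
                          threshold_source="manual", fsc_bounds=(0, None))
        assert (
            classify_events(table, high).counts["early_apoptotic"]
            <= classify_events(table, low).counts["early_apoptotic"]
        )

    def test_agreement_with_generator_labels(self, vehicle_well, treated_well):
        gate = fit_thresholds([vehicle_well], GateConfig())
        for well in (vehicle_well, treated_well):
            labels = classification_labels(well, gate)
            assert (labels == well.truth).mean() >= 0.99
            q = classify_events(well, gate)
            counts = pd.Series(labels).value_counts()
            assert q.counts["early_apoptotic"] == counts.get("early_apoptotic", 0)

    def test_denominator_modes(self, treated_well, vehicle_well):
        gate = fit_thresholds([vehicle_well], GateConfig())
        intact = classify_events(treated_well, gate)
        gate_live = fit_thresholds([vehicle_well], GateConfig(denominator="live_plus_early"))
        live = classify_events(treated_well, gate_live)
        assert live.denominator <= intact.denominator
        assert live.frac_early >= intact.frac_early


def test_gate_yaml_round_trip(tmp_path, vehicle_well):
    gate = fit_thresholds([vehicle_well], GateConfig())
    path = tmp_path / "gate.yaml"
    gate.to_yaml(path)
    back = GateConfig.from_yaml(path)
    assert back == gate
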