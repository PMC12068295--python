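"""∆ Annexin V, bead-normalized counts, ∆ cell death and CTG viability."""

import numpy as np
import pandas as pd
import pytest

from bh3kit import (
    AcquisitionError,
    DoseResponseTruth,
    GateConfig,
    ValidationError,
    VariabilityModel,
    WellSpec,
    absolute_count,
    annexin_fraction,
    classify_events,
    correlate,
    delta_annexin,
    delta_cell_death,
    fit_thresholds,
    simulate_plate,
    simulate_well,
    toxicity_ratio,
    viability_from_ctg,
)
from bh3kit.gating import WellQuant
from bh3kit.plate_io import PlateLayout
from bh3kit.quantify import delta_table, quantify_plate
from bh3kit.validation import recover_delta


def _quant(n_alive=0, n_early=0, n_dead=0, n_beads=0, n_debris=0):
    counts = {"alive": n_alive, "early_apoptotic": n_early, "dead": n_dead,
              "bead": n_beads, "debris": n_debris}
    denom = n_alive + n_early + n_dead
    total = sum(counts.values())
    return WellQuant(
        counts=counts, total_events=total, denominator=denom,
        frac_alive=n_alive / denom if denom else float("nan"),
        frac_early=n_early / denom if denom else float("nan"),
        frac_dead=n_dead / denom if denom else float("nan"),
    )


class TestAnnexinFraction:
    def test_arithmetic(self):
        assert annexin_fraction(_quant(n_alive=18_800, n_early=1_200)) == pytest.approx(6.0)

    def test_zero_early_is_zero_percent(self):
        assert annexin_fraction(_quant(n_alive=100)) == 0.0

    def test_zero_cells_is_error(self):
        with pytest.raises(AcquisitionError):
            annexin_fraction(_quant(n_beads=500))

    def test_binomial_recovery_at_true_fraction(self, vehicle_well):
        truth = DoseResponseTruth(
            "S1", "venetoclax",
            baseline_fractions={"alive": 0.396, "early_apoptotic": 0.554, "dead": 0.05},
            early_by_dose={0.0: 0.554},
        )
        spec = WellSpec("P1", "B1", "S1", drug="vehicle", dose_nM=0.0, beads_added=5000)
        well = simulate_well(spec, truth, variability=VariabilityModel(rng_seed=2),
                             n_events=20_000)
        gate = fit_thresholds([vehicle_well], GateConfig())
        assert annexin_fraction(classify_events(well, gate)) == pytest.approx(55.4, abs=1.0)


class TestDeltaAnnexin:
    def test_subtraction(self):
        assert delta_annexin([60.0], [4.6]).delta_pct == pytest.approx(55.4)

    def test_self_delta_is_zero(self):
        arm = [4.2, 5.1, 3.9]
        assert delta_annexin(arm, arm, paired=True).delta_pct == 0.0

    def test_paired_requires_equal_n(self):
        with pytest.raises(ValidationError, match="paired"):
            delta_annexin([1.0, 2.0], [1.0], paired=True)

    def test_sem_undefined_for_single_replicates(self):
        assert delta_annexin([60.0], [4.6]).sem is None

    def test_paired_sem_matches_manual(self):
        t, v = [60.0, 62.0, 58.0], [5.0, 4.0, 6.0]
        d = delta_annexin(t, v, paired=True)
        diffs = np.subtract(t, v)
        assert d.sem == pytest.approx(np.std(diffs, ddof=1) / np.sqrt(3))

    def test_out_of_range_delta_rejected(self):
        with pytest.raises(ValidationError):
            delta_annexin([150.0], [0.0])

    def test_recovery_against_generator_truth(self):
        out = recover_delta("OCI-Ly1", "venetoclax", 75.4, n_pairs=3, seed=0)
        assert out["estimated_delta"] == pytest.approx(75.4, abs=2.0)

    def test_estimator_bias_small_over_seeds(self):
        errors = [
            recover_delta("S1", "venetoclax", 55.4, n_pairs=1, seed=s)["estimated_delta"] - 55.4
            for s in range(40)
        ]
        assert abs(float(np.mean(errors))) < 0.5


class TestAbsoluteCount:
    def test_ratio_identity(self):
        q = _quant(n_alive=1000, n_beads=1000)
        assert absolute_count(q, 8_000).cells_per_well["alive"] == pytest.approx(8_000)

    def test_arithmetic(self):
        q = _quant(n_alive=2_000, n_beads=1_000)
        assert absolute_count(q, 10_000).cells_per_well["alive"] == pytest.approx(20_000)

    def test_zero_beads_is_acquisition_error(self):
        with pytest.raises(AcquisitionError, match="bead"):
            absolute_count(_quant(n_alive=10), 5_000)

    def test_scale_free(self):
        small = absolute_count(_quant(n_alive=500, n_early=100, n_beads=250), 5_000)
        double = absolute_count(_quant(n_alive=1000, n_early=200, n_beads=500), 5_000)
        assert small.cells_per_well == pytest.approx(double.cells_per_well)


class TestDeltaCellDeath:
    def test_identical_wells_zero(self):
        q = _quant(n_alive=900, n_early=50, n_dead=50)
        assert delta_cell_death(q, q) == 0.0

    def test_seventy_points(self):
        control = _quant(n_alive=900, n_early=50, n_dead=50)
        treated = _quant(n_alive=200, n_early=300, n_dead=500)
        assert delta_cell_death(control, treated) == pytest.approx(70.0)

    def test_timepoint_mismatch_rejected(self):
        q = _quant(n_alive=100)
        with pytest.raises(ValidationError, match="timepoint"):
            delta_cell_death(q, q, control_timepoint_h=28.0, treated_timepoint_h=4.0)

    def test_death_at_24h_tracks_early_apoptosis_at_4h(self):
        """Along a dose series with high progression, later death correlates with earlier ∆."""
        truth = DoseResponseTruth.from_deltas(
            "S1", "venetoclax", {10.0: 10.0, 100.0: 40.0, 1000.0: 75.0},
            progression_rate=0.9,
        )
        wells_specs = []
        i = 0
        for tp, plate in ((4.0, "T4"), (28.0, "T28")):
            for dose in (0.0, 10.0, 100.0, 1000.0):
                drug = "venetoclax" if dose else "vehicle"
                wells_specs.append(WellSpec(plate, f"A{i % 24 + 1}", "S1", drug=drug,
                                            dose_nM=dose, timepoint_h=tp, beads_added=5000))
                i += 1
        layout = PlateLayout(wells=wells_specs)
        layout.validate()
        wells, _ = simulate_plate(layout, {"S1": truth}, VariabilityModel(rng_seed=0),
                                  n_events=20_000)
        quant = quantify_plate(wells, layout)
        q4 = quant[quant["timepoint_h"] == 4.0].set_index("dose_nM")
        q28 = quant[quant["timepoint_h"] == 28.0].set_index("dose_nM")
        deltas, deaths = [], []
        for dose in (10.0, 100.0, 1000.0):
            deltas.append(q4.loc[dose, "annexin_pct"] - q4.loc[0.0, "annexin_pct"])
            deaths.append(100 * (q28.loc[0.0, "frac_alive"] - q28.loc[dose, "frac_alive"]))
        deltas.append(0.0)
        deaths.append(0.0)
        result = correlate(deltas, deaths)
        assert result.r >= 0.8
        assert result.r_squared == pytest.approx(result.r**2, abs=1e-12)


class TestViabilityFromCTG:
    def _table(self, ratios):
        rows = [{"sample_id": "S1", "drug": "vehicle", "dose_nM": 0, "luminescence": 1000.0}]
        for i, r in enumerate(ratios):
            rows.append({"sample_id": "S1", "drug": "venetoclax",
                         "dose_nM": [10, 100, 1000][i], "luminescence": 1000.0 * r})
        return pd.DataFrame(rows)

    def test_treated_equals_control(self):
        out = viability_from_ctg(self._table([1.0]))
        assert out.loc[0, "viability_pct"] == pytest.approx(100.0)
        assert out.loc[0, "cytotoxicity_pct"] == pytest.approx(0.0)

    def test_near_complete_kill_sign_convention(self):
        out = viability_from_ctg(self._table([0.5, 0.181, 0.007]))
        out = out.set_index("dose_nM")
        assert out.loc[1000, "cytotoxicity_pct"] == pytest.approx(-99.3)
        assert out.loc[100, "cytotoxicity_pct"] == pytest.approx(-81.9)

    def test_zero_control_rejected(self):
        table = self._table([0.5])
        table.loc[table["dose_nM"] == 0, "luminescence"] = 0.0
        with pytest.raises(ValidationError, match="zero"):
            viability_from_ctg(table)

    def test_missing_control_row_rejected(self):
        table = self._table([0.5])
        with pytest.raises(ValidationError, match="dose-0"):
            viability_from_ctg(table[table["dose_nM"] > 0])


def test_toxicity_ratio():
    early = absolute_count(_quant(n_alive=1700, n_beads=500), 5_000)
    late = absolute_count(_quant(n_alive=1428, n_early=1, n_beads=500), 5_000)
    assert toxicity_ratio(early, late) == pytest.approx(14290 / 17000, rel=1e-3)


def test_delta_table_pairs_conditions_with_matched_vehicle(baseline_truth):
    specs = [
        WellSpec("P1", "A1", "S1", drug="venetoclax", dose_nM=1000.0, beads_added=5000),
        WellSpec("P1", "A2", "S1", drug="venetoclax", dose_nM=1000.0, beads_added=5000),
        WellSpec("P1", "A3", "S1", drug="vehicle", dose_nM=0.0, beads_added=5000),
        WellSpec("P1", "A4", "S1", drug="vehicle", dose_nM=0.0, beads_added=5000),
    ]
    layout = PlateLayout(wells=specs)
    layout.validate()
    wells, truth = simulate_plate(layout, {"S1": baseline_truth},
                                  VariabilityModel(rng_seed=1), n_events=20_000)
    quant = quantify_plate(wells, layout)
    deltas = delta_table(quant, paired=True)
    assert len(deltas) == 1
    true_delta = 100 * (truth["true_fraction_early"].max() - 0.05)
    assert deltas.loc[0, "delta_pct"] == pytest.approx(true_delta, abs=2.0)
    assert deltas.loc[0, "n_replicates"] == 2
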