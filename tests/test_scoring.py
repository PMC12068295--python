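"""Dependency scores, dynamic shifts and control-batch QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bh3kit import (
    ConfigurationError,
    GateConfig,
    VariabilityModel,
    WellSpec,
    default_references,
    dependency_score,
    dynamic_shift,
    profile_sample,
    qc_check,
    simulate_plate,
)
from bh3kit.plate_io import PlateLayout
from bh3kit.presets import control_truths
from bh3kit.quantify import delta_table, quantify_plate
from bh3kit.scoring import ControlReference
from bh3kit.simulate import DoseResponseTruth


def _deltas(sample_id, rows):
    return pd.DataFrame(
        [{"sample_id": sample_id, "drug": d, "dose_nM": 1000.0, "delta_pct": v} for d, v in rows]
    )


CONTROLS = pd.concat([
    _deltas("OCI-Ly1", [("venetoclax", 75.4)]),
    _deltas("JJN3", [("AZD-5991", 55.4)]),
    _deltas("HEL", [("A-1155463", 69.1)]),
])


class TestDependencyScore:
    def test_self_normalization_is_100(self):
        assert dependency_score(49.06, 49.06, "BCL-2") == pytest.approx(100.0)

    def test_bcl2_ratio_example(self):
        assert dependency_score(68.0, 49.06, "BCL-2") == pytest.approx(138.6, abs=0.05)

    def test_mcl1_fixed_weight_variant(self):
        assert dependency_score(18.47, 55.4, "MCL-1", mcl1_weight=30) == pytest.approx(61.6, abs=0.05)

    def test_mcl1_variant_a_uses_control(self):
        assert dependency_score(18.47, 55.4, "MCL-1", formula_variant="A") == pytest.approx(
            100 * 18.47 / 55.4
        )

    def test_negative_delta_clips_to_zero(self):
        assert dependency_score(-12.0, 50.0, "BCL-XL") == 0.0

    def test_nonpositive_control_is_error(self):
        with pytest.raises(ConfigurationError, match="QC"):
            dependency_score(10.0, 0.0, "BCL-2")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=1.0, max_value=100.0),
        st.floats(min_value=0.01, max_value=10.0),
    )
    def test_scale_invariance(self, sample, control, factor):
        base = dependency_score(sample, control, "BCL-2")
        scaled = dependency_score(sample * factor, control * factor, "BCL-2")
        assert scaled == pytest.approx(base, rel=1e-9)


class TestProfileSample:
    def test_control_against_itself_scores_100(self):
        sample = pd.concat([
            _deltas("pt", [("venetoclax", 75.4), ("AZD-5991", 10.0), ("A-1155463", 69.1)]),
        ])
        profile = profile_sample(sample, CONTROLS)
        assert profile.scores["BCL-2"] == pytest.approx(100.0)
        assert profile.scores["BCL-XL"] == pytest.approx(100.0)
        assert profile.formula_variant == "B" and profile.mcl1_weight == 30

    def test_missing_control_names_axis(self):
        sample = _deltas("pt", [("venetoclax", 40.0), ("AZD-5991", 10.0), ("A-1155463", 5.0)])
        controls = CONTROLS[CONTROLS["sample_id"] != "JJN3"]
        with pytest.raises(ConfigurationError, match=r"MCL-1 control \(JJN3\)"):
            profile_sample(sample, controls)

    def test_navitoclax_annotated_not_scored(self):
        sample = _deltas("pt", [("venetoclax", 40.0), ("AZD-5991", 10.0),
                                ("A-1155463", 5.0), ("navitoclax", 33.0)])
        profile = profile_sample(sample, CONTROLS)
        assert profile.navitoclax_delta == pytest.approx(33.0)
        assert set(profile.scores) == {"BCL-2", "MCL-1", "BCL-XL"}

    def test_cll_like_sample_orders_axes_end_to_end(self):
        """A BCL-2-driven sample scores far higher on BCL-2 than BCL-XL through the pipeline."""
        truths = dict(control_truths())
        for drug, delta in (("venetoclax", 70.0), ("AZD-5991", 10.0), ("A-1155463", 3.0)):
            truths[("CLL-1", drug)] = DoseResponseTruth.from_deltas("CLL-1", drug, {1000.0: delta})
        specs, i = [], 0

        def add(sample, drug, dose, kind="primary", target=None):
            nonlocal i
            specs.append(WellSpec("SC", f"{chr(ord('A') + i // 24)}{i % 24 + 1}", sample,
                                  sample_kind=kind, control_target=target, drug=drug,
                                  dose_nM=dose, beads_added=5000))
            i += 1

        for drug in ("venetoclax", "AZD-5991", "A-1155463"):
            add("CLL-1", drug, 1000.0)
        add("CLL-1", "vehicle", 0.0)
        for line, target in (("OCI-Ly1", "BCL-2"), ("JJN3", "MCL-1"), ("HEL", "BCL-XL")):
            drug = {"BCL-2": "venetoclax", "MCL-1": "AZD-5991", "BCL-XL": "A-1155463"}[target]
            add(line, drug, 1000.0, kind="control_line", target=target)
            add(line, "vehicle", 0.0, kind="control_line", target=target)
        layout = PlateLayout(wells=specs)
        layout.validate()
        wells, _ = simulate_plate(layout, truths, VariabilityModel(rng_seed=0), n_events=20_000)
        quant = quantify_plate(wells, layout)
        deltas = delta_table(quant)
        profile = profile_sample(
            deltas[deltas["sample_id"] == "CLL-1"], deltas[deltas["sample_id"] != "CLL-1"]
        )
        assert profile.scores["BCL-2"] > 5 * profile.scores["BCL-XL"]
        # truth: sample ∆ 70.0 vs OCI-Ly1 control ∆ 75.4 at 1 µM
        assert profile.scores["BCL-2"] == pytest.approx(100 * 70.0 / 75.4, abs=6.0)


class TestDynamicShift:
    def test_identical_arms_shift_zero(self):
        arm = _deltas("pt", [("venetoclax", 20.0), ("AZD-5991", 10.0)])
        shifts = dynamic_shift(arm, arm.copy())
        assert (shifts["shift_pct"] == 0.0).all()

    def test_subtraction_preserves_sign(self):
        vehicle = _deltas("pt", [("AZD-5991", 10.0), ("A-1155463", 30.0)])
        treated = _deltas("pt", [("AZD-5991", 19.9), ("A-1155463", 18.1)])
        shifts = dynamic_shift(vehicle, treated).set_index("drug")
        assert shifts.loc["AZD-5991", "shift_pct"] == pytest.approx(9.9)
        assert shifts.loc["A-1155463", "shift_pct"] == pytest.approx(-11.9)

    def test_unmatched_pairs_skipped_with_warning(self):
        vehicle = _deltas("pt", [("AZD-5991", 10.0)])
        treated = _deltas("pt", [("AZD-5991", 15.0), ("venetoclax", 9.0)])
        with pytest.warns(UserWarning, match="skipped"):
            shifts = dynamic_shift(vehicle, treated)
        assert list(shifts["drug"]) == ["AZD-5991"]


class TestQC:
    REF = ControlReference("OCI-Ly1", "BCL-2", "venetoclax", 75.4, 5.0)

    def test_two_vials_at_reference_mean_pass(self):
        assert qc_check([75.4, 75.4], self.REF).passed

    def test_single_vial_fails_with_reason(self):
        result = qc_check([75.4], self.REF)
        assert not result.passed and "n_vials < 2" in result.reason

    def test_boundary_of_acceptance_band_passes(self):
        hi = 75.4 + 2 * 5.0
        assert qc_check([hi, hi], self.REF).passed
        assert not qc_check([hi + 0.01, hi + 0.01], self.REF).passed

    def test_default_references_match_published_bands(self):
        refs = default_references()
        assert refs["BCL-2"].reference_mean_delta == 75.4 and refs["BCL-2"].reference_sd == 5.0
        assert refs["MCL-1"].reference_mean_delta == 55.4 and refs["MCL-1"].reference_sd == 7.7
        assert refs["BCL-XL"].reference_mean_delta == 69.1 and refs["BCL-XL"].reference_sd == 5.9

    def test_drug_target_mismatch_rejected(self):
        with pytest.raises(Exception, match="match"):
            ControlReference("OCI-Ly1", "BCL-2", "AZD-5991", 75.4, 5.0)

    def test_variance_components_order(self):
        rng = np.random.default_rng(0)
        deltas, batches = [], []
        for b in range(6):
            shift = rng.normal(0, 8.0)
            for v in range(4):
                deltas.append(75.4 + shift + rng.normal(0, 2.0))
                batches.append(f"B{b}")
        result = qc_check(deltas, self.REF, batch_ids=batches)
        assert result.inter_batch_sd > result.intra_batch_sd

    def test_inter_batch_sd_recovery_over_200_experiments(self):
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(200):
            deltas, batches = [], []
            for b in range(6):
                shift = rng.normal(0, 8.0)
                deltas.extend(75.4 + shift + rng.normal(0, 2.0, size=4))
                batches.extend([f"B{b}"] * 4)
            result = qc_check(deltas, self.REF, batch_ids=batches)
            estimates.append(result.inter_batch_sd)
        assert float(np.median(estimates)) == pytest.approx(8.0, rel=0.20)
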