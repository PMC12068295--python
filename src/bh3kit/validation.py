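"""Simulation-based self-validation: recover known truths through the full pipeline.

Each workflow here wires the synthetic generator to the gating,
quantification and scoring stages and reports how well a known injected
truth is recovered end-to-end: ∆ Annexin V of the control lines,
thaw-to-thaw reproducibility SDs, dynamic-profiling shifts, bead-normalized
absolute counts, and per-event gating agreement. They are the package's own
positive controls; the test suite and the reproduction script both run them.
"""

from __future__ import annotations

import numpy as np

from .gating import GateConfig, classification_labels, classify_events, fit_thresholds
from .plate_io import PlateLayout, WellSpec
from .presets import DEFAULT_BASELINE, control_truths
from .quantify import absolute_count, annexin_fraction, delta_table, quantify_plate
from .scoring import dynamic_shift
from .simulate import DoseResponseTruth, VariabilityModel, simulate_plate, simulate_well

DEFAULT_N_EVENTS = 20_000
DEFAULT_BEADS = 5_000


def _well_id(i: int) -> str:
    return f"{chr(ord('A') + i // 24)}{i % 24 + 1}"


def _wells(
    plate_id: str,
    sample_id: str,
    conditions: list[dict],
    start: int = 0,
    cells_seeded: int = DEFAULT_N_EVENTS,
    beads_added: int = DEFAULT_BEADS,
) -> list[WellSpec]:
    specs = []
    for i, cond in enumerate(conditions, start=start):
        specs.append(
            WellSpec(
                plate_id=plate_id, well_id=_well_id(i), sample_id=sample_id,
                cells_seeded=cells_seeded, beads_added=beads_added, **cond,
            )
        )
    return specs


def recover_delta(
    sample_id: str,
    drug: str,
    true_delta_pp: float,
    dose_nM: float = 1000.0,
    baseline: dict[str, float] | None = None,
    n_pairs: int = 3,
    n_events: int = DEFAULT_N_EVENTS,
    seed: int = 0,
    replicate_sd: float = 0.0,
) -> dict:
    """Recover an injected ∆ Annexin V through gating + quantification.

    Simulates ``n_pairs`` treated/vehicle well pairs, fits thresholds from
    the vehicle wells, and returns the estimated mean ∆ alongside the truth.
    """
    truth = DoseResponseTruth.from_deltas(
        sample_id, drug, {dose_nM: true_delta_pp},
        baseline_fractions=dict(baseline or DEFAULT_BASELINE),
    )
    conditions = [{"drug": drug, "dose_nM": dose_nM} for _ in range(n_pairs)]
    conditions += [{"drug": "vehicle", "dose_nM": 0.0} for _ in range(n_pairs)]
    layout = PlateLayout(wells=_wells("REC", sample_id, conditions))
    layout.validate()
    wells, truth_table = simulate_plate(
        layout, {sample_id: truth}, VariabilityModel(rng_seed=seed, replicate_sd=replicate_sd),
        n_events=n_events,
    )
    quant = quantify_plate(wells, layout)  # auto thresholds from vehicle wells
    deltas = delta_table(quant, paired=True)
    row = deltas[(deltas["drug"] == drug) & (deltas["dose_nM"] == dose_nM)].iloc[0]
    return {
        "estimated_delta": float(row["delta_pct"]),
        "true_delta": float(true_delta_pp),
        "sem": None if row["sem"] is None else float(row["sem"]),
        "n_pairs": n_pairs,
        "truth_table": truth_table,
    }


def thaw_sd(
    injected_sd: float = 5.0,
    n_thaws: int = 12,
    sample_id: str = "OCI-Ly1",
    drug: str = "venetoclax",
    true_delta_pp: float = 75.4,
    dose_nM: float = 1000.0,
    n_events: int = DEFAULT_N_EVENTS,
    seed: int = 0,
) -> dict:
    """Reproducibility of a control line across independent thaws.

    Each thaw is an independent treated/vehicle pair with between-replicate
    variability ``injected_sd`` on the induced response; the pipeline is run
    per thaw and the sample SD of the estimated ∆ values is returned.
    """
    truth = DoseResponseTruth.from_deltas(
        sample_id, drug, {dose_nM: true_delta_pp}, baseline_fractions=dict(DEFAULT_BASELINE)
    )
    variability = VariabilityModel(replicate_sd=injected_sd, rng_seed=seed)
    deltas = []
    for i in range(n_thaws):
        plate = f"THAW{i:02d}"
        layout = PlateLayout(
            wells=_wells(plate, sample_id, [
                {"drug": drug, "dose_nM": dose_nM},
                {"drug": "vehicle", "dose_nM": 0.0},
            ])
        )
        layout.validate()
        wells, _ = simulate_plate(layout, {sample_id: truth}, variability, n_events=n_events)
        treated = wells[f"{plate}/A1"]
        vehicle = wells[f"{plate}/A2"]
        gate = fit_thresholds([vehicle], GateConfig())
        deltas.append(
            annexin_fraction(classify_events(treated, gate))
            - annexin_fraction(classify_events(vehicle, gate))
        )
    return {
        "estimated_sd": float(np.std(deltas, ddof=1)),
        "injected_sd": float(injected_sd),
        "deltas": deltas,
        "n_thaws": n_thaws,
    }


def recover_dynamic_shift(
    sample_id: str,
    pretreatment_name: str,
    drug: str,
    dose_nM: float,
    vehicle_arm_delta_pp: float,
    treated_arm_delta_pp: float,
    baseline: dict[str, float] | None = None,
    n_pairs: int = 3,
    n_events: int = DEFAULT_N_EVENTS,
    seed: int = 0,
) -> dict:
    """Recover a dynamic-profiling shift (pre-treated ∆ − vehicle ∆) end-to-end.

    Simulates both pre-treatment arms, each with its own toolkit-vehicle
    wells, runs per-arm ∆ Annexin V and then :func:`dynamic_shift`.
    """
    base = dict(baseline or DEFAULT_BASELINE)
    truths = {
        (sample_id, drug, "DMSO"): DoseResponseTruth.from_deltas(
            sample_id, drug, {dose_nM: vehicle_arm_delta_pp}, baseline_fractions=base
        ),
        (sample_id, drug, pretreatment_name): DoseResponseTruth.from_deltas(
            sample_id, drug, {dose_nM: treated_arm_delta_pp}, baseline_fractions=base
        ),
    }
    conditions = []
    for pre, name in (("vehicle", "DMSO"), ("drug_of_interest", pretreatment_name)):
        for _ in range(n_pairs):
            conditions.append({"drug": drug, "dose_nM": dose_nM, "pretreatment": pre,
                               "pretreatment_name": name, "timepoint_h": 4.0})
        for _ in range(n_pairs):
            conditions.append({"drug": "vehicle", "dose_nM": 0.0, "pretreatment": pre,
                               "pretreatment_name": name, "timepoint_h": 4.0})
    layout = PlateLayout(wells=_wells("DYN", sample_id, conditions))
    layout.validate()
    wells, _ = simulate_plate(layout, truths, VariabilityModel(rng_seed=seed), n_events=n_events)
    quant = quantify_plate(wells, layout)
    deltas = delta_table(quant, paired=True)
    shifts = dynamic_shift(
        deltas[deltas["pretreatment"] == "vehicle"],
        deltas[deltas["pretreatment"] == "drug_of_interest"],
    )
    row = shifts[(shifts["drug"] == drug) & (shifts["dose_nM"] == dose_nM)].iloc[0]
    return {
        "estimated_shift": float(row["shift_pct"]),
        "true_shift": float(treated_arm_delta_pp - vehicle_arm_delta_pp),
        "vehicle_arm_delta": float(row["vehicle_delta_pct"]),
        "treated_arm_delta": float(row["treated_delta_pct"]),
        "n_pairs": n_pairs,
    }


def recover_live_count(
    live_cells: int = 17_153,
    early_cells: int = 9_218,
    cells_seeded: int = 20_000,
    beads_added: int = DEFAULT_BEADS,
    n_events: int | None = None,
    seed: int = 0,
) -> dict:
    """Recover an absolute live-cell count through bead normalization.

    One well is drawn with the given true composition (living = alive +
    early apoptotic); thresholds come from a companion vehicle well with a
    healthy baseline. The bead-normalized live-cell estimate is compared to
    the truth.
    """
    alive = (live_cells - early_cells) / cells_seeded
    early = early_cells / cells_seeded
    dead = 1.0 - alive - early
    test_truth = DoseResponseTruth(
        "CLL-1", "venetoclax",
        baseline_fractions={"alive": alive, "early_apoptotic": early, "dead": dead},
        early_by_dose={0.0: early},
    )
    gate_truth = DoseResponseTruth(
        "CTRL", "vehicle", baseline_fractions=dict(DEFAULT_BASELINE),
        early_by_dose={0.0: DEFAULT_BASELINE["early_apoptotic"]},
    )
    variability = VariabilityModel(rng_seed=seed)
    test_spec = WellSpec("CNT", "A1", "CLL-1", cells_seeded=cells_seeded, beads_added=beads_added)
    gate_spec = WellSpec("CNT", "A2", "CTRL", cells_seeded=cells_seeded, beads_added=beads_added)
    test_well = simulate_well(test_spec, test_truth, variability=variability, n_events=n_events)
    gate_well = simulate_well(gate_spec, gate_truth, variability=variability, n_events=n_events)
    gate = fit_thresholds([gate_well], GateConfig())
    counts = absolute_count(classify_events(test_well, gate), beads_added)
    return {
        "estimated_live": float(counts.live_cells),
        "true_live": float(live_cells),
        "relative_error": float(counts.live_cells / live_cells - 1.0),
        "beads_observed": counts.beads_observed,
    }


def gating_agreement(
    n_wells: int = 100,
    n_events: int = DEFAULT_N_EVENTS,
    seed: int = 0,
) -> dict:
    """Per-event agreement between gating and hidden generator labels.

    Simulates ``n_wells`` wells cycling over the preset control-line
    conditions and the full dose grid, fits thresholds from the vehicle
    wells, and returns the pooled fraction of events whose gated class
    matches the generator's label.
    """
    truths = control_truths()
    keys = sorted(truths)
    doses = [0.0, 10.0, 100.0, 1000.0]
    specs, used_truths = [], {}
    for i in range(n_wells):
        line, drug = keys[i % len(keys)]
        dose = doses[(i // len(keys)) % len(doses)]
        specs.append(WellSpec(
            plate_id=f"AGR{i // 384}", well_id=_well_id(i % 384), sample_id=line,
            sample_kind="control_line",
            control_target={"OCI-Ly1": "BCL-2", "JJN3": "MCL-1", "HEL": "BCL-XL"}[line],
            drug=drug if dose > 0 else "vehicle", dose_nM=dose,
            cells_seeded=n_events, beads_added=DEFAULT_BEADS,
        ))
        used_truths[(line, drug)] = truths[(line, drug)]
    layout = PlateLayout(wells=specs)
    layout.validate()
    wells, _ = simulate_plate(layout, used_truths, VariabilityModel(rng_seed=seed),
                              n_events=n_events)
    spec_by_key = {f"{w.plate_id}/{w.well_id}": w for w in layout.wells}
    vehicle = [wells[k] for k, s in spec_by_key.items() if s.drug == "vehicle"]
    gate = fit_thresholds(vehicle, GateConfig())
    agree = total = 0
    for table in wells.values():
        labels = classification_labels(table, gate)
        agree += int((labels == table.truth).sum())
        total += table.n_events
    return {"agreement": agree / total, "n_wells": n_wells, "n_events_total": total}
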