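"""Per-condition statistics: ∆ Annexin V, absolute counts, ∆ cell death, CTG viability.

∆ Annexin V is the difference in the percentage of Annexin V single-positive
(early apoptotic) cells between a mimetic-treated condition and its vehicle
control. Counting beads spiked at a known number per well convert event
counts into absolute per-well cell numbers. CTG luminescence gives viability
as percent of the matched untreated control, with cytotoxicity signed so
that −99.3 means near-complete kill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AcquisitionError, ValidationError
from .events import EventTable
from .gating import GateConfig, WellQuant, classify_events, fit_thresholds
from .plate_io import PlateLayout

_CELL = ("alive", "early_apoptotic", "dead")


@dataclass
class DeltaAnnexin:
    """∆ Annexin V for one (sample, drug, dose, pretreatment) condition."""

    sample_id: str | None
    drug: str | None
    dose_nM: float | None
    pretreatment: str | None
    delta_pct: float
    sem: float | None
    n_replicates: int
    replicate_deltas: list[float] | None = None
    paired: bool = False

    def __post_init__(self) -> None:
        if not -100.0 <= self.delta_pct <= 100.0:
            raise ValidationError(f"delta_pct {self.delta_pct} outside [-100, 100]")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


@dataclass
class AbsoluteCount:
    """Bead-normalized absolute cell numbers for one well."""

    well_id: str | None
    cells_per_well: dict[str, float]
    beads_observed: int
    beads_added: int

    @property
    def live_cells(self) -> float:
        """Living cells = alive + early apoptotic (still intact, Annexin V+ only)."""
        return self.cells_per_well["alive"] + self.cells_per_well["early_apoptotic"]

    @property
    def total_cells(self) -> float:
        return sum(self.cells_per_well[c] for c in _CELL)


def annexin_fraction(q: WellQuant) -> float:
    """Percentage of Annexin V single-positive cells over the cell denominator."""
    if q.denominator <= 0:
        raise AcquisitionError(f"well {q.well_id}: zero cell events in denominator")
    return 100.0 * q.counts["early_apoptotic"] / q.denominator


def delta_annexin(
    treated: list[float],
    vehicle: list[float],
    paired: bool = False,
    sample_id: str | None = None,
    drug: str | None = None,
    dose_nM: float | None = None,
    pretreatment: str | None = None,
) -> DeltaAnnexin:
    """∆ Annexin V = mean(treated %) − mean(vehicle %).

    With ``paired=True`` (equal replicate counts, wells matched by position),
    per-replicate deltas are retained and the SEM is that of the paired
    differences; otherwise arms are aggregated by their means and the SEM is
    propagated from the two arms.
    """
    treated = [float(x) for x in np.atleast_1d(treated)]
    vehicle = [float(x) for x in np.atleast_1d(vehicle)]
    if not treated or not vehicle:
        raise ValidationError("both arms need at least one replicate")
    if paired:
        if len(treated) != len(vehicle):
            raise ValidationError(
                f"paired deltas need equal replicate counts (got {len(treated)} vs {len(vehicle)})"
            )
        reps = [t - v for t, v in zip(treated, vehicle)]
        n = len(reps)
        delta = float(np.mean(reps))
        sem = float(np.std(reps, ddof=1) / np.sqrt(n)) if n >= 2 else None
    else:
        reps = None
        n = min(len(treated), len(vehicle))
        delta = float(np.mean(treated) - np.mean(vehicle))
        if len(treated) >= 2 and len(vehicle) >= 2:
            sem = float(
                np.sqrt(
                    np.var(treated, ddof=1) / len(treated) + np.var(vehicle, ddof=1) / len(vehicle)
                )
            )
        else:
            sem = None
    return DeltaAnnexin(
        sample_id=sample_id, drug=drug, dose_nM=dose_nM, pretreatment=pretreatment,
        delta_pct=delta, sem=sem, n_replicates=n, replicate_deltas=reps, paired=paired,
    )


def absolute_count(q: WellQuant, beads_added: int) -> AbsoluteCount:
    """Per-class absolute counts: n_class × beads_added / beads_observed."""
    if q.counts["bead"] <= 0:
        raise AcquisitionError(
            f"well {q.well_id}: zero counting beads observed — acquisition failure, "
            "absolute counts unavailable"
        )
    if beads_added <= 0:
        raise ValidationError("beads_added must be positive")
    scale = beads_added / q.counts["bead"]
    cells = {cls: q.counts[cls] * scale for cls in _CELL}
    return AbsoluteCount(
        well_id=q.well_id, cells_per_well=cells, beads_observed=q.counts["bead"],
        beads_added=beads_added,
    )


def _percent_viable(x: WellQuant | AbsoluteCount) -> float:
    if isinstance(x, WellQuant):
        denom = x.counts["alive"] + x.counts["early_apoptotic"] + x.counts["dead"]
        if denom <= 0:
            raise AcquisitionError(f"well {x.well_id}: no cell events")
        return 100.0 * x.counts["alive"] / denom
    total = x.total_cells
    if total <= 0:
        raise AcquisitionError(f"well {x.well_id}: no cells estimated")
    return 100.0 * x.cells_per_well["alive"] / total


def delta_cell_death(
    control: WellQuant | AbsoluteCount,
    treated: WellQuant | AbsoluteCount,
    control_timepoint_h: float | None = None,
    treated_timepoint_h: float | None = None,
) -> float:
    """∆ cell death = (% viable, control) − (% viable, treated), percentage points."""
    if (
        control_timepoint_h is not None
        and treated_timepoint_h is not None
        and control_timepoint_h != treated_timepoint_h
    ):
        raise ValidationError(
            f"timepoint mismatch: control at {control_timepoint_h} h, treated at {treated_timepoint_h} h"
        )
    return _percent_viable(control) - _percent_viable(treated)


def viability_from_ctg(lum: pd.DataFrame) -> pd.DataFrame:
    """CTG viability per (sample, pretreatment, drug, dose): 100 × treated/control.

    Each (sample, pretreatment, drug) stratum must contain a dose-0 control
    row. Cytotoxicity = viability − 100 (negative = kill).
    """
    lum = pd.DataFrame(lum)
    if "pretreatment" not in lum.columns:
        lum = lum.assign(pretreatment="none")
    rows = []
    for (sample, pre), grp in lum.groupby(["sample_id", "pretreatment"], sort=False):
        controls = grp.loc[grp["dose_nM"] == 0, "luminescence"]
        if controls.empty:
            raise ValidationError(f"{sample}/{pre}: no dose-0 control row for CTG normalization")
        control_lum = float(controls.mean())
        if control_lum == 0:
            raise ValidationError(f"{sample}/{pre}: control luminescence is zero")
        treated = grp[grp["dose_nM"] > 0]
        for (drug, dose), cell in treated.groupby(["drug", "dose_nM"], sort=False):
            viability = 100.0 * float(cell["luminescence"].mean()) / control_lum
            rows.append({
                "sample_id": sample, "pretreatment": pre, "drug": drug, "dose_nM": dose,
                "viability_pct": viability, "cytotoxicity_pct": viability - 100.0,
                "n_replicates": len(cell),
            })
    return pd.DataFrame(rows)


def toxicity_ratio(live_24h: AbsoluteCount, live_48h: AbsoluteCount) -> float:
    """Between-plate toxicity monitor: ratio of bead-normalized live counts (later/earlier)."""
    early = live_24h.live_cells
    if early <= 0:
        raise AcquisitionError("no live cells estimated on the earlier plate")
    return live_48h.live_cells / early


# ---------------------------------------------------------------------------
# Plate-level glue: events -> per-well quant table -> per-condition deltas


def quantify_plate(
    wells: dict[str, EventTable],
    layout: PlateLayout,
    gate: GateConfig | None = None,
) -> pd.DataFrame:
    """Classify every well of a plate and tabulate per-well statistics.

    When the gate has no fitted thresholds, they are derived from the
    layout's vehicle wells. Returns one row per well with counts, fractions,
    the Annexin V+ percentage and bead-normalized absolute counts.
    """
    spec_by_key = {f"{w.plate_id}/{w.well_id}": w for w in layout.wells}
    missing = set(wells) - set(spec_by_key)
    if missing:
        raise ValidationError(f"event wells not in layout: {sorted(missing)}")

    if gate is None or not gate.complete:
        vehicle_keys = [k for k, s in spec_by_key.items() if s.drug == "vehicle" and k in wells]
        gate = fit_thresholds([wells[k] for k in vehicle_keys], gate or GateConfig())

    rows = []
    for key, table in wells.items():
        spec = spec_by_key[key]
        q = classify_events(table, gate)
        row = {
            "plate_id": spec.plate_id, "well_id": spec.well_id, "sample_id": spec.sample_id,
            "sample_kind": spec.sample_kind, "drug": spec.drug, "dose_nM": spec.dose_nM,
            "pretreatment": spec.pretreatment, "pretreatment_name": spec.pretreatment_name,
            "timepoint_h": spec.timepoint_h, "material": spec.material,
            "total_events": q.total_events,
            **{f"n_{cls}": q.counts[cls] for cls in ("alive", "early_apoptotic", "dead", "debris", "bead")},
            "frac_alive": q.frac_alive, "frac_early": q.frac_early, "frac_dead": q.frac_dead,
            "annexin_pct": annexin_fraction(q),
        }
        if q.counts["bead"] > 0 and spec.beads_added:
            counts = absolute_count(q, spec.beads_added)
            row.update({
                "cells_alive": counts.cells_per_well["alive"],
                "cells_early": counts.cells_per_well["early_apoptotic"],
                "cells_dead": counts.cells_per_well["dead"],
                "live_cells": counts.live_cells,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def delta_table(quant: pd.DataFrame, paired: bool = False) -> pd.DataFrame:
    """Collapse a per-well quant table into ∆ Annexin V per condition.

    Treated conditions are matched to the vehicle wells of the same
    (sample, pretreatment group, timepoint). With ``paired=True`` wells are
    matched in plate order within each arm.
    """
    keys = ["sample_id", "pretreatment", "pretreatment_name", "timepoint_h"]
    quant = quant.copy()
    quant["pretreatment_name"] = quant["pretreatment_name"].fillna("")
    rows = []
    for group_key, grp in quant.groupby(keys, sort=False):
        vehicle = grp[grp["drug"] == "vehicle"].sort_values(["plate_id", "well_id"])
        if vehicle.empty:
            raise ValidationError(f"no vehicle wells for stratum {dict(zip(keys, group_key))}")
        v_pct = vehicle["annexin_pct"].tolist()
        for (drug, dose), cell in grp[grp["drug"] != "vehicle"].groupby(["drug", "dose_nM"], sort=False):
            t_pct = cell.sort_values(["plate_id", "well_id"])["annexin_pct"].tolist()
            d = delta_annexin(
                t_pct, v_pct, paired=paired and len(t_pct) == len(v_pct),
                sample_id=group_key[0], drug=drug, dose_nM=dose,
                pretreatment=group_key[1],
            )
            rows.append({
                "sample_id": d.sample_id, "pretreatment": group_key[1],
                "pretreatment_name": group_key[2], "timepoint_h": group_key[3],
                "drug": drug, "dose_nM": dose, "delta_pct": d.delta_pct,
                "sem": d.sem, "n_replicates": d.n_replicates,
            })
    return pd.DataFrame(rows)
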