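"""Synthetic flow-cytometry generator with known ground truth.

Each well is a mixture of five event classes — alive, early-apoptotic
(Annexin V single-positive), dead (7AAD-positive), debris and counting
beads. Fluorescence intensities are drawn per class as Gaussians in
arcsinh-transformed space (log-normal-like raw intensities, the usual shape
of cytometer fluorescence), scatter as truncated Gaussians in linear space.
Every event keeps its class as a hidden label, so gating and every
downstream statistic can be checked against the truth that generated the
data.

The dose response of the early-apoptotic fraction is specified either as
explicit per-dose fractions on the assay's {0, 10, 100, 1000} nM grid or as
a Hill curve. Between the 4 h profiling plate and the plate acquired 24 h
later, a per-sample ``progression_rate`` converts early-apoptotic cells to
dead ones, and an attrition factor models the slow decline of untreated
thawed cells. Counting beads are Poisson-sampled around the spiked-in count
scaled by the same acquisition fraction as the cells, which is what makes
bead-normalized absolute counts recoverable.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fcs as _fcs
from .errors import ConfigurationError, ValidationError
from .events import (
    DEFAULT_CHANNEL_NAMES,
    EVENT_CLASSES,
    FLUOR_CHANNELS,
    LOGICAL_CHANNELS,
    EventTable,
)
from .plate_io import PlateLayout, WellSpec

logger = logging.getLogger(__name__)

#: Cell classes (beads and debris handled separately from the intact-cell mixture).
CELL_CLASSES: tuple[str, ...] = ("alive", "early_apoptotic", "dead")

#: arcsinh cofactor used when converting transformed-space locations to raw intensities.
GENERATOR_COFACTOR: float = 150.0


@dataclass
class PopulationModel:
    """Location/spread of one event class in channel space.

    Fluorescence locations are in arcsinh-transformed units (cofactor
    ``GENERATOR_COFACTOR``); scatter locations in raw linear units.
    """

    population_class: str
    fluor_mean: dict[str, float]
    fluor_sd: dict[str, float]
    scatter_mean: dict[str, float]
    scatter_sd: dict[str, float]

    def __post_init__(self) -> None:
        if self.population_class not in EVENT_CLASSES:
            raise ValidationError(f"unknown population class {self.population_class!r}")
        for name, sd in {**self.fluor_sd, **self.scatter_sd}.items():
            if sd <= 0:
                raise ValidationError(
                    f"{self.population_class}: dispersion for {name!r} must be > 0 (got {sd})"
                )
        for ch in FLUOR_CHANNELS:
            if ch not in self.fluor_mean or ch not in self.fluor_sd:
                raise ValidationError(f"{self.population_class}: missing fluorescence channel {ch!r}")
        for ch in ("fsc", "ssc"):
            if ch not in self.scatter_mean or ch not in self.scatter_sd:
                raise ValidationError(f"{self.population_class}: missing scatter channel {ch!r}")

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Draw n raw-intensity events of this class."""
        cols = {}
        for ch in ("fsc", "ssc"):
            cols[ch] = np.clip(
                rng.normal(self.scatter_mean[ch], self.scatter_sd[ch], size=n), 0.0, None
            )
        for ch in FLUOR_CHANNELS:
            t = rng.normal(self.fluor_mean[ch], self.fluor_sd[ch], size=n)
            cols[ch] = GENERATOR_COFACTOR * np.sinh(t)
        return pd.DataFrame(cols, columns=list(LOGICAL_CHANNELS))


# Transformed-space fluorescence levels for the default populations. "Negative"
# sits at the autofluorescence floor, "positive" ~2 decades up, beads are
# extreme in every channel (Biolegend precision beads fluoresce everywhere).
_NEG, _POS, _BRIGHT = 0.8, 4.5, 7.5
_SD = 0.35


def default_populations() -> dict[str, PopulationModel]:
    """The five default populations; pairwise separable under default gates."""

    def pop(cls, annexin, viability, bead, fsc, ssc, fluor_sd=_SD, fsc_sd=12_000.0, ssc_sd=10_000.0):
        return PopulationModel(
            population_class=cls,
            fluor_mean={"annexin": annexin, "viability_dye": viability, "bead": bead},
            fluor_sd={ch: fluor_sd for ch in FLUOR_CHANNELS},
            scatter_mean={"fsc": fsc, "ssc": ssc},
            scatter_sd={"fsc": fsc_sd, "ssc": ssc_sd},
        )

    return {
        "alive": pop("alive", _NEG, _NEG, 0.5, 60_000, 30_000),
        "early_apoptotic": pop("early_apoptotic", _POS, _NEG, 0.5, 55_000, 32_000),
        "dead": pop("dead", _POS, _POS, 0.5, 45_000, 35_000),
        "debris": pop("debris", 0.6, 1.1, 0.5, 8_000, 5_000, fsc_sd=3_000.0, ssc_sd=2_000.0),
        "bead": pop("bead", _BRIGHT, _BRIGHT, _BRIGHT, 40_000, 50_000, fluor_sd=0.2,
                    fsc_sd=4_000.0, ssc_sd=4_000.0),
    }


@dataclass
class DoseResponseTruth:
    """Ground-truth dose response of the early-apoptotic fraction for one sample/drug.

    Either ``early_by_dose`` (absolute early-apoptotic fractions on the dose
    grid, dose 0 = vehicle baseline) or the Hill triple
    (``max_induction``, ``ec50_nM``, ``hill_slope``) must be given.
    """

    sample_id: str
    drug: str
    baseline_fractions: dict[str, float] = field(
        default_factory=lambda: {"alive": 0.90, "early_apoptotic": 0.05, "dead": 0.05}
    )
    early_by_dose: dict[float, float] | None = None
    max_induction: float | None = None
    ec50_nM: float | None = None
    hill_slope: float = 1.0
    progression_rate: float = 0.8  # early -> dead conversion between 4 h and 24 h-later plates
    attrition_24h: float = 1.0  # survival factor of total cell number on the later plate
    debris_frac: float = 0.03

    def __post_init__(self) -> None:
        total = sum(self.baseline_fractions.get(c, 0.0) for c in CELL_CLASSES)
        if not np.isclose(total, 1.0):
            raise ValidationError(
                f"{self.sample_id}: baseline class fractions must sum to 1 (got {total:.4f})"
            )
        for cls in CELL_CLASSES:
            f = self.baseline_fractions.get(cls, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{self.sample_id}: baseline fraction {cls}={f} outside [0,1]")
        if self.early_by_dose is None and self.max_induction is None:
            raise ValidationError(
                f"{self.sample_id}/{self.drug}: provide early_by_dose or Hill parameters"
            )
        if self.early_by_dose is not None:
            self.early_by_dose = {float(d): float(f) for d, f in self.early_by_dose.items()}
            self.early_by_dose.setdefault(0.0, self.baseline_fractions["early_apoptotic"])
            for d, f in self.early_by_dose.items():
                if not 0.0 <= f <= 1.0:
                    raise ValidationError(
                        f"{self.sample_id}/{self.drug}: early fraction {f} at {d} nM outside [0,1]"
                    )
        if self.max_induction is not None:
            if self.ec50_nM is None or self.ec50_nM <= 0:
                raise ValidationError(f"{self.sample_id}/{self.drug}: Hill mode needs ec50_nM > 0")
        if not 0.0 <= self.progression_rate <= 1.0:
            raise ValidationError("progression_rate must be in [0,1]")
        if not 0.0 < self.attrition_24h <= 1.0:
            raise ValidationError("attrition_24h must be in (0,1]")
        if not 0.0 <= self.debris_frac < 1.0:
            raise ValidationError("debris_frac must be in [0,1)")

    @classmethod
    def from_deltas(
        cls,
        sample_id: str,
        drug: str,
        deltas_pp: dict[float, float],
        baseline_fractions: dict[str, float] | None = None,
        **kwargs,
    ) -> "DoseResponseTruth":
        """Build a truth from induced ∆ Annexin V values in percentage points."""
        base = baseline_fractions or {"alive": 0.90, "early_apoptotic": 0.05, "dead": 0.05}
        early0 = base["early_apoptotic"]
        early = {float(d): early0 + pp / 100.0 for d, pp in deltas_pp.items()}
        return cls(sample_id, drug, baseline_fractions=base, early_by_dose=early, **kwargs)

    def early_fraction(self, dose_nM: float) -> float:
        """True early-apoptotic fraction at a toolkit dose (4 h plate)."""
        dose = float(dose_nM)
        if self.early_by_dose is not None:
            if dose not in self.early_by_dose:
                raise ConfigurationError(
                    f"{self.sample_id}/{self.drug}: no truth at dose {dose} nM "
                    f"(known: {sorted(self.early_by_dose)})"
                )
            return self.early_by_dose[dose]
        base = self.baseline_fractions["early_apoptotic"]
        if dose == 0:
            return base
        h, ec50 = self.hill_slope, float(self.ec50_nM)
        return base + float(self.max_induction) * dose**h / (ec50**h + dose**h)

    def class_fractions(
        self, dose_nM: float, timepoint_h: float = 4.0, induced_shift_pp: float = 0.0
    ) -> dict[str, float]:
        """True (alive, early, dead) fractions over intact cells at a condition.

        ``induced_shift_pp`` perturbs the *induced* response (replicate/batch/
        fresh-frozen variability, percentage points); the vehicle baseline is
        untouched. Fractions outside [0,1] after perturbation are clipped with
        a logged warning.
        """
        base_early = self.baseline_fractions["early_apoptotic"]
        dead = self.baseline_fractions["dead"]
        induced = self.early_fraction(dose_nM) - base_early
        if dose_nM > 0:
            induced += induced_shift_pp / 100.0
        early = base_early + induced
        upper = 1.0 - dead
        if early < 0.0 or early > upper:
            logger.warning(
                "%s/%s at %g nM: early fraction %.4f outside [0, %.4f] after variability; clipping",
                self.sample_id, self.drug, dose_nM, early, upper,
            )
            early = float(np.clip(early, 0.0, upper))
        if timepoint_h >= 24.0:  # plate analyzed 24 h after the profiling plate
            moved = self.progression_rate * early
            early -= moved
            dead += moved
        alive = 1.0 - early - dead
        return {"alive": alive, "early_apoptotic": early, "dead": dead}

    def true_cell_count(self, cells_seeded: int, timepoint_h: float = 4.0) -> float:
        factor = self.attrition_24h if timepoint_h >= 24.0 else 1.0
        return cells_seeded * factor


@dataclass
class VariabilityModel:
    """Nuisance variability injected on top of the true dose response.

    All SDs in percentage points of the induced ∆ Annexin V. ``rng_seed``
    fully determines every draw: identical inputs give bit-identical wells.
    """

    replicate_sd: float = 0.0
    batch_shift_sd: float = 0.0
    fresh_frozen_offset: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0 or self.batch_shift_sd < 0:
            raise ValidationError("variability SDs must be >= 0")


def _well_rng(seed: int, plate_id: str, well_id: str) -> np.random.Generator:
    tag = zlib.crc32(f"{plate_id}:{well_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _batch_shift(variability: VariabilityModel, plate_id: str) -> float:
    if variability.batch_shift_sd == 0:
        return 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(variability.rng_seed), 0xBA7C4, zlib.crc32(plate_id.encode())])
    )
    return float(rng.normal(0.0, variability.batch_shift_sd))


def simulate_well(
    spec: WellSpec,
    truth: DoseResponseTruth,
    populations: dict[str, PopulationModel] | None = None,
    variability: VariabilityModel | None = None,
    n_events: int | None = None,
    beads_added: int | None = None,
) -> EventTable:
    """Draw one well's events from the class mixture implied by the truth.

    ``n_events`` is the number of non-bead events acquired (cells + debris);
    when omitted, the whole well is acquired (n ≈ true cell count). Beads are
    Poisson-sampled with mean ``beads_added`` scaled by the same acquisition
    fraction as the cells.
    """
    populations = populations or default_populations()
    variability = variability or VariabilityModel()
    beads_added = beads_added if beads_added is not None else spec.beads_added
    if beads_added is None or beads_added <= 0:
        raise ConfigurationError(f"{spec.plate_id}/{spec.well_id}: beads_added must be positive")
    if spec.drug != "vehicle" and spec.drug != truth.drug:
        # a vehicle well may borrow any truth of the sample; a treated well may not
        raise ConfigurationError(
            f"{spec.plate_id}/{spec.well_id}: drug {spec.drug!r} does not match truth "
            f"for {truth.sample_id}/{truth.drug}"
        )

    rng = _well_rng(variability.rng_seed, spec.plate_id, spec.well_id)

    shift_pp = 0.0
    if spec.dose_nM > 0:
        if variability.replicate_sd > 0:
            shift_pp += float(rng.normal(0.0, variability.replicate_sd))
        shift_pp += _batch_shift(variability, spec.plate_id)
        if spec.material == "frozen":
            shift_pp += variability.fresh_frozen_offset
    fracs = truth.class_fractions(spec.dose_nM, spec.timepoint_h, induced_shift_pp=shift_pp)

    true_cells = truth.true_cell_count(spec.cells_seeded, spec.timepoint_h)
    if n_events is None:
        n_events = int(round(true_cells / (1.0 - truth.debris_frac)))
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")

    probs = np.array(
        [(1.0 - truth.debris_frac) * fracs[c] for c in CELL_CLASSES] + [truth.debris_frac]
    )
    probs = probs / probs.sum()
    counts = rng.multinomial(n_events, probs)
    class_counts = dict(zip(list(CELL_CLASSES) + ["debris"], counts))

    acquisition_fraction = n_events * (1.0 - truth.debris_frac) / true_cells
    n_beads = int(rng.poisson(beads_added * acquisition_fraction))
    class_counts["bead"] = n_beads

    frames, labels = [], []
    for cls in ("alive", "early_apoptotic", "dead", "debris", "bead"):
        n = class_counts[cls]
        if n:
            frames.append(populations[cls].draw(n, rng))
            labels.append(np.repeat(cls, n))
    data = pd.concat(frames, ignore_index=True)
    labels = np.concatenate(labels)
    order = rng.permutation(len(data))
    data = data.iloc[order].reset_index(drop=True)
    labels = labels[order]

    meta = {
        "plate_id": spec.plate_id,
        "sample_id": spec.sample_id,
        "drug": spec.drug,
        "dose_nM": spec.dose_nM,
        "pretreatment": spec.pretreatment,
        "pretreatment_name": spec.pretreatment_name,
        "timepoint_h": spec.timepoint_h,
        "true_fraction_alive": fracs["alive"],
        "true_fraction_early": fracs["early_apoptotic"],
        "true_fraction_dead": fracs["dead"],
        "true_cell_count": true_cells,
        "true_bead_count": n_beads,
        "beads_added": beads_added,
        "acquisition_fraction": acquisition_fraction,
    }
    return EventTable(data=data, truth=labels, well_id=spec.well_id, meta=meta)


def _lookup_truth(truths: dict, spec: WellSpec) -> DoseResponseTruth:
    candidates = [
        (spec.sample_id, spec.drug, spec.pretreatment_name),
        (spec.sample_id, spec.drug),
        (spec.sample_id, spec.pretreatment_name),
        spec.sample_id,
    ]
    for key in candidates:
        if key in truths:
            return truths[key]
    # a vehicle well can borrow any truth of the same sample (baseline only)
    matches = [
        t for t in truths.values()
        if t.sample_id == spec.sample_id and (spec.drug == "vehicle" or t.drug == spec.drug)
    ]
    if spec.pretreatment_name is not None:
        keyed = [
            truths[k] for k in truths
            if isinstance(k, tuple) and spec.sample_id in k and spec.pretreatment_name in k
        ]
        if keyed:
            matches = keyed + matches
    if matches:
        return matches[0]
    raise ConfigurationError(
        f"{spec.plate_id}/{spec.well_id}: no dose-response truth for sample "
        f"{spec.sample_id!r} / drug {spec.drug!r}"
    )


def simulate_plate(
    layout: PlateLayout,
    truths: dict,
    variability: VariabilityModel | None = None,
    n_events: int | None = None,
) -> tuple[dict[str, EventTable], pd.DataFrame]:
    """Simulate every well of a layout.

    ``truths`` maps ``sample_id`` (or ``(sample_id, drug)`` /
    ``(sample_id, drug, pretreatment_name)`` for finer control) to a
    :class:`DoseResponseTruth`. Returns ``{plate/well: EventTable}`` plus a
    TruthTable recording every true fraction and count used.
    """
    layout.validate(allow_custom_doses=True)
    variability = variability or VariabilityModel()
    wells: dict[str, EventTable] = {}
    truth_rows = []
    for spec in layout.wells:
        truth = _lookup_truth(truths, spec)
        table = simulate_well(
            spec, truth, variability=variability, n_events=n_events, beads_added=spec.beads_added
        )
        key = f"{spec.plate_id}/{spec.well_id}"
        if key in wells:
            raise ValidationError(f"duplicate well id {key}")
        wells[key] = table
        truth_rows.append({"well_id": spec.well_id, **table.meta})
    truth_table = pd.DataFrame(truth_rows)
    cols = ["well_id", "plate_id", "sample_id", "drug", "dose_nM", "pretreatment",
            "pretreatment_name", "timepoint_h", "true_fraction_alive", "true_fraction_early",
            "true_fraction_dead", "true_cell_count", "true_bead_count", "beads_added",
            "acquisition_fraction"]
    return wells, truth_table[cols]


def write_fcs(events: EventTable, path, channel_map: dict[str, str] | None = None) -> None:
    """Write a well as FCS 3.1. Hidden truth labels are never written to FCS."""
    if events.n_events == 0:
        raise ValidationError("cannot write an empty event table")
    cmap = {**DEFAULT_CHANNEL_NAMES, **(channel_map or {})}
    names = [cmap[ch] for ch in LOGICAL_CHANNELS]
    _fcs.write_fcs(path, names, events.data[list(LOGICAL_CHANNELS)].to_numpy())


def write_csv_events(
    events: EventTable, path, channel_map: dict[str, str] | None = None, sidecar: bool = True
) -> None:
    """Write a well in the CSV event dialect (+ truth sidecar for synthetic data)."""
    from pathlib import Path

    if events.n_events == 0:
        raise ValidationError("cannot write an empty event table")
    path = Path(path)
    cmap = {**DEFAULT_CHANNEL_NAMES, **(channel_map or {})}
    out = events.data[list(LOGICAL_CHANNELS)].rename(columns=cmap)
    out.to_csv(path, index=False)
    if sidecar and events.truth is not None:
        sidecar_path = path.parent / (path.stem + ".truth.csv")
        pd.DataFrame({"__truth_class": events.truth}).to_csv(sidecar_path, index=False)
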