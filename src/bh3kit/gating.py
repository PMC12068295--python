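"""Event classification: beads, debris, alive, early-apoptotic, dead.

The gating strategy mirrors manual quadrant gating on Annexin V / 7AAD after
a scatter gate and bead exclusion: dead is any 7AAD-positive event (single
or double positive), early apoptosis is Annexin V single-positive, alive is
double-negative. Events exactly at a threshold count as negative.

Thresholds can be set manually or derived from vehicle wells. The default
automatic rule places each cutoff at the ``quantile_q`` point of the
*negative mode* of the vehicle distribution, estimated robustly as
``median + z_q · 1.4826 · MAD``. A plain empirical quantile
(``robust=False``) is also available, but is biased upward whenever the
vehicle well carries a baseline apoptotic subpopulation — which real thawed
samples always do.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats as sps

from .errors import AcquisitionError, ConfigurationError, ValidationError
from .events import FLUOR_CHANNELS, EventTable

logger = logging.getLogger(__name__)

#: Minimum usable vehicle events before fit_thresholds warns.
MIN_FIT_EVENTS = 500


@dataclass
class GateConfig:
    """Transform + thresholds defining the classification.

    Fluorescence thresholds are in transformed units. Scatter bounds are in
    raw (linear) units; a bound of ``None`` means unbounded, and a fully
    unset lower FSC bound is filled by ``fit_thresholds`` from the lowest 2%
    of vehicle FSC (debris tail).
    """

    transform: str = "arcsinh"  # arcsinh | log10 | none
    cofactor: float = 150.0
    fsc_bounds: tuple[float | None, float | None] = (20_000.0, None)
    ssc_bounds: tuple[float | None, float | None] = (None, None)
    bead_threshold: float = 5.0
    annexin_threshold: float | None = None
    viability_threshold: float | None = None
    threshold_source: str = "quantile_from_vehicle"  # or "manual"
    quantile_q: float = 0.995
    robust: bool = True
    denominator: str = "intact_cells"  # or "live_plus_early"

    def __post_init__(self) -> None:
        if self.transform not in ("arcsinh", "log10", "none"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.cofactor <= 0:
            raise ValidationError("cofactor must be > 0")
        if not 0.0 < self.quantile_q < 1.0:
            raise ValidationError("quantile_q must be in (0,1)")
        if self.threshold_source not in ("manual", "quantile_from_vehicle"):
            raise ValidationError(f"unknown threshold_source {self.threshold_source!r}")
        if self.denominator not in ("intact_cells", "live_plus_early"):
            raise ValidationError(f"unknown denominator {self.denominator!r}")
        for thr in (self.annexin_threshold, self.viability_threshold, self.bead_threshold):
            if thr is not None and not np.isfinite(thr):
                raise ValidationError("thresholds must be finite")

    @property
    def complete(self) -> bool:
        return self.annexin_threshold is not None and self.viability_threshold is not None

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["fsc_bounds"] = list(self.fsc_bounds)
        doc["ssc_bounds"] = list(self.ssc_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("fsc_bounds", "ssc_bounds"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class WellQuant:
    """Per-well classified counts and fractions."""

    counts: dict[str, int]
    total_events: int
    frac_alive: float
    frac_early: float
    frac_dead: float
    denominator: int
    denominator_mode: str = "intact_cells"
    all_beads: bool = False
    well_id: str | None = None

    @property
    def n_beads(self) -> int:
        return self.counts["bead"]

    @property
    def n_early(self) -> int:
        return self.counts["early_apoptotic"]


def _transform_values(x: np.ndarray, transform: str, cofactor: float) -> np.ndarray:
    if transform == "arcsinh":
        return np.arcsinh(x / cofactor)
    if transform == "log10":
        return np.log10(1.0 + np.clip(x, 0.0, None) / cofactor)
    return np.asarray(x, dtype=float)


def _inverse_transform_values(t: np.ndarray, transform: str, cofactor: float) -> np.ndarray:
    if transform == "arcsinh":
        return cofactor * np.sinh(t)
    if transform == "log10":
        return cofactor * (np.power(10.0, t) - 1.0)
    return np.asarray(t, dtype=float)


def apply_transform(events: EventTable, transform: str = "arcsinh", cofactor: float = 150.0) -> EventTable:
    """Transform fluorescence channels (scatter stays linear); invertible."""
    if cofactor <= 0:
        raise ValidationError("cofactor must be > 0")
    if events.transformed:
        raise ValidationError("events are already transformed")
    out = events.copy()
    for ch in FLUOR_CHANNELS:
        out.data[ch] = _transform_values(out.data[ch].to_numpy(), transform, cofactor)
    out.transformed = transform != "none"
    out.cofactor = cofactor if out.transformed else None
    out.meta["transform"] = transform
    return out


def inverse_transform(events: EventTable, transform: str = "arcsinh", cofactor: float = 150.0) -> EventTable:
    """Undo :func:`apply_transform`."""
    out = events.copy()
    for ch in FLUOR_CHANNELS:
        out.data[ch] = _inverse_transform_values(out.data[ch].to_numpy(), transform, cofactor)
    out.transformed = False
    out.cofactor = None
    return out


def _in_bounds(x: np.ndarray, bounds: tuple[float | None, float | None]) -> np.ndarray:
    lo, hi = bounds
    mask = np.ones(len(x), dtype=bool)
    if lo is not None:
        mask &= x >= lo
    if hi is not None:
        mask &= x <= hi
    return mask


def _negative_mode_quantile(values: np.ndarray, q: float) -> float:
    """q-quantile of a Gaussian fit to the dominant (negative) mode: median + z_q·1.4826·MAD."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + sps.norm.ppf(q) * 1.4826 * mad


def fit_thresholds(vehicle_wells: list[EventTable], config: GateConfig | None = None) -> GateConfig:
    """Derive fluorescence thresholds (and, if unset, the debris FSC bound) from vehicle wells.

    Pools all scatter-gated, bead-excluded vehicle events and sets the
    Annexin V and 7AAD cutoffs per the config's quantile rule. Manual fields
    of the input config are preserved.
    """
    config = config or GateConfig()
    if config.threshold_source != "quantile_from_vehicle":
        raise ConfigurationError("fit_thresholds requires threshold_source='quantile_from_vehicle'")
    if not vehicle_wells:
        raise ConfigurationError("at least one vehicle well is required to fit thresholds")

    transformed = [
        w if w.transformed else apply_transform(w, config.transform, config.cofactor)
        for w in vehicle_wells
    ]
    fsc = np.concatenate([w.channel("fsc") for w in transformed])
    ssc = np.concatenate([w.channel("ssc") for w in transformed])
    bead = np.concatenate([w.channel("bead") for w in transformed])
    annexin = np.concatenate([w.channel("annexin") for w in transformed])
    viability = np.concatenate([w.channel("viability_dye") for w in transformed])

    not_bead = bead <= config.bead_threshold
    fsc_bounds = config.fsc_bounds
    if fsc_bounds[0] is None:
        # debris gate default: exclude the lowest 2% of FSC among non-bead events
        fsc_bounds = (float(np.quantile(fsc[not_bead], 0.02)), fsc_bounds[1])
    usable = not_bead & _in_bounds(fsc, fsc_bounds) & _in_bounds(ssc, config.ssc_bounds)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ConfigurationError("no usable vehicle events after scatter gating and bead exclusion")
    if n_usable < MIN_FIT_EVENTS:
        warnings.warn(
            f"only {n_usable} usable vehicle events (<{MIN_FIT_EVENTS}); thresholds may be unstable",
            stacklevel=2,
        )

    if config.robust:
        ann_thr = _negative_mode_quantile(annexin[usable], config.quantile_q)
        via_thr = _negative_mode_quantile(viability[usable], config.quantile_q)
    else:
        ann_thr = float(np.quantile(annexin[usable], config.quantile_q))
        via_thr = float(np.quantile(viability[usable], config.quantile_q))

    fitted = GateConfig(**{**asdict(config), "fsc_bounds": fsc_bounds,
                           "annexin_threshold": float(ann_thr),
                           "viability_threshold": float(via_thr)})
    fitted.fsc_bounds = tuple(fsc_bounds)
    fitted.ssc_bounds = tuple(config.ssc_bounds)
    return fitted


def classify_events(events: EventTable, gate: GateConfig) -> WellQuant:
    """Assign each event exactly one class and tabulate counts/fractions.

    Order: bead → debris (scatter) → dead (7AAD+) → early (Annexin V+ only)
    → alive. ``x <= threshold`` is negative (tie rule).
    """
    if events.n_events == 0:
        raise AcquisitionError("empty event table")
    if not gate.complete:
        raise ConfigurationError("gate is incomplete: fit or set annexin/viability thresholds")
    if gate.fsc_bounds[0] is None and gate.fsc_bounds[1] is None:
        logger.info("no scatter gate set; debris class will be empty")

    t = events if events.transformed else apply_transform(events, gate.transform, gate.cofactor)
    annexin = t.channel("annexin")
    viability = t.channel("viability_dye")
    bead = t.channel("bead")
    fsc, ssc = t.channel("fsc"), t.channel("ssc")

    labels = np.empty(events.n_events, dtype=object)
    is_bead = bead > gate.bead_threshold
    in_scatter = _in_bounds(fsc, gate.fsc_bounds) & _in_bounds(ssc, gate.ssc_bounds)
    is_debris = ~is_bead & ~in_scatter
    is_dead = ~is_bead & ~is_debris & (viability > gate.viability_threshold)
    is_early = ~is_bead & ~is_debris & ~is_dead & (annexin > gate.annexin_threshold)
    is_alive = ~(is_bead | is_debris | is_dead | is_early)
    for mask, cls in [(is_bead, "bead"), (is_debris, "debris"), (is_dead, "dead"),
                      (is_early, "early_apoptotic"), (is_alive, "alive")]:
        labels[mask] = cls

    counts = {cls: int(m.sum()) for cls, m in
              [("bead", is_bead), ("debris", is_debris), ("alive", is_alive),
               ("early_apoptotic", is_early), ("dead", is_dead)]}
    assert sum(counts.values()) == events.n_events

    all_beads = counts["bead"] == events.n_events
    if all_beads:
        warnings.warn(f"well {events.well_id}: all events classified as beads", stacklevel=2)

    if gate.denominator == "intact_cells":
        denom = counts["alive"] + counts["early_apoptotic"] + counts["dead"]
    else:
        denom = counts["alive"] + counts["early_apoptotic"]
    if denom:
        frac_alive = counts["alive"] / denom
        frac_early = counts["early_apoptotic"] / denom
        frac_dead = counts["dead"] / denom if gate.denominator == "intact_cells" else float("nan")
    else:
        frac_alive = frac_early = frac_dead = float("nan")

    return WellQuant(
        counts=counts,
        total_events=events.n_events,
        frac_alive=frac_alive,
        frac_early=frac_early,
        frac_dead=frac_dead,
        denominator=denom,
        denominator_mode=gate.denominator,
        all_beads=all_beads,
        well_id=events.well_id,
    )


def classification_labels(events: EventTable, gate: GateConfig) -> np.ndarray:
    """Per-event class labels (same rules as :func:`classify_events`)."""
    if events.n_events == 0:
        raise AcquisitionError("empty event table")
    t = events if events.transformed else apply_transform(events, gate.transform, gate.cofactor)
    labels = np.full(events.n_events, "alive", dtype=object)
    in_scatter = _in_bounds(t.channel("fsc"), gate.fsc_bounds) & _in_bounds(
        t.channel("ssc"), gate.ssc_bounds
    )
    viability = t.channel("viability_dye")
    annexin = t.channel("annexin")
    labels[(viability > gate.viability_threshold)] = "dead"
    labels[(viability <= gate.viability_threshold) & (annexin > gate.annexin_threshold)] = "early_apoptotic"
    labels[~in_scatter] = "debris"
    labels[t.channel("bead") > gate.bead_threshold] = "bead"
    return labels
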