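"""Plate metadata, event-file and luminescence I/O.

The pipeline is driven by a plate layout: one :class:`WellSpec` per well,
mapping the well to its sample, BH3 mimetic, dose, pre-treatment, timepoint
and the number of counting beads spiked in. Layouts are written as YAML (see
``read_layout`` for the schema); events come in as FCS 3.0/3.1 or as a CSV
dialect with one row per event and channel names in the header.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs
from .errors import ValidationError
from .events import DEFAULT_CHANNEL_NAMES, LOGICAL_CHANNELS, EventTable

#: The four toolkit compounds plus the vehicle arm.
DRUGS: tuple[str, ...] = ("venetoclax", "navitoclax", "AZD-5991", "A-1155463", "vehicle")

#: Anti-apoptotic targets with a dedicated internal-control line.
TARGETS: tuple[str, ...] = ("BCL-2", "MCL-1", "BCL-XL")

#: Default dose grid in nM (0 = vehicle). Custom grids need allow_custom_doses.
DOSE_GRID_NM: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0)

#: Analysis timepoints, hours after toolkit addition. The second plate of the
#: baseline protocol ("24 h later") is encoded as 28; the dynamic protocol's
#: viability plate as 48.
TIMEPOINTS_H: tuple[float, ...] = (4.0, 24.0, 28.0, 48.0)

_TIMEPOINT_ALIASES = {"4h": 4.0, "24h-later": 28.0}

PRETREATMENTS: tuple[str, ...] = ("none", "vehicle", "drug_of_interest")

_WELL_ID_RE = re.compile(r"^[A-P](?:[1-9]|1[0-9]|2[0-4])$")


def normalize_well_id(well_id: str) -> str:
    wid = str(well_id).strip().upper()
    if not _WELL_ID_RE.match(wid):
        raise ValidationError(f"invalid well id {well_id!r} (expected e.g. 'A1'..'P24')")
    return wid


def parse_timepoint(value) -> float:
    if isinstance(value, str) and value.strip().lower() in _TIMEPOINT_ALIASES:
        return _TIMEPOINT_ALIASES[value.strip().lower()]
    return float(value)


@dataclass
class WellSpec:
    """Experimental metadata for a single well."""

    plate_id: str
    well_id: str
    sample_id: str
    sample_kind: str = "primary"  # or "control_line"
    control_target: str | None = None
    drug: str = "vehicle"
    dose_nM: float = 0.0
    pretreatment: str = "none"
    pretreatment_name: str | None = None
    timepoint_h: float = 4.0
    cells_seeded: int = 20_000
    beads_added: int | None = None
    material: str = "frozen"  # or "fresh"

    def validate(self, allow_custom_doses: bool = False) -> list[str]:
        """Return a list of violations (empty when valid)."""
        problems: list[str] = []
        try:
            self.well_id = normalize_well_id(self.well_id)
        except ValidationError as exc:
            problems.append(str(exc))
        if self.drug not in DRUGS:
            problems.append(f"unknown drug {self.drug!r}")
        if self.sample_kind not in ("primary", "control_line"):
            problems.append(f"unknown sample_kind {self.sample_kind!r}")
        if (self.drug == "vehicle") != (self.dose_nM == 0):
            problems.append(
                f"dose_nM must be 0 iff drug is vehicle (got drug={self.drug}, dose={self.dose_nM})"
            )
        if not allow_custom_doses and self.dose_nM not in DOSE_GRID_NM:
            problems.append(
                f"dose {self.dose_nM} nM outside the standard grid {DOSE_GRID_NM}; "
                "pass allow_custom_doses=True to accept"
            )
        if (self.sample_kind == "control_line") != (self.control_target is not None):
            problems.append("control_target must be set iff sample_kind is 'control_line'")
        if self.control_target is not None and self.control_target not in TARGETS:
            problems.append(f"unknown control_target {self.control_target!r}")
        if self.pretreatment not in PRETREATMENTS:
            problems.append(f"unknown pretreatment {self.pretreatment!r}")
        if self.pretreatment == "drug_of_interest" and not self.pretreatment_name:
            problems.append("pretreatment_name required when pretreatment='drug_of_interest'")
        try:
            self.timepoint_h = parse_timepoint(self.timepoint_h)
        except (TypeError, ValueError):
            problems.append(f"unparseable timepoint {self.timepoint_h!r}")
        else:
            if self.timepoint_h not in TIMEPOINTS_H:
                problems.append(
                    f"timepoint {self.timepoint_h} h not in {TIMEPOINTS_H}"
                )
        if self.cells_seeded <= 0:
            problems.append("cells_seeded must be positive")
        if self.material not in ("fresh", "frozen"):
            problems.append(f"unknown material {self.material!r}")
        return [f"{self.plate_id}/{self.well_id}: {p}" for p in problems]

    @property
    def key(self) -> tuple[str, str]:
        return (self.plate_id, self.well_id)


@dataclass
class PlateLayout:
    """A set of wells plus the channel map and bead-lot information."""

    wells: list[WellSpec]
    channel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_NAMES))
    bead_lot: dict | None = None  # {"concentration_per_uL": x, "volume_uL": 5}

    def validate(self, allow_custom_doses: bool = False) -> None:
        problems: list[str] = []
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            problems.extend(w.validate(allow_custom_doses=allow_custom_doses))
            if w.key in seen:
                problems.append(f"{w.plate_id}/{w.well_id}: duplicate well id")
            seen.add(w.key)
        missing = [c for c in LOGICAL_CHANNELS if c not in self.channel_map]
        if missing:
            problems.append(f"channel_map missing logical channel(s): {missing}")
        default_beads = self._beads_from_lot()
        for w in self.wells:
            if w.beads_added is None:
                if default_beads is None:
                    problems.append(
                        f"{w.plate_id}/{w.well_id}: beads_added not given and no bead_lot "
                        "(lot concentration is required — there is no safe default)"
                    )
                else:
                    w.beads_added = default_beads
            elif w.beads_added <= 0:
                problems.append(f"{w.plate_id}/{w.well_id}: beads_added must be positive")
        if problems:
            raise ValidationError("invalid plate layout:\n  " + "\n  ".join(problems))

    def _beads_from_lot(self) -> int | None:
        if not self.bead_lot:
            return None
        conc = float(self.bead_lot["concentration_per_uL"])
        volume = float(self.bead_lot.get("volume_uL", 5.0))  # 5 µL spike per well
        return int(round(conc * volume))

    def well(self, plate_id: str, well_id: str) -> WellSpec:
        wid = normalize_well_id(well_id)
        for w in self.wells:
            if w.plate_id == plate_id and w.well_id == wid:
                return w
        raise KeyError(f"no well {plate_id}/{wid} in layout")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(w) for w in self.wells])


def layout_from_dict(doc: dict, allow_custom_doses: bool = False) -> PlateLayout:
    """Build and validate a PlateLayout from a parsed YAML document."""
    if not isinstance(doc, dict) or "wells" not in doc:
        raise ValidationError("layout document must be a mapping with a 'wells' list")
    key_map = {
        "plate": "plate_id",
        "well": "well_id",
        "sample": "sample_id",
    }
    wells = []
    for i, entry in enumerate(doc["wells"]):
        if not isinstance(entry, dict):
            raise ValidationError(f"wells[{i}] is not a mapping")
        kwargs = {key_map.get(k, k): v for k, v in entry.items()}
        kwargs.setdefault("plate_id", "P1")
        unknown = set(kwargs) - set(WellSpec.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"wells[{i}]: unknown field(s) {sorted(unknown)}")
        wells.append(WellSpec(**kwargs))
    layout = PlateLayout(
        wells=wells,
        channel_map={**DEFAULT_CHANNEL_NAMES, **doc.get("channel_map", {})},
        bead_lot=doc.get("bead_lot"),
    )
    layout.validate(allow_custom_doses=allow_custom_doses)
    return layout


def read_layout(path, allow_custom_doses: bool = False) -> PlateLayout:
    """Read a layout YAML file.

    Schema::

        channel_map: {annexin: AnnexinV-APC-A, viability_dye: 7AAD-A, ...}   # optional
        bead_lot: {concentration_per_uL: 1000, volume_uL: 5}                 # optional
        wells:
          - {plate: P1, well: A1, sample: OCI-Ly1, sample_kind: control_line,
             control_target: BCL-2, drug: venetoclax, dose_nM: 1000,
             timepoint_h: 4h, cells_seeded: 20000, beads_added: 5000}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return layout_from_dict(doc, allow_custom_doses=allow_custom_doses)


def read_events(path, channel_map: dict[str, str] | None = None) -> EventTable:
    """Read one well's events from FCS or the CSV event dialect.

    ``channel_map`` maps logical channel names to the physical names in the
    file; defaults to the generator's conventions.
    """
    path = Path(path)
    cmap = {**DEFAULT_CHANNEL_NAMES, **(channel_map or {})}
    if path.suffix.lower() == ".fcs":
        names, matrix, kw = fcs.read_fcs(path)
        frame = pd.DataFrame(matrix, columns=names)
        declared = int(kw["$TOT"])
        if len(frame) != declared:
            raise ValidationError(f"{path}: event count {len(frame)} != declared $TOT {declared}")
        truth = None
    else:
        frame = pd.read_csv(path)
        truth = None
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            truth_col = pd.read_csv(sidecar)["__truth_class"]
            if len(truth_col) == len(frame):
                truth = truth_col.to_numpy()
    data = {}
    for logical in LOGICAL_CHANNELS:
        physical = cmap[logical]
        if physical not in frame.columns:
            raise ValidationError(
                f"{path}: channel {physical!r} (logical '{logical}') not found; "
                f"file has {list(frame.columns)}"
            )
        data[logical] = frame[physical].to_numpy(dtype=float)
    return EventTable(data=pd.DataFrame(data), truth=truth, well_id=path.stem)


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".truth.csv")


def read_luminescence(path) -> pd.DataFrame:
    """Read a CTG luminescence CSV: sample_id, drug, dose_nM, luminescence [, well_id, pretreatment]."""
    table = pd.read_csv(path)
    required = {"sample_id", "drug", "dose_nM", "luminescence"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: luminescence table missing columns {sorted(missing)}")
    if (table["luminescence"] < 0).any():
        bad = table.loc[table["luminescence"] < 0]
        raise ValidationError(f"{path}: negative luminescence in rows {list(bad.index)}")
    bad_drug = set(table["drug"]) - set(DRUGS)
    if bad_drug:
        raise ValidationError(f"{path}: unknown drug(s) {sorted(bad_drug)}")
    if "pretreatment" not in table.columns:
        table["pretreatment"] = "none"
    return table


def write_report(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Serialize a pipeline output table as CSV or JSON (lossless round-trip)."""
    table = pd.DataFrame(table)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "columns": list(table.columns),
            "data": json.loads(table.to_json(orient="values", double_precision=15)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown report format {format!r} (use 'csv' or 'json')")


def read_report(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    raise ValidationError(f"unknown report format {fmt!r}")
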