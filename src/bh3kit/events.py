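"""Per-well event tables.

An :class:`EventTable` holds one well's worth of cytometer events as a
DataFrame whose columns are the five *logical* channels of the assay:
forward scatter, side scatter, the Annexin V conjugate, the viability dye
(7AAD) and the counting-bead channel. Synthetic tables additionally carry a
hidden per-event ground-truth class used only by recovery tests — it is
never consulted by gating or quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Logical channel names, in canonical column order.
LOGICAL_CHANNELS: tuple[str, ...] = ("fsc", "ssc", "annexin", "viability_dye", "bead")

#: Scatter channels are acquired linearly and never transformed.
SCATTER_CHANNELS: tuple[str, ...] = ("fsc", "ssc")

#: Fluorescence channels, subject to the arcsinh/log display transform.
FLUOR_CHANNELS: tuple[str, ...] = ("annexin", "viability_dye", "bead")

#: Default physical detector names used when writing FCS/CSV files.
DEFAULT_CHANNEL_NAMES: dict[str, str] = {
    "fsc": "FSC-A",
    "ssc": "SSC-A",
    "annexin": "AnnexinV-APC-A",
    "viability_dye": "7AAD-A",
    "bead": "Beads-A",
}

#: Event classes assigned by gating and by the generator's hidden truth.
EVENT_CLASSES: tuple[str, ...] = ("alive", "early_apoptotic", "dead", "debris", "bead")


@dataclass
class EventTable:
    """Raw (or transformed) events for a single well.

    Parameters
    ----------
    data:
        One row per event; columns are `LOGICAL_CHANNELS`.
    truth:
        Optional hidden per-event class labels (synthetic data only).
    transformed:
        Whether fluorescence channels are already in arcsinh/log space.
    cofactor:
        Transform cofactor used, when ``transformed``.
    """

    data: pd.DataFrame
    truth: np.ndarray | None = None
    transformed: bool = False
    cofactor: float | None = None
    well_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LOGICAL_CHANNELS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"event table missing logical channel(s): {missing}")
        if self.truth is not None:
            self.truth = np.asarray(self.truth)
            if len(self.truth) != len(self.data):
                raise ValidationError(
                    f"truth labels ({len(self.truth)}) do not match event count ({len(self.data)})"
                )
            unknown = set(np.unique(self.truth)) - set(EVENT_CLASSES)
            if unknown:
                raise ValidationError(f"unknown truth classes: {sorted(unknown)}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def copy(self) -> "EventTable":
        return EventTable(
            data=self.data.copy(),
            truth=None if self.truth is None else self.truth.copy(),
            transformed=self.transformed,
            cofactor=self.cofactor,
            well_id=self.well_id,
            meta=dict(self.meta),
        )
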