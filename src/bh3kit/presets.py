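"""Reference conditions for the three internal-control cell lines.

The toolkit anchors every dependency score to three lines with known
single-protein dependencies: OCI-Ly1 (BCL-2), JJN3 (MCL-1) and HEL (BCL-XL).
Their published 1 µM ∆ Annexin V responses to the matched mimetic — 75.4,
55.4 and 69.1 percentage points — and the thaw-to-thaw standard deviations
of those responses (5.0, 7.7, 5.9) are encoded here, together with plausible
monotone mid-dose values where only the 1 µM endpoint is published.
"""

from __future__ import annotations

from .simulate import DoseResponseTruth

#: control line -> anti-apoptotic target it reports on
CONTROL_LINES: dict[str, str] = {"OCI-Ly1": "BCL-2", "JJN3": "MCL-1", "HEL": "BCL-XL"}

#: target -> specific BH3 mimetic
TARGET_DRUG: dict[str, str] = {"BCL-2": "venetoclax", "MCL-1": "AZD-5991", "BCL-XL": "A-1155463"}

#: Published ∆ Annexin V (percentage points) of each control at 1 µM of its
#: matched mimetic, and the thaw-reproducibility SD.
CONTROL_DELTA_1UM: dict[str, float] = {"OCI-Ly1": 75.4, "JJN3": 55.4, "HEL": 69.1}
CONTROL_SD_1UM: dict[str, float] = {"OCI-Ly1": 5.0, "JJN3": 7.7, "HEL": 5.9}

#: Baseline class fractions of a freshly thawed, vehicle-treated well.
DEFAULT_BASELINE: dict[str, float] = {"alive": 0.90, "early_apoptotic": 0.05, "dead": 0.05}

# ∆ Annexin V (pp) by dose for each (line, drug). 1 µM endpoints and the
# starred mid/low doses are published; the rest are plausible monotone fills.
_CONTROL_DELTAS: dict[tuple[str, str], dict[float, float]] = {
    ("OCI-Ly1", "venetoclax"): {10: 6.0, 100: 49.0, 1000: 75.4},   # all published
    ("OCI-Ly1", "navitoclax"): {10: 3.0, 100: 18.0, 1000: 41.7},   # 1 µM published
    ("OCI-Ly1", "AZD-5991"): {10: 1.0, 100: 6.0, 1000: 15.0},      # 1 µM published
    ("OCI-Ly1", "A-1155463"): {10: 0.5, 100: 1.0, 1000: 2.0},      # no response published
    ("JJN3", "AZD-5991"): {10: 4.0, 100: 24.0, 1000: 55.4},        # 1 µM published
    ("JJN3", "venetoclax"): {10: 0.5, 100: 1.5, 1000: 4.0},
    ("JJN3", "navitoclax"): {10: 0.5, 100: 2.0, 1000: 6.0},
    ("JJN3", "A-1155463"): {10: 0.5, 100: 1.5, 1000: 4.0},
    ("HEL", "A-1155463"): {10: 7.6, 100: 35.0, 1000: 69.1},        # 10 nM and 1 µM published
    ("HEL", "navitoclax"): {10: 1.0, 100: 7.0, 1000: 17.9},        # 1 µM published
    ("HEL", "venetoclax"): {10: 0.5, 100: 1.5, 1000: 4.0},
    ("HEL", "AZD-5991"): {10: 0.5, 100: 2.0, 1000: 5.0},
}


def control_truth(cell_line: str, drug: str, **kwargs) -> DoseResponseTruth:
    """Ground-truth dose response of a control line to one toolkit compound."""
    key = (cell_line, drug)
    if key not in _CONTROL_DELTAS:
        raise KeyError(f"no preset truth for {cell_line} / {drug}")
    return DoseResponseTruth.from_deltas(
        cell_line, drug, _CONTROL_DELTAS[key], baseline_fractions=dict(DEFAULT_BASELINE), **kwargs
    )


def control_truths() -> dict[tuple[str, str], DoseResponseTruth]:
    """All preset control-line truths, keyed by (sample_id, drug)."""
    return {key: control_truth(*key) for key in _CONTROL_DELTAS}
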