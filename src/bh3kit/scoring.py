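"""Dependency scores, dynamic-profiling shifts and internal-control QC.

A sample's dependency on BCL-2, MCL-1 or BCL-XL is its ∆ Annexin V at 1 µM
of the specific mimetic, normalized to the matched internal-control cell
line measured in the same run and expressed on a control=100 scale. Because
the MCL-1 control (JJN3) responds far less than the other two lines, the
MCL-1 axis is weighted: by default the JJN3 denominator is replaced by the
constant 30 (variant "B"); the plain control-ratio ("A") is selectable and
the variant used is stamped into every profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .presets import CONTROL_DELTA_1UM, CONTROL_LINES, CONTROL_SD_1UM, TARGET_DRUG

logger = logging.getLogger(__name__)

#: Anti-apoptotic axes of the radar profile, in plot order.
SCORE_AXES: tuple[str, ...] = ("BCL-2", "MCL-1", "BCL-XL")

#: Default weighting constant replacing the JJN3 denominator on the MCL-1 axis.
DEFAULT_MCL1_WEIGHT: float = 30.0


@dataclass
class ControlReference:
    """Expected 1 µM response of an internal-control line and its acceptance band."""

    cell_line: str
    target: str
    drug: str
    reference_mean_delta: float
    reference_sd: float
    acceptance_k: float = 2.0

    def __post_init__(self) -> None:
        if self.reference_sd < 0:
            raise ValidationError("reference_sd must be >= 0")
        if self.target not in SCORE_AXES:
            raise ValidationError(f"unknown target {self.target!r}")
        if TARGET_DRUG[self.target] != self.drug:
            raise ValidationError(
                f"drug {self.drug!r} does not match target {self.target} "
                f"(expected {TARGET_DRUG[self.target]!r})"
            )

    @property
    def acceptance_range(self) -> tuple[float, float]:
        half = self.acceptance_k * self.reference_sd
        return (self.reference_mean_delta - half, self.reference_mean_delta + half)


def default_references(acceptance_k: float = 2.0) -> dict[str, ControlReference]:
    """Published control responses/SDs, keyed by target."""
    refs = {}
    for line, target in CONTROL_LINES.items():
        refs[target] = ControlReference(
            cell_line=line, target=target, drug=TARGET_DRUG[target],
            reference_mean_delta=CONTROL_DELTA_1UM[line],
            reference_sd=CONTROL_SD_1UM[line], acceptance_k=acceptance_k,
        )
    return refs


@dataclass
class DependencyProfile:
    """Control-normalized dependency scores for one sample (control = 100)."""

    sample_id: str
    scores: dict[str, float]
    control_deltas: dict[str, float]
    sample_deltas: dict[str, float]
    mcl1_weight: float = DEFAULT_MCL1_WEIGHT
    formula_variant: str = "B"
    navitoclax_delta: float | None = None  # overall-priming annotation, never scored
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "scores": dict(self.scores),
            "sample_deltas": dict(self.sample_deltas),
            "control_deltas": dict(self.control_deltas),
            "mcl1_weight": self.mcl1_weight,
            "formula_variant": self.formula_variant,
            "navitoclax_delta_overall_priming": self.navitoclax_delta,
            "notes": list(self.notes),
        }


@dataclass
class QCResult:
    """Batch acceptance check of an internal control against its reference band."""

    cell_line: str
    batch_id: str | None
    vial_deltas: list[float]
    mean: float
    passed: bool
    reason: str
    inter_batch_sd: float | None = None
    intra_batch_sd: float | None = None


def dependency_score(
    sample_delta_1uM: float,
    control_delta_1uM: float | None,
    target: str,
    mcl1_weight: float = DEFAULT_MCL1_WEIGHT,
    formula_variant: str = "B",
) -> float:
    """Score = 100 × sample ∆ / denominator, clipped at 0.

    Denominator is the control line's ∆ at 1 µM for BCL-2 and BCL-XL. For
    MCL-1 under the default variant "B" the denominator is the fixed weight
    (default 30); variant "A" uses the JJN3 control ∆ unweighted.
    """
    if target not in SCORE_AXES:
        raise ValidationError(f"unknown target {target!r}")
    if formula_variant not in ("A", "B"):
        raise ValidationError(f"unknown formula_variant {formula_variant!r}")
    if target == "MCL-1" and formula_variant == "B":
        if mcl1_weight <= 0:
            raise ValidationError("mcl1_weight must be > 0 under variant B")
        denom = mcl1_weight
    else:
        if control_delta_1uM is None or control_delta_1uM <= 0:
            raise ConfigurationError(
                f"{target}: control ∆ Annexin V is missing or non-positive "
                f"({control_delta_1uM}); review control-line QC before scoring"
            )
        denom = control_delta_1uM
    score = 100.0 * sample_delta_1uM / denom
    if score < 0:
        logger.info("%s: negative sample ∆ (%.2f) clipped to score 0", target, sample_delta_1uM)
        return 0.0
    return score


def profile_sample(
    sample_deltas: pd.DataFrame,
    control_deltas: pd.DataFrame,
    refs: dict[str, ControlReference] | None = None,
    mcl1_weight: float = DEFAULT_MCL1_WEIGHT,
    formula_variant: str = "B",
    dose_nM: float = 1000.0,
) -> DependencyProfile:
    """Three-axis dependency profile of one sample from ∆ Annexin V tables.

    Both tables need columns (sample_id, drug, dose_nM, delta_pct); controls
    must contain, at ``dose_nM``, one row per control line treated with its
    matched mimetic. A navitoclax ∆ of the sample, if present, is carried as
    an overall-priming annotation.
    """
    refs = refs or default_references()
    sample_ids = sample_deltas["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValidationError(f"profile_sample expects one sample, got {list(sample_ids)}")
    sample_id = sample_ids[0]

    scores: dict[str, float] = {}
    used_controls: dict[str, float] = {}
    used_sample: dict[str, float] = {}
    notes: list[str] = []
    for target in SCORE_AXES:
        drug = TARGET_DRUG[target]
        line = refs[target].cell_line
        ctrl = control_deltas[
            (control_deltas["sample_id"] == line)
            & (control_deltas["drug"] == drug)
            & (control_deltas["dose_nM"] == dose_nM)
        ]
        if ctrl.empty:
            raise ConfigurationError(f"no {target} control ({line}) on plate at {dose_nM:g} nM")
        samp = sample_deltas[
            (sample_deltas["drug"] == drug) & (sample_deltas["dose_nM"] == dose_nM)
        ]
        if samp.empty:
            raise ConfigurationError(
                f"sample {sample_id}: no {drug} well at {dose_nM:g} nM for the {target} axis"
            )
        control_delta = float(ctrl["delta_pct"].mean())
        sample_delta = float(samp["delta_pct"].mean())
        if sample_delta < 0:
            notes.append(f"{target}: negative sample ∆ ({sample_delta:.2f}) clipped to 0")
        scores[target] = dependency_score(
            sample_delta, control_delta, target,
            mcl1_weight=mcl1_weight, formula_variant=formula_variant,
        )
        used_controls[target] = control_delta
        used_sample[target] = sample_delta

    nav = sample_deltas[
        (sample_deltas["drug"] == "navitoclax") & (sample_deltas["dose_nM"] == dose_nM)
    ]
    nav_delta = float(nav["delta_pct"].mean()) if not nav.empty else None

    return DependencyProfile(
        sample_id=sample_id, scores=scores, control_deltas=used_controls,
        sample_deltas=used_sample, mcl1_weight=mcl1_weight,
        formula_variant=formula_variant, navitoclax_delta=nav_delta, notes=notes,
    )


def dynamic_shift(vehicle_arm: pd.DataFrame, treated_arm: pd.DataFrame) -> pd.DataFrame:
    """Dynamic-profiling shifts: ∆(drug-pretreated) − ∆(vehicle-pretreated) per (drug, dose).

    Sign is preserved — a pre-treatment can also *reduce* a dependency.
    Unmatched (drug, dose) pairs are skipped with a warning.
    """
    keys = ["drug", "dose_nM"]
    v = vehicle_arm.set_index(keys)
    t = treated_arm.set_index(keys)
    rows = []
    for key in t.index.unique():
        if key not in v.index:
            warnings.warn(f"no vehicle-arm ∆ for {key}; skipped", stacklevel=2)
            continue
        t_rows, v_rows = t.loc[[key]], v.loc[[key]]
        shift = float(t_rows["delta_pct"].mean() - v_rows["delta_pct"].mean())
        rows.append({
            "sample_id": t_rows["sample_id"].iloc[0] if "sample_id" in t_rows else None,
            "pretreatment_name": (
                t_rows["pretreatment_name"].iloc[0] if "pretreatment_name" in t_rows else None
            ),
            "drug": key[0], "dose_nM": key[1],
            "vehicle_delta_pct": float(v_rows["delta_pct"].mean()),
            "treated_delta_pct": float(t_rows["delta_pct"].mean()),
            "shift_pct": shift,
        })
    unmatched_vehicle = set(v.index.unique()) - set(t.index.unique())
    if unmatched_vehicle:
        warnings.warn(f"vehicle-arm conditions without treated arm: {sorted(unmatched_vehicle)}",
                      stacklevel=2)
    return pd.DataFrame(rows)


def _variance_components(values: np.ndarray, batches: np.ndarray) -> tuple[float, float]:
    """One-way random-effects method-of-moments decomposition (inter, intra SD)."""
    frame = pd.DataFrame({"y": values, "b": batches})
    groups = frame.groupby("b")["y"]
    k = groups.ngroups
    n_i = groups.size().to_numpy(dtype=float)
    n = float(n_i.sum())
    grand = frame["y"].mean()
    ss_between = float((n_i * (groups.mean() - grand) ** 2).sum())
    ss_within = float(((frame["y"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    df_within = n - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n - float((n_i**2).sum()) / n) / (k - 1)  # balanced: n0 = per-batch n
    var_between = max(0.0, (ms_between - ms_within) / n0)
    return float(np.sqrt(var_between)), float(np.sqrt(ms_within))


def qc_check(
    vial_deltas: list[float],
    ref: ControlReference,
    batch_ids: list | None = None,
    batch_id: str | None = None,
) -> QCResult:
    """Accept or reject a control batch from its vial responses at 1 µM.

    Pass requires ≥2 vials and a batch mean inside the closed interval
    ``reference_mean ± k·SD`` (boundary values pass). With ≥2 distinct
    batches supplied via ``batch_ids``, inter- and intra-batch SDs are
    estimated by one-way random-effects method of moments.
    """
    values = np.asarray([float(x) for x in np.atleast_1d(vial_deltas)], dtype=float)
    if values.size == 0:
        return QCResult(ref.cell_line, batch_id, [], float("nan"), False, "no vials supplied")
    mean = float(values.mean())
    lo, hi = ref.acceptance_range
    if values.size < 2:
        passed, reason = False, "n_vials < 2"
    elif lo <= mean <= hi:
        passed, reason = True, f"mean {mean:.2f} within [{lo:.2f}, {hi:.2f}]"
    else:
        passed, reason = False, f"mean {mean:.2f} outside [{lo:.2f}, {hi:.2f}]"

    inter = intra = None
    if batch_ids is not None:
        batches = np.asarray(batch_ids)
        if batches.shape != values.shape:
            raise ValidationError("batch_ids must match vial_deltas in length")
        if len(np.unique(batches)) >= 2:
            inter, intra = _variance_components(values, batches)
    return QCResult(
        cell_line=ref.cell_line, batch_id=batch_id, vial_deltas=values.tolist(),
        mean=mean, passed=passed, reason=reason,
        inter_batch_sd=inter, intra_batch_sd=intra,
    )
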