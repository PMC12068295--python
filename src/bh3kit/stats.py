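"""Statistical comparisons: two-way ANOVA contrasts vs control, Pearson correlation.

Replicate measurements crossed by two factors (typically drug/pre-treatment
× dose) are fit with a two-way fixed-effects ANOVA with interaction; each
treated cell is then contrasted against the matched control cell using the
model's pooled residual variance, with a configurable multiplicity
correction (Šídák by default) and the usual star convention
(* ≤0.05, ** ≤0.01, *** ≤0.001, **** ≤0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .errors import ValidationError

STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"),
)


def significance_stars(p_value: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p_value <= thr:
            return stars
    return "ns"


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p and the least-squares line.

    For simple regression R² is exactly r²; both are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(r), p_value=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), r_squared=float(r) ** 2, n=len(x),
    )


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if method == "none" or p.size <= 1:
        return p
    if method == "sidak":
        return 1.0 - (1.0 - p) ** p.size
    if method == "holm":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="holm")[1]
    raise ValidationError(f"unknown correction {method!r} (use none|sidak|holm)")


def compare_to_control(
    measurements: pd.DataFrame,
    value_col: str = "value",
    condition_col: str = "condition",
    dose_col: str = "dose_nM",
    control_level: str = "vehicle",
    correction: str = "sidak",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way ANOVA (condition × dose, with interaction) and per-cell contrasts vs control.

    Each (condition ≠ control, dose) cell is contrasted against the control
    condition at the same dose; p-values use the pooled residual variance of
    the full model and are corrected over the dose contrasts within each
    condition. The returned table also carries the ANOVA p-values for the
    two main effects and the interaction (identical per row).
    """
    df = measurements.rename(
        columns={value_col: "value", condition_col: "condition", dose_col: "dose"}
    )[["value", "condition", "dose"]].copy()
    if control_level not in set(df["condition"]):
        raise ValidationError(f"control level {control_level!r} not present in {condition_col}")
    cell_sizes = df.groupby(["condition", "dose"]).size()
    if (cell_sizes < 2).any():
        small = cell_sizes[cell_sizes < 2]
        raise ValidationError(f"cells with <2 replicates cannot be compared: {small.index.tolist()}")
    if cell_sizes.nunique() > 1:
        warnings.warn("unbalanced design: type-II sums of squares are order-dependent here",
                      stacklevel=2)

    model = ols("value ~ C(condition) * C(dose)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = model.mse_resid
    df_resid = model.df_resid

    def p_of(row_label: str) -> float:
        return float(anova.loc[row_label, "PR(>F)"])

    anova_p = {
        "p_condition": p_of("C(condition)"),
        "p_dose": p_of("C(dose)"),
        "p_interaction": p_of("C(condition):C(dose)"),
    }

    rows = []
    for condition in [c for c in df["condition"].unique() if c != control_level]:
        contrasts = []
        for dose in sorted(df.loc[df["condition"] == condition, "dose"].unique()):
            treated = df[(df["condition"] == condition) & (df["dose"] == dose)]["value"]
            control = df[(df["condition"] == control_level) & (df["dose"] == dose)]["value"]
            if control.empty:
                warnings.warn(f"no control cell at dose {dose}; contrast skipped", stacklevel=2)
                continue
            diff = float(treated.mean() - control.mean())
            se = float(np.sqrt(mse * (1.0 / len(treated) + 1.0 / len(control))))
            if se > 0:
                t = diff / se
                p = 2.0 * sps.t.sf(abs(t), df_resid)
            else:  # degenerate: zero residual variance
                t = 0.0 if diff == 0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0 else 0.0
            contrasts.append({"condition": condition, "dose_nM": dose, "estimate": diff,
                              "se": se, "t": t, "p_raw": float(p)})
        adjusted = _adjust(np.array([c["p_raw"] for c in contrasts]), correction)
        for c, p_adj in zip(contrasts, adjusted):
            p_adj = float(min(1.0, p_adj))
            rows.append({**c, "p_value": p_adj, "significant": p_adj <= alpha,
                         "stars": significance_stars(p_adj), "correction": correction,
                         **anova_p})
    return pd.DataFrame(rows)
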