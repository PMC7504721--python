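"""Complement activity assays: plate normalization, single-dose tests,
constrained IC50 fitting, pathway selectivity and progress-curve rates.

ELISA readouts (absorbance at 450 nm) are normalized per plate column
against its own controls — the positive control (serum, no inhibitor)
defines 100% activity and the negative control (no serum) defines 0% —
so percent activity is affine-invariant to plate-wide offsets. Dose
responses are fitted to the inhibitor-vs-response model

    pct(C) = 100 / (1 + (C / IC50)^h)

with top and bottom constrained to 100 and 0; the fixed-slope variant
pins h = 1. The 95% confidence interval comes from the asymptotic
covariance of the fit on the log-IC50 scale (t quantile, N − p degrees of
freedom), so it is positive and brackets the estimate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

DEGENERATE_CONTROL_TOL = 1e-9


def percent_activity(column: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate column's absorbances to percent activity.

    ``column`` needs ``role`` (sample / positive_control / negative_control)
    and ``absorbance`` columns. Returns a copy with ``pct_activity`` for
    every well; values are not clipped to [0, 100]. Raises if the controls
    are degenerate (positive ≈ negative).
    """
    roles = set(column["role"])
    if "positive_control" not in roles or "negative_control" not in roles:
        raise ValueError("column needs at least one positive and one negative control")
    pos = column.loc[column["role"] == "positive_control", "absorbance"].mean()
    neg = column.loc[column["role"] == "negative_control", "absorbance"].mean()
    span = pos - neg
    if abs(span) < DEGENERATE_CONTROL_TOL:
        raise ValueError("degenerate controls: positive and negative coincide")
    out = column.copy()
    out["pct_activity"] = 100.0 * (out["absorbance"] - neg) / span
    return out


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`percent_activity` column-by-column (controls are per
    column, matching the plate layout)."""
    parts = [percent_activity(g) for _, g in plate.groupby("col", sort=True)]
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool  # p < 0.05


def single_dose_test(
    sample: Sequence[float],
    control: Sequence[float],
    *,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided unpaired t-test of a single-dose group against its control
    (Student's equal-variance form by default; Welch via flag). Two
    identical zero-variance groups return p = 1 by convention."""
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, significant=False)
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf,
                           p=0.0, significant=True)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p), significant=bool(p < alpha))


@dataclass(frozen=True)
class DoseResponseResult:
    ic50: float  # M
    hill: float
    ci95: tuple[float, float]  # M
    n_points: int
    model: str  # fixed_slope | variable_slope
    rss: float
    extrapolated: bool  # IC50 outside the tested concentration span


def dose_response_pct(conc, ic50: float, hill: float = 1.0):
    c = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (c / ic50) ** hill)


def fit_ic50(
    doses: Sequence[tuple[float, float]],
    model: str = "fixed_slope",
    *,
    min_span_pct: float = 10.0,
) -> DoseResponseResult:
    """Fit IC50 (and optionally the Hill slope) from (concentration,
    percent activity) points with the curve top/bottom fixed at 100/0.

    A response spanning less than ``min_span_pct`` percentage points is
    rejected as showing no dose dependence (such curves cannot be fit).
    The IC50 is flagged ``extrapolated`` when it falls outside the tested
    concentration range.
    """
    if model not in ("fixed_slope", "variable_slope"):
        raise ValueError("model must be fixed_slope or variable_slope")
    arr = np.asarray([(c, p) for c, p in doses], dtype=float)
    conc, pct = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    # group means define the observed span; replicate scatter alone is not
    # dose dependence
    mean_by_c = pd.Series(pct).groupby(pd.Series(conc)).mean()
    if float(mean_by_c.max() - mean_by_c.min()) < min_span_pct:
        raise RuntimeError("no dose dependence: response span below "
                           f"{min_span_pct} percentage points")

    # initial guess: concentration whose mean response is nearest 50%
    guess = float(mean_by_c.index[np.argmin(np.abs(mean_by_c.values - 50.0))])
    free_hill = model == "variable_slope"
    x0 = [np.log(guess)] + ([0.0] if free_hill else [])

    def residuals(x):
        ic50 = np.exp(x[0])
        h = np.exp(x[1]) if free_hill else 1.0
        return dose_response_pct(conc, ic50, h) - pct

    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"IC50 fit did not converge: {sol.message}")
    ic50 = float(np.exp(sol.x[0]))
    hill = float(np.exp(sol.x[1])) if free_hill else 1.0

    n, p = conc.size, len(x0)
    dof = max(n - p, 1)
    rss = float(2.0 * sol.cost)
    s2 = rss / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_log = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("no dose dependence: singular fit") from exc
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = (ic50 * np.exp(-tcrit * se_log), ic50 * np.exp(tcrit * se_log))
    return DoseResponseResult(
        ic50=ic50, hill=hill, ci95=(float(ci[0]), float(ci[1])),
        n_points=int(n), model=model, rss=rss,
        extrapolated=not (conc.min() <= ic50 <= conc.max()),
    )


@dataclass(frozen=True)
class SelectivityProfile:
    table: pd.DataFrame  # pathway, inhibits, p
    label: str  # "<pathway>-specific" | "multi-pathway" | "inactive"


def selectivity_table(results: Mapping[str, TTestResult]) -> SelectivityProfile:
    """Classify a compound's pathway selectivity from per-pathway single-dose
    outcomes (e.g. classical / lectin / alternative)."""
    if len(results) < 2:
        raise ValueError("need results for at least 2 pathways")
    rows = [{"pathway": k, "inhibits": v.significant, "p": v.p}
            for k, v in results.items()]
    table = pd.DataFrame(rows)
    inhibited = sorted(table.loc[table["inhibits"], "pathway"])
    if not inhibited:
        label = "inactive"
    elif len(inhibited) == 1:
        label = f"{inhibited[0]}-specific"
    else:
        label = "multi-pathway"
    return SelectivityProfile(table=table, label=label)


@dataclass(frozen=True)
class ProgressCurve:
    times: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and absorbance must be matching 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)


def initial_rate(curve: ProgressCurve, window: tuple[float, float]) -> float:
    """Least-squares slope (AU/s) of the progress curve over ``window``;
    needs at least 5 points in the window."""
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    if mask.sum() < 5:
        raise ValueError("rate window must contain at least 5 points")
    slope = np.polyfit(curve.times[mask], curve.absorbance[mask], 1)[0]
    return float(slope)


@dataclass(frozen=True)
class RateComparison:
    ratio: float
    inhibited: bool


def compare_rates(treated: float, control: float,
                  threshold: float = 0.5) -> RateComparison:
    """Ratio of treated to control initial rates; inhibited when the ratio
    drops below ``threshold`` (default 0.5)."""
    if control == 0:
        raise ValueError("control rate is zero; ratio undefined")
    ratio = treated / control
    return RateComparison(ratio=float(ratio), inhibited=bool(ratio < threshold))
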