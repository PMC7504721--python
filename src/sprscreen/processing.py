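"""Sensorgram processing: double referencing, DMSO solvent correction and
report-point extraction.

An SPR screening cycle yields an *active* trace (analyte over the ligand
surface) and a *reference* trace (same injection over a bare surface).
Processing subtracts the reference and a blank (buffer-only) cycle
("double referencing"), corrects the residual excluded-volume artifact
caused by DMSO mismatch between sample and running buffer using solvent
calibration cycles, and reduces each corrected trace to report points:
a late-association *binding* point (steady-state response) and a
*residual* point 10 s after the end of the injection (non-specific
stickiness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class CycleMeta:
    """Per-cycle bookkeeping carried alongside each trace."""

    cycle: int = 0
    compound_id: str | None = None
    conc_M: float = 0.0
    dmso_pct: float = 0.0
    flow_cell: int = 2
    role: str = "active"
    is_calibration: bool = False
    is_blank: bool = False
    stage: str = "binding"


@dataclass(frozen=True)
class SurfaceDef:
    """An immobilized-ligand flow cell.

    ``immobilization`` is the captured ligand level in RU and must be
    positive for ligand surfaces; reference (bare) surfaces carry 0.
    """

    name: str
    ligand_mw: float
    immobilization: float
    flow_cell: int = 2
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not self.is_reference and self.immobilization <= 0:
            raise ValueError("ligand surfaces need immobilization > 0")
        if self.ligand_mw <= 0:
            raise ValueError("ligand molecular weight must be positive")


@dataclass
class Sensorgram:
    """One injection cycle's time course in resonance units.

    ``t_start``/``t_stop`` mark the association window (injection); the
    trace continues through dissociation. Times must be strictly
    increasing and the markers must lie inside the sampled range.
    """

    times: np.ndarray
    response: np.ndarray
    t_start: float
    t_stop: float
    meta: CycleMeta = field(default_factory=CycleMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape or self.times.ndim != 1:
            raise ValueError("times and response must be matching 1-D arrays")
        if self.times.size < 2 or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (self.times[0] <= self.t_start < self.t_stop <= self.times[-1]):
            raise ValueError("phase markers must lie within the time range")

    def window_mean(self, center: float, width: float) -> float:
        lo, hi = center - width / 2.0, center + width / 2.0
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError(
                f"window [{lo:.2f}, {hi:.2f}] s outside trace "
                f"[{self.times[0]:.2f}, {self.times[-1]:.2f}] s"
            )
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValueError("window contains no samples")
        return float(self.response[mask].mean())

    def interpolated(self, times: np.ndarray) -> "Sensorgram":
        resp = np.interp(times, self.times, self.response)
        return Sensorgram(times=np.asarray(times, float), response=resp,
                          t_start=self.t_start, t_stop=self.t_stop, meta=self.meta)


class ReportPointKind(str, Enum):
    BINDING = "binding_late_association"
    RESIDUAL = "residual_post_injection"


@dataclass(frozen=True)
class ReportPoint:
    value: float
    center: float
    width: float
    kind: ReportPointKind

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("report-point window width must be positive")


def double_reference(
    active: Sensorgram,
    reference: Sensorgram,
    blank: Sensorgram | tuple[Sensorgram, Sensorgram] | None = None,
    *,
    interpolate: bool = False,
) -> Sensorgram:
    """Reference- and blank-subtract a cycle.

    corrected = (active - reference) - (blank_active - blank_reference).
    ``blank`` may be an already reference-subtracted blank cycle, a
    (blank_active, blank_reference) pair, or None (reference subtraction
    only). Traces must share the active trace's time grid unless
    ``interpolate`` is set, in which case they are linearly resampled.
    """

    def aligned(s: Sensorgram) -> np.ndarray:
        if s.times.shape == active.times.shape and np.allclose(s.times, active.times):
            return s.response
        if not interpolate:
            raise ValueError("time grids differ; pass interpolate=True to resample")
        return np.interp(active.times, s.times, s.response)

    corrected = active.response - aligned(reference)
    if blank is not None:
        if isinstance(blank, tuple):
            blank_active, blank_reference = blank
            corrected = corrected - (aligned(blank_active) - aligned(blank_reference))
        else:
            corrected = corrected - aligned(blank)
    return Sensorgram(
        times=active.times.copy(), response=corrected,
        t_start=active.t_start, t_stop=active.t_stop, meta=active.meta,
    )


# -- solvent (DMSO excluded-volume) correction --------------------------------

#: fraction of the association window skipped before measuring bulk, to let
#: the injection step settle
_BULK_SKIP_FRACTION = 0.2


def measure_ref_bulk(reference: Sensorgram) -> float:
    """Bulk refractive-index response of a cycle: mean reference signal during
    the (settled) association window minus the pre-injection baseline."""
    t0, t1 = reference.t_start, reference.t_stop
    settle = t0 + _BULK_SKIP_FRACTION * (t1 - t0)
    assoc = (reference.times >= settle) & (reference.times <= t1)
    base = reference.times < t0
    if not assoc.any() or not base.any():
        raise ValueError("cannot measure bulk: missing baseline or association samples")
    return float(reference.response[assoc].mean() - reference.response[base].mean())


@dataclass
class SolventCalibration:
    """Polynomial map from reference bulk response to the excluded-volume
    offset left in the active-minus-reference signal, with the validity
    range of bulk responses it was fitted over."""

    points: list[tuple[float, float]]
    coeffs: np.ndarray  # np.polyval convention, highest power first
    validity: tuple[float, float]
    cycle_span: tuple[int, int] = (0, 0)

    def offset(self, ref_bulk: float) -> float:
        return float(np.polyval(self.coeffs, ref_bulk))

    def in_range(self, ref_bulk: float) -> bool:
        lo, hi = self.validity
        return lo <= ref_bulk <= hi


def fit_solvent_calibration(
    calibration_cycles: Sequence[tuple[Sensorgram, Sensorgram]],
    degree: int = 2,
    cycle_span: tuple[int, int] = (0, 0),
) -> SolventCalibration:
    """Fit the solvent-correction curve from solvent-only cycles.

    Each cycle is an (active, reference) pair of a buffer injection at a
    known DMSO level. For each, the reference bulk response and the
    active-minus-reference offset are measured over the association
    window; a least-squares polynomial (default degree 2) of offset
    versus bulk is fitted and its validity range recorded.
    """
    if len(calibration_cycles) < 3:
        raise ValueError("need at least 3 solvent calibration cycles")
    points: list[tuple[float, float]] = []
    for active, reference in calibration_cycles:
        bulk = measure_ref_bulk(reference)
        diff = double_reference(active, reference)
        t0, t1 = active.t_start, active.t_stop
        settle = t0 + _BULK_SKIP_FRACTION * (t1 - t0)
        assoc = (diff.times >= settle) & (diff.times <= t1)
        base = diff.times < t0
        offset = float(diff.response[assoc].mean() - diff.response[base].mean())
        points.append((bulk, offset))
    bulks = np.array([p[0] for p in points])
    offsets = np.array([p[1] for p in points])
    if np.ptp(bulks) < 1e-9:
        raise ValueError("degenerate calibration: bulk responses do not vary")
    coeffs = np.polyfit(bulks, offsets, deg=degree)
    return SolventCalibration(
        points=points,
        coeffs=coeffs,
        validity=(float(bulks.min()), float(bulks.max())),
        cycle_span=cycle_span,
    )


def select_calibration(
    calibrations: Sequence[SolventCalibration], cycle: int
) -> SolventCalibration:
    """Pick the calibration whose cycle span contains ``cycle``; if none
    does, the nearest span. Calibrations are applied piecewise, matching
    the every-N-cycles collection schedule, with no temporal interpolation."""
    if not calibrations:
        raise ValueError("no solvent calibrations available")
    for cal in calibrations:
        lo, hi = cal.cycle_span
        if lo <= cycle <= hi:
            return cal

    def dist(cal: SolventCalibration) -> int:
        lo, hi = cal.cycle_span
        return min(abs(cycle - lo), abs(cycle - hi))

    return min(calibrations, key=dist)


def apply_solvent_correction(
    value: float | ReportPoint, ref_bulk: float, cal: SolventCalibration
) -> tuple[float | ReportPoint, bool]:
    """Subtract the calibrated excluded-volume offset from a corrected value
    or report point. Returns the corrected quantity and an ``in_range``
    flag; out-of-range bulks are flagged (for downstream exclusion), never
    extrapolated into an exception."""
    delta = cal.offset(ref_bulk)
    ok = cal.in_range(ref_bulk)
    if isinstance(value, ReportPoint):
        return replace(value, value=value.value - delta), ok
    return float(value) - delta, ok


def report_point(
    s: Sensorgram,
    kind: ReportPointKind,
    width: float | None = None,
    residual_offset: float = 10.0,
) -> ReportPoint:
    """Reduce a trace to a report point.

    The *binding* point averages the last 2 s of the association phase
    (steady-state response); the *residual* point averages a 1 s window
    centered ``residual_offset`` s (default 10) after the injection end.
    A window rather than a single sample resists point noise.
    """
    kind = ReportPointKind(kind)
    if kind is ReportPointKind.BINDING:
        w = 2.0 if width is None else width
        center = s.t_stop - w / 2.0
    else:
        w = 1.0 if width is None else width
        center = s.t_stop + residual_offset
    return ReportPoint(value=s.window_mean(center, w), center=center, width=w, kind=kind)
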