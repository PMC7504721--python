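"""Screening cascade: clean screen, theoretical-Rmax hit calling and
campaign bookkeeping.

A fragment screen at a single concentration triages each compound through
(in order): an insolubility flag (visual inspection upstream — consumed,
never computed here), a *clean screen* that excludes non-specifically
sticky compounds (> 5.0 RU residual on a bare surface 10 s after the
injection), a solvent-correction range check, and hit calling against the
theoretical maximal response

    Rmax = immobilization (RU) × (MW analyte / MW ligand) × n

with two criteria: binding ≥ 60% of Rmax makes a hit, binding > 2 × Rmax
(superstoichiometric, aggregation-like) excludes. Comparison directions
are exactly the printed inequalities: strict ``>`` for exclusions,
``≥`` for the hit fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import Compound
from .processing import ReportPoint, ReportPointKind, SurfaceDef


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the screening cascade (defaults are the campaign's
    published operating point)."""

    clean_threshold: float = 5.0  # RU; residual above this fails the clean screen
    residual_offset: float = 10.0  # s post injection for the residual point
    screen_conc: float = 5e-4  # M
    hit_fraction: float = 0.60  # of theoretical Rmax
    superstoich_factor: float = 2.0  # × Rmax exclusion
    stoich_n: float = 1.0
    baseline_noise_ru: float = 0.5  # RU; scales the abnormal-shape heuristic

    def __post_init__(self) -> None:
        for name in ("clean_threshold", "residual_offset", "screen_conc",
                     "hit_fraction", "superstoich_factor", "stoich_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hit_fraction >= self.superstoich_factor:
            raise ValueError("hit_fraction must be below superstoich_factor")


@dataclass
class ScreenRecord:
    """Per-compound triage outcome. ``hit`` is None until decided; a decided
    record is either a hit or carries an explanatory flag / sub-threshold
    pct_rmax — nothing is dropped silently."""

    compound_id: str
    binding_ru: float | None = None
    residual_ru: float | None = None
    rmax_theoretical: float | None = None
    pct_rmax: float | None = None
    flags: set[str] = field(default_factory=set)
    hit: bool | None = None


def theoretical_rmax(surface: SurfaceDef, compound: Compound | float,
                     n: float = 1.0) -> float:
    """Theoretical maximal binding response in RU for an analyte over a
    surface: immobilization × (MW analyte / MW ligand) × stoichiometry."""
    mw = compound.mw if isinstance(compound, Compound) else float(compound)
    if not np.isfinite(mw) or mw <= 0:
        raise ValueError("analyte molecular weight must be positive")
    if surface.immobilization <= 0:
        raise ValueError("surface immobilization must be positive")
    return surface.immobilization * (mw / surface.ligand_mw) * n


def clean_screen(residual: ReportPoint, cfg: TriageConfig = TriageConfig()) -> bool:
    """True if the compound passes (residual ≤ threshold); strictly greater
    residuals fail, so a residual exactly at 5.0 RU passes."""
    if residual.kind is not ReportPointKind.RESIDUAL:
        raise ValueError("clean screen needs a residual_post_injection report point")
    return not residual.value > cfg.clean_threshold


def abnormal_shape(binding: ReportPoint, residual: ReportPoint,
                   cfg: TriageConfig = TriageConfig()) -> bool:
    """Heuristic for a distorted sensorgram: the post-injection residual
    exceeding the late-association response by more than 3× baseline noise
    (signal persisting after the analyte is gone), or binding more negative
    than 3× baseline noise."""
    margin = 3.0 * cfg.baseline_noise_ru
    return (residual.value > binding.value + margin
            or binding.value < -margin)


def call_hit(record: ScreenRecord, cfg: TriageConfig = TriageConfig()) -> ScreenRecord:
    """Decide hit status on a record carrying a corrected binding value and
    theoretical Rmax. Sets pct_rmax, the superstoichiometric flag, and
    hit = (no flags) and pct_rmax ≥ 100·hit_fraction."""
    if record.rmax_theoretical is None or record.rmax_theoretical <= 0:
        raise ValueError("rmax_theoretical must be positive before hit calling")
    if record.binding_ru is None:
        raise ValueError("record has no corrected binding value")
    record.pct_rmax = 100.0 * record.binding_ru / record.rmax_theoretical
    if record.binding_ru > cfg.superstoich_factor * record.rmax_theoretical:
        record.flags.add("superstoichiometric")
    record.hit = (not record.flags) and record.pct_rmax >= 100.0 * cfg.hit_fraction
    return record


def _round_half_up(x: float, places: int = 1) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def screening_bookkeeping(
    clean_failures: Mapping[str, int] | Sequence[int],
    library_total: int,
    n_hits: int | None = None,
) -> dict:
    """Campaign-level counts from per-sublibrary clean-screen failures.

    Returns the failure total, the number carried forward, and (when
    ``n_hits`` is given) the hit rate as a percentage of the full library,
    rounded half-up to one decimal (so 95/2000 prints as 4.8)."""
    values = (list(clean_failures.values()) if isinstance(clean_failures, Mapping)
              else list(clean_failures))
    total_fail = int(sum(values))
    out = {
        "clean_screen_failures": total_fail,
        "carried_forward": int(library_total) - total_fail,
    }
    if n_hits is not None:
        out["hits"] = int(n_hits)
        out["hit_rate_pct"] = _round_half_up(100.0 * n_hits / library_total, 1)
    return out


def campaign_summary(records: Sequence[ScreenRecord],
                     library: Sequence[Compound]) -> dict:
    """Totals and per-sublibrary breakdown of a triaged campaign."""
    sub_of = {c.id: c.sublibrary.value for c in library}
    per_sub: dict[str, dict[str, int]] = {}
    counters = {"total": 0, "insoluble": 0, "clean_fail": 0,
                "out_of_calibration": 0, "superstoichiometric": 0,
                "abnormal_shape": 0, "screened": 0, "hits": 0}

    def bucket(sub: str) -> dict[str, int]:
        return per_sub.setdefault(sub, dict.fromkeys(counters, 0))

    for rec in records:
        sub = sub_of.get(rec.compound_id, "?")
        for tgt in (counters, bucket(sub)):
            tgt["total"] += 1
            for flag in ("insoluble", "clean_fail", "out_of_calibration",
                         "superstoichiometric", "abnormal_shape"):
                if flag in rec.flags:
                    tgt[flag] += 1
            if not {"insoluble", "clean_fail"} & rec.flags:
                tgt["screened"] += 1
            if rec.hit:
                tgt["hits"] += 1

    n = counters["total"]
    summary = {
        **counters,
        "carried_forward": n - counters["insoluble"] - counters["clean_fail"],
        "hit_rate_pct": _round_half_up(100.0 * counters["hits"] / n, 1) if n else 0.0,
        "per_sublibrary": per_sub,
    }
    return summary


def summary_frame(summary: dict) -> pd.DataFrame:
    rows = [{"sublibrary": sub, **counts}
            for sub, counts in summary["per_sublibrary"].items()]
    return pd.DataFrame(rows)
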