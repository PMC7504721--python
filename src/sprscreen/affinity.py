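"""Constrained steady-state affinity fitting and domain mapping.

Plateau responses from a dilution series are fitted to the 1:1 Langmuir
steady-state isotherm

    Req(C) = C · Rmax / (C + KD)

with Rmax *fixed* to the theoretical value computed from the analyte and
surface molecular weights and the immobilization level. Fixing Rmax is
what keeps KD estimable for weak fragment binders whose KD exceeds the
highest tested concentration; it is never relaxed silently. KD is the
only free parameter (an optional constant offset can be enabled), fitted
by unweighted least squares in linear response space with an internal
log10 parameterization for stability.

Domain mapping normalizes raw responses measured on several surfaces
(full-length ligand and domain truncations) to stoichiometric occupancy,
raw × MW_ligand / (immobilization × MW_analyte × n) — i.e. the fraction
of theoretical saturation — so binding is comparable across surfaces of
different ligand sizes and densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .library import Compound
from .processing import SurfaceDef
from .triage import theoretical_rmax

KD_BOUNDS_M = (1e-9, 10.0)


@dataclass(frozen=True)
class SteadyStateFit:
    kd: float  # M
    rmax_constraint: float  # RU
    rss: float
    offset: float
    saturation: float  # max tested C divided by fitted KD
    n_points: int


@dataclass(frozen=True)
class AffinityResult:
    """Replicate-aggregated affinity: arithmetic mean ± sample SD of the
    per-replicate KD values (on the KD scale, not log), provisional when
    fewer than three replicates back it."""

    kd_per_replicate: tuple[float, ...]
    kd_mean: float
    kd_sd: float
    rss_per_replicate: tuple[float, ...]
    n_replicates: int
    provisional: bool


def steady_state_response(conc, kd: float, rmax: float, offset: float = 0.0):
    c = np.asarray(conc, dtype=float)
    return c * rmax / (c + kd) + offset


def fit_steady_state(
    series: Sequence[tuple[float, float]],
    rmax_constraint: float,
    *,
    fit_offset: bool = False,
    min_points: int = 4,
) -> SteadyStateFit:
    """Fit KD from (concentration, plateau response) pairs with Rmax fixed.

    The initial guess is the concentration nearest half of the maximum
    observed response; KD is bounded to [1e-9, 10] M via an internal
    log10 parameterization.
    """
    arr = np.asarray([(c, r) for c, r in series], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (conc, response) pairs")
    conc, resp = arr[:, 0], arr[:, 1]
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < min_points:
        raise ValueError(f"need >= {min_points} distinct concentrations")
    if rmax_constraint <= 0:
        raise ValueError("rmax_constraint must be positive")
    if np.allclose(resp, 0.0):
        raise ValueError("all responses are zero; nothing to fit")

    half = resp.max() / 2.0
    guess = conc[np.argmin(np.abs(resp - half))]
    lo, hi = np.log10(KD_BOUNDS_M)
    x0 = [float(np.clip(np.log10(guess), lo, hi))]
    bounds_lo, bounds_hi = [lo], [hi]
    if fit_offset:
        x0.append(0.0)
        bounds_lo.append(-np.inf)
        bounds_hi.append(np.inf)

    def residuals(x):
        kd = 10.0 ** x[0]
        off = x[1] if fit_offset else 0.0
        return steady_state_response(conc, kd, rmax_constraint, off) - resp

    sol = least_squares(residuals, x0, bounds=(bounds_lo, bounds_hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"steady-state fit did not converge: {sol.message}")
    kd = float(10.0 ** sol.x[0])
    return SteadyStateFit(
        kd=kd,
        rmax_constraint=float(rmax_constraint),
        rss=float(2.0 * sol.cost),
        offset=float(sol.x[1]) if fit_offset else 0.0,
        saturation=float(conc.max() / kd),
        n_points=len(conc),
    )


def aggregate_replicates(fits: Sequence[SteadyStateFit | float]) -> AffinityResult:
    """Mean ± sample SD over replicate KD fits. Fewer than three replicates
    yields a provisional result rather than an error."""
    if len(fits) == 0:
        raise ValueError("no replicate fits to aggregate")
    kds = tuple(float(f.kd) if isinstance(f, SteadyStateFit) else float(f)
                for f in fits)
    rss = tuple(float(f.rss) if isinstance(f, SteadyStateFit) else np.nan
                for f in fits)
    if any(k <= 0 for k in kds):
        raise ValueError("KD values must be positive")
    n = len(kds)
    return AffinityResult(
        kd_per_replicate=kds,
        kd_mean=float(np.mean(kds)),
        kd_sd=float(np.std(kds, ddof=1)) if n > 1 else 0.0,
        rss_per_replicate=rss,
        n_replicates=n,
        provisional=n < 3,
    )


@dataclass(frozen=True)
class DomainMapEntry:
    surface: str
    raw_ru: float
    occupancy: float  # fraction of theoretical stoichiometric saturation


def domain_map(
    responses: Mapping[str, float],
    surfaces: Sequence[SurfaceDef],
    compound: Compound | float,
    n: float = 1.0,
) -> list[DomainMapEntry]:
    """Normalize one analyte's raw responses across several surfaces to
    occupancy = raw / Rmax_theoretical(surface, analyte, n), removing the
    effect of ligand size and immobilization density so binding-site
    localization can be read off directly."""
    by_name = {s.name: s for s in surfaces}
    out = []
    for name, raw in responses.items():
        if name not in by_name:
            raise KeyError(f"no surface definition named {name!r}")
        surf = by_name[name]
        rmax = theoretical_rmax(surf, compound, n=n)
        out.append(DomainMapEntry(surface=name, raw_ru=float(raw),
                                  occupancy=float(raw) / rmax))
    return out
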